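import numpy as np
import pandas as pd
import pytest

from methylfoot.io import MethylomeTable, SampleTrack
from methylfoot.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def dmr_study_sim():
    """One realisation of the planted-DMR design (4 vs 6 replicates,
    coverage 30, kappa 100, 30 DMRs at delta 0.4)."""
    return simulate(SimConfig.dmr_study(seed=11))


@pytest.fixture(scope="session")
def spike_study_sim():
    """Planted protected CpGs (0.9) inside regions demethylated to 0.1."""
    return simulate(SimConfig.spike_study(seed=7))


@pytest.fixture(scope="session")
def footprint_study_sim():
    """Spike design plus a planted motif whose core CpG is protected."""
    return simulate(SimConfig.footprint_study(seed=5))


def make_table(chrom_pos, ratio, coverage, groups):
    """Build a MethylomeTable from plain lists.

    chrom_pos: list of (chrom, pos); ratio/coverage: (site x sample)
    nested lists with None for missing; groups: dict name -> 'A'/'B'.
    """
    sites = pd.DataFrame(chrom_pos, columns=["chrom", "pos"])
    samples = list(groups)
    r = np.array([[np.nan if v is None else v for v in row] for row in ratio], dtype=float)
    c = np.array([[np.nan if v is None else v for v in row] for row in coverage], dtype=float)
    return MethylomeTable(sites.reset_index(drop=True), samples, dict(groups), r, c)


def make_track(records):
    """SampleTrack from (chrom, pos, ratio, coverage) tuples."""
    sites = pd.DataFrame([(c, p) for c, p, *_ in records], columns=["chrom", "pos"])
    return SampleTrack(
        sites,
        np.array([r for *_, r, _ in records], dtype=float),
        np.array([cv for *_, cv in records], dtype=float),
    )
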