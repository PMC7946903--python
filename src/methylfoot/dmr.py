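"""Replicate-aware DMR calling.

A CpG qualifies when its two-sided Mann-Whitney p-value across the two
replicate groups is at or below ``alpha`` AND the absolute difference of
the group mean ratios is at least ``min_diff``. Runs of at least
``min_consecutive`` qualifying CpGs — consecutive in the coverage-filtered
table, with a uniform difference sign and inter-CpG distance at most
``max_gap`` — become one DMR. The core span covers the qualifying CpGs
(last CpG's CG dinucleotide included); the reported interval is the core
extended by ``extension`` bp on each side, clipped to the chromosome.

With 4-vs-6 replicate groups the exact test's smallest attainable
two-sided p is 2/210 ~ 0.0095, so a per-CpG alpha of 0.05 leaves no room
for multiple-testing correction to change which CpGs can qualify; no
per-CpG correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import IntervalSet, MethylomeTable
from .stats import mannwhitney_exact, mannwhitney_exact_matrix

HYPO_IN_B = "hypo_in_B"
HYPER_IN_B = "hyper_in_B"


@dataclass
class DmrConfig:
    alpha: float = 0.05
    min_diff: float = 0.25
    min_consecutive: int = 2
    max_gap: int = 500
    extension: int = 100
    repeat_overlap_max: float = 0.5
    min_mappability: float = 0.8
    autosomes_only: bool = True

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 <= self.min_diff <= 1:
            raise ValueError("min_diff must be in [0, 1]")
        if self.min_consecutive < 2:
            raise ValueError("min_consecutive must be >= 2")
        if self.extension < 0:
            raise ValueError("extension must be >= 0")


@dataclass
class Dmr:
    chrom: str
    start: int  # post-extension, half-open
    end: int
    core_start: int
    core_end: int
    n_cpgs: int
    mean_a: float
    mean_b: float
    direction: str
    name: str = ""

    @property
    def interval(self):
        return (self.chrom, self.start, self.end)


def cpg_test(values_a, values_b) -> float:
    """Two-sided Mann-Whitney p for one CpG (NaN-aware).

    Returns NaN when either group has fewer than two non-missing values.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return float("nan")
    return mannwhitney_exact(a, b)


def _per_cpg_stats(table: MethylomeTable):
    """p-value, group means and difference for every site (vectorised;
    sites grouped by their missingness pattern so each group runs one
    enumeration)."""
    ra = table.group_ratio("A")
    rb = table.group_ratio("B")
    n = len(table)
    mean_a = np.nanmean(np.where(np.isnan(ra), np.nan, ra), axis=1) if ra.size else np.full(n, np.nan)
    mean_b = np.nanmean(np.where(np.isnan(rb), np.nan, rb), axis=1) if rb.size else np.full(n, np.nan)
    pvals = np.full(n, np.nan)
    miss_a, miss_b = np.isnan(ra), np.isnan(rb)
    testable = (np.sum(~miss_a, axis=1) >= 2) & (np.sum(~miss_b, axis=1) >= 2)
    pattern = np.concatenate([miss_a, miss_b], axis=1)
    # group testable sites by identical missingness pattern
    if testable.any():
        keys = np.packbits(pattern[testable], axis=1)
        df = pd.DataFrame({"row": np.where(testable)[0]})
        df["key"] = [k.tobytes() for k in keys]
        for _, sub in df.groupby("key", sort=False):
            rows = sub["row"].to_numpy()
            pa = ra[rows][:, ~miss_a[rows[0]]]
            pb = rb[rows][:, ~miss_b[rows[0]]]
            pvals[rows] = mannwhitney_exact_matrix(pa, pb)
    return pvals, mean_a, mean_b


def call_dmrs(
    table: MethylomeTable,
    config: DmrConfig = DmrConfig(),
    chrom_sizes: dict[str, int] | None = None,
) -> list[Dmr]:
    """Call DMRs from a coverage-filtered methylome table."""
    if len(table) == 0:
        return []
    pvals, mean_a, mean_b = _per_cpg_stats(table)
    diff = mean_a - mean_b
    qualifies = (pvals <= config.alpha) & (np.abs(diff) >= config.min_diff)
    qualifies &= ~np.isnan(pvals)

    dmrs: list[Dmr] = []
    chroms = table.sites["chrom"].to_numpy()
    poss = table.sites["pos"].to_numpy()

    run: list[int] = []

    def _flush():
        if len(run) >= config.min_consecutive:
            idx = np.array(run)
            chrom = chroms[idx[0]]
            core_start = int(poss[idx[0]])
            core_end = int(poss[idx[-1]]) + 2
            start = max(0, core_start - config.extension)
            end = core_end + config.extension
            if chrom_sizes and chrom in chrom_sizes:
                end = min(end, chrom_sizes[chrom])
            m_a = float(np.mean(mean_a[idx]))
            m_b = float(np.mean(mean_b[idx]))
            direction = HYPO_IN_B if m_a > m_b else HYPER_IN_B
            dmrs.append(Dmr(chrom, start, end, core_start, core_end,
                            len(run), m_a, m_b, direction,
                            name=f"dmr_{len(dmrs) + 1}"))
        run.clear()

    for i in range(len(table)):
        if not qualifies[i]:
            _flush()
            continue
        if run:
            j = run[-1]
            same_chrom = chroms[i] == chroms[j]
            # the next table row must be this CpG (consecutive rule)
            adjacent = i == j + 1
            close = same_chrom and (poss[i] - poss[j]) <= config.max_gap
            same_sign = np.sign(diff[i]) == np.sign(diff[j])
            if not (same_chrom and adjacent and close and same_sign):
                _flush()
        run.append(i)
    _flush()
    return dmrs


def dmrs_to_intervals(dmrs: list[Dmr]) -> IntervalSet:
    if not dmrs:
        return IntervalSet.empty()
    return IntervalSet(pd.DataFrame(
        {
            "chrom": [d.chrom for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
            "name": [d.name for d in dmrs],
            "score": [float(d.n_cpgs) for d in dmrs],
            "strand": ["." for _ in dmrs],
        }
    ))


def dmrs_to_table(dmrs: list[Dmr]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [d.name for d in dmrs],
            "chrom": [d.chrom for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
            "core_start": [d.core_start for d in dmrs],
            "core_end": [d.core_end for d in dmrs],
            "n_cpgs": [d.n_cpgs for d in dmrs],
            "mean_A": [d.mean_a for d in dmrs],
            "mean_B": [d.mean_b for d in dmrs],
            "direction": [d.direction for d in dmrs],
        }
    )


_NON_AUTOSOMES = {"chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT"}


def is_autosome(chrom: str) -> bool:
    return chrom not in _NON_AUTOSOMES


def mean_mappability(track: IntervalSet, chrom: str, start: int, end: int) -> float:
    """Mean mappability over [start, end); uncovered bp count as 0."""
    total = 0.0
    for row in track.overlapping(chrom, start, end).itertuples(index=False):
        ov = min(row.end, end) - max(row.start, start)
        total += ov * float(row.score)
    return total / (end - start)


def filter_dmrs(
    dmrs: list[Dmr],
    blacklist: IntervalSet | None = None,
    repeats: IntervalSet | None = None,
    mappability: IntervalSet | None = None,
    config: DmrConfig = DmrConfig(),
) -> list[Dmr]:
    """Blacklist / repeat-fraction / autosome / mappability filters,
    applied in that order."""
    out = []
    for d in dmrs:
        if blacklist is not None and len(blacklist.overlapping(d.chrom, d.start, d.end)):
            continue
        if repeats is not None:
            frac = repeats.overlap_bp(d.chrom, d.start, d.end) / (d.end - d.start)
            if frac > config.repeat_overlap_max:
                continue
        if config.autosomes_only and not is_autosome(d.chrom):
            continue
        if mappability is not None:
            if mean_mappability(mappability, d.chrom, d.start, d.end) < config.min_mappability:
                continue
        out.append(d)
    return out


def sample_control_regions(
    dmrs: list[Dmr],
    cpg_positions: dict[str, np.ndarray],
    chrom_sizes: dict[str, int],
    n_per_dmr: int = 1,
    seed: int = 0,
    cpg_tolerance: float = 0.2,
    blacklist: IntervalSet | None = None,
    repeats: IntervalSet | None = None,
    mappability: IntervalSet | None = None,
    config: DmrConfig = DmrConfig(),
    max_tries: int = 200,
) -> IntervalSet:
    """Length-matched random control regions, CpG-count matched within
    +/- ``cpg_tolerance``, avoiding the DMRs themselves and passing the
    same blacklist/repeat/mappability filters. Fewer regions may be
    returned when matching fails within the retry budget."""
    rng = np.random.default_rng(seed)
    dmr_set = dmrs_to_intervals(dmrs)
    chrom_list = sorted(chrom_sizes)
    records = []
    for d in dmrs:
        length = d.end - d.start
        src_cpgs = _count_cpgs(cpg_positions, d.chrom, d.start, d.end)
        found = 0
        for _ in range(max_tries):
            if found >= n_per_dmr:
                break
            chrom = chrom_list[rng.integers(len(chrom_list))]
            if chrom_sizes[chrom] <= length:
                continue
            start = int(rng.integers(0, chrom_sizes[chrom] - length))
            end = start + length
            if len(dmr_set) and len(dmr_set.overlapping(chrom, start, end)):
                continue
            n_cpg = _count_cpgs(cpg_positions, chrom, start, end)
            if abs(n_cpg - src_cpgs) > cpg_tolerance * max(src_cpgs, 1):
                continue
            cand = Dmr(chrom, start, end, start, end, n_cpg, np.nan, np.nan, HYPO_IN_B)
            if filter_dmrs([cand], blacklist, repeats, mappability, config):
                records.append((chrom, start, end, f"ctrl_{d.name}_{found}", float(n_cpg), "."))
                found += 1
    if not records:
        return IntervalSet.empty()
    return IntervalSet.from_records(records)


def _count_cpgs(cpg_positions: dict[str, np.ndarray], chrom: str, start: int, end: int) -> int:
    pos = cpg_positions.get(chrom)
    if pos is None:
        return 0
    return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
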