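"""5mC-spike detection.

A 5mC-spike is a narrow (at most ~6 bp) methylation peak that stays
methylated while its neighbourhood is demethylated — the footprint of a
factor protecting its core CpG from the demethylation machinery. On the
averaged, coverage-filtered track, a spike is a CpG whose ratio rises by
more than ``min_rise`` over its left neighbour (within
``max_neighbor_dist`` bp) and falls by more than ``min_fall`` to its
right neighbour. If another CpG starts within ``merge_window`` bp of the
peak CpG the two are combined (unweighted mean) into one unit before the
fall is evaluated against the next CpG beyond the unit.

The >50% rise/fall is an absolute ratio change (ratios are bounded in
[0, 1], so a relative reading would be ill-behaved near 0); the fall is
measured from the combined-unit mean when merging occurred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dmr import mean_mappability
from .io import IntervalSet, MethylomeTable


@dataclass
class SpikeConfig:
    min_rise: float = 0.5
    min_fall: float = 0.5
    max_neighbor_dist: int = 100
    merge_window: int = 6
    min_reads: int = 5
    min_mappability: float = 0.8

    def __post_init__(self):
        if not (0 < self.min_rise <= 1 and 0 < self.min_fall <= 1):
            raise ValueError("min_rise / min_fall must be in (0, 1]")
        if self.merge_window < 0:
            raise ValueError("merge_window must be >= 0")


@dataclass
class Spike:
    chrom: str
    start: int  # half-open; end - start <= merge_window + 2
    end: int
    peak_ratio: float
    left_ratio: float
    right_ratio: float
    left_dist: int
    right_dist: int
    name: str = ""


def average_track(table: MethylomeTable) -> pd.DataFrame:
    """Per-site mean ratio over non-missing samples
    (columns chrom, pos, ratio)."""
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(table.ratio, axis=1)
    out = table.sites.copy()
    out["ratio"] = mean
    return out[~np.isnan(mean)].reset_index(drop=True)


def call_spikes(avg_track: pd.DataFrame, config: SpikeConfig = SpikeConfig()) -> list[Spike]:
    """Scan an averaged per-CpG track (chrom, pos, ratio) for 5mC-spikes."""
    spikes: list[Spike] = []
    track = avg_track.sort_values(["chrom", "pos"], kind="stable")
    for chrom, sub in track.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy(int)
        ratio = sub["ratio"].to_numpy(float)
        n = len(pos)
        i = 1
        while i < n:
            left = i - 1
            d_left = pos[i] - pos[left]
            if d_left >= config.max_neighbor_dist:
                i += 1
                continue
            if ratio[i] - ratio[left] <= config.min_rise:
                i += 1
                continue
            # try to combine with one more CpG inside the merge window
            unit_last = i
            if i + 1 < n and pos[i + 1] - pos[i] <= config.merge_window:
                unit_last = i + 1
            peak = float(np.mean(ratio[i:unit_last + 1]))
            # the combined unit must itself clear the rise threshold
            if peak - ratio[left] <= config.min_rise:
                i = unit_last + 1
                continue
            right = unit_last + 1
            if right >= n:
                i = unit_last + 1
                continue
            d_right = pos[right] - pos[unit_last]
            if d_right >= config.max_neighbor_dist or peak - ratio[right] <= config.min_fall:
                i = unit_last + 1
                continue
            spikes.append(
                Spike(
                    chrom=chrom,
                    start=int(pos[i]),
                    end=int(pos[unit_last]) + 2,
                    peak_ratio=peak,
                    left_ratio=float(ratio[left]),
                    right_ratio=float(ratio[right]),
                    left_dist=int(d_left),
                    right_dist=int(d_right),
                    name=f"spike_{len(spikes) + 1}",
                )
            )
            i = unit_last + 1  # a CpG belongs to at most one spike
    return spikes


def filter_spikes(
    spikes: list[Spike],
    repeats: IntervalSet | None = None,
    mappability: IntervalSet | None = None,
    config: SpikeConfig = SpikeConfig(),
) -> list[Spike]:
    """Drop spikes overlapping repeats or with low mean mappability."""
    out = []
    for s in spikes:
        if repeats is not None and len(repeats.overlapping(s.chrom, s.start, s.end)):
            continue
        if mappability is not None:
            if mean_mappability(mappability, s.chrom, s.start, s.end) < config.min_mappability:
                continue
        out.append(s)
    return out


def spikes_to_intervals(spikes: list[Spike]) -> IntervalSet:
    if not spikes:
        return IntervalSet.empty()
    return IntervalSet(pd.DataFrame(
        {
            "chrom": [s.chrom for s in spikes],
            "start": [s.start for s in spikes],
            "end": [s.end for s in spikes],
            "name": [s.name for s in spikes],
            "score": [float(round(1000 * s.peak_ratio)) for s in spikes],
            "strand": ["." for _ in spikes],
        }
    ))


def spikes_to_table(spikes: list[Spike]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [s.name for s in spikes],
            "chrom": [s.chrom for s in spikes],
            "start": [s.start for s in spikes],
            "end": [s.end for s in spikes],
            "peak_ratio": [s.peak_ratio for s in spikes],
            "left_ratio": [s.left_ratio for s in spikes],
            "right_ratio": [s.right_ratio for s in spikes],
            "left_dist": [s.left_dist for s in spikes],
            "right_dist": [s.right_dist for s in spikes],
        }
    )


def compare_spike_sets(sets: dict[str, list[Spike]]) -> dict:
    """Partition spike sets from several cell types into common and
    cell-type-specific spikes (any-overlap semantics).

    Returns {'specific': {cell: [Spike]}, 'common': {cell: [Spike]},
    'pairwise': {(c1, c2): count of c1 spikes overlapping c2 spikes},
    'membership': {cell: [frozenset of cells each spike overlaps]}}.
    """
    if len(sets) < 2:
        raise ValueError("need at least two spike sets to compare")
    ivals = {cell: spikes_to_intervals(sp) for cell, sp in sets.items()}
    specific: dict[str, list[Spike]] = {c: [] for c in sets}
    common: dict[str, list[Spike]] = {c: [] for c in sets}
    membership: dict[str, list[frozenset]] = {c: [] for c in sets}
    pairwise: dict[tuple[str, str], int] = {}
    for cell, spike_list in sets.items():
        for s in spike_list:
            hits = {
                other
                for other in sets
                if other != cell and len(ivals[other].overlapping(s.chrom, s.start, s.end))
            }
            membership[cell].append(frozenset(hits | {cell}))
            (common if hits else specific)[cell].append(s)
    for c1 in sets:
        for c2 in sets:
            if c1 != c2:
                pairwise[(c1, c2)] = sum(
                    1 for m in membership[c1] if c2 in m
                )
    return {"specific": specific, "common": common, "pairwise": pairwise,
            "membership": membership}
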