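"""Genomic-distance profiles of methylation and coverage signals.

Profiles aggregate a signal by offset from region centers: every region
contributes one row of a (region x offset) matrix with explicit
missingness, and the profile is the per-offset mean over the available
entries, with n and a normal-approximation 95% CI. This is the native
equivalent of tools that encode missingness by shifting all values +1 and
treating 0 as absent — averaging available values gives identical means.

A CpG's ratio is assigned to both bp of its CG dinucleotide
``[pos, pos + 2)``. Methylation is a property of the strand-symmetric
dinucleotide, and this makes motif-centered profiles exactly symmetric
under strand flips: a motif-core CpG covers oriented offsets {0, 1} no
matter which strand the motif instance is on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntervalSet
from .motifs import MotifModel, scan


@dataclass
class Profile:
    offsets: np.ndarray  # bp relative to center (bin starts when binned)
    matrix: np.ndarray  # (n_regions, n_offsets), NaN = missing
    bin_bp: int = 1

    @property
    def n(self) -> np.ndarray:
        return np.sum(~np.isnan(self.matrix), axis=0)

    @property
    def mean(self) -> np.ndarray:
        n = self.n
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, np.nansum(self.matrix, axis=0), np.nan) / np.maximum(n, 1)

    @property
    def ci_half_width(self) -> np.ndarray:
        """1.96 * SD / sqrt(n); NaN where n < 2."""
        n = self.n
        mean = self.mean
        dev = self.matrix - mean
        with np.errstate(invalid="ignore"):
            ss = np.nansum(dev * dev, axis=0)
        out = np.full(len(n), np.nan)
        ok = n >= 2
        out[ok] = 1.96 * np.sqrt(ss[ok] / (n[ok] - 1)) / np.sqrt(n[ok])
        return out

    def to_frame(self) -> pd.DataFrame:
        mean, ci = self.mean, self.ci_half_width
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "mean": mean,
                "n": self.n,
                "ci_lo": mean - ci,
                "ci_hi": mean + ci,
            }
        )


def region_center(start: int, end: int) -> int:
    return (start + end) // 2


def _centers_from_regions(regions: IntervalSet) -> pd.DataFrame:
    df = regions.df
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "center": (df["start"] + df["end"]) // 2,
            "strand": df["strand"].where(df["strand"].isin(["+", "-"]), "+"),
        }
    )


def profile_from_centers(
    centers: pd.DataFrame,  # chrom, center, strand
    avg_track: pd.DataFrame,  # chrom, pos, ratio
    window_bp: int,
) -> Profile:
    """Per-bp methylation profile around given centers (strand-aware)."""
    offsets = np.arange(-window_bp, window_bp + 1)
    n_off = len(offsets)
    matrix = np.full((len(centers), n_off), np.nan)
    by_chrom = {
        chrom: (sub["pos"].to_numpy(int), sub["ratio"].to_numpy(float))
        for chrom, sub in avg_track.groupby("chrom", sort=False)
    }
    for ri, row in enumerate(centers.itertuples(index=False)):
        data = by_chrom.get(row.chrom)
        if data is None:
            continue
        pos, ratio = data
        lo = np.searchsorted(pos, row.center - window_bp - 1)
        hi = np.searchsorted(pos, row.center + window_bp + 1)
        flip = row.strand == "-"
        for p, r in zip(pos[lo:hi], ratio[lo:hi]):
            for g in (p, p + 1):  # the CG dinucleotide
                o = int(g - row.center)
                if flip:
                    o = -o
                if -window_bp <= o <= window_bp:
                    matrix[ri, o + window_bp] = r
    return Profile(offsets, matrix, bin_bp=1)


def methylation_profile(
    regions: IntervalSet, avg_track: pd.DataFrame, window_bp: int
) -> Profile:
    """Methylation-ratio profile centered on region midpoints."""
    return profile_from_centers(_centers_from_regions(regions), avg_track, window_bp)


# ---------------------------------------------------------------------------
# coverage profiles over bedGraph step functions


class StepTrack:
    """A bedGraph step function; uncovered positions have value 0."""

    def __init__(self, df: pd.DataFrame):  # chrom, start, end, value
        self._chroms = {}
        for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
            self._chroms[chrom] = (
                sub["start"].to_numpy(int),
                sub["end"].to_numpy(int),
                sub["value"].to_numpy(float),
            )

    @classmethod
    def read(cls, path) -> "StepTrack":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t") if "\t" in line else line.split()
                rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean value over [start, end); gaps count as 0."""
        if end <= start:
            return 0.0
        data = self._chroms.get(chrom)
        if data is None:
            return 0.0
        starts, ends, values = data
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        total = 0.0
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            ov = min(e, end) - max(s, start)
            if ov > 0:
                total += ov * v
        return total / (end - start)


def coverage_profile(
    regions: IntervalSet,
    coverage_track: StepTrack,
    window_bp: int,
    bin_bp: int = 25,
) -> Profile:
    """Binned coverage profile around region midpoints; each bin value is
    the mean of the track over the bin."""
    offsets = np.arange(-window_bp, window_bp, bin_bp)
    matrix = np.full((len(regions), len(offsets)), np.nan)
    centers = _centers_from_regions(regions)
    for ri, row in enumerate(centers.itertuples(index=False)):
        for oi, o in enumerate(offsets):
            if row.strand == "-":
                a = row.center - (o + bin_bp)
                b = row.center - o
            else:
                a = row.center + o
                b = row.center + o + bin_bp
            matrix[ri, oi] = coverage_track.mean(row.chrom, int(a), int(b))
    return Profile(offsets, matrix, bin_bp=bin_bp)


# ---------------------------------------------------------------------------
# motif-centered footprints


@dataclass
class MotifCenteredRegions:
    centers: pd.DataFrame  # chrom, center, strand, source_name
    motif: MotifModel
    n_dropped: int  # source regions without a hit at threshold


def recenter_on_motif(
    regions: IntervalSet, motif: MotifModel, genome: dict[str, str]
) -> MotifCenteredRegions:
    """Recenter regions on their best motif hit (both strands).

    Ties on score are broken by distance to the region center; regions
    without a hit at threshold (or shorter than the motif) are dropped
    and counted. The new center is the hit window's midpoint.
    """
    L = len(motif)
    rows = []
    dropped = 0
    for row in regions.df.itertuples(index=False):
        seq = genome[row.chrom][row.start:row.end]
        if len(seq) < L:
            dropped += 1
            continue
        hits, _ = scan(seq, motif)
        if not hits:
            dropped += 1
            continue
        mid0 = (row.end - row.start) // 2
        best = max(hits, key=lambda h: (h.score, -abs(h.offset + L // 2 - mid0)))
        rows.append(
            (row.chrom, row.start + best.offset + L // 2, best.strand, row.name)
        )
    centers = pd.DataFrame(rows, columns=["chrom", "center", "strand", "source_name"])
    return MotifCenteredRegions(centers, motif, dropped)


def motif_centered_profile(
    centered: MotifCenteredRegions, avg_track: pd.DataFrame, window_bp: int
) -> Profile:
    """Methylation profile around motif centers, oriented by hit strand."""
    return profile_from_centers(centered.centers, avg_track, window_bp)


def motif_core_profile(
    centered: MotifCenteredRegions, avg_track: pd.DataFrame, core_window_bp: int = 12
) -> Profile:
    """Profile restricted to +/- core_window/2 around the motif center
    (the motif-covered CpGs only)."""
    return profile_from_centers(centered.centers, avg_track, core_window_bp // 2)
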