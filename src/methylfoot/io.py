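"""Methylation-track and interval I/O, site union and coverage filters.

Internal conventions: all coordinates are 0-based half-open; a CpG site is
anchored at the C of the plus strand and occupies ``[pos, pos + 2)``.
Methylation ratios live in [0, 1]; missing observations are NaN and are
never coerced to 0 (a covered-but-unmethylated CpG and an unobserved CpG
are different things). Plus/minus strand CpG evidence is assumed to be
pre-merged by the producer of the tracks.

Two input dialects are accepted: ``bedgraph-pair`` (a 4-column ratio
bedGraph plus a 4-column integer coverage bedGraph) and ``bismark-cov``
(chrom, start, end, percent methylation, n_methylated, n_unmethylated).
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

MISSING = np.nan


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


class ParseError(ValueError):
    """Malformed input line; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------------------
# intervals


@dataclass
class IntervalSet:
    """Sorted set of half-open genomic intervals with optional BED6 fields."""

    df: pd.DataFrame  # columns: chrom, start, end, name, score, strand

    COLUMNS = ("chrom", "start", "end", "name", "score", "strand")

    def __post_init__(self):
        df = self.df
        for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(f"interval start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}")
        self.df = (
            df[list(self.COLUMNS)]
            .sort_values(["chrom", "start", "end"], kind="stable")
            .reset_index(drop=True)
        )
        self._trees: dict[str, IntervalTree] | None = None

    @classmethod
    def from_records(cls, records) -> "IntervalSet":
        rows = []
        for rec in records:
            rec = tuple(rec)
            row = {"chrom": rec[0], "start": int(rec[1]), "end": int(rec[2])}
            if len(rec) > 3:
                row["name"] = rec[3]
            if len(rec) > 4:
                row["score"] = float(rec[4])
            if len(rec) > 5:
                row["strand"] = rec[5]
            rows.append(row)
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
                   if rows else cls.empty().df)

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            cls.COLUMNS, ("str", "int64", "int64", "str", "float64", "str"))}))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.df.itertuples(index=False))

    def trees(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for chrom, sub in self.df.groupby("chrom", sort=False):
                trees[chrom] = IntervalTree.from_tuples(
                    (int(s), int(e), i) for i, s, e in zip(sub.index, sub["start"], sub["end"])
                )
            self._trees = trees
        return self._trees

    def overlapping(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """All intervals overlapping [start, end) on chrom."""
        tree = self.trees().get(chrom)
        if tree is None:
            return self.df.iloc[0:0]
        idx = sorted(iv.data for iv in tree.overlap(start, end))
        return self.df.loc[idx]

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Total bp of [start, end) covered by this set (union of overlaps)."""
        tree = self.trees().get(chrom)
        if tree is None:
            return 0
        pieces = sorted((max(iv.begin, start), min(iv.end, end)) for iv in tree.overlap(start, end))
        covered, cursor = 0, start
        for s, e in pieces:
            s = max(s, cursor)
            if e > s:
                covered += e - s
                cursor = e
        return covered


def read_intervals(path) -> IntervalSet:
    """Read a BED3/BED6 file (0-based half-open). Sorted on load."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "expected at least 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from exc
            if start >= end:
                raise ParseError(path, lineno, f"start >= end ({start} >= {end})")
            row = [parts[0], start, end,
                   parts[3] if len(parts) > 3 else ".",
                   float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0,
                   parts[5] if len(parts) > 5 else "."]
            rows.append(row)
    if not rows:
        return IntervalSet.empty()
    return IntervalSet(pd.DataFrame(rows, columns=list(IntervalSet.COLUMNS)))


def write_intervals(iset: IntervalSet, path, bed6: bool = True) -> None:
    df = iset.df
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            if bed6:
                score = int(row.score) if float(row.score).is_integer() else row.score
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t{score}\t{row.strand}\n")
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


# ---------------------------------------------------------------------------
# single-sample methylation tracks


@dataclass
class SampleTrack:
    """Per-CpG methylation of one sample: parallel position/ratio/coverage."""

    sites: pd.DataFrame  # columns chrom, pos; sorted, unique
    ratio: np.ndarray
    coverage: np.ndarray

    def __post_init__(self):
        if self.sites.duplicated(["chrom", "pos"]).any():
            dup = self.sites[self.sites.duplicated(["chrom", "pos"])].iloc[0]
            raise ValueError(f"duplicate site {dup['chrom']}:{dup['pos']} within one sample")
        order = self.sites.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        self.sites = self.sites.loc[order].reset_index(drop=True)
        self.ratio = np.asarray(self.ratio, dtype=float)[order]
        self.coverage = np.asarray(self.coverage, dtype=float)[order]

    def __len__(self):
        return len(self.sites)


def read_methylation_track(path, dialect: str = "bismark-cov", coverage_path=None) -> SampleTrack:
    """Read one sample's methylation track.

    dialect 'bismark-cov': columns chrom, start, end, ratio%, n_meth,
    n_unmeth -> ratio = %/100, coverage = n_meth + n_unmeth.
    dialect 'bedgraph-pair': ``path`` is the ratio bedGraph (value in
    [0,1]) and ``coverage_path`` the matching integer coverage bedGraph.
    """
    if dialect == "bismark-cov":
        chroms, poss, ratios, covs = [], [], [], []
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 6:
                    raise ParseError(path, lineno, "expected 6 bismark-cov columns")
                try:
                    pos = int(parts[1])
                    pct = float(parts[3])
                    n_m, n_u = int(parts[4]), int(parts[5])
                except ValueError as exc:
                    raise ParseError(path, lineno, str(exc)) from exc
                ratio = pct / 100.0
                if not 0.0 <= ratio <= 1.0:
                    raise ParseError(path, lineno, f"ratio {ratio} outside [0,1]")
                chroms.append(parts[0]); poss.append(pos)
                ratios.append(ratio); covs.append(n_m + n_u)
        sites = pd.DataFrame({"chrom": chroms, "pos": poss})
        return SampleTrack(sites, np.array(ratios, float), np.array(covs, float))
    if dialect == "bedgraph-pair":
        if coverage_path is None:
            raise ValueError("bedgraph-pair dialect requires coverage_path")
        ratio_df = _read_bedgraph(path)
        cov_df = _read_bedgraph(coverage_path)
        merged = ratio_df.merge(cov_df, on=["chrom", "pos"], how="outer",
                                suffixes=("_ratio", "_cov"))
        merged = merged.sort_values(["chrom", "pos"]).reset_index(drop=True)
        if (merged["value_ratio"].dropna() > 1.0).any() or (merged["value_ratio"].dropna() < 0).any():
            raise ValueError(f"{path}: ratio values outside [0,1]")
        return SampleTrack(
            merged[["chrom", "pos"]],
            merged["value_ratio"].to_numpy(float),
            merged["value_cov"].fillna(0).to_numpy(float),
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_bedgraph(path) -> pd.DataFrame:
    chroms, poss, vals = [], [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ParseError(path, lineno, "expected 4 bedGraph columns")
            try:
                chroms.append(parts[0]); poss.append(int(parts[1])); vals.append(float(parts[3]))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return pd.DataFrame({"chrom": chroms, "pos": poss, "value": vals})


def write_methylation_track(track: SampleTrack, ratio_path, coverage_path) -> None:
    """Write a sample as a bedgraph-pair (ratio to 6 decimals, int coverage)."""
    with open(ratio_path, "w") as rfh, open(coverage_path, "w") as cfh:
        for (chrom, pos), r, c in zip(
            track.sites.itertuples(index=False), track.ratio, track.coverage
        ):
            if np.isnan(r) or np.isnan(c) or c <= 0:
                continue
            rfh.write(f"{chrom}\t{pos}\t{pos + 1}\t{r:.6f}\n")
            cfh.write(f"{chrom}\t{pos}\t{pos + 1}\t{int(c)}\n")


def write_bismark_cov(track: SampleTrack, path) -> None:
    with open(path, "w") as fh:
        for (chrom, pos), r, c in zip(
            track.sites.itertuples(index=False), track.ratio, track.coverage
        ):
            if np.isnan(r) or np.isnan(c) or c <= 0:
                continue
            n_m = int(round(r * c))
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{100.0 * r:.6g}\t{n_m}\t{int(c) - n_m}\n")


# ---------------------------------------------------------------------------
# the union table


@dataclass
class MethylomeTable:
    """Per-CpG x per-sample methylation ratios and coverages.

    ``ratio`` and ``coverage`` are (n_sites x n_samples) float arrays with
    NaN for missing; a ratio is present iff its coverage is present and
    positive. ``groups`` maps each sample name to its condition label
    ('A' or 'B', e.g. MO / moDC).
    """

    sites: pd.DataFrame  # chrom, pos; sorted
    samples: list[str]
    groups: dict[str, str]
    ratio: np.ndarray
    coverage: np.ndarray

    def __post_init__(self):
        assert self.ratio.shape == (len(self.sites), len(self.samples))
        assert self.coverage.shape == self.ratio.shape

    def __len__(self):
        return len(self.sites)

    def group_columns(self, label: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if self.groups[s] == label])

    def group_ratio(self, label: str) -> np.ndarray:
        return self.ratio[:, self.group_columns(label)]

    def subset(self, mask: np.ndarray) -> "MethylomeTable":
        return MethylomeTable(
            self.sites[mask].reset_index(drop=True),
            list(self.samples),
            dict(self.groups),
            self.ratio[mask],
            self.coverage[mask],
        )


def union_sites(tracks: dict[str, SampleTrack], groups: dict[str, str]) -> MethylomeTable:
    """Combine single-sample tracks over the union of their CpG sites
    (unionbedg semantics); values absent in a sample are missing."""
    if not tracks:
        raise ValueError("need at least one sample")
    names = list(tracks)
    frames = []
    for name in names:
        t = tracks[name]
        df = t.sites.copy()
        df[f"r_{name}"] = t.ratio
        df[f"c_{name}"] = t.coverage
        frames.append(df.set_index(["chrom", "pos"]))
    merged = pd.concat(frames, axis=1, join="outer").sort_index()
    sites = merged.index.to_frame(index=False)
    ratio = merged[[f"r_{n}" for n in names]].to_numpy(float)
    coverage = merged[[f"c_{n}" for n in names]].to_numpy(float)
    # coverage 0 means unobserved: blank both matrices
    unobserved = ~(coverage > 0)
    ratio[unobserved] = MISSING
    coverage[unobserved] = MISSING
    return MethylomeTable(sites, names, dict(groups), ratio, coverage)


def filter_coverage(
    table: MethylomeTable,
    min_reads: int = 5,
    min_samples_a: int = 2,
    min_samples_b: int = 3,
) -> MethylomeTable:
    """Keep sites covered by >= min_reads in at least min_samples_a group-A
    and min_samples_b group-B samples (the replicate-support filter applied
    before DMR calling)."""
    cols_a, cols_b = table.group_columns("A"), table.group_columns("B")
    if len(cols_a) < min_samples_a or len(cols_b) < min_samples_b:
        raise ValueError("group sizes smaller than the required sample thresholds")
    cov = table.coverage
    ok_a = np.nansum(cov[:, cols_a] >= min_reads, axis=1) >= min_samples_a
    ok_b = np.nansum(cov[:, cols_b] >= min_reads, axis=1) >= min_samples_b
    return table.subset(ok_a & ok_b)


def filter_spike_coverage(table: MethylomeTable, min_reads: int = 5) -> MethylomeTable:
    """Keep sites with coverage strictly greater than min_reads in at least
    half of all samples (the filter applied before 5mC-spike screening)."""
    need = int(np.ceil(len(table.samples) / 2))
    cov = table.coverage
    ok = np.nansum(cov > min_reads, axis=1) >= need
    return table.subset(ok)


def shift_plus_one(values: np.ndarray) -> np.ndarray:
    """Encode a track for tools that use 0 as the missing sentinel: add 1
    to every available value, write 0 for missing. I/O convention only;
    internally missingness stays NaN."""
    out = np.where(np.isnan(values), 0.0, values + 1.0)
    return out


def unshift_minus_one(values: np.ndarray) -> np.ndarray:
    """Inverse of :func:`shift_plus_one` (0 decodes back to missing)."""
    return np.where(values == 0.0, np.nan, values - 1.0)
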