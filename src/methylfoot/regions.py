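"""Region-level analyses: overlap algebra, DMR group classification,
methylation quintiles, Venn-style membership counts and genomic-location
annotation.

DMR classification follows the three-way split used for demethylated
regions: a DMR overlapping any TF ChIP peak is "TF_peak"; of the rest,
those overlapping ATAC peaks are "open"; everything else is "no_peak".
TF binding takes precedence because TF-bound DMRs are removed first and
only the remainder is split by accessibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntervalSet

TF_PEAK = "TF_peak"
OPEN = "open"
NO_PEAK = "no_peak"


def overlap(a: IntervalSet, b: IntervalSet) -> pd.DataFrame:
    """All overlapping pairs between two interval sets.

    Returns a DataFrame with the positional indices of the two intervals
    (``a_index``, ``b_index``) and the overlap length in bp.
    """
    rows = []
    b_trees = b.trees()
    for ai, row in enumerate(a.df.itertuples(index=False)):
        tree = b_trees.get(row.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(row.start, row.end), key=lambda v: (v.begin, v.end)):
            rows.append(
                (ai, iv.data, min(row.end, iv.end) - max(row.start, iv.begin))
            )
    return pd.DataFrame(rows, columns=["a_index", "b_index", "overlap_bp"])


def overlaps_any(region, isets: list[IntervalSet]) -> bool:
    chrom, start, end = region
    return any(len(s.overlapping(chrom, start, end)) for s in isets)


def classify_dmrs(
    dmr_intervals: IntervalSet,
    tf_peak_sets: list[IntervalSet],
    atac_peaks: IntervalSet,
) -> list[str]:
    """Label each DMR TF_peak / open / no_peak (exhaustive partition)."""
    labels = []
    for row in dmr_intervals.df.itertuples(index=False):
        region = (row.chrom, row.start, row.end)
        if overlaps_any(region, tf_peak_sets):
            labels.append(TF_PEAK)
        elif len(atac_peaks.overlapping(*region)):
            labels.append(OPEN)
        else:
            labels.append(NO_PEAK)
    return labels


def quintile_bins(names: list[str], group_a_means: list[float],
                  n_bins: int = 5) -> dict[str, int]:
    """Assign regions to ``n_bins`` near-equal bins ranked by group-A mean
    methylation (bin 1 = highest). Stable descending sort, ties broken by
    input (genomic) order; the first n mod n_bins bins take the extra
    region."""
    n = len(names)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} regions for {n_bins} bins")
    order = sorted(range(n), key=lambda i: (-group_a_means[i], i))
    base, extra = divmod(n, n_bins)
    assignment: dict[str, int] = {}
    cursor = 0
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        for i in order[cursor:cursor + size]:
            assignment[names[i]] = b + 1
        cursor += size
    return assignment


def venn_counts(sets: dict[str, IntervalSet]) -> dict[str, dict[frozenset, int]]:
    """Membership-class counts for 2-3 interval sets.

    Any-overlap semantics; because overlaps need not be one-to-one the
    counts are reported from each set's own perspective:
    result[set_name][frozenset of set names] = number of ``set_name``
    regions overlapping exactly that combination of sets.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts supports 2 or 3 sets")
    out: dict[str, dict[frozenset, int]] = {}
    for name, iset in sets.items():
        counts: dict[frozenset, int] = {}
        for row in iset.df.itertuples(index=False):
            members = {name}
            for other, oset in sets.items():
                if other != name and len(oset.overlapping(row.chrom, row.start, row.end)):
                    members.add(other)
            key = frozenset(members)
            counts[key] = counts.get(key, 0) + 1
        out[name] = counts
    return out


# ---------------------------------------------------------------------------
# genomic-location annotation


@dataclass
class Transcript:
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]  # half-open, sorted
    name: str = "."

    @property
    def tss(self) -> int:
        return self.start if self.strand != "-" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand != "-" else self.start


def read_gene_model_bed12(path) -> list[Transcript]:
    """Parse a BED12 gene model into transcripts with exon blocks."""
    transcripts = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "."
            strand = f[5] if len(f) > 5 else "+"
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            else:
                exons = [(start, end)]
            transcripts.append(Transcript(chrom, start, end, strand, exons, name))
    return transcripts


PROMOTER = "promoter"
TTS = "TTS"
EXON = "exon"
INTRON = "intron"
INTERGENIC = "intergenic"

_PRIORITY = (PROMOTER, TTS, EXON, INTRON, INTERGENIC)


def annotate_location(
    regions: IntervalSet,
    transcripts: list[Transcript],
    promoter_window: int = 1000,
    tts_window: int = 1000,
) -> list[str]:
    """Categorise each region by its midpoint: promoter (TSS +/- window)
    > TTS (transcript end +/- window) > exon > intron > intergenic."""
    labels = []
    for row in regions.df.itertuples(index=False):
        mid = (row.start + row.end) // 2
        found = set()
        for t in transcripts:
            if t.chrom != row.chrom:
                continue
            if abs(mid - t.tss) <= promoter_window:
                found.add(PROMOTER)
            if abs(mid - t.tes) <= tts_window:
                found.add(TTS)
            if t.start <= mid < t.end:
                if any(s <= mid < e for s, e in t.exons):
                    found.add(EXON)
                else:
                    found.add(INTRON)
        label = next((c for c in _PRIORITY if c in found), INTERGENIC)
        labels.append(label)
    return labels
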