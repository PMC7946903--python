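"""PWM log-odds scanning and motif statistics.

Scoring is the standard log-odds model: for a window w,
``score(w) = sum_i log2(P_motif[i, w_i] / P_bg[w_i])`` in bits, evaluated
on both strands; windows containing N are skipped. The default hit
threshold is 60% of a motif's maximum achievable score (configurable per
motif, in bits). Probability columns are regularised with a 0.01
pseudocount before taking logs.

Enrichment is region presence/absence (a region "contains" a motif iff it
has at least one hit at or above threshold on either strand), tested with
the hypergeometric upper tail against a background region set and
BH-corrected across motifs. Co-association networks reduce per-region
motif hits to motif-class presence and report node sizes / edge weights
as percentages of all regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .io import IntervalSet
from .stats import benjamini_hochberg, hypergeometric_enrichment_p, mannwhitney_exact

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PSEUDOCOUNT = 0.01
DEFAULT_THRESHOLD_FRACTION = 0.6


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """Position probability matrix with background and hit threshold."""

    name: str
    ppm: np.ndarray  # (L, 4) rows sum to 1, order A C G T
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float | None = None  # bits; None -> 60% of max score
    motif_class: str = ""

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.ppm.ndim != 2 or self.ppm.shape[1] != 4:
            raise ValueError("ppm must be (L, 4)")
        if self.ppm.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.ppm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("ppm rows must each sum to 1")
        self.background = np.asarray(self.background, dtype=float)
        if not self.motif_class:
            self.motif_class = self.name
        # pseudocount-regularised log-odds matrix, bits
        reg = self.ppm + PSEUDOCOUNT
        reg = reg / reg.sum(axis=1, keepdims=True)
        self.log_odds = np.log2(reg / self.background)
        if self.threshold is None:
            self.threshold = DEFAULT_THRESHOLD_FRACTION * self.max_score

    def __len__(self) -> int:
        return self.ppm.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.ppm.argmax(axis=1))

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, **kwargs) -> "MotifModel":
        counts = np.asarray(counts, dtype=float)
        return cls(name, counts / counts.sum(axis=1, keepdims=True), **kwargs)

    @classmethod
    def from_consensus(cls, name: str, consensus: str, p_major: float = 0.97,
                       **kwargs) -> "MotifModel":
        """Near-deterministic PPM from a consensus string (handy for
        planting and for simple motif definitions)."""
        ppm = np.full((len(consensus), 4), (1 - p_major) / 3)
        for i, base in enumerate(consensus.upper()):
            ppm[i, _CODE[base]] = p_major
        return cls(name, ppm, **kwargs)


def read_jaspar(path, threshold: float | None = None,
                classes: dict[str, str] | None = None) -> list[MotifModel]:
    """Read JASPAR-format PFMs (count matrices) into MotifModels."""
    models = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([[m.counts[b][i] for b in ALPHABET] for i in range(m.length)])
            name = m.name or m.matrix_id
            cls_label = (classes or {}).get(name, "")
            models.append(MotifModel.from_counts(
                name, counts + 1e-12, threshold=threshold, motif_class=cls_label))
    return models


@dataclass
class MotifHit:
    offset: int  # window start, 0-based on the scanned sequence
    strand: str  # '+' or '-'
    score: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(arr.shape, -1, dtype=np.int8)
    for base, i in _CODE.items():
        code[arr == ord(base)] = i
    return code


def _window_scores(code: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score every window of length L; windows containing N get -inf."""
    L = log_odds.shape[0]
    n_win = len(code) - L + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for i in range(L):
        c = code[i:i + n_win]
        bad = c < 0
        valid &= ~bad
        scores += log_odds[i, np.where(bad, 0, c)]
    scores[~valid] = -np.inf
    return scores


def scan(sequence: str, motif: MotifModel,
         threshold: float | None = None) -> tuple[list[MotifHit], float]:
    """Scan both strands; returns (hits at/above threshold, best score).

    Hit offsets are window starts on the given (plus) strand regardless
    of hit strand. Best score is -inf when no window is scoreable.
    """
    thr = motif.threshold if threshold is None else threshold
    code = _encode(sequence)
    L = len(motif)
    fwd = _window_scores(code, motif.log_odds)
    rev = _window_scores(code, motif.log_odds[::-1, ::-1])  # revcomp motif
    hits: list[MotifHit] = []
    best = -np.inf
    for strand, scores in (("+", fwd), ("-", rev)):
        if scores.size:
            best = max(best, float(np.max(scores)))
        for off in np.nonzero((scores >= thr) & np.isfinite(scores))[0]:
            hits.append(MotifHit(int(off), strand, float(scores[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits, best


def region_sequences(regions: IntervalSet, genome: dict[str, str]) -> list[str]:
    return [genome[row.chrom][row.start:row.end] for row in regions.df.itertuples(index=False)]


@dataclass
class EnrichmentResult:
    motif: str
    fraction_target: float
    fraction_background: float
    fold_enrichment: float
    p_value: float
    q_value: float = float("nan")
    n_target: int = 0
    n_background: int = 0


def motif_enrichment(
    target: IntervalSet,
    background: IntervalSet,
    genome: dict[str, str],
    motif_list: list[MotifModel],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of motif-containing regions in
    the target set vs target+background universe, BH across motifs."""
    if len(target) == 0 or len(background) == 0:
        raise ValueError("target and background must be non-empty")
    t_seqs = region_sequences(target, genome)
    b_seqs = region_sequences(background, genome)
    results = []
    for m in motif_list:
        k_t = sum(1 for s in t_seqs if scan(s, m)[0])
        k_b = sum(1 for s in b_seqs if scan(s, m)[0])
        f_t = k_t / len(t_seqs)
        f_b = k_b / len(b_seqs)
        if k_t == 0:
            fold = 0.0
        elif f_b == 0:
            fold = float("inf")
        else:
            fold = f_t / f_b
        p = hypergeometric_enrichment_p(
            k_t, len(t_seqs), k_t + k_b, len(t_seqs) + len(b_seqs))
        results.append(EnrichmentResult(m.name, f_t, f_b, fold, p,
                                        n_target=k_t, n_background=k_b))
    qs = benjamini_hochberg([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif": [r.motif for r in results],
            "fraction_target": [r.fraction_target for r in results],
            "fraction_background": [r.fraction_background for r in results],
            "fold_enrichment": [r.fold_enrichment for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    )


def score_distribution_test(scores_group1, scores_group2) -> float:
    """Two-sided Mann-Whitney comparison of best-score-per-region lists
    (exact enumeration when feasible)."""
    return mannwhitney_exact(scores_group1, scores_group2)


@dataclass
class MotifNetwork:
    nodes: dict[str, float]  # class -> % of regions containing it
    edges: dict[frozenset, float]  # {class pair} -> % of regions with both
    pct_co_associated: float  # % of regions containing >= 2 classes
    pct_any_motif: float  # % of regions containing >= 1 class
    n_regions: int


def co_association_network(
    regions: IntervalSet,
    genome: dict[str, str],
    motif_classes: dict[str, list[MotifModel]],
    min_dist: int = 4,
) -> MotifNetwork:
    """Motif-class co-association across regions.

    Per region, hits of all class members are collected; hits of
    different classes whose starts lie within ``min_dist`` bp count once
    (the higher-scoring hit wins), approximating a minimum inter-motif
    spacing. A class is present when it retains at least one hit.
    """
    seqs = region_sequences(regions, genome)
    n = len(seqs)
    class_names = list(motif_classes)
    presence = np.zeros((n, len(class_names)), dtype=bool)
    for ri, seq in enumerate(seqs):
        all_hits: list[tuple[float, int, int]] = []  # (score, start, class idx)
        for ci, cls in enumerate(class_names):
            for m in motif_classes[cls]:
                hits, _ = scan(seq, m)
                all_hits.extend((h.score, h.offset, ci) for h in hits)
        all_hits.sort(key=lambda t: (-t[0], t[1], t[2]))
        kept: list[tuple[float, int, int]] = []
        for score, start, ci in all_hits:
            clash = any(
                abs(start - ks) < min_dist and kc != ci for _, ks, kc in kept
            )
            if not clash:
                kept.append((score, start, ci))
        for _, _, ci in kept:
            presence[ri, ci] = True
    if n == 0:
        return MotifNetwork({}, {}, 0.0, 0.0, 0)
    nodes = {cls: 100.0 * presence[:, ci].mean() for ci, cls in enumerate(class_names)}
    edges = {}
    for i in range(len(class_names)):
        for j in range(i + 1, len(class_names)):
            both = float(np.mean(presence[:, i] & presence[:, j]))
            edges[frozenset((class_names[i], class_names[j]))] = 100.0 * both
    n_classes = presence.sum(axis=1)
    return MotifNetwork(
        nodes=nodes,
        edges=edges,
        pct_co_associated=100.0 * float(np.mean(n_classes >= 2)),
        pct_any_motif=100.0 * float(np.mean(n_classes >= 1)),
        n_regions=n,
    )


def network_tables(net: MotifNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    node_df = pd.DataFrame(
        {"class": list(net.nodes), "pct_regions": list(net.nodes.values())}
    )
    edge_rows = [(tuple(sorted(k))[0], tuple(sorted(k))[1], v) for k, v in net.edges.items()]
    edge_df = pd.DataFrame(edge_rows, columns=["class_a", "class_b", "pct_regions"])
    return node_df, edge_df
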