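"""Shared statistical machinery.

The per-CpG test of the DMR caller and the motif-score comparisons are
two-sided Mann-Whitney tests on very small replicate groups (typically
4 vs 6 donors). At those sizes the exact null distribution is cheap to
enumerate, so we enumerate it: all C(nA+nB, nA) assignments of the pooled
mid-ranks to group A. The two-sided p-value is the fraction of assignments
whose rank sum deviates from its expectation at least as much as the
observed one. For larger groups we fall back to the tie- and
continuity-corrected normal approximation.

Enrichment helpers (hypergeometric upper tail, Benjamini-Hochberg) live
here too so that every module shares one implementation.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

MAX_EXACT_ENUMERATION = 50_000

_comb_cache: dict[tuple[int, int], np.ndarray] = {}


def _combination_matrix(n_a: int, n_total: int) -> np.ndarray:
    """Boolean matrix (C(n_total, n_a) x n_total); each row marks one
    choice of which pooled observations belong to group A."""
    key = (n_a, n_total)
    if key not in _comb_cache:
        rows = list(combinations(range(n_total), n_a))
        m = np.zeros((len(rows), n_total), dtype=bool)
        for i, idx in enumerate(rows):
            m[i, list(idx)] = True
        _comb_cache[key] = m
    return _comb_cache[key]


def mannwhitney_exact(values_a, values_b) -> float:
    """Exact two-sided Mann-Whitney p-value by full enumeration.

    Mid-ranks handle ties; the statistic is the group-A rank sum. Exact
    enumeration is used when C(nA+nB, nA) <= 50,000, otherwise the
    normal approximation with tie and continuity correction.

    Returns a p-value in (0, 1]. All-identical input gives p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    if comb(n, n_a) > MAX_EXACT_ENUMERATION:
        return _mannwhitney_normal(a, b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    observed = ranks[:n_a].sum()
    expected = n_a * (n + 1) / 2.0
    assign = _combination_matrix(n_a, n)
    sums = assign @ ranks
    dev = np.abs(sums - expected)
    obs_dev = abs(observed - expected)
    # tolerance guards float noise in midrank sums
    p = float(np.mean(dev >= obs_dev - 1e-9))
    return min(p, 1.0)


def _mannwhitney_normal(a: np.ndarray, b: np.ndarray) -> float:
    if np.all(a == a[0]) and np.all(b == a[0]):
        return 1.0
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(min(res.pvalue, 1.0))


def mannwhitney_exact_matrix(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Vectorised exact Mann-Whitney over many sites at once.

    ``values_a`` (sites x nA) and ``values_b`` (sites x nB) must be free of
    NaN (group sites by missingness pattern before calling). Returns one
    two-sided p-value per site, identical to :func:`mannwhitney_exact`
    applied row-wise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    n = n_a + n_b
    pooled = np.concatenate([a, b], axis=1)
    ranks = sps.rankdata(pooled, axis=1)
    if comb(n, n_a) > MAX_EXACT_ENUMERATION:
        return np.array(
            [_mannwhitney_normal(pooled[i, :n_a], pooled[i, n_a:]) for i in range(len(pooled))]
        )
    expected = n_a * (n + 1) / 2.0
    assign = _combination_matrix(n_a, n)  # (n_comb, n)
    sums = ranks @ assign.T  # (sites, n_comb)
    obs_dev = np.abs(ranks[:, :n_a].sum(axis=1) - expected)
    dev = np.abs(sums - expected)
    p = np.mean(dev >= obs_dev[:, None] - 1e-9, axis=1)
    return np.minimum(p, 1.0)


def hypergeometric_enrichment_p(k: int, n_target: int, k_total: int, n_total: int) -> float:
    """Over-representation p-value P(X >= k) for drawing ``n_target``
    regions out of ``n_total`` of which ``k_total`` contain the motif."""
    if k <= 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, n_total, k_total, n_target))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up q-values; monotone and >= p elementwise."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
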