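"""Log-odds scanning, enrichment, score comparisons and networks."""

from math import comb

import numpy as np
import pytest

from methylfoot.io import IntervalSet
from methylfoot.motifs import (
    MotifModel,
    PSEUDOCOUNT,
    co_association_network,
    motif_enrichment,
    read_jaspar,
    reverse_complement,
    scan,
    score_distribution_test,
)

ALPHABET = "ACGT"


def oracle_score(window, motif):
    """Independent per-position summation from the scoring definition."""
    total = 0.0
    for i, base in enumerate(window):
        reg = motif.ppm[i] + PSEUDOCOUNT
        reg = reg / reg.sum()
        total += np.log2(reg[ALPHABET.index(base)] / motif.background[ALPHABET.index(base)])
    return total


def test_background_motif_scores_zero_everywhere():
    m = MotifModel("flat", np.full((5, 4), 0.25))
    code_scores = [oracle_score("ACGTA", m)]
    hits, best = scan("ACGTACGTAC", m, threshold=-1.0)
    assert best == pytest.approx(0.0, abs=1e-12)
    assert all(h.score == pytest.approx(0.0, abs=1e-12) for h in hits)
    assert code_scores[0] == pytest.approx(0.0, abs=1e-12)


def test_scores_match_independent_summation_oracle():
    rng = np.random.default_rng(0)
    ppm = rng.dirichlet(np.ones(4), size=8)
    m = MotifModel("rand", ppm)
    seq = "".join(rng.choice(list(ALPHABET), 500))
    hits, best = scan(seq, m, threshold=-np.inf)
    fwd = {h.offset: h.score for h in hits if h.strand == "+"}
    rev = {h.offset: h.score for h in hits if h.strand == "-"}
    for off in range(len(seq) - 8 + 1):
        w = seq[off:off + 8]
        assert fwd[off] == pytest.approx(oracle_score(w, m), abs=1e-9)
        assert rev[off] == pytest.approx(oracle_score(reverse_complement(w), m), abs=1e-9)
    assert best == pytest.approx(max(max(fwd.values()), max(rev.values())), abs=1e-12)


def test_windows_containing_n_are_skipped():
    m = MotifModel.from_consensus("x", "ACGT" + "A")
    hits, best = scan("NNNNN", m, threshold=-np.inf)
    assert hits == [] and best == -np.inf


def test_sequence_shorter_than_motif_gives_no_hits():
    m = MotifModel.from_consensus("x", "ACGTA")
    hits, best = scan("ACG", m)
    assert hits == [] and best == -np.inf


def test_reverse_complement_scan_symmetry():
    rng = np.random.default_rng(1)
    m = MotifModel("rand", rng.dirichlet(np.ones(4), size=6))
    seq = "".join(rng.choice(list(ALPHABET), 300))
    fwd_hits, _ = scan(seq, m, threshold=2.0)
    rc_hits, _ = scan(reverse_complement(seq), m, threshold=2.0)
    L, n = 6, len(seq)
    mapped = sorted((n - h.offset - L, {"+": "-", "-": "+"}[h.strand],
                     round(h.score, 9)) for h in rc_hits)
    original = sorted((h.offset, h.strand, round(h.score, 9)) for h in fwd_hits)
    assert mapped == original


def test_jaspar_round_trip(tmp_path):
    p = tmp_path / "m.jaspar"
    p.write_text(
        ">MA0001.1 TEST\n"
        "A [ 10  0  0 10 ]\n"
        "C [  0 10  0  0 ]\n"
        "G [  0  0 10  0 ]\n"
        "T [  0  0  0  0 ]\n"
    )
    (m,) = read_jaspar(p)
    assert m.consensus == "ACGA"
    assert len(m) == 4


class TestEnrichment:
    MOTIF = MotifModel.from_consensus("EGR_like", "GTGGCGTGG")

    def build(self, n_with_target, n_target, n_with_bg, n_bg, seed=0):
        rng = np.random.default_rng(seed)
        genome = {}
        target, bg = [], []
        cursor = 0
        consensus = self.MOTIF.consensus
        seqs = []
        for k, (n_with, n_tot, out) in enumerate(
            ((n_with_target, n_target, target), (n_with_bg, n_bg, bg))):
            for i in range(n_tot):
                s = "".join(rng.choice(list("AT"), 60))
                if i < n_with:
                    s = s[:25] + consensus + s[34:]
                seqs.append(s)
                out.append((f"chr{k}_{i}", 0, 60))
                genome[f"chr{k}_{i}"] = s
        return genome, IntervalSet.from_records(target), IntervalSet.from_records(bg)

    def test_equal_fractions_give_fold_one(self):
        genome, t, b = self.build(5, 10, 50, 100)
        (r,) = motif_enrichment(t, b, genome, [self.MOTIF])
        assert r.fold_enrichment == pytest.approx(1.0)

    def test_fold_and_exact_tail_for_designed_counts(self):
        genome, t, b = self.build(10, 20, 100, 1000)
        (r,) = motif_enrichment(t, b, genome, [self.MOTIF])
        assert r.fraction_target == pytest.approx(0.5)
        assert r.fraction_background == pytest.approx(0.1)
        assert r.fold_enrichment == pytest.approx(5.0)
        # exact upper tail P(X >= 10 | N=1020, K=110, n=20)
        N, K, n = 1020, 110, 20
        tail = sum(comb(K, x) * comb(N - K, n - x) / comb(N, n)
                   for x in range(10, min(n, K) + 1))
        assert r.p_value == pytest.approx(tail, abs=1e-10)

    def test_zero_target_hits(self):
        genome, t, b = self.build(0, 10, 20, 100)
        (r,) = motif_enrichment(t, b, genome, [self.MOTIF])
        assert r.fold_enrichment == 0.0 and r.p_value == 1.0

    def test_q_values_dominate_p_values(self):
        genome, t, b = self.build(8, 20, 40, 100)
        motifs = [self.MOTIF, MotifModel.from_consensus("AP1_like", "TGACTCA"),
                  MotifModel.from_consensus("other", "AAAACCCC")]
        res = motif_enrichment(t, b, genome, motifs)
        assert all(r.q_value >= r.p_value - 1e-15 for r in res)


def test_score_test_identical_groups_give_p_one():
    s = [1.0, 2.0, 3.0, 4.0]
    assert score_distribution_test(s, list(s)) == 1.0


def test_score_test_separated_small_groups():
    assert score_distribution_test([9.0, 9.5, 8.5, 9.2], [1, 2, 3, 2.5, 1.5, 2.2]) == (
        pytest.approx(2 / comb(10, 4)))


class TestNetwork:
    EGR = MotifModel.from_consensus("EGR_like", "GTGGCGTGG", motif_class="EGR")
    AP1 = MotifModel.from_consensus("AP1_like", "TGACTCA", motif_class="AP1")

    def genome_for(self, memberships, seed=0):
        """memberships: list of sets like {'EGR','AP1'} per region."""
        rng = np.random.default_rng(seed)
        genome, recs = {}, []
        for i, classes in enumerate(memberships):
            s = list("".join(rng.choice(list("AT"), 80)))
            if "EGR" in classes:
                s[10:19] = self.EGR.consensus
            if "AP1" in classes:
                s[40:47] = self.AP1.consensus
            genome[f"r{i}"] = "".join(s)
            recs.append((f"r{i}", 0, 80))
        return genome, IntervalSet.from_records(recs)

    def test_all_regions_with_both_classes(self):
        genome, regions = self.genome_for([{"EGR", "AP1"}] * 5)
        net = co_association_network(regions, genome,
                                     {"EGR": [self.EGR], "AP1": [self.AP1]})
        assert net.nodes == {"EGR": 100.0, "AP1": 100.0}
        assert net.edges[frozenset(("EGR", "AP1"))] == 100.0
        assert net.pct_co_associated == 100.0 and net.pct_any_motif == 100.0

    def test_no_motifs_anywhere(self):
        genome, regions = self.genome_for([set()] * 4)
        net = co_association_network(regions, genome,
                                     {"EGR": [self.EGR], "AP1": [self.AP1]})
        assert net.pct_any_motif == 0.0
        assert all(v == 0.0 for v in net.nodes.values())

    def test_hand_counted_fixture(self):
        memberships = ([{"EGR", "AP1"}] * 4 + [{"EGR"}] * 6 + [{"AP1"}] * 2
                       + [set()] * 8)
        genome, regions = self.genome_for(memberships)
        net = co_association_network(regions, genome,
                                     {"EGR": [self.EGR], "AP1": [self.AP1]})
        assert net.nodes["EGR"] == pytest.approx(100 * 10 / 20)
        assert net.nodes["AP1"] == pytest.approx(100 * 6 / 20)
        assert net.edges[frozenset(("EGR", "AP1"))] == pytest.approx(100 * 4 / 20)
        assert net.pct_co_associated == pytest.approx(100 * 4 / 20)
        assert net.pct_any_motif == pytest.approx(100 * 12 / 20)

    def test_removing_a_class_preserves_other_node_sizes(self):
        memberships = [{"EGR", "AP1"}] * 3 + [{"EGR"}] * 5 + [set()] * 4
        genome, regions = self.genome_for(memberships)
        full = co_association_network(regions, genome,
                                      {"EGR": [self.EGR], "AP1": [self.AP1]})
        solo = co_association_network(regions, genome, {"EGR": [self.EGR]})
        assert solo.nodes["EGR"] == full.nodes["EGR"]
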