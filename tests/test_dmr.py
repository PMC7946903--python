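"""DMR calling: the per-CpG test, run assembly, filters and controls."""

import numpy as np
import pytest

from conftest import make_table
from methylfoot.dmr import (
    Dmr,
    DmrConfig,
    call_dmrs,
    cpg_test,
    filter_dmrs,
    sample_control_regions,
)
from methylfoot.io import IntervalSet

GROUPS = {**{f"a{i}": "A" for i in range(4)}, **{f"b{i}": "B" for i in range(6)}}

HIGH = [0.90, 0.85, 0.95, 0.88]
LOW = [0.10, 0.20, 0.15, 0.12, 0.18, 0.11]


def separated_table(positions, chrom="chrS1"):
    """Fully separated groups (p = 2/210, diff ~0.8) at every position."""
    n = len(positions)
    return make_table(
        [(chrom, p) for p in positions],
        [HIGH + LOW for _ in range(n)],
        [[30] * 10 for _ in range(n)],
        GROUPS,
    )


def test_cpg_test_returns_missing_with_fewer_than_two_per_group():
    assert np.isnan(cpg_test([0.5, np.nan, np.nan, np.nan], LOW))


def test_three_separated_cpgs_become_one_extended_dmr():
    table = separated_table([100, 150, 200])
    dmrs = call_dmrs(table, DmrConfig())
    assert len(dmrs) == 1
    d = dmrs[0]
    assert (d.core_start, d.core_end) == (100, 202)
    assert (d.start, d.end) == (0, 302)
    assert d.n_cpgs == 3
    assert d.direction == "hypo_in_B"
    assert d.mean_a == pytest.approx(np.mean(HIGH))
    assert d.mean_b == pytest.approx(np.mean(LOW))


def test_single_qualifying_cpg_is_not_a_dmr():
    dmrs = call_dmrs(separated_table([100]), DmrConfig())
    assert dmrs == []


def test_small_difference_fails_min_diff():
    a = [0.60, 0.58, 0.62, 0.59]
    b = [0.40, 0.42, 0.38, 0.41, 0.39, 0.40]  # separated but diff = 0.2
    table = make_table(
        [("chrS1", 100), ("chrS1", 150)],
        [a + b, a + b],
        [[30] * 10] * 2,
        GROUPS,
    )
    assert call_dmrs(table, DmrConfig()) == []


def test_gap_above_max_gap_splits_runs():
    table = separated_table([100, 150, 5000, 5050])
    dmrs = call_dmrs(table, DmrConfig(max_gap=500))
    assert len(dmrs) == 2
    assert [d.core_start for d in dmrs] == [100, 5000]


def test_sign_flip_terminates_a_run():
    rows = [HIGH + LOW, LOW[:4] + HIGH + LOW[4:6][:2]]  # second row reversed sense
    rows[1] = [0.1, 0.2, 0.15, 0.12] + [0.9, 0.85, 0.95, 0.88, 0.92, 0.87]
    table = make_table(
        [("chrS1", 100), ("chrS1", 150)],
        rows,
        [[30] * 10] * 2,
        GROUPS,
    )
    # two qualifying CpGs of opposite sign: no uniform-sign pair
    assert call_dmrs(table, DmrConfig()) == []


def test_intervening_nonqualifying_cpg_breaks_consecutiveness():
    table = make_table(
        [("chrS1", 100), ("chrS1", 150), ("chrS1", 200)],
        [HIGH + LOW, [0.5] * 10, HIGH + LOW],
        [[30] * 10] * 3,
        GROUPS,
    )
    assert call_dmrs(table, DmrConfig()) == []


def test_group_label_swap_mirrors_direction_and_keeps_coordinates():
    table = separated_table([100, 150, 200])
    swapped = make_table(
        [("chrS1", p) for p in (100, 150, 200)],
        [LOW + HIGH for _ in range(3)],
        [[30] * 10 for _ in range(3)],
        {**{f"a{i}": "A" for i in range(6)}, **{f"b{i}": "B" for i in range(4)}},
    )
    d1 = call_dmrs(table, DmrConfig())[0]
    d2 = call_dmrs(swapped, DmrConfig())[0]
    assert (d1.start, d1.end, d1.core_start, d1.core_end) == (
        d2.start, d2.end, d2.core_start, d2.core_end)
    assert {d1.direction, d2.direction} == {"hypo_in_B", "hyper_in_B"}


def test_empty_table_gives_no_dmrs():
    table = separated_table([100, 150]).subset(np.zeros(2, dtype=bool))
    assert call_dmrs(table, DmrConfig()) == []


class TestFilters:
    def dmr(self, start=1000, end=1400):
        return Dmr("chrS1", start, end, start + 100, end - 100, 3, 0.9, 0.1, "hypo_in_B", "d")

    def test_dmr_inside_repeat_removed(self):
        repeats = IntervalSet.from_records([("chrS1", 0, 10_000)])
        assert filter_dmrs([self.dmr()], repeats=repeats) == []

    def test_partial_repeat_and_good_mappability_retained(self):
        d = self.dmr(1000, 1400)
        repeats = IntervalSet.from_records([("chrS1", 1000, 1160)])  # 40%
        mapp = IntervalSet.from_records([("chrS1", 0, 10_000, "m", 0.9, ".")])
        assert filter_dmrs([d], repeats=repeats, mappability=mapp) == [d]

    def test_blacklisted_and_non_autosomal_removed(self):
        black = IntervalSet.from_records([("chrS1", 1100, 1101)])
        assert filter_dmrs([self.dmr()], blacklist=black) == []
        chx = Dmr("chrX", 0, 100, 10, 90, 2, 0.9, 0.1, "hypo_in_B")
        assert filter_dmrs([chx]) == []

    def test_missing_mappability_counts_as_zero(self):
        mapp = IntervalSet.from_records([("chrS2", 0, 100, "m", 1.0, ".")])
        assert filter_dmrs([self.dmr()], mappability=mapp) == []

    def test_random_fixtures_match_naive_recheck(self):
        rng = np.random.default_rng(9)
        cfg = DmrConfig()
        repeats = IntervalSet.from_records(
            [("chrS1", int(s), int(s) + 200) for s in rng.integers(0, 50_000, 40) * 1]
        )
        mapp = IntervalSet.from_records(
            [("chrS1", i * 500, (i + 1) * 500, "m", float(v), ".")
             for i, v in enumerate(rng.random(100))]
        )
        dmrs = [self.dmr(int(s), int(s) + int(w))
                for s, w in zip(rng.integers(0, 49_000, 100), rng.integers(100, 900, 100))]
        got = filter_dmrs(dmrs, repeats=repeats, mappability=mapp, config=cfg)
        expect = []
        for d in dmrs:
            rep_bp = repeats.overlap_bp(d.chrom, d.start, d.end)
            if rep_bp / (d.end - d.start) > cfg.repeat_overlap_max:
                continue
            mp = sum(
                (min(r.end, d.end) - max(r.start, d.start)) * r.score
                for r in mapp.df.itertuples(index=False)
                if r.start < d.end and r.end > d.start
            ) / (d.end - d.start)
            if mp < cfg.min_mappability:
                continue
            expect.append(d)
        assert got == expect


class TestControlRegions:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.cpgs = {"chrS1": np.sort(rng.choice(np.arange(0, 200_000, 2), 2000, replace=False))}
        self.sizes = {"chrS1": 200_000}
        self.dmrs = [
            Dmr("chrS1", s, s + 400, s + 100, s + 300, 4, 0.9, 0.1, "hypo_in_B", f"d{i}")
            for i, s in enumerate(range(10_000, 30_000, 4000))
        ]

    def test_zero_per_dmr_gives_empty_set(self):
        out = sample_control_regions(self.dmrs, self.cpgs, self.sizes, n_per_dmr=0, seed=1)
        assert len(out) == 0

    def test_controls_are_length_matched_and_cpg_matched(self):
        out = sample_control_regions(self.dmrs, self.cpgs, self.sizes, n_per_dmr=1, seed=1)
        assert len(out) >= 1
        for row in out.df.itertuples(index=False):
            assert row.end - row.start == 400
            pos = self.cpgs["chrS1"]
            n = int(np.sum((pos >= row.start) & (pos < row.end)))
            src = [d for d in self.dmrs if row.name.startswith(f"ctrl_{d.name}_")]
            src_n = int(np.sum((pos >= src[0].start) & (pos < src[0].end)))
            assert abs(n - src_n) <= 0.2 * max(src_n, 1)
            # non-overlapping with any DMR
            assert all(row.start >= d.end or row.end <= d.start for d in self.dmrs)

    def test_same_seed_reproduces_controls(self):
        a = sample_control_regions(self.dmrs, self.cpgs, self.sizes, seed=5)
        b = sample_control_regions(self.dmrs, self.cpgs, self.sizes, seed=5)
        assert a.df.equals(b.df)
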