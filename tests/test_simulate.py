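"""The synthetic-data generator: determinism, genome structure, the
noise model's calibration, planting and peak memberships."""

import numpy as np
import pytest

from methylfoot.io import IntervalSet
from methylfoot.motifs import MotifModel
from methylfoot.regions import classify_dmrs
from methylfoot.simulate import (
    DmrSpec,
    MotifSpec,
    SimConfig,
    SpikeSpec,
    TruthTable,
    egr_like_motif,
    plant_motifs,
    simulate,
    simulate_genome,
    simulate_methylomes,
    simulate_peaks,
    true_ratio_tracks,
)


def small_config(**kwargs):
    defaults = dict(seed=1, n_chroms=1, chrom_length=100_000)
    defaults.update(kwargs)
    return SimConfig(**defaults)


def test_same_seed_reproduces_genome_and_tracks_exactly():
    a = simulate(SimConfig.demo(seed=9))
    b = simulate(SimConfig.demo(seed=9))
    assert a.genome == b.genome
    for c in a.cpg_positions:
        np.testing.assert_array_equal(a.cpg_positions[c], b.cpg_positions[c])
    for s in a.tracks:
        np.testing.assert_array_equal(a.tracks[s].ratio, b.tracks[s].ratio)
        np.testing.assert_array_equal(a.tracks[s].coverage, b.tracks[s].coverage)


def test_zero_rates_give_empty_cpg_list():
    cfg = small_config(background_cpg_rate=0.0, cpg_island_rate=0.0)
    _, cpgs = simulate_genome(cfg)
    assert all(len(v) == 0 for v in cpgs.values())


def test_every_listed_site_is_a_cg_dinucleotide_and_no_others():
    cfg = small_config()
    genome, cpgs = simulate_genome(cfg)
    for chrom, pos in cpgs.items():
        seq = genome[chrom]
        for p in pos:
            assert seq[p:p + 2] == "CG"
        # independent counting oracle: listed sites are ALL the CGs
        found = []
        i = seq.find("CG")
        while i != -1:
            found.append(i)
            i = seq.find("CG", i + 1)
        assert found == list(pos)


def test_island_cpg_count_near_expectation():
    """10 islands on 1 Mb at ~10 bp spacing: the CG count from direct
    sequence counting should sit within 3 SD of the configured density."""
    cfg = SimConfig(seed=3, n_chroms=1, chrom_length=1_000_000,
                    cpg_island_rate=10, background_cpg_rate=1.0,
                    island_length=600, island_cpg_spacing=10.0)
    genome, cpgs = simulate_genome(cfg)
    seq = genome["chrS1"]
    n_cg = seq.count("CG")
    # expectation: 1000 background CpGs plus 10 islands of renewals with
    # mean gap 11 bp (geometric(1/10) + 1); renewal-count variance
    # L * var(gap) / mean(gap)^3 per island
    expect = 1000 + 10 * 600 / 11
    sd = np.sqrt(10 * 600 * 90 / 11**3)
    assert abs(n_cg - expect) < 3 * sd
    assert n_cg == len(cpgs["chrS1"])


class TestPlantMotifs:
    def test_zero_plants_leave_genome_unchanged(self):
        cfg = small_config()
        genome, cpgs = simulate_genome(cfg)
        rng = np.random.default_rng(0)
        g2, c2, sites = plant_motifs(genome, cpgs, egr_like_motif(), 0, [], rng)
        assert g2 == genome and sites == []

    def test_planted_consensus_recovered_by_rescan_and_cpg_list_updated(self):
        from methylfoot.motifs import scan

        cfg = small_config()
        genome, cpgs = simulate_genome(cfg)
        motif = egr_like_motif()
        targets = [("chrS1", 1000 + i * 5000, 1400 + i * 5000) for i in range(10)]
        rng = np.random.default_rng(1)
        g2, c2, sites = plant_motifs(genome, cpgs, motif, 10, targets, rng)
        assert len(sites) == 10
        for s in sites:
            window = g2[s.chrom][s.start:s.end]
            expect = motif.consensus if s.strand == "+" else None
            if s.strand == "+":
                assert window == motif.consensus
            hits, best = scan(window, motif)
            assert best == pytest.approx(motif.max_score)
            # the motif's CpG is in the updated site list
            cg = g2[s.chrom].find("CG", s.start - 1, s.end)
            assert cg in c2[s.chrom]
        # site list consistency: every listed site is CG
        for p in c2["chrS1"]:
            assert g2["chrS1"][p:p + 2] == "CG"

    def test_overlapping_plants_rejected(self):
        cfg = small_config()
        genome, cpgs = simulate_genome(cfg)
        rng = np.random.default_rng(2)
        # both targets share the center 1200, forcing identical plant sites
        targets = [("chrS1", 1000, 1400), ("chrS1", 1100, 1300)]
        with pytest.raises(ValueError, match="overlap"):
            plant_motifs(genome, cpgs, egr_like_motif(), 2, targets, rng)


class TestMethylomes:
    def test_null_config_mean_difference_centered_on_zero(self):
        cfg = small_config(seed=5)
        _, cpgs = simulate_genome(cfg)
        tracks, groups = simulate_methylomes(cfg, TruthTable(), cpgs)
        assert len(tracks) == 10
        from methylfoot.io import union_sites
        table = union_sites(tracks, groups)
        d = np.nanmean(table.group_ratio("A"), axis=1) - np.nanmean(
            table.group_ratio("B"), axis=1)
        assert abs(np.nanmean(d)) < 0.01

    def test_low_noise_limit_recovers_true_ratio(self):
        cfg = small_config(seed=6, replicate_precision=1e7, coverage_mean=10_000,
                           coverage_dispersion=1e6, dropout_rate=0.0,
                           background_cpg_rate=1.0, cpg_island_rate=0.0,
                           background_methylation=0.62)
        _, cpgs = simulate_genome(cfg)
        tracks, _ = simulate_methylomes(cfg, TruthTable(), cpgs)
        for t in tracks.values():
            assert np.all(np.abs(t.ratio - 0.62) < 0.02)

    def test_full_dropout_gives_empty_tracks(self):
        cfg = small_config(seed=7, dropout_rate=1.0)
        _, cpgs = simulate_genome(cfg)
        tracks, _ = simulate_methylomes(cfg, TruthTable(), cpgs)
        assert all(len(t) == 0 for t in tracks.values())

    def test_calibration_within_three_standard_errors(self):
        """Mean observed ratio over >= 50 CpGs tracks the true ratio."""
        cfg = small_config(seed=8, background_methylation=0.7)
        _, cpgs = simulate_genome(cfg)
        tracks, _ = simulate_methylomes(cfg, TruthTable(), cpgs)
        vals = np.concatenate([t.ratio for t in tracks.values()])
        assert len(vals) >= 50
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.7) < 3 * se + 1e-3

    def test_protected_spike_keeps_level_in_both_conditions(self):
        cfg = small_config(
            seed=9,
            dmr_specs=[DmrSpec(5, 300, 500, 0.8, 0.9)],
            spike_specs=[SpikeSpec(5, 0.9)],
        )
        sim = simulate(cfg)
        mu = true_ratio_tracks(sim.config, sim.truth, sim.cpg_positions)
        for s in sim.truth.planted_spikes:
            pos = sim.cpg_positions[s.chrom]
            i = int(np.searchsorted(pos, s.pos))
            assert pos[i] == s.pos
            mu_a, mu_b = mu[s.chrom]
            assert mu_a[i] == mu_b[i] == s.protected_level
            # flanking DMR CpGs dropped in condition B
            host = next(d for d in sim.truth.planted_dmrs if d.name == s.dmr_name)
            inside = (pos >= host.start) & (pos < host.end) & (pos != s.pos)
            assert np.all(mu_b[inside] == pytest.approx(host.baseline - host.delta))


def test_truth_containment_spikes_inside_one_dmr(spike_study_sim):
    sim = spike_study_sim
    for s in sim.truth.planted_spikes:
        hosts = [d for d in sim.truth.planted_dmrs
                 if d.chrom == s.chrom and d.start <= s.pos < d.end]
        assert len(hosts) == 1
    for d in sim.truth.planted_dmrs:
        assert d.chrom in sim.genome and 0 <= d.start < d.end <= len(sim.genome[d.chrom])


class TestPeaks:
    def truth_with(self, n):
        from methylfoot.simulate import PlantedDmr

        t = TruthTable()
        t.planted_dmrs = [PlantedDmr(f"d{i}", "chrS1", i * 5000, i * 5000 + 400, 0.4, 0.85)
                          for i in range(n)]
        return t

    def test_zero_fractions_give_empty_peaks(self):
        truth = self.truth_with(10)
        tf, atac = simulate_peaks(truth, (0.0, 0.0), np.random.default_rng(0))
        assert tf == [] and atac == []
        assert all(v == "none" for v in truth.peak_memberships.values())

    def test_designed_fractions_partition_memberships(self):
        truth = self.truth_with(10)
        tf, atac = simulate_peaks(truth, (0.5, 0.2), np.random.default_rng(1))
        counts = {"TF": 0, "ATAC": 0, "none": 0}
        for v in truth.peak_memberships.values():
            counts[v] += 1
        assert counts == {"TF": 5, "ATAC": 2, "none": 3}

    def test_classifier_recovers_recorded_memberships(self):
        truth = self.truth_with(10)
        tf, atac = simulate_peaks(truth, (0.4, 0.3), np.random.default_rng(2))
        dmr_set = IntervalSet.from_records(
            [(d.chrom, d.start, d.end, d.name) for d in truth.planted_dmrs])
        tf_set = IntervalSet.from_records([p[:3] for p in tf]) if tf else IntervalSet.empty()
        atac_set = IntervalSet.from_records([p[:3] for p in atac]) if atac else IntervalSet.empty()
        labels = classify_dmrs(dmr_set, [tf_set], atac_set)
        want = {"TF": "TF_peak", "ATAC": "open", "none": "no_peak"}
        for d, label in zip(dmr_set.df.itertuples(index=False), labels):
            assert label == want[truth.peak_memberships[d.name]]

    def test_fractions_must_not_exceed_one(self):
        with pytest.raises(ValueError):
            simulate_peaks(self.truth_with(4), (0.8, 0.4), np.random.default_rng(0))
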