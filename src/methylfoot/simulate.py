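"""Synthetic methylomes with planted ground truth.

The generator emulates the statistical structure of a two-condition WGBS
replicate design (default 4 condition-A vs 6 condition-B donors, the
MO / moDC layout): CpG-clustered chromosomes, beta-binomial methylation
counts with negative-binomial coverage, planted demethylated regions,
demethylation-protected motif-core CpGs inside those regions, and peak
sets covering known subsets of the planted regions.

Noise model per CpG, replicate and condition: the condition's true ratio
mu is perturbed per replicate as Beta(mean = mu, precision = kappa); read
coverage is NegBin(mean, dispersion); methylated reads are
Binomial(coverage, replicate ratio); the observed ratio is their
quotient. A CpG is unobserved in a sample with probability
``dropout_rate`` (or when coverage draws 0).

Planted DMRs receive their own CpG ladder (~60-80 bp spacing) on top of
the background rate, reflecting the CpG enrichment of regulatory regions;
protected (spike) CpGs keep their high level in BOTH conditions while the
surrounding DMR CpGs drop in condition B.

Each replicate draws from its own RNG stream derived from the master
seed and the sample name by stable hashing, so adding replicates never
perturbs existing ones. Identical configs (including seed) give
bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import SampleTrack
from .motifs import MotifModel, reverse_complement

_BASES = np.array(list("ACGT"))
A, C, G, T = 0, 1, 2, 3


@dataclass(frozen=True)
class DmrSpec:
    count: int
    width_min: int
    width_max: int
    delta: float  # methylation drop in condition B, in [0, 1]
    baseline: float  # condition-A true ratio inside the region

    def __post_init__(self):
        if not 0 <= self.delta <= 1 or not 0 <= self.baseline <= 1:
            raise ValueError("delta and baseline must be in [0, 1]")
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass(frozen=True)
class SpikeSpec:
    count: int
    protected_level: float  # true ratio of the protected CpG, both conditions

    def __post_init__(self):
        if not 0 <= self.protected_level <= 1:
            raise ValueError("protected_level must be in [0, 1]")


@dataclass(frozen=True)
class MotifSpec:
    motif: MotifModel
    count: int


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    cpg_island_rate: float = 10.0  # islands per Mb
    background_cpg_rate: float = 10.0  # CpGs per kb
    island_length: int = 600
    island_cpg_spacing: float = 10.0
    n_replicates_a: int = 4
    n_replicates_b: int = 6
    coverage_mean: float = 30.0
    coverage_dispersion: float = 10.0
    replicate_precision: float = 100.0  # beta precision kappa
    dropout_rate: float = 0.01
    background_methylation: float = 0.75
    dmr_specs: list[DmrSpec] = field(default_factory=list)
    spike_specs: list[SpikeSpec] = field(default_factory=list)
    motif_specs: list[MotifSpec] = field(default_factory=list)

    def __post_init__(self):
        for p in (self.dropout_rate, self.background_methylation):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.chrom_length < 1000:
            raise ValueError("chrom_length too small")

    # -- study presets: the simulated counterparts of the analysed design --

    @classmethod
    def dmr_study(cls, seed: int = 0) -> "SimConfig":
        """Planted demethylated regions at moderate effect size: 30 DMRs
        of 300-800 bp dropping from 0.85 to 0.45 in condition B."""
        return cls(seed=seed, dmr_specs=[DmrSpec(30, 300, 800, 0.4, 0.85)])

    @classmethod
    def null_study(cls, seed: int = 0) -> "SimConfig":
        """No planted differences anywhere (false-positive calibration)."""
        return cls(seed=seed)

    @classmethod
    def spike_study(cls, seed: int = 0) -> "SimConfig":
        """50 protected CpGs at true level 0.9 inside regions demethylated
        from 0.9 to 0.1 in condition B."""
        return cls(
            seed=seed,
            dmr_specs=[DmrSpec(50, 300, 800, 0.8, 0.9)],
            spike_specs=[SpikeSpec(50, 0.9)],
        )

    @classmethod
    def footprint_study(cls, seed: int = 0) -> "SimConfig":
        """Spike study plus a planted zinc-finger-like motif whose central
        CpG is the protected one (the motif-core methylation footprint)."""
        cfg = cls.spike_study(seed)
        cfg.motif_specs = [MotifSpec(egr_like_motif(), 50)]
        return cfg

    @classmethod
    def demo(cls, seed: int = 0) -> "SimConfig":
        """Small, fast end-to-end configuration."""
        return cls(
            seed=seed,
            n_chroms=1,
            chrom_length=300_000,
            dmr_specs=[DmrSpec(10, 300, 600, 0.5, 0.9)],
            spike_specs=[SpikeSpec(6, 0.9)],
            motif_specs=[MotifSpec(egr_like_motif(), 6)],
        )


def egr_like_motif() -> MotifModel:
    """A GC-rich zinc-finger-style motif with a single CpG at its center
    (the demethylation-protection footprint sits on that CpG)."""
    return MotifModel.from_consensus("EGR_like", "GTGGCGTGG", motif_class="EGR")


def ap1_like_motif() -> MotifModel:
    """A bZIP-style TPA-response-element motif without any CpG."""
    return MotifModel.from_consensus("AP1_like", "TGACTCA", motif_class="AP1")


@dataclass
class PlantedDmr:
    name: str
    chrom: str
    start: int
    end: int
    delta: float
    baseline: float


@dataclass
class PlantedSpike:
    chrom: str
    pos: int  # CpG C position
    protected_level: float
    dmr_name: str


@dataclass
class PlantedMotifSite:
    chrom: str
    start: int
    end: int
    strand: str
    motif_name: str
    dmr_name: str = ""


@dataclass
class TruthTable:
    planted_dmrs: list[PlantedDmr] = field(default_factory=list)
    planted_spikes: list[PlantedSpike] = field(default_factory=list)
    planted_motif_sites: list[PlantedMotifSite] = field(default_factory=list)
    peak_memberships: dict[str, str] = field(default_factory=dict)  # dmr -> TF/ATAC/none


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Random chromosomes plus their CpG site list.

    Returns (genome: dict chrom -> str, cpg_positions: dict chrom ->
    sorted int array). Accidental CG dinucleotides are scrubbed from the
    background sequence so the listed sites are exactly the CpGs present.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, _tag("genome")]))
    genome: dict[str, str] = {}
    cpgs: dict[str, np.ndarray] = {}
    for ci in range(config.n_chroms):
        chrom = f"chrS{ci + 1}"
        code = rng.integers(0, 4, size=config.chrom_length, dtype=np.int8)
        _scrub_cg(code)
        positions = []
        # background CpGs
        n_bg = int(round(config.background_cpg_rate * config.chrom_length / 1000))
        if n_bg:
            positions.append(rng.integers(1, config.chrom_length - 2, size=n_bg))
        # islands
        n_isl = int(round(config.cpg_island_rate * config.chrom_length / 1e6))
        for _ in range(n_isl):
            if config.chrom_length <= config.island_length + 2:
                raise ValueError("chrom_length too small for requested islands")
            start = int(rng.integers(0, config.chrom_length - config.island_length - 2))
            gaps = rng.geometric(1.0 / max(config.island_cpg_spacing, 1.0),
                                 size=max(2 * config.island_length // max(int(config.island_cpg_spacing), 1), 4))
            pos = start + np.cumsum(gaps + 1)
            positions.append(pos[pos < start + config.island_length])
        pos = np.sort(np.unique(np.concatenate(positions))) if positions else np.empty(0, int)
        pos = _enforce_spacing(pos, 2)
        for p in pos:
            code[p], code[p + 1] = C, G
        # planting CpGs can butt new C against an existing G downstream
        _scrub_cg(code, protect=pos)
        genome[chrom] = "".join(_BASES[code])
        cpgs[chrom] = pos.astype(np.int64)
    return genome, cpgs


def _tag(label: str) -> int:
    return zlib.crc32(label.encode())


def _scrub_cg(code: np.ndarray, protect: np.ndarray | None = None) -> None:
    """Replace the G of every CG pair with A, except protected sites."""
    while True:
        mask = (code[:-1] == C) & (code[1:] == G)
        if protect is not None and protect.size:
            keep = np.zeros(len(code) - 1, dtype=bool)
            keep[protect[protect < len(code) - 1]] = True
            mask &= ~keep
        if not mask.any():
            return
        code[1:][mask] = A


def _enforce_spacing(pos: np.ndarray, min_gap: int) -> np.ndarray:
    if pos.size == 0:
        return pos
    kept = [int(pos[0])]
    for p in pos[1:]:
        if p - kept[-1] >= min_gap:
            kept.append(int(p))
    return np.array(kept, dtype=np.int64)


# ---------------------------------------------------------------------------
# planting


def plant_motifs(
    genome: dict[str, str],
    cpg_positions: dict[str, np.ndarray],
    motif: MotifModel,
    n: int,
    target_intervals: list[tuple[str, int, int]],
    rng: np.random.Generator,
):
    """Write ``n`` exact consensus instances (random strand) into the
    targets, one per interval, rejecting overlaps.

    Returns (genome, cpg_positions, planted_sites); the CpG list is
    updated for sites destroyed or created by the edit.
    """
    consensus = motif.consensus
    L = len(consensus)
    planted: list[PlantedMotifSite] = []
    occupied: list[tuple[str, int, int]] = []
    genome = dict(genome)
    cpg_positions = {k: v.copy() for k, v in cpg_positions.items()}
    for chrom, t_start, t_end in target_intervals:
        if len(planted) >= n:
            break
        if t_end - t_start < L:
            raise ValueError("target interval shorter than motif")
        center = (t_start + t_end) // 2
        start = center - L // 2
        if any(c == chrom and start < e and start + L > s for c, s, e in occupied):
            raise ValueError("overlapping motif plants rejected")
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = consensus if strand == "+" else reverse_complement(consensus)
        seq = genome[chrom]
        genome[chrom] = seq[:start] + inserted + seq[start + L:]
        cpg_positions[chrom] = _refresh_cpgs(
            genome[chrom], cpg_positions[chrom], start, start + L)
        planted.append(PlantedMotifSite(chrom, start, start + L, strand, motif.name))
        occupied.append((chrom, start, start + L))
    return genome, cpg_positions, planted


def _refresh_cpgs(seq: str, pos: np.ndarray, edit_start: int, edit_end: int) -> np.ndarray:
    """Recompute CpG sites whose dinucleotide touches the edited span
    [edit_start, edit_end)."""
    lo = max(edit_start - 1, 0)  # a dinucleotide at edit_start-1 overlaps the edit
    hi = min(edit_end, len(seq) - 1)  # last dinucleotide start inside the edit
    keep = pos[(pos < lo) | (pos >= hi)]
    local = np.array(
        [p for p in range(lo, hi) if seq[p:p + 2] == "CG"], dtype=np.int64
    )
    return np.sort(np.unique(np.concatenate([keep, local])))


def _place_dmrs(config: SimConfig, cpg_positions, rng) -> tuple[list[PlantedDmr], dict[str, np.ndarray]]:
    """Choose non-overlapping DMR intervals and seed them with a CpG
    ladder (~60-80 bp spacing)."""
    chroms = sorted(cpg_positions)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    planted: list[PlantedDmr] = []
    new_pos = {c: [cpg_positions[c]] for c in chroms}
    idx = 0
    for spec in config.dmr_specs:
        for _ in range(spec.count):
            for attempt in range(500):
                chrom = chroms[int(rng.integers(len(chroms)))]
                width = int(rng.integers(spec.width_min, spec.width_max + 1))
                if config.chrom_length <= width + 4:
                    raise ValueError("chrom_length too small for requested DMR widths")
                start = int(rng.integers(2, config.chrom_length - width - 2))
                end = start + width
                if any(start - 2000 < e and end + 2000 > s for s, e in occupied[chrom]):
                    continue
                occupied[chrom].append((start, end))
                idx += 1
                planted.append(PlantedDmr(f"true_dmr_{idx}", chrom, start, end,
                                          spec.delta, spec.baseline))
                ladder = [start + 10]
                while ladder[-1] + 80 < end - 10:
                    ladder.append(ladder[-1] + int(rng.integers(60, 81)))
                new_pos[chrom].append(np.array(ladder, dtype=np.int64))
                break
            else:
                raise ValueError("could not place requested DMRs; chromosomes too small")
    merged = {}
    for c in chroms:
        pos = np.sort(np.unique(np.concatenate(new_pos[c])))
        merged[c] = _enforce_spacing(pos, 2)
    return planted, merged


# ---------------------------------------------------------------------------
# methylomes


def true_ratio_tracks(config: SimConfig, truth: TruthTable,
                      cpg_positions: dict[str, np.ndarray]):
    """Per-condition true methylation ratios for every CpG site.

    Background CpGs sit at ``background_methylation`` in both conditions;
    inside a planted DMR condition A is the spec baseline and condition B
    is baseline - delta; protected spike CpGs keep their level in both.
    """
    mu = {}
    for chrom, pos in cpg_positions.items():
        mu_a = np.full(pos.shape, config.background_methylation)
        mu_b = mu_a.copy()
        for d in truth.planted_dmrs:
            if d.chrom != chrom:
                continue
            inside = (pos >= d.start) & (pos < d.end)
            mu_a[inside] = d.baseline
            mu_b[inside] = max(d.baseline - d.delta, 0.0)
        for s in truth.planted_spikes:
            if s.chrom != chrom:
                continue
            hit = pos == s.pos
            mu_a[hit] = s.protected_level
            mu_b[hit] = s.protected_level
        mu[chrom] = (mu_a, mu_b)
    return mu


def _sample_rng(config: SimConfig, sample_name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _tag(sample_name)]))


def simulate_methylomes(config: SimConfig, truth: TruthTable,
                        cpg_positions: dict[str, np.ndarray]):
    """Draw the per-replicate observed ratio and coverage tracks.

    Returns (tracks: dict sample -> SampleTrack, groups: dict sample ->
    'A'|'B'). Sample names are A1..AnA and B1..BnB.
    """
    mu = true_ratio_tracks(config, truth, cpg_positions)
    chroms = sorted(cpg_positions)
    tracks: dict[str, SampleTrack] = {}
    groups: dict[str, str] = {}
    samples = [("A", f"A{i + 1}") for i in range(config.n_replicates_a)] + [
        ("B", f"B{i + 1}") for i in range(config.n_replicates_b)
    ]
    kappa = config.replicate_precision
    theta = config.coverage_dispersion
    for cond, name in samples:
        rng = _sample_rng(config, name)
        chrom_col, pos_col, ratio_col, cov_col = [], [], [], []
        for chrom in chroms:
            pos = cpg_positions[chrom]
            if pos.size == 0:
                continue
            true_mu = mu[chrom][0 if cond == "A" else 1]
            m = np.clip(true_mu, 1e-4, 1 - 1e-4)
            rep_ratio = rng.beta(m * kappa, (1 - m) * kappa)
            cov = rng.negative_binomial(theta, theta / (theta + config.coverage_mean),
                                        size=pos.size).astype(float)
            meth = rng.binomial(np.maximum(cov, 0).astype(int), rep_ratio)
            dropout = rng.random(pos.size) < config.dropout_rate
            observed = (cov > 0) & ~dropout
            if not observed.any():
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(observed, meth / np.maximum(cov, 1), np.nan)
            chrom_col.extend([chrom] * int(observed.sum()))
            pos_col.append(pos[observed])
            ratio_col.append(ratio[observed])
            cov_col.append(cov[observed])
        sites = pd.DataFrame({
            "chrom": chrom_col,
            "pos": np.concatenate(pos_col) if pos_col else np.empty(0, int),
        })
        tracks[name] = SampleTrack(
            sites,
            np.concatenate(ratio_col) if ratio_col else np.empty(0),
            np.concatenate(cov_col) if cov_col else np.empty(0),
        )
        groups[name] = cond
    return tracks, groups


# ---------------------------------------------------------------------------
# peaks


def simulate_peaks(truth: TruthTable, fractions: tuple[float, float],
                   rng: np.random.Generator, peak_halfwidth: int = 150):
    """TF and ATAC-only peak sets covering known DMR subsets.

    ``fractions`` = (fraction of planted DMRs covered by a TF peak,
    disjoint fraction covered by an ATAC-only peak); must sum to <= 1.
    Memberships are recorded into ``truth.peak_memberships``.
    Returns (tf_peaks, atac_peaks) as lists of (chrom, start, end, name).
    """
    f_tf, f_atac = fractions
    if f_tf + f_atac > 1 + 1e-9:
        raise ValueError("fractions must sum to <= 1")
    dmrs = list(truth.planted_dmrs)
    n = len(dmrs)
    n_tf = int(round(n * f_tf))
    n_atac = int(round(n * f_atac))
    if n_tf + n_atac > n:
        n_atac = n - n_tf
    order = rng.permutation(n)
    tf_peaks, atac_peaks = [], []
    for rank, i in enumerate(order):
        d = dmrs[i]
        center = (d.start + d.end) // 2
        peak = (d.chrom, max(0, center - peak_halfwidth), center + peak_halfwidth)
        if rank < n_tf:
            truth.peak_memberships[d.name] = "TF"
            tf_peaks.append((*peak, f"tf_peak_{len(tf_peaks) + 1}"))
        elif rank < n_tf + n_atac:
            truth.peak_memberships[d.name] = "ATAC"
            atac_peaks.append((*peak, f"atac_peak_{len(atac_peaks) + 1}"))
        else:
            truth.peak_memberships[d.name] = "none"
    # open chromatin also covers TF-bound sites; classification gives TF
    # binding precedence, so these extra ATAC peaks never relabel a DMR
    atac_full = atac_peaks + [
        (c, s, e, f"atac_peak_{len(atac_peaks) + i + 1}")
        for i, (c, s, e, _) in enumerate(tf_peaks)
    ]
    return tf_peaks, atac_full


# ---------------------------------------------------------------------------
# one-call orchestration


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    cpg_positions: dict[str, np.ndarray]
    truth: TruthTable
    tracks: dict[str, SampleTrack]
    groups: dict[str, str]


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: genome, planted features, methylomes."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _tag("plan")]))
    genome, cpgs = simulate_genome(config)
    truth = TruthTable()
    truth.planted_dmrs, cpgs = _place_dmrs(config, cpgs, rng)

    # motifs are planted centered in planted DMRs (one per DMR)
    motif_hosts = list(truth.planted_dmrs)
    for mspec in config.motif_specs:
        targets = [(d.chrom, d.start, d.end) for d in motif_hosts[: mspec.count]]
        genome, cpgs, sites = plant_motifs(genome, cpgs, mspec.motif,
                                           mspec.count, targets, rng)
        for site, host in zip(sites, motif_hosts):
            site.dmr_name = host.name
        truth.planted_motif_sites.extend(sites)
        motif_hosts = motif_hosts[mspec.count:]

    # protected spike CpGs: the motif-core CpG where a motif was planted,
    # otherwise the CpG nearest the DMR center
    spike_hosts = list(truth.planted_dmrs)
    site_by_dmr = {s.dmr_name: s for s in truth.planted_motif_sites}
    for sspec in config.spike_specs:
        for d in spike_hosts[: sspec.count]:
            pos = cpgs[d.chrom]
            site = site_by_dmr.get(d.name)
            if site is not None:
                inside = pos[(pos >= site.start) & (pos < site.end - 1)]
            else:
                inside = pos[(pos >= d.start) & (pos < d.end)]
            if inside.size == 0:
                continue
            center = (d.start + d.end) // 2
            p = int(inside[np.argmin(np.abs(inside - center))])
            truth.planted_spikes.append(PlantedSpike(d.chrom, p, sspec.protected_level, d.name))
        spike_hosts = spike_hosts[sspec.count:]

    tracks, groups = simulate_methylomes(config, truth, cpgs)
    return SimResult(config, genome, cpgs, truth, tracks, groups)


# ---------------------------------------------------------------------------
# text-format writers (FASTA, BED, truth tables)


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    genome: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            else:
                chunks.append(line)
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


def write_truth_tables(truth: TruthTable, prefix) -> None:
    pd.DataFrame(
        [(d.chrom, d.start, d.end, d.name, d.delta, d.baseline,
          truth.peak_memberships.get(d.name, "none"))
         for d in truth.planted_dmrs],
        columns=["chrom", "start", "end", "name", "delta", "baseline", "peak_membership"],
    ).to_csv(f"{prefix}.dmrs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(s.chrom, s.pos, s.protected_level, s.dmr_name) for s in truth.planted_spikes],
        columns=["chrom", "pos", "protected_level", "dmr_name"],
    ).to_csv(f"{prefix}.spikes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(m.chrom, m.start, m.end, m.strand, m.motif_name, m.dmr_name)
         for m in truth.planted_motif_sites],
        columns=["chrom", "start", "end", "strand", "motif", "dmr_name"],
    ).to_csv(f"{prefix}.motifs.tsv", sep="\t", index=False)
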