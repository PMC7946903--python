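"""End-to-end orchestration with a reproducible run manifest.

The stage DAG: simulate -> union/filter -> call-dmrs -> call-spikes ->
classify -> quintiles -> profile -> motifs. All thresholds flow from one
YAML config (defaults are the DmrConfig / SpikeConfig defaults); every
stage writes plain-text outputs and records a sha256 checksum and a
record count in the manifest, so two runs with the same seed can be
compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dmr import DmrConfig, call_dmrs, dmrs_to_intervals, dmrs_to_table
from .io import filter_coverage, filter_spike_coverage, union_sites, write_intervals, write_methylation_track
from .motifs import co_association_network, motif_enrichment, enrichment_table, network_tables
from .profiles import motif_centered_profile, motif_core_profile, recenter_on_motif
from .regions import classify_dmrs, quintile_bins
from .simulate import (
    SimConfig,
    simulate,
    simulate_peaks,
    write_fasta,
    write_truth_tables,
    egr_like_motif,
    ap1_like_motif,
)
from .io import IntervalSet
from .spikes import SpikeConfig, average_track, call_spikes, spikes_to_intervals, spikes_to_table


class ConfigError(ValueError):
    pass


_SCHEMA = {
    "seed": int,
    "preset": str,
    "peaks": {"tf_fraction": float, "atac_fraction": float},
    "dmr": {
        "alpha": float, "min_diff": float, "min_consecutive": int,
        "max_gap": int, "extension": int, "repeat_overlap_max": float,
        "min_mappability": float, "autosomes_only": bool,
    },
    "spike": {
        "min_rise": float, "min_fall": float, "max_neighbor_dist": int,
        "merge_window": int, "min_reads": int, "min_mappability": float,
    },
    "filter": {"min_reads": int, "min_samples_a": int, "min_samples_b": int},
    "profile": {"window": int, "core_window": int},
}

_RANGES = {
    ("dmr", "alpha"): (0.0, 1.0, "alpha must be in (0, 1]"),
    ("dmr", "min_diff"): (-1e-9, 1.0, "min_diff must be in [0, 1]"),
    ("spike", "min_rise"): (0.0, 1.0, "min_rise must be in (0, 1]"),
    ("spike", "min_fall"): (0.0, 1.0, "min_fall must be in (0, 1]"),
}

DEFAULT_CONFIG = {
    "seed": 0,
    "preset": "demo",
    "peaks": {"tf_fraction": 0.5, "atac_fraction": 0.2},
    "dmr": {},
    "spike": {},
    "filter": {},
    "profile": {"window": 500, "core_window": 12},
}


def validate_config(config: dict) -> list[str]:
    """Type/range checks; raises ConfigError for hard violations and
    returns a list of warnings."""
    warnings: list[str] = []
    for key, value in config.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown config key: {key!r}")
        spec = _SCHEMA[key]
        if isinstance(spec, dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{key!r} must be a mapping")
            for sub, sval in value.items():
                if sub not in spec:
                    raise ConfigError(f"unknown config key: {key}.{sub}")
                want = spec[sub]
                if want is float and isinstance(sval, int) and not isinstance(sval, bool):
                    sval = float(sval)
                if not isinstance(sval, want):
                    raise ConfigError(f"{key}.{sub} must be {want.__name__}")
                rng = _RANGES.get((key, sub))
                if rng is not None:
                    lo, hi, msg = rng
                    if not (lo < sval <= hi):
                        raise ConfigError(msg)
        elif not isinstance(value, spec):
            raise ConfigError(f"{key!r} must be {spec.__name__}")
    window = config.get("profile", {}).get("window", 500)
    if window <= 0:
        raise ConfigError("profile.window must be > 0")
    if config.get("dmr", {}).get("min_consecutive", 2) < 2:
        warnings.append(
            "dmr.min_consecutive < 2 is below the two-consecutive-CpG rule")
    return warnings


def load_config(path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise ConfigError("config must be a YAML mapping")
    merged = {**DEFAULT_CONFIG, **loaded}
    for key in ("peaks", "dmr", "spike", "filter", "profile"):
        merged[key] = {**DEFAULT_CONFIG.get(key, {}), **(loaded.get(key) or {})}
    validate_config(merged)
    return merged


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_PRESETS = {
    "demo": SimConfig.demo,
    "dmr_study": SimConfig.dmr_study,
    "null_study": SimConfig.null_study,
    "spike_study": SimConfig.spike_study,
    "footprint_study": SimConfig.footprint_study,
}


def run_pipeline(config: dict | str | Path, outdir, seed: int | None = None,
                 resume: bool = False, log=print) -> dict:
    """Run the full stage DAG; returns (and writes) the run manifest.

    With ``resume=True`` a stage's files are only rewritten when absent,
    so deleting downstream outputs and resuming reproduces them.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
        config = {**DEFAULT_CONFIG, **config}
    if seed is not None:
        config = {**config, "seed": seed}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config["seed"],
        "config": config,
        "stages": {},
    }

    def _write(stage: str, name: str, writer, count: int):
        path = outdir / name
        if not (resume and path.exists()):
            writer(path)
        entry = manifest["stages"].setdefault(stage, {"outputs": {}, "counts": {}})
        entry["outputs"][name] = _sha256(path)
        entry["counts"][name] = count
        return path

    preset = config.get("preset", "demo")
    if preset not in _PRESETS:
        raise ConfigError(f"unknown preset {preset!r}")
    sim_cfg = _PRESETS[preset](seed=config["seed"])

    # --- simulate ---------------------------------------------------------
    log(f"[simulate] preset={preset} seed={config['seed']}")
    sim = simulate(sim_cfg)
    _write("simulate", "genome.fa", lambda p: write_fasta(sim.genome, p),
           len(sim.genome))
    for name, track in sorted(sim.tracks.items()):
        _write("simulate", f"{name}.ratio.bedGraph",
               lambda p, t=track: write_methylation_track(
                   t, p, str(p).replace(".ratio.", ".cov.")), len(track))
        entry = manifest["stages"]["simulate"]
        cov = Path(str(outdir / f"{name}.cov.bedGraph"))
        entry["outputs"][cov.name] = _sha256(cov)
    write_truth_tables(sim.truth, outdir / "truth")
    for suffix, count in (("dmrs", len(sim.truth.planted_dmrs)),
                          ("spikes", len(sim.truth.planted_spikes)),
                          ("motifs", len(sim.truth.planted_motif_sites))):
        p = outdir / f"truth.{suffix}.tsv"
        entry = manifest["stages"]["simulate"]
        entry["outputs"][p.name] = _sha256(p)
        entry["counts"][p.name] = count
    rng = np.random.default_rng(np.random.SeedSequence([config["seed"], 917]))
    tf_peaks, atac_peaks = simulate_peaks(
        sim.truth,
        (config["peaks"]["tf_fraction"], config["peaks"]["atac_fraction"]),
        rng,
    )
    tf_set = IntervalSet.from_records(tf_peaks) if tf_peaks else IntervalSet.empty()
    atac_set = IntervalSet.from_records(atac_peaks) if atac_peaks else IntervalSet.empty()
    _write("simulate", "tf_peaks.bed", lambda p: write_intervals(tf_set, p), len(tf_set))
    _write("simulate", "atac_peaks.bed", lambda p: write_intervals(atac_set, p), len(atac_set))

    # --- union + coverage filter ------------------------------------------
    table = union_sites(sim.tracks, sim.groups)
    n_union = len(table)
    fcfg = config["filter"]
    table_f = filter_coverage(
        table,
        min_reads=fcfg.get("min_reads", 5),
        min_samples_a=fcfg.get("min_samples_a", 2),
        min_samples_b=fcfg.get("min_samples_b", 3),
    )
    log(f"[filter] sites union={n_union} surviving={len(table_f)}")
    manifest["stages"]["filter"] = {
        "outputs": {}, "counts": {"sites_union": n_union, "sites_filtered": len(table_f)}}

    # --- DMRs ---------------------------------------------------------------
    dmr_cfg = DmrConfig(**config["dmr"])
    chrom_sizes = {c: len(s) for c, s in sim.genome.items()}
    dmrs = call_dmrs(table_f, dmr_cfg, chrom_sizes)
    log(f"[call-dmrs] called={len(dmrs)}")
    dmr_set = dmrs_to_intervals(dmrs)
    _write("call_dmrs", "dmrs.bed", lambda p: write_intervals(dmr_set, p), len(dmrs))
    _write("call_dmrs", "dmrs.tsv",
           lambda p: dmrs_to_table(dmrs).to_csv(p, sep="\t", index=False), len(dmrs))

    # --- spikes ------------------------------------------------------------
    spike_cfg = SpikeConfig(**config["spike"])
    cols_b = [s for s, g in sim.groups.items() if g == "B"]
    table_b = union_sites({s: sim.tracks[s] for s in cols_b},
                          {s: "B" for s in cols_b})
    table_b = filter_spike_coverage(table_b, min_reads=spike_cfg.min_reads)
    avg_b = average_track(table_b)
    spikes = call_spikes(avg_b, spike_cfg)
    log(f"[call-spikes] called={len(spikes)}")
    spike_set = spikes_to_intervals(spikes)
    _write("call_spikes", "spikes.bed", lambda p: write_intervals(spike_set, p), len(spikes))
    _write("call_spikes", "spikes.tsv",
           lambda p: spikes_to_table(spikes).to_csv(p, sep="\t", index=False), len(spikes))

    # --- classify + quintiles -----------------------------------------------
    labels = classify_dmrs(dmr_set, [tf_set], atac_set)
    class_df = dmrs_to_table(dmrs)
    class_df["group"] = labels
    if len(dmrs) >= 5:
        bins = quintile_bins([d.name for d in dmrs], [d.mean_a for d in dmrs])
        class_df["quintile"] = [bins[d.name] for d in dmrs]
    _write("classify", "dmr_groups.tsv",
           lambda p: class_df.to_csv(p, sep="\t", index=False), len(class_df))
    log(f"[classify] TF_peak={labels.count('TF_peak')} open={labels.count('open')} "
        f"no_peak={labels.count('no_peak')}")

    # --- motif-centered profiles ---------------------------------------------
    motif = sim_cfg.motif_specs[0].motif if sim_cfg.motif_specs else egr_like_motif()
    centered = recenter_on_motif(dmr_set, motif, sim.genome)
    prof_cfg = config["profile"]
    prof = motif_centered_profile(centered, avg_b, prof_cfg["window"])
    core = motif_core_profile(centered, avg_b, prof_cfg["core_window"])
    _write("profile", "motif_profile.tsv",
           lambda p: prof.to_frame().to_csv(p, sep="\t", index=False),
           len(centered.centers))
    _write("profile", "motif_core_profile.tsv",
           lambda p: core.to_frame().to_csv(p, sep="\t", index=False),
           len(centered.centers))
    log(f"[profile] centered={len(centered.centers)} dropped={centered.n_dropped}")

    # --- motif statistics ------------------------------------------------------
    if len(dmr_set) and len(atac_set):
        background = atac_set  # stand-in background set from the run itself
        enr = motif_enrichment(dmr_set, background, sim.genome,
                               [motif, ap1_like_motif()])
        _write("motifs", "enrichment.tsv",
               lambda p: enrichment_table(enr).to_csv(p, sep="\t", index=False), len(enr))
        net = co_association_network(
            dmr_set, sim.genome,
            {"EGR": [motif], "AP1": [ap1_like_motif()]})
        nodes, edges = network_tables(net)
        _write("motifs", "network_nodes.tsv",
               lambda p: nodes.to_csv(p, sep="\t", index=False), len(nodes))
        _write("motifs", "network_edges.tsv",
               lambda p: edges.to_csv(p, sep="\t", index=False), len(edges))
        log(f"[motifs] any_motif={net.pct_any_motif:.1f}% "
            f"co_associated={net.pct_co_associated:.1f}%")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
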