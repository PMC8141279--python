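"""End-to-end orchestration: simulate -> filter -> test -> annotate -> enrich -> motifs.

One YAML config drives the whole run; every analysis threshold is a named,
defaulted field so a zero-argument run reproduces the standard analysis
settings (min_cov 10, FDR 0.05, |delta| 0.20, windows {0,500,1000,5000,10000},
n_perm 1000, motif size 400, profile flank 2000).  A JSON manifest records the
config snapshot, master seed, package version and a SHA-256 digest of every
stage output, so a rerun with the same seed can be checked for byte identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import integrate_expression, nearest_tss, rank_genes_by_dml
from .dml import BetaBinomialDML
from .genome import build_genome, write_fasta
from .io import (
    conversion_efficiency,
    coverage_filter,
    global_methylation_summary,
    write_bed,
    write_bedgraph,
    write_cytosine_report,
)
from .intervals import merge_peaks, aggregate_signal, compare_anchor_signal, permutation_overlap_test
from .motifs import bundled_pwms, extract_windows, motif_centered_profiles, motif_enrichment, sample_background_windows, scan_pwm
from .simulate import (
    DMRSpec,
    PeakEnrichmentParams,
    SimulationConfig,
    default_dmr_specs,
    plant_motifs,
    simulate_expression,
    simulate_genes,
    simulate_methylomes,
    simulate_peaks_and_signal,
    simulate_spikein,
)

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "genome": {"n_chroms": 1, "chrom_length_bp": 500_000, "cpg_density": 0.01,
               "with_sequence": True},
    "simulate": {"n_replicates": 3, "mean_coverage": 20.0, "dispersion": 0.02,
                 "dmr_fraction": 0.05, "hypo_fraction": 0.96, "delta_magnitude": 0.5,
                 "dmr_span_cpgs": 10,
                 "spikein": {"n_sites": 1000, "depth": 50, "conversion_rate": 0.995},
                 "peaks": {"enrichment_fraction": 0.9, "max_offset": 500,
                           "n_background": 100},
                 "n_genes": 200, "coupling": 0.8, "planting_rate": 0.8},
    "filter": {"min_cov": 10, "per_sample": False, "conversion_threshold": 0.99},
    "dml": {"fdr": 0.05, "min_delta": 0.20},
    "enrich": {"windows": [0, 500, 1000, 5000, 10000], "n_perm": 1000},
    "motifs": {"size": 400, "max_foreground": 300},
    "profile": {"flank": 2000, "n_bins": 40},
}


def _deep_update(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Load a YAML config merged over the defaults."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_update(cfg, user)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Field-level schema checks; raises ConfigError naming the offending field."""
    def check(cond, field, msg):
        if not cond:
            raise ConfigError(f"config field {field}: {msg}")

    check(isinstance(cfg.get("seed"), int) and cfg["seed"] >= 0, "seed", "non-negative int required")
    g = cfg["genome"]
    check(g["n_chroms"] >= 1, "genome.n_chroms", ">= 1 required")
    check(g["chrom_length_bp"] >= 10_000, "genome.chrom_length_bp", ">= 10000 required")
    check(0 < g["cpg_density"] <= 0.1, "genome.cpg_density", "in (0, 0.1] required")
    s = cfg["simulate"]
    check(s["n_replicates"] >= 1, "simulate.n_replicates", ">= 1 required")
    check(0 <= s["hypo_fraction"] <= 1, "simulate.hypo_fraction", "in [0,1] required")
    check(0 <= s["coupling"] <= 1, "simulate.coupling", "in [0,1] required")
    check(0 < s["spikein"]["conversion_rate"] <= 1, "simulate.spikein.conversion_rate",
          "in (0,1] required")
    d = cfg["dml"]
    check(0 < d["fdr"] < 1, "dml.fdr", "in (0,1) required")
    check(0 < d["min_delta"] < 1, "dml.min_delta", "in (0,1) required")
    check(cfg["filter"]["min_cov"] >= 1, "filter.min_cov", ">= 1 required")
    e = cfg["enrich"]
    check(e["n_perm"] >= 1, "enrich.n_perm", ">= 1 required")
    check(all(w >= 0 for w in e["windows"]), "enrich.windows", "non-negative required")
    check(cfg["motifs"]["size"] >= 2, "motifs.size", ">= 2 required")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config=None, outdir="dmlkit_run") -> dict:
    """Run every stage and write artifacts plus ``manifest.json`` to ``outdir``.

    ``config`` may be a path to a YAML file, a dict (merged over defaults), or
    None for the default run.  Returns the manifest dict.
    """
    if config is None:
        cfg = dict(DEFAULT_CONFIG)
    elif isinstance(config, dict):
        cfg = _deep_update(DEFAULT_CONFIG, config)
    else:
        cfg = load_config(config)
    validate_config(cfg)
    seed = cfg["seed"]
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    files: dict[str, Path] = {}

    # --- stage 1: simulate ---
    g = cfg["genome"]
    s = cfg["simulate"]
    genome = build_genome(g["n_chroms"], g["chrom_length_bp"], g["cpg_density"], seed,
                          with_sequence=g["with_sequence"])
    sim_cfg = SimulationConfig(
        n_replicates=s["n_replicates"], mean_coverage=s["mean_coverage"],
        dispersion=s["dispersion"], dmr_fraction=s["dmr_fraction"],
        hypo_fraction=s["hypo_fraction"], spikein_conversion=s["spikein"]["conversion_rate"],
        seed=seed)
    dmrs = default_dmr_specs(genome, sim_cfg, dmr_span_cpgs=s["dmr_span_cpgs"],
                             delta_magnitude=s["delta_magnitude"])
    # plant TF consensus sites near the centres of hypo regions before scanning
    hypo_centres = pd.DataFrame(
        [{"chrom": d.chrom, "pos": (d.start + d.end) // 2 + 1}
         for d in dmrs if d.direction == "hypo"])
    planting_log = pd.DataFrame()
    if g["with_sequence"] and len(hypo_centres):
        genome, planting_log = plant_motifs(genome, hypo_centres, "TGACTCA",
                                            s["planting_rate"], seed)
    methylomes, truth = simulate_methylomes(genome, dmrs, sim_cfg)
    spike = simulate_spikein(s["spikein"]["n_sites"], s["spikein"]["depth"],
                             s["spikein"]["conversion_rate"], seed)
    naive, effector, naive_track, eff_track = simulate_peaks_and_signal(
        genome, truth,
        PeakEnrichmentParams(enrichment_fraction=s["peaks"]["enrichment_fraction"],
                             max_offset=s["peaks"]["max_offset"],
                             n_background=s["peaks"]["n_background"]),
        seed)
    genes = simulate_genes(genome, s["n_genes"], seed)
    expression = simulate_expression(genes, truth, s["coupling"], seed)

    for m in methylomes:
        p = out / f"{m.sample_id}.cytosine_report.tsv"
        write_cytosine_report(m, p)
        files[f"report:{m.sample_id}"] = p
    truth.to_csv(out / "truth_dml.tsv", sep="\t", index=False)
    spike.to_csv(out / "spikein.tsv", sep="\t", index=False)
    write_bed(naive, out / "naive_peaks.bed")
    write_bed(effector, out / "effector_peaks.bed")
    write_bedgraph(naive_track, out / "naive_signal.bedgraph")
    write_bedgraph(eff_track, out / "effector_signal.bedgraph")
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    if genome.sequence is not None:
        write_fasta(genome, out / "genome.fa")
        files["genome"] = out / "genome.fa"
    if len(planting_log):
        planting_log.to_csv(out / "planting_log.tsv", sep="\t", index=False)
    for name in ("truth_dml", "spikein", "genes", "expression"):
        files[name] = out / f"{name}.tsv"
    for name in ("naive_peaks", "effector_peaks"):
        files[name] = out / f"{name}.bed"
    logger.info("simulate: %d CpGs, %d DMRs, %d truth DML", genome.n_cpgs, len(dmrs), len(truth))

    # --- stage 2: QC + filter ---
    f = cfg["filter"]
    conv = conversion_efficiency(spike, threshold=f["conversion_threshold"])
    conv.to_csv(out / "conversion_efficiency.tsv", sep="\t", index=False)
    files["conversion"] = out / "conversion_efficiency.tsv"
    matrix = coverage_filter(methylomes, min_cov=f["min_cov"], per_sample=f["per_sample"])
    glob = global_methylation_summary(matrix)
    (out / "global_summary.json").write_text(json.dumps(glob, indent=2, sort_keys=True))
    files["global_summary"] = out / "global_summary.json"
    logger.info("filter: %d CpGs retained, %d dropped", matrix.n_cpgs, matrix.n_dropped)

    # --- stage 3: DML test ---
    d = cfg["dml"]
    res = BetaBinomialDML(matrix).fit(fdr_threshold=d["fdr"], min_delta=d["min_delta"])
    res.table.to_csv(out / "dml_table.tsv", sep="\t", index=False)
    res.volcano_table().to_csv(out / "volcano.tsv", sep="\t", index=False)
    write_bedgraph(res.significance_profile(10_000), out / "significance_profile.bedgraph")
    (out / "dml_summary.json").write_text(json.dumps(res.direction_summary, indent=2, sort_keys=True))
    for name in ("dml_table", "volcano"):
        files[name] = out / f"{name}.tsv"
    files["dml_summary"] = out / "dml_summary.json"
    logger.info("dml: %s", res.direction_summary)

    # --- stage 4: annotate + integrate ---
    sig = res.dml
    annotated = nearest_tss(sig, genes)
    annotated.to_csv(out / "annotated_dml.tsv", sep="\t", index=False)
    files["annotated_dml"] = out / "annotated_dml.tsv"
    joined, integ = integrate_expression(annotated, expression)
    ranks = rank_genes_by_dml(joined)
    ranks.to_csv(out / "gene_ranks.tsv", sep="\t", index=False)
    files["gene_ranks"] = out / "gene_ranks.tsv"
    (out / "integration_summary.json").write_text(json.dumps(integ, indent=2, sort_keys=True))
    files["integration_summary"] = out / "integration_summary.json"

    # --- stage 5: interval enrichment ---
    e = cfg["enrich"]
    merged = merge_peaks(naive, effector)
    perm = permutation_overlap_test(sig, merged, genome, e["windows"],
                                    n_perm=e["n_perm"], seed=seed)
    (out / "enrichment.json").write_text(json.dumps([r.to_dict() for r in perm],
                                                    indent=2, sort_keys=True))
    pd.DataFrame({f"w{r.window}": r.permuted_counts for r in perm}).to_csv(
        out / "permuted_counts.tsv", sep="\t", index=False)
    files["enrichment"] = out / "enrichment.json"
    files["permuted_counts"] = out / "permuted_counts.tsv"
    prof = cfg["profile"]
    prof_naive, _, _ = aggregate_signal(naive_track, sig, flank=prof["flank"],
                                        n_bins=prof["n_bins"])
    prof_eff, _, _ = aggregate_signal(eff_track, sig, flank=prof["flank"],
                                      n_bins=prof["n_bins"])
    if len(sig) >= 2:
        comp = compare_anchor_signal(prof_naive, prof_eff)
        comp.pop("per_anchor_means")
        (out / "signal_comparison.json").write_text(json.dumps(comp, indent=2, sort_keys=True))
        files["signal_comparison"] = out / "signal_comparison.json"

    # --- stage 6: motifs ---
    mo = cfg["motifs"]
    motif_table = pd.DataFrame()
    if genome.sequence is not None:
        flank = mo["size"] // 2
        hypo_sig = sig[sig["direction"] == "hypo"]
        fg_anchors = hypo_sig[["chrom", "pos"]].head(mo["max_foreground"])
        if len(fg_anchors):
            fg = extract_windows(genome, fg_anchors, flank)
            bg = sample_background_windows(genome, fg_anchors, flank=flank, seed=seed)
            pwms = bundled_pwms()
            motif_table = motif_enrichment(fg, bg, pwms)
            motif_table.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
            files["motif_enrichment"] = out / "motif_enrichment.tsv"
            top = [p for p in pwms if p.name == "AP1"]
            hits = scan_pwm(fg, top[0]) if top else []
            if hits:
                profiles = motif_centered_profiles(
                    hits, matrix, {"naive": naive_track, "effector": eff_track}, flank=200)
                profiles.to_csv(out / "motif_profiles.tsv", sep="\t", index=False)
                files["motif_profiles"] = out / "motif_profiles.tsv"

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "elapsed_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "digests": {k: _digest(p) for k, p in sorted(files.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete in %.1fs; %d artifacts", manifest["elapsed_s"], len(files))
    return manifest
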