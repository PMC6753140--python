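"""End-to-end orchestration: simulate/load -> score -> classify -> model.

Stages run in dependency order and communicate only through their output
tables; a machine-readable manifest (inputs, thresholds, seed, output
hashes) makes reruns verifiable.  Thresholds default to the analysis
constants used throughout the package (probe filter 45 bp / 0.90; domain
merge 300 kb; hyper-CGI 2 SD; aneuploidy 0.2 with 10% arm / 5% chromosome;
regression FDR 0.05; enrichment FDR 0.25 with minimum set size 10;
30/70 percentile cuts; 10,000 permutations).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import association_models as am
from . import genomic_instability as gi
from . import io
from . import methylation_core as mc
from . import pmd_domains as pmd
from . import replication_timing as rt
from . import survival_clinical as sv
from .synthetic_data import CohortBundle, SimulationConfig, simulate_cohort

log = logging.getLogger("methylink")


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    outdir: str = "methylink_out"
    simulate: bool = True
    seed: int = 1234
    sim: SimulationConfig | None = None
    # input paths, used when simulate is False
    paths: dict[str, str] = field(default_factory=dict)
    # analysis constants
    min_mapped_bp: int = 45
    min_mapped_fraction: float = 0.90
    min_domain_length: int = 300_000
    n_pmd_clusters: int = 3
    hyper_sd_multiplier: float = 2.0
    aneuploidy_threshold: float = 0.2
    regression_fdr: float = 0.05
    enrichment_fdr: float = 0.25
    min_set_size: int = 10
    percentile_low: float = 30.0
    percentile_high: float = 70.0
    n_perm_proximity: int = 10_000
    n_perm_enrichment: int = 1000


def _sha1(path: str) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, bundle: CohortBundle | None = None) -> dict:
    """Execute all stages; returns the run manifest (also written as JSON)."""
    io.ensure_dir(cfg.outdir)
    results: dict = {"stages": {}, "seed": cfg.seed, "thresholds": {}}
    results["thresholds"] = {
        k: getattr(cfg, k)
        for k in (
            "min_mapped_bp", "min_mapped_fraction", "min_domain_length", "hyper_sd_multiplier",
            "aneuploidy_threshold", "regression_fdr", "enrichment_fdr", "min_set_size",
            "percentile_low", "percentile_high", "n_perm_proximity",
        )
    }
    outputs: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str, **kw) -> str:
        path = os.path.join(cfg.outdir, name)
        df.to_csv(path, sep="\t", **kw)
        outputs[name] = path
        return path

    # ---- stage: inputs -------------------------------------------------
    if bundle is None and cfg.simulate:
        sim = cfg.sim if cfg.sim is not None else SimulationConfig(seed=cfg.seed)
        log.info("simulating cohort (seed=%d, n=%d)", sim.seed, sim.n_samples)
        bundle = simulate_cohort(sim)
    if bundle is not None:
        manifest_df = bundle.manifest
        beta = bundle.beta
        domains = bundle.domains[["chrom", "start", "end", "dtype", "meth_variability", "rep_timing"]]
        segments = bundle.segments
        geom = bundle.config.geometry()
        gene_models = bundle.gene_models
        expression = bundle.expression
        clinical = bundle.cohort
        tracks, track_groups = bundle.tracks, bundle.track_groups
        immune_genes = set(bundle.immune_genes)
    else:
        p = cfg.paths
        manifest_df = io.read_probe_manifest(p["probe_manifest"])
        beta = io.read_beta_matrix(p["beta_matrix"])
        domains = io.read_domains(p["domains"])
        segments = io.read_segments(p["segments"])
        geom = io.read_genome_geometry(p["genome"])
        gene_models = io.read_gene_models(p["genes"])
        expression = io.read_expression(p["expression"]) if "expression" in p else None
        clinical = io.read_clinical(p["clinical"]).set_index("sample_id") if "clinical" in p else None
        tracks = track_groups = None
        if "tracks" in p:
            # JSON mapping {"normal": {line: bedgraph_path}, "cancer": {...}}
            with open(p["tracks"]) as fh:
                track_paths = json.load(fh)
            flat = {line: path for d in track_paths.values() for line, path in d.items()}
            tracks = io.read_track_set(flat)
            track_groups = {g: list(d.keys()) for g, d in track_paths.items()}
        immune_genes = set(open(p["immune_genes"]).read().split()) if "immune_genes" in p else set()

    # ---- stage: global methylation ------------------------------------
    l1_probes = mc.select_l1_probes(manifest_df)
    gms = mc.global_methylation(beta, l1_probes)
    save(gms, "global_methylation.tsv")
    results["stages"]["global_methylation"] = {"n_probes": len(l1_probes), "n_samples": len(gms)}

    # ---- stage: domains ------------------------------------------------
    merged = pmd.merge_domains(domains, min_length=cfg.min_domain_length)
    dropped_bp = int((domains["end"] - domains["start"]).sum() - (merged["end"] - merged["start"]).sum())
    log.info("domain merge: %d merged domains, %d bp dropped by the >%d bp filter",
             len(merged), dropped_bp, cfg.min_domain_length)
    clustered = pmd.cluster_pmds(merged, k=cfg.n_pmd_clusters)
    save(clustered, "pmd_clusters.tsv", index=False)
    short_pmds = clustered[clustered["is_short"]][["chrom", "start", "end"]]
    merged_hmds = merged[merged["dtype"] == "HMD"]
    results["stages"]["domains"] = {
        "n_merged": len(merged), "n_pmds": int((merged["dtype"] == "PMD").sum()),
        "n_short_pmds": len(short_pmds), "dropped_bp": dropped_bp,
    }

    # ---- stage: hyper-CGI count ---------------------------------------
    hyper = mc.count_hypermethylated_short_pmd_cgi(beta, manifest_df, merged_hmds, short_pmds)
    save(hyper, "hyper_cgi_counts.tsv")
    results["stages"]["hyper_cgi"] = {"n_samples": len(hyper)}

    # ---- stage: aneuploidy --------------------------------------------
    flagged = gi.call_qualifying_segments(segments, geom, threshold=cfg.aneuploidy_threshold)
    aneu = gi.aneuploidy_level(flagged, geom)
    save(aneu, "aneuploidy.tsv")
    results["stages"]["aneuploidy"] = {"n_samples": len(aneu)}

    # ---- stage: replication timing ------------------------------------
    gene_timing = None
    if tracks is not None:
        groups = rt.TrackGroups(normal=tuple(track_groups["normal"]), cancer=tuple(track_groups["cancer"]))
        norm = rt.normalize_tracks(tracks, groups)
        wstats = rt.window_ttest(norm, groups)
        autosomal = gene_models[~gene_models["chrom"].isin({"chrX", "chrY", "X", "Y"})]
        tested_genes = autosomal[~autosomal["gene_id"].isin(immune_genes)] if immune_genes else autosomal
        gene_timing = rt.gene_level_timing(wstats, tested_genes)
        save(gene_timing, "gene_timing.tsv", index=False)
        results["stages"]["replication_timing"] = {
            "n_windows": len(norm),
            "n_late": int((gene_timing["class"] == rt.CLASS_LATE).sum()),
            "n_early": int((gene_timing["class"] == rt.CLASS_EARLY).sum()),
        }
    else:
        results["stages"]["replication_timing"] = "skipped (no tracks)"

    # ---- stage: proximity ----------------------------------------------
    if immune_genes:
        pmd_intervals = merged[merged["dtype"] == "PMD"][["chrom", "start", "end"]]
        universe = _genes_in_intervals(gene_models, pmd_intervals)
        test_set = immune_genes & universe
        hmd_units = domains[domains["dtype"] == "HMD"]
        prox = pmd.proximity_permutation_test(
            test_set, universe, hmd_units, gene_models,
            n_perm=cfg.n_perm_proximity, seed=cfg.seed,
        )
        results["stages"]["proximity"] = {
            "observed_mean_distance_bp": prox.observed_mean_distance,
            "null_mean_bp": float(np.mean(prox.null_means)),
            "p_empirical": prox.p_empirical,
            "n_test_genes": len(test_set),
            "n_universe": len(universe),
        }
    else:
        results["stages"]["proximity"] = "skipped (no immune gene set)"

    # ---- stage: association -------------------------------------------
    feature_cols = {"mutation_burden", "purity", "age", "stage"}
    if expression is not None and clinical is not None and feature_cols <= set(clinical.columns):
        features = pd.DataFrame(
            {
                "global_methylation": gms["score"],
                "mutation_burden": clinical["mutation_burden"],
                "aneuploidy": aneu["level"],
                "purity": clinical["purity"],
                "age": clinical["age"],
                "stage": clinical["stage"],
            }
        ).dropna()
        include_stage = features["stage"].notna().sum() >= 100
        fits = am.fit_gene_models(expression[features.index], features,
                                  include_stage=include_stage, fdr_alpha=cfg.regression_fdr)
        save(fits["z"], "regression_z.tsv")
        save(fits["q"], "regression_q.tsv")
        # rank by the demethylation-association z (sign convention: genes
        # repressed upon methylation loss rank at the negative extreme)
        ranking = -fits["z"]["global_methylation"]
        enr = am.preranked_enrichment(
            ranking, {"immune_planted": immune_genes} if immune_genes else {},
            n_perm=cfg.n_perm_enrichment, min_set_size=cfg.min_set_size, seed=cfg.seed,
        )
        if not enr.empty:
            save(enr, "enrichment.tsv")
            results["stages"]["association"] = {
                "include_stage": bool(include_stage),
                "immune_nes": float(enr["nes"].iloc[0]),
                "immune_fdr": float(enr["fdr"].iloc[0]),
            }
        else:
            results["stages"]["association"] = {"include_stage": bool(include_stage)}
    else:
        results["stages"]["association"] = "skipped (needs expression and clinical)"

    # ---- stage: group comparisons and survival ------------------------
    if clinical is not None:
        groups_med = sv.stratify(gms["score"], rule="median")
        per_sample = pd.DataFrame(
            {
                "aneuploidy": aneu["level"],
                "hyper_cgi_count": hyper["hyper_cgi_count"],
            }
        )
        if "mutation_burden" in clinical.columns:
            per_sample["mutation_burden"] = clinical["mutation_burden"]
        comps = {}
        for col in per_sample.columns:
            comps[col] = am.group_compare(per_sample[col], groups_med, test="mannwhitney")
        results["stages"]["group_compare"] = comps

        fit = sv.km_logrank(clinical, groups_med)
        for g, curve in fit.km_curves.items():
            save(curve, f"km_{g}.tsv")
        results["stages"]["survival"] = {
            "logrank_chi2": fit.logrank_chi2,
            "logrank_p": fit.logrank_p,
            "hr_low_vs_high": fit.hr,
            "hr_ci": list(fit.hr_ci),
        }
        if "response" in clinical.columns and clinical["response"].notna().any():
            covs = pd.DataFrame(
                {
                    "global_methylation_z": (gms["score"] - gms["score"].mean()) / gms["score"].std(),
                    "log_mutation_burden": np.log10(1.0 + clinical["mutation_burden"]),
                }
            )
            logit = sv.response_logistic(clinical["response"], covs)
            save(logit, "response_logistic.tsv")
            results["stages"]["response"] = {
                "or_methylation": float(logit.loc["global_methylation_z", "odds_ratio"]),
                "p_methylation": float(logit.loc["global_methylation_z", "p"]),
            }
    else:
        results["stages"]["group_compare"] = "skipped (no clinical table)"
        results["stages"]["survival"] = "skipped (no clinical table)"

    results["outputs"] = {name: _sha1(path) for name, path in sorted(outputs.items())}
    manifest_path = os.path.join(cfg.outdir, "run_manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=str)
    return results


def _genes_in_intervals(gene_models: pd.DataFrame, intervals: pd.DataFrame) -> set[str]:
    """Gene ids whose body overlaps any of the given intervals."""
    from ._intervals import overlap_lengths

    out = set()
    for chrom, sub in intervals.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        s, e = sub["start"].to_numpy(), sub["end"].to_numpy()
        for g in gene_models[gene_models["chrom"] == chrom].itertuples(index=False):
            idx, _ = overlap_lengths(g.start, g.end, s, e)
            if idx.size:
                out.add(g.gene_id)
    return out
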