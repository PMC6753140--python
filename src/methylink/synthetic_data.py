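"""Synthetic multi-omic cohorts with a planted latent demethylation factor.

Every downstream stage of the pipeline is exercisable without external
data: the generator plants a single per-sample latent factor ``d`` (the
extent of genome-wide demethylation, uniform on [0, 1]) and couples it,
with the signs the biology dictates, to

* open-sea LINE-1 probe betas        (decreasing in d),
* promoter-CGI hypermethylation in short PMDs (probability increasing in d),
* mutation burden                    (log-mean increasing in d),
* large-scale copy-number events     (rate increasing in d),
* immune-gene expression             (decreasing in d),
* post-treatment hazard              (higher in the low-methylation group,
                                      hazard ratio ``planted_hr``).

The low/high methylation groups are defined by the median of the realized
global L1 score, matching the cohort analysis convention.  All randomness
flows from one ``numpy`` generator seeded by the config, so a fixed seed
gives bit-identical bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

UNIT = 100_000  # domain call resolution in bp
DEFAULT_GENOME: tuple[tuple[str, int, int], ...] = (
    ("chr1", 60_000_000, 25_000_000),
    ("chr2", 45_000_000, 20_000_000),
    ("chr3", 30_000_000, 12_000_000),
)


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the clinical setting the pipeline targets: a combined
    immunotherapy cohort of 141 samples, a hazard ratio of 2 for the
    demethylated (low-methylation) group, moderate array noise, and a
    quarter-beta open-sea loss across the full latent range.
    """

    n_samples: int = 141
    n_l1_probes: int = 300
    n_hmd_cgi_probes: int = 200
    n_shortpmd_promoter_probes: int = 150
    n_genes: int = 1000
    genome: tuple[tuple[str, int, int], ...] = DEFAULT_GENOME
    planted_hr: float = 2.0
    beta_noise_sd: float = 0.05
    demethylation_effect: float = 0.25
    hyperme_gain_rate: float = 0.4
    mutation_link: float = 1.5
    cna_link: float = 5.0
    seed: int = 1234
    # secondary knobs (free parameters of the generator, not claims about biology)
    l1_baseline: float = 0.75
    cgi_baseline: float = 0.10
    n_immune_genes: int = 77
    n_pmd_background_genes: int = 400
    immune_repression_effect: float = 1.5
    median_pfs_high_days: float = 180.0
    censor_fraction: float = 0.30
    missing_beta_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_l1_probes", "n_hmd_cgi_probes", "n_shortpmd_promoter_probes", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.planted_hr <= 0:
            raise ConfigError("planted_hr must be > 0")
        if self.beta_noise_sd < 0:
            raise ConfigError("beta_noise_sd must be >= 0")
        for chrom, length, cen in self.genome:
            if not (0 < cen < length):
                raise ConfigError(f"genome: centromere of {chrom} must satisfy 0 < centromere < length")
        if self.n_immune_genes + self.n_pmd_background_genes > self.n_genes:
            raise ConfigError("n_genes must cover immune + PMD background genes")

    def geometry(self) -> pd.DataFrame:
        return pd.DataFrame(self.genome, columns=["chrom", "length", "centromere"])


@dataclass
class LatentState:
    """Planted per-sample truth: demethylation extent and realized group."""

    d: pd.Series
    group: pd.Series


@dataclass
class CohortBundle:
    """Everything one simulated cohort produces, keyed by shared sample ids."""

    config: SimulationConfig
    manifest: pd.DataFrame
    beta: pd.DataFrame
    domains: pd.DataFrame
    merged_domains: pd.DataFrame
    segments: pd.DataFrame
    expression: pd.DataFrame
    gene_models: pd.DataFrame
    tracks: pd.DataFrame
    track_groups: dict[str, list[str]]
    cohort: pd.DataFrame
    latent: LatentState
    immune_genes: list[str]
    short_pmds: pd.DataFrame
    l1_probe_ids: list[str]


# ---------------------------------------------------------------------------
# domain landscape

_PMD_CLASSES = {
    # name: (units_lo, units_hi, variability_mean, timing_mean)
    "short": (4, 8, 0.14, 1.0),
    "mid": (9, 14, 0.18, 0.0),
    "long": (15, 30, 0.22, -1.0),
}
_HMD_PARAMS = (5, 15, 0.03, 1.2)


def _simulate_domains(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Tile each chromosome with alternating HMD / PMD runs of 100-kb units."""
    rows = []
    for chrom, length, _cen in cfg.genome:
        n_units = length // UNIT
        pos = 0
        next_is_hmd = True
        while pos < n_units:
            if next_is_hmd:
                lo, hi, var_mu, tim_mu = _HMD_PARAMS
                dtype, cls = "HMD", "HMD"
            else:
                cls = rng.choice(["short", "mid", "long", "tiny"], p=[0.35, 0.25, 0.2, 0.2])
                if cls == "tiny":  # merged length <= 300 kb: dropped by the merge filter
                    lo, hi, var_mu, tim_mu = 2, 3, 0.18, 0.0
                else:
                    lo, hi, var_mu, tim_mu = _PMD_CLASSES[cls]
                dtype = "PMD"
            run = int(rng.integers(lo, hi + 1))
            run = min(run, n_units - pos)
            var = var_mu + rng.normal(0, 0.008)
            tim = tim_mu + rng.normal(0, 0.1)
            for u in range(run):
                rows.append(
                    {
                        "chrom": chrom,
                        "start": (pos + u) * UNIT,
                        "end": (pos + u + 1) * UNIT,
                        "dtype": dtype,
                        "meth_variability": max(var + rng.normal(0, 0.004), 0.001),
                        "rep_timing": tim + rng.normal(0, 0.05),
                        "planted_class": cls,
                    }
                )
            pos += run
            next_is_hmd = not next_is_hmd
    return pd.DataFrame(rows)


def _planted_runs(domains: pd.DataFrame, planted_class: str) -> pd.DataFrame:
    """Contiguous runs of units of one planted class, as merged intervals."""
    sel = domains[domains["planted_class"] == planted_class]
    rows = []
    for chrom, sub in sel.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        start = prev_end = None
        for r in sub.itertuples(index=False):
            if start is None:
                start, prev_end = r.start, r.end
            elif r.start == prev_end:
                prev_end = r.end
            else:
                rows.append({"chrom": chrom, "start": start, "end": prev_end})
                start, prev_end = r.start, r.end
        if start is not None:
            rows.append({"chrom": chrom, "start": start, "end": prev_end})
    return pd.DataFrame(rows)


def _place_probes_in(
    intervals: pd.DataFrame, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """n random (chrom, pos) pairs uniform over the given intervals."""
    lens = (intervals["end"] - intervals["start"]).to_numpy(dtype=float)
    pick = rng.choice(len(intervals), size=n, p=lens / lens.sum())
    offs = (rng.random(n) * lens[pick]).astype(np.int64)
    chroms = intervals["chrom"].to_numpy()[pick]
    pos = intervals["start"].to_numpy()[pick] + offs
    return chroms, pos


def _simulate_manifest(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    hmd_runs: pd.DataFrame,
    short_runs: pd.DataFrame,
) -> pd.DataFrame:
    rows = []
    fams = ["L1HS", "L1PA2", "L1PA3", "L1PA4"]
    chroms, pos = _place_probes_in(hmd_runs, cfg.n_l1_probes, rng)
    for i in range(cfg.n_l1_probes):
        rows.append(
            {
                "probe_id": f"L1_{i:05d}",
                "chrom": chroms[i],
                "pos": int(pos[i]),
                "cgi_class": "opensea",
                "promoter_flag": False,
                "repeat_family": fams[i % len(fams)],
                "mapped_len": int(rng.integers(46, 51)),
                "probe_len": 50,
                "layer": "l1",
            }
        )
    chroms, pos = _place_probes_in(hmd_runs, cfg.n_hmd_cgi_probes, rng)
    for i in range(cfg.n_hmd_cgi_probes):
        rows.append(
            {
                "probe_id": f"HMDCGI_{i:05d}",
                "chrom": chroms[i],
                "pos": int(pos[i]),
                "cgi_class": "island",
                "promoter_flag": bool(i % 2),
                "repeat_family": None,
                "mapped_len": 0,
                "probe_len": 50,
                "layer": "hmd_cgi",
            }
        )
    chroms, pos = _place_probes_in(short_runs, cfg.n_shortpmd_promoter_probes, rng)
    for i in range(cfg.n_shortpmd_promoter_probes):
        rows.append(
            {
                "probe_id": f"SPMD_{i:05d}",
                "chrom": chroms[i],
                "pos": int(pos[i]),
                "cgi_class": "island",
                "promoter_flag": True,
                "repeat_family": None,
                "mapped_len": 0,
                "probe_len": 50,
                "layer": "shortpmd_promoter",
            }
        )
    # decoys that must fail the L1 probe filter
    chroms, pos = _place_probes_in(hmd_runs, 30, rng)
    decoy_specs = [("AluY", 50, 50), ("L1HS", 44, 50), ("L1PA2", 45, 60)]
    for i in range(30):
        fam, mapped, plen = decoy_specs[i % 3]
        rows.append(
            {
                "probe_id": f"DECOY_{i:05d}",
                "chrom": chroms[i],
                "pos": int(pos[i]),
                "cgi_class": "opensea",
                "promoter_flag": False,
                "repeat_family": fam,
                "mapped_len": mapped,
                "probe_len": plen,
                "layer": "decoy",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# layers


def _simulate_beta(
    cfg: SimulationConfig, rng: np.random.Generator, manifest: pd.DataFrame, d: np.ndarray
) -> pd.DataFrame:
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    n = cfg.n_samples
    blocks = []
    for layer, sub in manifest.groupby("layer", sort=False):
        k = len(sub)
        if cfg.beta_noise_sd > 0:
            noise = rng.normal(0.0, cfg.beta_noise_sd, size=(k, n))
        else:
            noise = np.zeros((k, n))
        if layer in ("l1", "decoy"):
            base = cfg.l1_baseline - cfg.demethylation_effect * d[None, :]
            vals = base + noise
        elif layer == "hmd_cgi":
            vals = cfg.cgi_baseline + noise
        else:  # shortpmd_promoter
            p_hyper = np.clip(cfg.hyperme_gain_rate * d, 0.0, 1.0)
            hyper = rng.random((k, n)) < p_hyper[None, :]
            vals = cfg.cgi_baseline + 0.02 + 0.5 * hyper + noise
        blocks.append(pd.DataFrame(vals, index=sub["probe_id"], columns=samples))
    beta = pd.concat(blocks).reindex(manifest["probe_id"])
    beta = beta.clip(lower=0.001, upper=0.999)
    if cfg.missing_beta_rate > 0:
        mask = rng.random(beta.shape) < cfg.missing_beta_rate
        beta = beta.mask(mask)
    beta.index.name = "probe_id"
    return beta


def _simulate_gene_models(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    short_runs: pd.DataFrame,
    pmd_runs: pd.DataFrame,
    hmd_runs: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Gene bodies: immune genes hug short-PMD edges, others sit anywhere."""
    rows = []
    immune_ids = [f"IMM_{i:04d}" for i in range(cfg.n_immune_genes)]
    runs = short_runs.reset_index(drop=True)
    for i, gid in enumerate(immune_ids):
        run = runs.iloc[int(rng.integers(0, len(runs)))]
        glen = int(rng.integers(5_000, 30_000))
        offset = int(rng.integers(5_000, 60_000))
        if rng.random() < 0.5:
            start = run["start"] + offset
        else:
            start = run["end"] - offset - glen
        start = int(np.clip(start, run["start"], run["end"] - glen - 1))
        rows.append({"chrom": run["chrom"], "start": start, "end": start + glen, "gene_id": gid})
    pmd_ids = [f"PMDG_{i:04d}" for i in range(cfg.n_pmd_background_genes)]
    chroms, pos = _place_probes_in(pmd_runs, len(pmd_ids), rng)
    for i, gid in enumerate(pmd_ids):
        glen = int(rng.integers(5_000, 30_000))
        rows.append({"chrom": chroms[i], "start": int(pos[i]), "end": int(pos[i]) + glen, "gene_id": gid})
    n_bg = cfg.n_genes - cfg.n_immune_genes - cfg.n_pmd_background_genes
    chroms, pos = _place_probes_in(hmd_runs, n_bg, rng)
    for i in range(n_bg):
        glen = int(rng.integers(5_000, 30_000))
        rows.append({"chrom": chroms[i], "start": int(pos[i]), "end": int(pos[i]) + glen, "gene_id": f"BG_{i:04d}"})
    models = pd.DataFrame(rows)
    chrom_len = {c: l for c, l, _ in cfg.genome}
    limits = models["chrom"].map(chrom_len)
    models["start"] = np.minimum(models["start"], limits - 2_000)
    models["end"] = np.minimum(models["end"], limits)
    models = models.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return models, immune_ids


def _simulate_expression(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    gene_ids: list[str],
    immune_ids: list[str],
    d: np.ndarray,
    samples: list[str],
) -> pd.DataFrame:
    zd = (d - d.mean()) / (d.std() if d.std() > 0 else 1.0)
    expr = rng.normal(0.0, 1.0, size=(len(gene_ids), len(samples)))
    imm_mask = np.isin(gene_ids, immune_ids)
    expr[imm_mask] -= cfg.immune_repression_effect * zd[None, :]
    return pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"), columns=samples)


def _simulate_segments(
    cfg: SimulationConfig, rng: np.random.Generator, d: np.ndarray, samples: list[str]
) -> pd.DataFrame:
    geom = cfg.geometry()
    rows = []
    for j, sample in enumerate(samples):
        n_events = rng.poisson(0.3 + cfg.cna_link * d[j])
        for _ in range(n_events):
            c = geom.iloc[int(rng.integers(0, len(geom)))]
            if rng.random() < 0.5:
                arm_start, arm_end = 0, int(c["centromere"])
            else:
                arm_start, arm_end = int(c["centromere"]), int(c["length"])
            arm_len = arm_end - arm_start
            seg_len = int(rng.uniform(0.15, 0.6) * arm_len)
            start = arm_start + int(rng.uniform(0, arm_len - seg_len))
            log2 = float(rng.choice([-1, 1]) * (0.25 + rng.exponential(0.2)))
            rows.append(
                {"sample_id": sample, "chrom": c["chrom"], "start": start, "end": start + seg_len, "log2_ratio": log2}
            )
        for _ in range(2):  # small, low-ratio decoy segments that must not qualify
            c = geom.iloc[int(rng.integers(0, len(geom)))]
            seg_len = int(0.01 * c["length"])
            start = int(rng.uniform(0, c["length"] - seg_len))
            rows.append(
                {
                    "sample_id": sample,
                    "chrom": c["chrom"],
                    "start": start,
                    "end": start + seg_len,
                    "log2_ratio": float(rng.normal(0.0, 0.05)),
                }
            )
    return pd.DataFrame(rows)


def _censor_horizon(cfg: SimulationConfig, rate_high: float, rate_low: float) -> float:
    """Administrative horizon giving the configured expected censoring fraction."""
    target = cfg.censor_fraction

    def frac_censored(c: float) -> float:
        return 0.5 * math.exp(-rate_high * c) + 0.5 * math.exp(-rate_low * c) - target

    return float(brentq(frac_censored, 1.0, 1e6))


def _simulate_clinical(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    d: np.ndarray,
    group: pd.Series,
    samples: list[str],
) -> pd.DataFrame:
    from .survival_clinical import classify_response

    rate_high = math.log(2.0) / cfg.median_pfs_high_days
    rate_low = cfg.planted_hr * rate_high
    horizon = _censor_horizon(cfg, rate_high, rate_low)
    rates = np.where(group.to_numpy() == "low", rate_low, rate_high)
    t_event = rng.exponential(1.0 / rates)
    pfs = np.minimum(t_event, horizon)
    event = t_event <= horizon
    pfs = np.maximum(pfs, 0.5)  # PFS is recorded in half-day resolution at minimum

    labels, durations, responses = [], [], []
    for j in range(len(samples)):
        p_pr = float(np.clip(0.45 - 0.30 * d[j], 0.05, 0.95))
        p_pd = float(np.clip(0.25 + 0.30 * d[j], 0.05, 0.90 - p_pr))
        label = rng.choice(["PR", "PD", "SD"], p=[p_pr, p_pd, 1.0 - p_pr - p_pd])
        dur = float(rng.exponential(8.0 * (1.0 - 0.4 * d[j]))) if label == "SD" else float("nan")
        labels.append(label)
        durations.append(dur)
        responses.append(classify_response(label, dur if label == "SD" else None))
    return pd.DataFrame(
        {
            "sample_id": samples,
            "pfs_time": pfs,
            "event": event,
            "best_response": labels,
            "sd_duration_months": durations,
            "response": responses,
            "purity": rng.uniform(0.3, 0.9, size=len(samples)),
            "age": np.clip(rng.normal(64.0, 9.0, size=len(samples)), 30, 90),
            "stage": rng.choice([1, 2, 3, 4], p=[0.2, 0.3, 0.3, 0.2], size=len(samples)),
        }
    ).set_index("sample_id")


# ---------------------------------------------------------------------------
# replication timing tracks


def simulate_replication_tracks(
    cfg: SimulationConfig,
    gene_models: pd.DataFrame,
    late_gene_ids: list[str] | None = None,
    shift: float = 1.5,
    noise_sd: float = 0.4,
    n_normal: int = 5,
    n_cancer: int = 10,
    missing_rate: float = 0.01,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Wavelet-smoothed-style replication signal on a 5-kb grid per cell line.

    A designated gene subset is planted as later-replicating in cancer: the
    cancer lines' signal drops by ``shift`` on every window the gene bodies
    overlap.  A ``missing_rate`` fraction of (window, line) cells is NaN so
    downstream exclusion of incomplete windows is exercised.  Genes outside
    the configured genome raise a coordinate error.
    """
    chrom_len = {c: l for c, l, _ in cfg.genome}
    for g in gene_models.itertuples(index=False):
        if g.chrom not in chrom_len or g.end > chrom_len[g.chrom] or g.start < 0:
            raise ValueError(f"gene {g.gene_id} outside the configured genome")
    rng = np.random.default_rng(cfg.seed + 7_919 if seed is None else seed)
    window = 5_000
    frames = []
    for chrom, length, _ in cfg.genome:
        n_win = length // window
        starts = np.arange(n_win, dtype=np.int64) * window
        base = np.cumsum(rng.normal(0.0, 0.15, size=n_win))
        base = (base - base.mean()) / (base.std() if base.std() > 0 else 1.0)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + window, "_base": base}))
    tracks = pd.concat(frames, ignore_index=True)

    late = set(late_gene_ids or [])
    late_mask = np.zeros(len(tracks), dtype=bool)
    if late:
        for chrom, sub in tracks.groupby("chrom", sort=False):
            genes = gene_models[(gene_models["gene_id"].isin(late)) & (gene_models["chrom"] == chrom)]
            if genes.empty:
                continue
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            m = np.zeros(len(sub), dtype=bool)
            for g in genes.itertuples(index=False):
                m |= (s < g.end) & (e > g.start)
            late_mask[sub.index] = m

    normal = [f"NORM{i}" for i in range(n_normal)]
    cancer = [f"CANC{i}" for i in range(n_cancer)]
    for line in normal:
        tracks[line] = tracks["_base"] + rng.normal(0.0, noise_sd, size=len(tracks))
    for line in cancer:
        vals = tracks["_base"] + rng.normal(0.0, noise_sd, size=len(tracks))
        vals = vals - shift * late_mask
        tracks[line] = vals
    tracks = tracks.drop(columns="_base")
    if missing_rate > 0:
        for line in normal + cancer:
            mask = rng.random(len(tracks)) < missing_rate / (n_normal + n_cancer)
            tracks.loc[mask, line] = np.nan
    return tracks, {"normal": normal, "cancer": cancer}


# ---------------------------------------------------------------------------
# top level


def simulate_cohort(cfg: SimulationConfig) -> CohortBundle:
    """Generate one internally consistent cohort bundle from the config."""
    from .pmd_domains import merge_domains

    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    d = rng.uniform(0.0, 1.0, size=cfg.n_samples)

    domains = _simulate_domains(cfg, rng)
    hmd_runs = _planted_runs(domains, "HMD")
    short_runs = _planted_runs(domains, "short")
    pmd_runs = pd.concat(
        [_planted_runs(domains, c) for c in ("short", "mid", "long")], ignore_index=True
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    manifest = _simulate_manifest(cfg, rng, hmd_runs, short_runs)
    beta = _simulate_beta(cfg, rng, manifest, d)
    gene_models, immune_ids = _simulate_gene_models(cfg, rng, short_runs, pmd_runs, hmd_runs)
    expression = _simulate_expression(cfg, rng, gene_models["gene_id"].tolist(), immune_ids, d, samples)
    segments = _simulate_segments(cfg, rng, d, samples)

    l1_ids = manifest.loc[manifest["layer"] == "l1", "probe_id"].tolist()
    global_score = beta.loc[l1_ids].mean(axis=0, skipna=True)
    med = global_score.median()
    group = pd.Series(np.where(global_score <= med, "low", "high"), index=global_score.index, name="group")

    clinical = _simulate_clinical(cfg, rng, d, group, samples)
    tracks, track_groups = simulate_replication_tracks(cfg, gene_models, late_gene_ids=immune_ids)

    d_series = pd.Series(d, index=samples, name="d")
    cohort = clinical.copy()
    cohort["global_methylation"] = global_score
    cohort["group"] = group
    mu = np.exp(np.log(30.0) + cfg.mutation_link * (d - 0.5))
    cohort["mutation_burden"] = rng.poisson(mu)
    cohort["d"] = d_series

    merged = merge_domains(domains[["chrom", "start", "end", "dtype", "meth_variability", "rep_timing"]])
    short_pmds = short_runs.copy()
    return CohortBundle(
        config=cfg,
        manifest=manifest,
        beta=beta,
        domains=domains,
        merged_domains=merged,
        segments=segments,
        expression=expression,
        gene_models=gene_models,
        tracks=tracks,
        track_groups=track_groups,
        cohort=cohort,
        latent=LatentState(d=d_series, group=group),
        immune_genes=immune_ids,
        short_pmds=short_pmds,
        l1_probe_ids=l1_ids,
    )


def write_bundle(bundle: CohortBundle, outdir: str) -> dict[str, str]:
    """Write every table of the bundle as plain text under ``outdir``."""
    from . import io

    io.ensure_dir(outdir)
    paths = {}

    def _p(name: str) -> str:
        paths[name] = f"{outdir}/{name}"
        return paths[name]

    io.write_probe_manifest(bundle.manifest, _p("probe_manifest.tsv"))
    io.write_beta_matrix(bundle.beta, _p("beta_matrix.tsv"))
    io.write_domains(bundle.domains[["chrom", "start", "end", "dtype", "meth_variability", "rep_timing"]], _p("domains.bed"))
    io.write_segments(bundle.segments, _p("segments.seg"))
    io.write_genome_geometry(bundle.config.geometry(), _p("genome.tsv"))
    io.write_gene_models(bundle.gene_models, _p("genes.bed"))
    io.write_expression(bundle.expression, _p("expression.tsv"))
    bundle.cohort.to_csv(_p("clinical.tsv"), sep="\t")
    for grp, lines in bundle.track_groups.items():
        for line in lines:
            io.write_bedgraph(bundle.tracks, _p(f"track_{grp}_{line}.bedgraph"), value_col=line)
    with open(f"{outdir}/immune_genes.txt", "w") as fh:
        fh.write("\n".join(bundle.immune_genes) + "\n")
    paths["immune_genes.txt"] = f"{outdir}/immune_genes.txt"
    return paths
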