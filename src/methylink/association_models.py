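"""Per-gene association models and enrichment statistics.

The central model regresses each gene's expression on six sample-level
predictors — global methylation level, mutation burden, aneuploidy level,
tumour purity, age and tumour stage — and ranks genes by the Wald z score
of a chosen coefficient.  Rankings feed a preranked enrichment statistic
(weighted Kolmogorov–Smirnov running sum with gene-label permutation null,
NES and positive/negative-tail FDR) and a single-sample enrichment score
for per-sample signature activity.  Helpers cover first-order partial
Spearman correlation, the immune-specific gene filter (5-fold leukocyte /
lymph-node over other tissues), repeat-expression normalization, and the
low-vs-high methylation group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

REQUIRED_PREDICTORS = ["global_methylation", "mutation_burden", "aneuploidy", "purity", "age"]


# ---------------------------------------------------------------------------
# per-gene regression


def build_design(
    features: pd.DataFrame, include_stage: bool, log_mutation_burden: bool = True
) -> pd.DataFrame:
    """Design matrix with intercept; mutation burden enters as log10(1 + n) by default."""
    cols = list(REQUIRED_PREDICTORS) + (["stage"] if include_stage else [])
    missing = set(cols) - set(features.columns)
    if missing:
        raise ValueError(f"features missing predictors: {sorted(missing)}")
    X = features[cols].astype(float).copy()
    if X.isna().any().any():
        bad = X.columns[X.isna().any()][0]
        raise ValueError(f"missing values in predictor {bad!r}")
    if log_mutation_burden:
        X["mutation_burden"] = np.log10(1.0 + X["mutation_burden"])
    X.insert(0, "intercept", 1.0)
    return X


def fit_gene_models(
    expression: pd.DataFrame,
    features: pd.DataFrame,
    include_stage: bool = True,
    log_mutation_burden: bool = True,
    fdr_alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """OLS of each gene's expression on the sample-level predictors.

    ``expression`` is genes x samples; ``features`` is indexed by sample.
    Returns per-statistic frames (``coef``, ``se``, ``z``, ``p``, ``q``),
    each genes x predictors.  z is the Wald statistic coef/SE with two-sided
    P from the t distribution on n - p degrees of freedom; q is
    Benjamini–Hochberg across genes, separately per predictor.

    All genes share one design matrix, so the fit is vectorized: with
    pseudo-inverse ``A = (X'X)^-1 X'``, coefficients are ``A @ Y`` and
    standard errors come from the per-gene residual variance.
    """
    samples = [s for s in expression.columns if s in features.index]
    if len(samples) < len(expression.columns):
        raise ValueError("expression columns missing from features table")
    X = build_design(features.loc[samples], include_stage, log_mutation_burden)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} samples for {p - 1} predictors, have {n}")
    Xv = X.to_numpy()
    # singularity check with a named culprit
    if np.linalg.matrix_rank(Xv) < p:
        for col in X.columns[1:]:
            if X[col].nunique() <= 1:
                raise ValueError(f"singular design: predictor {col!r} is constant")
        raise ValueError("singular design matrix (collinear predictors)")

    Y = expression[samples].to_numpy(dtype=float).T  # n x genes
    xtx_inv = np.linalg.inv(Xv.T @ Xv)
    coef = xtx_inv @ Xv.T @ Y  # p x genes
    resid = Y - Xv @ coef
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(z), df=dof)

    genes = expression.index
    preds = X.columns
    frames = {
        name: pd.DataFrame(arr.T, index=genes, columns=preds)
        for name, arr in [("coef", coef), ("se", se), ("z", z), ("p", pvals)]
    }
    q = np.empty_like(pvals)
    for j in range(p):
        q[j] = multipletests(pvals[j], alpha=fdr_alpha, method="fdr_bh")[1]
    frames["q"] = pd.DataFrame(q.T, index=genes, columns=preds)
    return frames


# ---------------------------------------------------------------------------
# preranked enrichment


def enrichment_score(ranked_scores: pd.Series, gene_set: set[str]) -> float:
    """Weighted running-sum enrichment score (weight = |score|, exponent 1).

    ``ranked_scores`` must be sorted in decreasing score order.  The ES is
    the running sum's extremum (largest absolute deviation, signed).
    """
    genes = ranked_scores.index.to_numpy()
    weights = np.abs(ranked_scores.to_numpy(dtype=float))
    in_set = np.isin(genes, list(gene_set))
    n_miss = (~in_set).sum()
    if in_set.sum() == 0:
        raise ValueError("gene set does not intersect the ranking")
    w_in = weights * in_set
    total_in = w_in.sum()
    if total_in == 0:  # all set genes have score 0: uniform hit weights
        w_in = in_set.astype(float)
        total_in = w_in.sum()
    if n_miss == 0:
        # degenerate: set == universe; use the uniform ECDF as the miss term so
        # the walk ends at 0 and the reported ES is the intermediate extremum
        run = np.cumsum(w_in / total_in) - np.arange(1, in_set.size + 1) / in_set.size
    else:
        run = np.cumsum(w_in / total_in - (~in_set) / n_miss)
    return float(run[np.argmax(np.abs(run))])


@dataclass
class EnrichmentResult:
    set_id: str
    es: float
    nes: float
    p_perm: float
    fdr: float
    size: int


def preranked_enrichment(
    scores: pd.Series,
    gene_sets: dict[str, set[str] | list[str]],
    n_perm: int = 1000,
    min_set_size: int = 10,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Preranked enrichment over several gene sets with a permutation null.

    Scores are sorted decreasingly; sets are intersected with the ranked
    universe and dropped below ``min_set_size``.  The null permutes gene
    labels (equivalently: draws random sets of the same size).  NES divides
    each ES by the mean |null ES| of its sign; P is the one-tailed fraction
    of same-sign nulls at least as extreme; FDR follows the standard
    positive/negative-tail ratio over the pooled normalized nulls.
    """
    if scores.empty:
        raise ValueError("empty ranking")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ranked = scores.sort_values(ascending=False, kind="stable")
    universe = set(ranked.index)

    kept: dict[str, set[str]] = {}
    for sid, members in gene_sets.items():
        inter = universe & set(members)
        if len(inter) >= min_set_size:
            kept[sid] = inter
    results = []
    null_nes_pool: list[np.ndarray] = []
    obs_nes: dict[str, tuple[float, float, float, int]] = {}
    genes_arr = ranked.index.to_numpy()
    for sid, members in kept.items():
        es = enrichment_score(ranked, members)
        m = len(members)
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            rand_set = set(genes_arr[rng.choice(len(genes_arr), size=m, replace=False)])
            null_es[b] = enrichment_score(ranked, rand_set)
        pos = null_es[null_es >= 0]
        neg = null_es[null_es < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        if es >= 0:
            nes = es / mean_pos if pos.size else np.nan
            p = (1 + (pos >= es).sum()) / (1 + pos.size) if pos.size else 1.0
        else:
            nes = -(abs(es) / mean_neg) if neg.size else np.nan
            p = (1 + (np.abs(neg) >= abs(es)).sum()) / (1 + neg.size) if neg.size else 1.0
        null_nes = np.where(null_es >= 0, null_es / mean_pos, null_es / mean_neg)
        null_nes_pool.append(null_nes[np.isfinite(null_nes)])
        obs_nes[sid] = (es, float(nes), float(p), m)

    pool = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    all_nes = np.array([v[1] for v in obs_nes.values()])
    for sid, (es, nes, p, m) in obs_nes.items():
        if not np.isfinite(nes):
            fdr = np.nan
        elif nes >= 0:
            num = (pool >= nes).mean() if pool.size else 1.0
            den = (all_nes >= nes).mean()
            fdr = min(1.0, num / den) if den > 0 else 1.0
        else:
            num = (pool <= nes).mean() if pool.size else 1.0
            den = (all_nes <= nes).mean()
            fdr = min(1.0, num / den) if den > 0 else 1.0
        results.append(EnrichmentResult(sid, es, nes, p, float(fdr), m))
    out = pd.DataFrame([r.__dict__ for r in results])
    return out.set_index("set_id") if not out.empty else out


# ---------------------------------------------------------------------------
# single-sample enrichment


def ssgsea_score(expression: pd.Series, gene_set: set[str], alpha: float = 0.25) -> float:
    """Single-sample enrichment of ``gene_set`` in one sample's expression vector.

    Genes are ranked by expression (descending); the score sums, over all
    rank positions, the difference between the rank-weighted ECDF of set
    genes (weights = rank value ** alpha) and the unweighted ECDF of
    non-set genes.  Rank-based, hence invariant to monotone transforms.
    Returns NaN if the set does not intersect the vector.
    """
    expr = expression.dropna()
    order = expr.sort_values(ascending=False, kind="stable").index.to_numpy()
    n = order.size
    in_set = np.isin(order, list(gene_set))
    if in_set.sum() == 0:
        return float("nan")
    if in_set.all():
        raise ValueError("gene set covers the whole expression vector")
    rank_vals = np.arange(n, 0, -1, dtype=float)  # top gene gets n
    w = np.where(in_set, rank_vals**alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_set) / (~in_set).sum()
    return float((p_in - p_out).sum())


def ssgsea_scores(expression: pd.DataFrame, gene_set: set[str], alpha: float = 0.25) -> pd.Series:
    """``ssgsea_score`` per sample over a genes x samples matrix."""
    out = expression.apply(lambda col: ssgsea_score(col, gene_set, alpha), axis=0)
    out.name = "ssgsea"
    return out


# ---------------------------------------------------------------------------
# partial correlation and simple comparisons


def partial_spearman(x, y, z) -> tuple[float, float]:
    """First-order partial Spearman correlation of x and y given z.

    Ranks all three vectors and applies
    (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); the P value uses
    the t approximation with n - 3 degrees of freedom.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
    x, y, z = x[ok], y[ok], z[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete triples")
    if any(np.unique(v).size == 1 for v in (x, y, z)):
        raise ValueError("constant input vector: partial correlation undefined")
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    denom = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if denom == 0:
        raise ValueError("conditioning variable perfectly correlated with x or y")
    r = (r_xy - r_xz * r_yz) / denom
    r = float(np.clip(r, -1.0, 1.0))
    dof = n - 3
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1 - r**2))
    return r, float(2 * stats.t.sf(abs(t), df=dof))


def immune_specific_genes(
    tissue_expression: pd.DataFrame,
    immune_tissues: tuple[str, str] = ("leukocyte", "lymph_node"),
    fold: float = 5.0,
    pseudocount: float = 1e-8,
) -> set[str]:
    """Genes expressed >= ``fold`` higher in leukocytes/lymph nodes than elsewhere.

    ``tissue_expression`` is genes x tissues.  The flag compares the mean of
    the two immune tissues with the mean of all remaining tissues (with a
    pseudocount on the denominator).
    """
    missing = set(immune_tissues) - set(tissue_expression.columns)
    if missing:
        raise ValueError(f"tissue matrix lacks columns: {sorted(missing)}")
    others = [c for c in tissue_expression.columns if c not in immune_tissues]
    if not others:
        raise ValueError("no non-immune tissue columns")
    imm = tissue_expression[list(immune_tissues)].mean(axis=1)
    rest = tissue_expression[others].mean(axis=1)
    ratio = imm / (rest + pseudocount)
    return set(tissue_expression.index[ratio >= fold])


def normalize_repeat_expression(
    counts: pd.DataFrame, totals: pd.Series, tumour_type: pd.Series
) -> pd.DataFrame:
    """Repeat-class read counts -> per-type standardized expression.

    Counts (classes x samples) are divided by each sample's total aligned
    reads, then z-standardized within tumour type per class.  Types with a
    single sample get NaN (the SD is undefined).
    """
    if (totals <= 0).any():
        raise ValueError("total aligned read counts must be positive")
    rates = counts.div(totals, axis=1)
    out = pd.DataFrame(np.nan, index=rates.index, columns=rates.columns)
    for _, samples in rates.columns.to_series().groupby(tumour_type):
        block = rates[samples.index]
        if block.shape[1] < 2:
            continue
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        out[samples.index] = block.sub(mu, axis=0).div(sd, axis=0)
    return out


def methylation_percentile_groups(
    scores: pd.Series, low_cut: float = 30.0, high_cut: float = 70.0
) -> pd.Series:
    """Label samples 'low' (< low_cut percentile), 'high' (> high_cut), else NaN."""
    lo = np.percentile(scores, low_cut)
    hi = np.percentile(scores, high_cut)
    lab = pd.Series(index=scores.index, dtype=object)
    lab[scores < lo] = "low"
    lab[scores > hi] = "high"
    return lab


def group_compare(
    values: pd.Series,
    groups: pd.Series,
    test: str = "mannwhitney",
) -> dict[str, float]:
    """Compare a per-sample quantity between the low and high methylation groups.

    ``test`` is ``mannwhitney`` (two-sided U) for per-sample quantities, or
    ``paired_t`` when ``values`` holds per-gene paired differences of group
    means (pass the low-group means as ``values`` and high-group means as
    ``groups`` in that mode).
    """
    if test == "paired_t":
        a = np.asarray(values, dtype=float)
        b = np.asarray(groups, dtype=float)
        t, p = stats.ttest_rel(a, b)
        return {"statistic": float(t), "p": float(p), "mean_low": float(a.mean()), "mean_high": float(b.mean())}
    low = values[groups == "low"].dropna()
    high = values[groups == "high"].dropna()
    if len(low) < 2 or len(high) < 2:
        raise ValueError("each group needs at least 2 samples")
    u, p = stats.mannwhitneyu(low, high, alternative="two-sided")
    return {
        "statistic": float(u),
        "p": float(p),
        "median_low": float(low.median()),
        "median_high": float(high.median()),
        "n_low": float(len(low)),
        "n_high": float(len(high)),
    }
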