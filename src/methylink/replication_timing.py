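"""Differential replication timing between cancer and normal cell lines.

Input is wavelet-smoothed Repli-seq signal averaged in 5-kb windows, one
column per cell line (higher signal = earlier replication).  Tracks are
z-scaled per line and quantile-normalized across lines, each window is
tested with an equal-variance two-sample t-test (cancer vs normal), and
windows are combined per gene with Fisher's method plus the mean t
statistic.  Genes passing Bonferroni at 0.05 are classified as replicating
earlier or later in cancer according to the sign of the mean t.

Sign convention: positive t means higher signal in cancer, i.e. EARLIER
replication in cancer; ``late_in_cancer`` requires negative mean t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import overlap_lengths

WINDOW_SIZE = 5_000
COORD_COLS = ["chrom", "start", "end"]

CLASS_LATE = "late_in_cancer"
CLASS_EARLY = "early_in_cancer"
CLASS_NONE = "unclassified"


@dataclass(frozen=True)
class TrackGroups:
    """Cell-line labels split into the two comparison groups."""

    normal: tuple[str, ...]
    cancer: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.normal) < 2 or len(self.cancer) < 2:
            raise ValueError("need at least 2 cell lines per group")
        if set(self.normal) & set(self.cancer):
            raise ValueError("a cell line cannot be in both groups")

    @property
    def all_lines(self) -> list[str]:
        return list(self.normal) + list(self.cancer)


def normalize_tracks(tracks: pd.DataFrame, groups: TrackGroups) -> pd.DataFrame:
    """Z-scale each cell line, then quantile-normalize across lines.

    Windows with a missing value in any line are dropped first.  After
    quantile normalization every line shares the same sorted value multiset
    (the mean of the per-line sorted distributions); ties get the mean of
    the reference values at their positions.
    """
    lines = groups.all_lines
    missing_cols = set(lines) - set(tracks.columns)
    if missing_cols:
        raise ValueError(f"tracks lack cell lines: {sorted(missing_cols)}")
    kept = tracks.dropna(subset=lines).reset_index(drop=True)
    vals = kept[lines].to_numpy(dtype=float)
    # per-line z-scale
    vals = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=0)
    # quantile normalization against the mean of sorted distributions
    order = np.argsort(vals, axis=0, kind="stable")
    ref = np.sort(vals, axis=0).mean(axis=1)
    qn = np.empty_like(vals)
    for j in range(vals.shape[1]):
        ranks = stats.rankdata(vals[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        qn[:, j] = 0.5 * (ref[lo] + ref[hi])
    del order
    out = kept[COORD_COLS].copy()
    out[lines] = qn
    return out


def window_ttest(tracks: pd.DataFrame, groups: TrackGroups) -> pd.DataFrame:
    """Equal-variance Student's t per window, cancer minus normal.

    Windows with zero pooled variance and equal group means are reported as
    t=0, P=1 and flagged ``degenerate``.
    """
    a = tracks[list(groups.cancer)].to_numpy(dtype=float)
    b = tracks[list(groups.normal)].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    degenerate = ~np.isfinite(t)
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    t = np.where(degenerate & (mean_diff == 0), 0.0, t)
    p = np.where(degenerate & (mean_diff == 0), 1.0, p)
    t = np.where(degenerate & (mean_diff != 0), np.sign(mean_diff) * np.inf, t)
    p = np.where(degenerate & (mean_diff != 0), 0.0, p)
    out = tracks[COORD_COLS].copy()
    out["t"] = t
    out["p"] = p
    out["degenerate"] = degenerate
    return out


def fisher_combine(pvalues: np.ndarray) -> float:
    """Fisher's combined probability: X^2 = -2 sum(ln p), df = 2k, upper tail.

    Zeros are floored at the smallest positive float so the statistic stays
    finite; k = 1 returns the input P exactly.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no P values to combine")
    if p.size == 1:
        return float(p[0])
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, df=2 * p.size))


def gene_level_timing(
    window_stats: pd.DataFrame,
    gene_models: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Combine per-window statistics into per-gene timing calls.

    A gene inherits every window its body overlaps (any overlap).  Multi-
    window genes combine P values with Fisher's method and average the t
    statistics.  Bonferroni correction runs over genes with at least one
    window; genes overlapping none are ``unclassified`` with NaN statistics.
    """
    per_chrom = {
        chrom: sub.sort_values("start").reset_index(drop=True)
        for chrom, sub in window_stats.groupby("chrom", sort=False)
    }
    rows = []
    for gene in gene_models.itertuples(index=False):
        sub = per_chrom.get(gene.chrom)
        if sub is None:
            rows.append((gene.gene_id, np.nan, np.nan, 0))
            continue
        idx, _ = overlap_lengths(gene.start, gene.end, sub["start"].to_numpy(), sub["end"].to_numpy())
        if idx.size == 0:
            rows.append((gene.gene_id, np.nan, np.nan, 0))
            continue
        t_mean = float(sub["t"].to_numpy()[idx].mean())
        p_comb = fisher_combine(sub["p"].to_numpy()[idx])
        rows.append((gene.gene_id, t_mean, p_comb, int(idx.size)))
    out = pd.DataFrame(rows, columns=["gene_id", "t_mean", "p_combined", "n_windows"])
    tested = out["n_windows"] > 0
    n_tested = int(tested.sum())
    out["p_adj"] = np.nan
    out.loc[tested, "p_adj"] = np.minimum(out.loc[tested, "p_combined"] * n_tested, 1.0)
    cls = np.full(len(out), CLASS_NONE, dtype=object)
    sig = tested & (out["p_adj"] < alpha)
    cls[(sig & (out["t_mean"] < 0)).to_numpy()] = CLASS_LATE
    cls[(sig & (out["t_mean"] > 0)).to_numpy()] = CLASS_EARLY
    out["class"] = cls
    return out


def domain_weighted_timing(track: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    """Overlap-length-weighted mean signal of the windows covering an interval.

    ``track`` has chrom/start/end plus a ``signal`` column.  Returns NaN if
    the interval overlaps no window.
    """
    sub = track[track["chrom"] == chrom].sort_values("start")
    idx, ov = overlap_lengths(start, end, sub["start"].to_numpy(), sub["end"].to_numpy())
    if idx.size == 0:
        return float("nan")
    sig = sub["signal"].to_numpy()[idx]
    return float(np.average(sig, weights=ov))
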