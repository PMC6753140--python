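"""Partially methylated domain (PMD) handling.

PMD/HMD calls arrive as 100-kb units typed by the variability of solo-WCGW
CpG methylation across samples.  Consecutive units of the same type are
merged, merged domains longer than 300 kb are retained, and merged PMDs are
subclassified by Ward clustering on (methylation variability, replication
timing).  The subclass with the smallest median genomic length — the
"short PMDs" — is where focal promoter-CGI hypermethylation is counted.

A permutation test checks whether a gene set inside PMDs lies closer to
HMDs (i.e. to PMD boundaries) than random PMD genes do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

from ._intervals import gap_to_nearest, validate_sorted_nonoverlapping

MIN_MERGED_LENGTH = 300_000


def merge_domains(table: pd.DataFrame, min_length: int = MIN_MERGED_LENGTH) -> pd.DataFrame:
    """Merge adjacent same-type units and keep merged domains > ``min_length``.

    Units are adjacent when one ends exactly where the next starts.  The
    merged domain's variability and timing are the unweighted means of its
    constituent units (units share a common width).  Domains of exactly
    ``min_length`` are dropped (strict inequality).
    """
    table = table.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    validate_sorted_nonoverlapping(table)
    rows = []
    for chrom, sub in table.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        run_start = 0
        for i in range(1, len(sub) + 1):
            new_run = (
                i == len(sub)
                or sub.at[i, "dtype"] != sub.at[run_start, "dtype"]
                or sub.at[i, "start"] != sub.at[i - 1, "end"]
            )
            if new_run:
                block = sub.iloc[run_start:i]
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(block["start"].iloc[0]),
                        "end": int(block["end"].iloc[-1]),
                        "dtype": block["dtype"].iloc[0],
                        "meth_variability": float(block["meth_variability"].mean()),
                        "rep_timing": float(block["rep_timing"].mean()),
                        "n_units": len(block),
                    }
                )
                run_start = i
    merged = pd.DataFrame(rows)
    kept = merged[(merged["end"] - merged["start"]) > min_length].reset_index(drop=True)
    return kept


def cluster_pmds(merged: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Ward clustering of merged PMDs on standardized (variability, timing).

    Returns the PMD table with a ``cluster`` label and ``is_short`` flag for
    the cluster with the smallest median length.  Input is sorted by
    (chrom, start) first so labels are reproducible.
    """
    pmds = merged[merged["dtype"] == "PMD"].sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    if len(pmds) < k:
        raise ValueError(f"need at least k={k} PMDs, have {len(pmds)}")
    feats = pmds[["meth_variability", "rep_timing"]].to_numpy(dtype=float)
    feats = (feats - feats.mean(axis=0)) / np.where(feats.std(axis=0) > 0, feats.std(axis=0), 1.0)
    if k == 1:
        labels = np.zeros(len(pmds), dtype=int)
    else:
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(feats)
    out = pmds.copy()
    out["cluster"] = labels
    out["length"] = out["end"] - out["start"]
    med = out.groupby("cluster")["length"].median()
    short_cluster = med.idxmin()
    out["is_short"] = out["cluster"] == short_cluster
    return out


@dataclass
class ProximityTestResult:
    """Permutation test of a gene set's mean distance to the nearest HMD."""

    observed_mean_distance: float
    null_means: np.ndarray
    p_empirical: float
    n_perm: int
    gene_distances: pd.Series = field(repr=False, default=None)


def gene_hmd_distances(gene_models: pd.DataFrame, hmds: pd.DataFrame) -> pd.Series:
    """Per-gene minimum gap in bp between the gene body and any HMD (0 if overlapping)."""
    if hmds.empty:
        raise ValueError("HMD table is empty")
    per_chrom = {
        chrom: (sub.sort_values("start")["start"].to_numpy(), sub.sort_values("start")["end"].to_numpy())
        for chrom, sub in hmds.groupby("chrom", sort=False)
    }
    dists = {}
    for gene in gene_models.itertuples(index=False):
        se = per_chrom.get(gene.chrom)
        if se is None:
            dists[gene.gene_id] = np.inf
        else:
            dists[gene.gene_id] = gap_to_nearest(gene.start, gene.end, se[0], se[1])
    out = pd.Series(dists, name="distance_bp")
    out.index.name = "gene_id"
    return out


def proximity_permutation_test(
    genes: set[str],
    pmd_genes: set[str],
    hmds: pd.DataFrame,
    gene_models: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> ProximityTestResult:
    """Is the mean gene-to-HMD distance of ``genes`` smaller than random PMD gene sets'?

    The null resamples ``len(genes)`` identifiers uniformly without
    replacement from ``pmd_genes``; the one-sided empirical P uses add-one
    smoothing, P = (1 + #{null <= observed}) / (1 + n_perm), so it is never
    exactly zero.
    """
    genes = set(genes)
    pmd_genes = sorted(set(pmd_genes))
    if not genes <= set(pmd_genes):
        raise ValueError("test genes must be a subset of the PMD gene universe")
    if len(pmd_genes) < len(genes):
        raise ValueError("PMD gene universe smaller than the test set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    universe_models = gene_models[gene_models["gene_id"].isin(pmd_genes)]
    dist = gene_hmd_distances(universe_models, hmds)
    dist = dist.loc[pmd_genes]
    observed = float(dist.loc[sorted(genes)].mean())

    # vectorized draws without replacement: smallest-|genes| of random keys per row
    m = len(genes)
    keys = rng.random((n_perm, len(pmd_genes)))
    picks = np.argpartition(keys, m - 1, axis=1)[:, :m]
    null_means = dist.to_numpy()[picks].mean(axis=1)
    p = (1 + int((null_means <= observed).sum())) / (1 + n_perm)
    return ProximityTestResult(
        observed_mean_distance=observed,
        null_means=null_means,
        p_empirical=float(p),
        n_perm=n_perm,
        gene_distances=dist,
    )
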