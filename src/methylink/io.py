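"""Readers and writers for the plain-text table formats used across the pipeline.

All coordinates are 0-based half-open.  Domain files are BED6+2
(chrom, start, end, name, score, strand, meth_variability, rep_timing);
segments are SEG-like TSV (sample_id, chrom, start, end, log2_ratio);
replication tracks are four-column bedGraph, one file per cell line.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

DOMAIN_COLUMNS = ["chrom", "start", "end", "dtype", "score", "strand", "meth_variability", "rep_timing"]


def read_probe_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "chrom", "pos", "cgi_class", "promoter_flag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"probe manifest missing columns: {sorted(missing)}")
    df["promoter_flag"] = df["promoter_flag"].astype(bool)
    return df


def write_probe_manifest(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_beta_matrix(path: str, sep: str = "\t") -> pd.DataFrame:
    """Beta matrix, probes (rows) x samples (columns)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    vals = df.to_numpy(dtype=float)
    bad = ((vals < 0) | (vals > 1)) & ~pd.isna(vals)
    if bad.any():
        raise ValueError("beta values outside [0, 1]")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate probe or sample identifiers in beta matrix")
    return df


def write_beta_matrix(df: pd.DataFrame, path: str, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index_label="probe_id")


def read_domains(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 8:
        raise ValueError("domain BED must have 8 columns (BED6 + variability, timing)")
    df.columns = DOMAIN_COLUMNS[: df.shape[1]]
    return df[["chrom", "start", "end", "dtype", "meth_variability", "rep_timing"]]


def write_domains(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    out["score"] = 0
    out["strand"] = "."
    out[DOMAIN_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_segments(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "chrom", "start", "end", "log2_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    return df


def write_segments(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_genome_geometry(path: str) -> pd.DataFrame:
    """Chromosome geometry TSV: chrom, length, centromere."""
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "length", "centromere"} <= set(df.columns):
        raise ValueError("geometry table needs columns chrom, length, centromere")
    bad = (df["centromere"] <= 0) | (df["centromere"] >= df["length"])
    if bad.any():
        raise ValueError(f"centromere outside (0, length) for {df.loc[bad, 'chrom'].tolist()}")
    return df


def write_genome_geometry(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_models(path: str) -> pd.DataFrame:
    """BED4+ gene models: chrom, start, end, gene_id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "gene_id"]
    return df


def write_gene_models(df: pd.DataFrame, path: str) -> None:
    df[["chrom", "start", "end", "gene_id"]].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str, value_name: str = "signal") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", na_values=["NA", "nan", "."])
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", value_name]
    return df


def write_bedgraph(df: pd.DataFrame, path: str, value_col: str = "signal") -> None:
    df[["chrom", "start", "end", value_col]].to_csv(path, sep="\t", header=False, index=False, na_rep="NA")


def read_track_set(paths: Mapping[str, str]) -> pd.DataFrame:
    """Merge per-cell-line bedGraphs into one windows x cell-lines frame.

    ``paths`` maps cell-line name -> bedGraph file.  Windows are matched on
    (chrom, start, end); a window absent from a file is missing for that line.
    """
    merged: pd.DataFrame | None = None
    for line, path in paths.items():
        df = read_bedgraph(path, value_name=line)
        merged = df if merged is None else merged.merge(df, on=["chrom", "start", "end"], how="outer")
    if merged is None:
        raise ValueError("no track files given")
    return merged.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def read_clinical(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "pfs_time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if (df["pfs_time"] <= 0).any():
        raise ValueError("pfs_time must be positive")
    df["event"] = df["event"].astype(bool)
    return df


def read_gmt(path: str) -> dict[str, list[str]]:
    """GMT gene sets: set name, description, genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_expression(path: str) -> pd.DataFrame:
    """Expression matrix TSV, genes (rows) x samples (columns)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
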