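"""Aneuploidy scoring from copy-number segments.

A segment qualifies as a large-scale (arm/chromosome-level) event when its
absolute log2 tumour/normal ratio reaches the 0.2 threshold and it covers
at least 10% of a chromosome arm or 5% of the chromosome.  The aneuploidy
level of a sample is the sum of |log2 ratio| over qualifying segments, each
weighted by segment length; lengths are normalized by the total autosome
length so the score does not depend on genome size.  Sex chromosomes are
excluded by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LOG2_THRESHOLD = 0.2
ARM_FRACTION = 0.10
CHROM_FRACTION = 0.05
SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def _check_geometry(geom: pd.DataFrame) -> pd.DataFrame:
    bad = (geom["centromere"] <= 0) | (geom["centromere"] >= geom["length"])
    if bad.any():
        raise ValueError(f"centromere outside (0, length): {geom.loc[bad, 'chrom'].tolist()}")
    return geom.set_index("chrom")


def call_qualifying_segments(
    segments: pd.DataFrame,
    geom: pd.DataFrame,
    threshold: float = LOG2_THRESHOLD,
    strict: bool = False,
    exclude_sex: bool = True,
) -> pd.DataFrame:
    """Flag segments that count toward the aneuploidy level.

    A segment qualifies iff |log2_ratio| >= ``threshold`` (strictly greater
    when ``strict``) AND its overlap with some arm is >= 10% of that arm's
    length OR the segment itself is >= 5% of the chromosome length.
    """
    g = _check_geometry(geom)
    unknown = set(segments["chrom"]) - set(g.index)
    if unknown:
        raise KeyError(f"segments on chromosomes absent from geometry: {sorted(unknown)}")
    out = segments.copy()
    mag = out["log2_ratio"].abs()
    amp_ok = (mag > threshold) if strict else (mag >= threshold)

    size_ok = np.zeros(len(out), dtype=bool)
    lengths = (out["end"] - out["start"]).to_numpy()
    for i, seg in enumerate(out.itertuples(index=False)):
        chrom = g.loc[seg.chrom]
        cen, clen = chrom["centromere"], chrom["length"]
        p_ov = max(0, min(seg.end, cen) - max(seg.start, 0))
        q_ov = max(0, min(seg.end, clen) - max(seg.start, cen))
        arm_rule = p_ov >= ARM_FRACTION * cen or q_ov >= ARM_FRACTION * (clen - cen)
        chrom_rule = lengths[i] >= CHROM_FRACTION * clen
        size_ok[i] = arm_rule or chrom_rule
    out["qualifies"] = amp_ok.to_numpy() & size_ok
    if exclude_sex:
        out.loc[out["chrom"].isin(SEX_CHROMS), "qualifies"] = False
    return out


def aneuploidy_level(
    flagged: pd.DataFrame, geom: pd.DataFrame, exclude_sex: bool = True
) -> pd.DataFrame:
    """Length-weighted sum of |log2 ratio| over qualifying segments, per sample.

    Weights are segment length divided by total autosome length, so a single
    full-genome event of |log2| = c scores exactly c.  Samples present in
    the input with no qualifying segment score 0.
    """
    if "qualifies" not in flagged.columns:
        raise ValueError("run call_qualifying_segments first")
    auto = geom[~geom["chrom"].isin(SEX_CHROMS)] if exclude_sex else geom
    total = float(auto["length"].sum())
    q = flagged[flagged["qualifies"]]
    contrib = q["log2_ratio"].abs() * (q["end"] - q["start"]) / total
    level = contrib.groupby(q["sample_id"]).sum()
    n_seg = q.groupby("sample_id").size()
    out = pd.DataFrame({"level": level, "n_qualifying_segments": n_seg})
    out = out.reindex(sorted(flagged["sample_id"].unique()))
    out["level"] = out["level"].fillna(0.0)
    out["n_qualifying_segments"] = out["n_qualifying_segments"].fillna(0).astype(int)
    out.index.name = "sample_id"
    return out
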