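"""Global LINE-1 methylation scoring and focal CGI hypermethylation counting.

The global methylation level of a tumour sample is estimated as the mean
array beta value over probes whose sequence maps predominantly to the
evolutionarily young LINE-1 subfamilies (L1HS, L1PA*).  Young L1 copies are
dispersed through the methylated genomic background, so their mean
methylation tracks genome-wide methylation without sequencing.

A WGBS-based variant scores repeat elements directly from per-CpG beta
values, for validating the array score on matched samples.

Focal hypermethylation is quantified per sample as the number of promoter
CpG-island probes inside short partially methylated domains (PMDs) whose
beta exceeds the sample's highly-methylated-domain (HMD) CGI baseline by
more than two standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import points_in_intervals

L1_YOUNG_PREFIXES = ("L1HS", "L1PA")
MIN_MAPPED_BP = 45
MIN_MAPPED_FRACTION = 0.90


class NoQualifyingProbesError(ValueError):
    """Raised when a probe/element filter leaves nothing to average."""


@dataclass(frozen=True)
class WgbsElementRecord:
    """Per-repeat-element WGBS summary: per-CpG coverage and beta."""

    element_id: str
    coverage: tuple[int, ...]
    beta: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.coverage) != len(self.beta):
            raise ValueError(f"{self.element_id}: coverage/beta length mismatch")
        if any(c < 0 for c in self.coverage):
            raise ValueError(f"{self.element_id}: negative coverage")
        if any(not 0 <= b <= 1 for b in self.beta):
            raise ValueError(f"{self.element_id}: beta outside [0, 1]")


def select_l1_probes(manifest: pd.DataFrame) -> set[str]:
    """Probes usable for the global score: young-L1 family, >=45 bp and >=90% mapped.

    Both printed thresholds apply conjunctively: the aligned stretch must be
    at least 45 bp long and cover at least 90% of the probe sequence.
    """
    if manifest.empty:
        raise NoQualifyingProbesError("empty probe manifest")
    fam = manifest.get("repeat_family")
    if fam is None:
        raise ValueError("manifest lacks a repeat_family column")
    fam = fam.fillna("")
    is_young = fam.str.startswith(L1_YOUNG_PREFIXES)
    mapped = manifest["mapped_len"].to_numpy(dtype=float)
    plen = manifest["probe_len"].to_numpy(dtype=float)
    ok = is_young.to_numpy() & (mapped >= MIN_MAPPED_BP) & (mapped / plen >= MIN_MAPPED_FRACTION)
    selected = set(manifest.loc[ok, "probe_id"])
    if not selected:
        raise NoQualifyingProbesError("no qualifying LINE-1 probes in manifest")
    return selected


def global_methylation(beta: pd.DataFrame, probes: set[str]) -> pd.DataFrame:
    """Per-sample mean beta over the selected probes.

    Returns a frame indexed by sample with ``score`` and ``n_probes_used``.
    Missing betas are dropped per cell; a sample with no observed probe
    raises, since its score would be undefined.
    """
    missing = probes - set(beta.index)
    if missing:
        raise KeyError(f"probes absent from beta matrix: {sorted(missing)[:5]} ...")
    sub = beta.loc[sorted(probes)]
    n_used = sub.notna().sum(axis=0)
    empty = n_used[n_used == 0]
    if not empty.empty:
        raise ValueError(f"sample {empty.index[0]!r} has no observed beta among selected probes")
    out = pd.DataFrame({"score": sub.mean(axis=0, skipna=True), "n_probes_used": n_used})
    out.index.name = "sample_id"
    return out


def wgbs_global_methylation(
    records_by_sample: dict[str, list[WgbsElementRecord]],
    min_cpgs: int = 3,
    min_coverage: int = 10,
) -> pd.Series:
    """WGBS element-level global score per sample.

    An element is retained iff it has >= ``min_cpgs`` CpGs each covered by
    >= ``min_coverage`` reads; its methylation is the mean beta over those
    covered CpGs.  The sample score is the unweighted mean of element means.
    """
    scores = {}
    for sample, records in records_by_sample.items():
        element_means = []
        for rec in records:
            cov = np.asarray(rec.coverage)
            betas = np.asarray(rec.beta)
            keep = cov >= min_coverage
            if keep.sum() >= min_cpgs:
                element_means.append(betas[keep].mean())
        if not element_means:
            raise NoQualifyingProbesError(f"sample {sample!r}: no repeat element passes coverage filter")
        scores[sample] = float(np.mean(element_means))
    out = pd.Series(scores, name="score")
    out.index.name = "sample_id"
    return out


def _probes_in_domains(manifest: pd.DataFrame, domains: pd.DataFrame) -> np.ndarray:
    """Boolean mask over manifest rows: probe position falls in any domain interval."""
    inside = np.zeros(len(manifest), dtype=bool)
    for chrom, dom in domains.groupby("chrom", sort=False):
        sel = manifest["chrom"] == chrom
        if not sel.any():
            continue
        dom = dom.sort_values("start")
        idx = points_in_intervals(
            manifest.loc[sel, "pos"].to_numpy(),
            dom["start"].to_numpy(),
            dom["end"].to_numpy(),
        )
        inside[np.flatnonzero(sel.to_numpy())] = idx >= 0
    return inside


def count_hypermethylated_short_pmd_cgi(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    merged_hmds: pd.DataFrame,
    short_pmds: pd.DataFrame,
    promoter_only_baseline: bool = False,
) -> pd.DataFrame:
    """Per-sample count of hypermethylated promoter-CGI probes in short PMDs.

    For each sample the baseline mean and standard deviation are taken over
    CGI probes inside the merged HMDs (all CGI probes by default; promoter
    CGI probes only if ``promoter_only_baseline``).  The count is the number
    of promoter-flagged CGI probes inside short PMDs with beta strictly
    greater than mean + 2 SD.  SD uses the n-1 denominator.
    """
    is_island = (manifest["cgi_class"] == "island").to_numpy()
    base_mask = is_island & _probes_in_domains(manifest, merged_hmds)
    if promoter_only_baseline:
        base_mask &= manifest["promoter_flag"].to_numpy()
    base_probes = manifest.loc[base_mask, "probe_id"]
    base_probes = base_probes[base_probes.isin(beta.index)]
    if len(base_probes) < 2:
        raise ValueError("need at least 2 HMD CGI probes to estimate the baseline SD")

    target_mask = is_island & manifest["promoter_flag"].to_numpy() & _probes_in_domains(manifest, short_pmds)
    target_probes = manifest.loc[target_mask, "probe_id"]
    target_probes = target_probes[target_probes.isin(beta.index)]

    base = beta.loc[base_probes]
    mu = base.mean(axis=0, skipna=True)
    sd = base.std(axis=0, ddof=1, skipna=True)
    threshold = mu + 2.0 * sd
    target = beta.loc[target_probes]
    counts = (target.gt(threshold, axis=1)).sum(axis=0)
    out = pd.DataFrame(
        {"hyper_cgi_count": counts.astype(int), "baseline_mean": mu, "baseline_sd": sd}
    )
    out.index.name = "sample_id"
    return out
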