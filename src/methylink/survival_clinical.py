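"""Survival stratification and response modelling for immunotherapy cohorts.

Patients are split into low/high groups by a per-sample score (median split
by default, or 30/70 percentile split with the middle excluded), survival
curves are estimated by Kaplan–Meier with a two-group log-rank test, and
hazard ratios come from Cox proportional-hazards models (Efron tie
handling, via lifelines).  Durable clinical benefit (DCB) follows the
RECIST-derived rule: partial response, or stable disease lasting more than
6 months; progression-free survival is measured in days with 1 month =
30.44 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

DAYS_PER_MONTH = 30.44
DCB, NDB = "DCB", "NDB"


def classify_response(best_response: str, duration_months: float | None = None) -> str:
    """DCB/NDB call from the best RECIST response and its duration.

    PR is DCB; SD is DCB only when it lasted more than 6 months; PD is NDB.
    """
    label = best_response.upper()
    if label == "PR" or label == "CR":
        return DCB
    if label == "PD":
        return NDB
    if label == "SD":
        if duration_months is None:
            raise ValueError("SD requires a duration to classify")
        return DCB if duration_months > 6.0 else NDB
    raise ValueError(f"unknown response label {best_response!r}")


def stratify(
    scores: pd.Series,
    rule: str = "median",
    p_low: float = 30.0,
    p_high: float = 70.0,
    ties_low: bool = True,
) -> pd.Series:
    """Low/high group labels from a per-sample score.

    ``median`` puts samples at or below the median in the low group
    (``ties_low=False`` sends exact ties high); ``percentile`` labels
    ``< p_low`` percentile low and ``> p_high`` high, excluding the middle
    (NaN).  Rank-based, hence invariant to monotone transforms.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to stratify")
    if scores.nunique() == 1:
        raise ValueError("all scores identical: degenerate split")
    lab = pd.Series(index=scores.index, dtype=object, name="group")
    if rule == "median":
        med = scores.median()
        if ties_low:
            lab[scores <= med] = "low"
            lab[scores > med] = "high"
        else:
            lab[scores < med] = "low"
            lab[scores >= med] = "high"
    elif rule == "percentile":
        lo, hi = np.percentile(scores, [p_low, p_high])
        lab[scores < lo] = "low"
        lab[scores > hi] = "high"
    else:
        raise ValueError(f"unknown stratification rule {rule!r}")
    return lab


@dataclass
class SurvivalFit:
    """Kaplan–Meier curves with log-rank comparison and optional Cox summary."""

    km_curves: dict[str, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float
    hr: float | None = None
    hr_ci: tuple[float, float] | None = None
    hr_p: float | None = None
    covariates: pd.DataFrame | None = field(default=None, repr=False)


def km_logrank(clinical: pd.DataFrame, groups: pd.Series) -> SurvivalFit:
    """Kaplan–Meier curves per group plus the two-group log-rank test.

    ``clinical`` needs sample_id-indexed ``pfs_time`` (days) and boolean
    ``event``; censored subjects contribute until their last follow-up.
    Also reports the univariate Cox hazard ratio of low vs high.
    """
    df = clinical.drop(columns=["group"], errors="ignore").join(groups.rename("group"), how="inner")
    df = df.dropna(subset=["group"])
    labels = sorted(df["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    curves = {}
    for g, sub in df.groupby("group"):
        if len(sub) == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["pfs_time"], event_observed=sub["event"], label=str(g))
        curves[g] = kmf.survival_function_
    a = df[df["group"] == labels[0]]
    b = df[df["group"] == labels[1]]
    lr = logrank_test(a["pfs_time"], b["pfs_time"], event_observed_A=a["event"], event_observed_B=b["event"])
    ref = "low" if "low" in labels else labels[0]
    indicator = (df["group"] == ref).astype(float).rename(f"group_{ref}")
    cox = cox_fit(df, indicator.to_frame())
    return SurvivalFit(
        km_curves=curves,
        logrank_chi2=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        hr=cox.hr,
        hr_ci=cox.hr_ci,
        hr_p=cox.hr_p,
        covariates=cox.covariates,
    )


def cox_fit(clinical: pd.DataFrame, covariates: pd.DataFrame) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron ties) of PFS on the given covariates.

    Reports exp(coef) with 95% Wald CI and P per covariate; ``hr`` is the
    first covariate's hazard ratio.
    """
    if int(clinical["event"].sum()) < 2:
        raise ValueError("need at least 2 events for a Cox fit")
    df = pd.concat([clinical[["pfs_time", "event"]], covariates], axis=1, join="inner")
    for col in covariates.columns:
        if df[col].nunique() <= 1:
            raise ValueError(f"degenerate covariate {col!r}")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="pfs_time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    summ = cph.summary
    first = summ.index[0]
    table = summ[["coef", "se(coef)", "exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]].copy()
    table.columns = ["coef", "se", "hr", "hr_lo", "hr_hi", "p"]
    return SurvivalFit(
        km_curves={},
        logrank_chi2=float("nan"),
        logrank_p=float("nan"),
        hr=float(table.at[first, "hr"]),
        hr_ci=(float(table.at[first, "hr_lo"]), float(table.at[first, "hr_hi"])),
        hr_p=float(table.at[first, "p"]),
        covariates=table,
    )


def response_logistic(response: pd.Series, covariates: pd.DataFrame) -> pd.DataFrame:
    """Logistic regression of DCB (1) vs NDB (0) on the given covariates.

    Returns per-covariate odds ratio with Wald P.  Raises when only one
    response class is present; quasi-separation surfaces as huge SEs, which
    are reported rather than masked.
    """
    y = response.map({DCB: 1, NDB: 0, 1: 1, 0: 0}).astype(float)
    if y.nunique() <= 1:
        raise ValueError("response has a single class; logistic model undefined")
    X = sm.add_constant(covariates.astype(float), has_constant="add")
    df = pd.concat([y.rename("_y"), X], axis=1, join="inner").dropna()
    fit = sm.Logit(df["_y"], df[X.columns]).fit(disp=0)
    out = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "odds_ratio": np.exp(fit.params),
            "p": fit.pvalues,
        }
    )
    out["separation_flag"] = out["se"] > 50
    return out.drop(index="const", errors="ignore")
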