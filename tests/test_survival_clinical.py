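"""Response classification, stratification, KM/log-rank, Cox, logistic models."""

import numpy as np
import pandas as pd
import pytest

from methylink import classify_response, cox_fit, km_logrank, response_logistic, stratify


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "label,duration,expected",
        [
            ("PR", None, "DCB"),
            ("SD", 7.0, "DCB"),
            ("SD", 6.0, "NDB"),   # exactly 6 months is not "more than 6"
            ("SD", 5.0, "NDB"),
            ("PD", None, "NDB"),
            ("PD", 12.0, "NDB"),
        ],
    )
    def test_rules(self, label, duration, expected):
        assert classify_response(label, duration) == expected

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="MR"):
            classify_response("MR")

    def test_sd_without_duration_raises(self):
        with pytest.raises(ValueError, match="duration"):
            classify_response("SD")


class TestStratify:
    def test_median_split_even(self):
        s = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        lab = stratify(s, rule="median")
        assert set(lab[lab == "low"].index) == {"a", "b"}
        assert set(lab[lab == "high"].index) == {"c", "d"}

    def test_median_ties_go_low_by_default(self):
        s = pd.Series({"a": 1.0, "b": 2.0, "c": 2.0})
        lab = stratify(s, rule="median")
        assert lab["b"] == "low" and lab["c"] == "low"
        lab2 = stratify(s, rule="median", ties_low=False)
        assert lab2["b"] == "high"

    def test_percentile_30_70_on_ten_scores(self):
        s = pd.Series(np.arange(10, dtype=float), index=[f"s{i}" for i in range(10)])
        lab = stratify(s, rule="percentile")
        assert (lab == "low").sum() == 3 and (lab == "high").sum() == 3 and lab.isna().sum() == 4

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.uniform(1, 10, 25), index=[f"s{i}" for i in range(25)])
        pd.testing.assert_series_equal(stratify(s), stratify(np.exp(s)))
        pd.testing.assert_series_equal(stratify(s, rule="percentile"), stratify(s**3, rule="percentile"))

    def test_degenerate_scores_raise(self):
        with pytest.raises(ValueError, match="identical"):
            stratify(pd.Series({"a": 1.0, "b": 1.0}))


def _clinical(times, events, index=None):
    idx = index or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"pfs_time": times, "event": events}, index=idx)


class TestKmLogrank:
    def test_identical_groups_chi2_zero(self):
        clin = _clinical([5, 10, 15, 5, 10, 15], [True] * 6)
        groups = pd.Series(["low"] * 3 + ["high"] * 3, index=clin.index)
        fit = km_logrank(clin, groups)
        assert fit.logrank_chi2 == pytest.approx(0.0, abs=1e-10)
        assert fit.logrank_p == pytest.approx(1.0)

    def test_km_curve_is_product_limit(self):
        clin = _clinical([2, 4, 6], [True, True, True])
        groups = pd.Series(["low", "low", "low"] , index=clin.index)
        clin2 = _clinical([1, 3, 5], [True, True, True], index=["x", "y", "z"])
        both = pd.concat([clin, clin2])
        groups = pd.Series(["low"] * 3 + ["high"] * 3, index=both.index)
        fit = km_logrank(both, groups)
        low = fit.km_curves["low"]
        # no censoring: KM equals the empirical survival function 2/3, 1/3, 0
        assert np.allclose(low.loc[[2, 4, 6]].to_numpy().ravel(), [2 / 3, 1 / 3, 0.0])

    def test_six_subject_logrank_matches_hand_computation(self):
        """Textbook O-E / variance computation over explicit risk sets."""
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([True, True, True, True, True, False])
        group_a = np.array([True, False, True, False, True, False])  # A: 1,3,5
        clin = _clinical(times, events)
        groups = pd.Series(np.where(group_a, "low", "high"), index=clin.index)

        o_minus_e, var = 0.0, 0.0
        for t in sorted(times[events]):
            at_risk = times >= t
            n, n_a = at_risk.sum(), (at_risk & group_a).sum()
            d = ((times == t) & events).sum()
            d_a = ((times == t) & events & group_a).sum()
            o_minus_e += d_a - d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        chi2_hand = o_minus_e**2 / var

        fit = km_logrank(clin, groups)
        assert fit.logrank_chi2 == pytest.approx(chi2_hand, rel=1e-8)

    def test_label_swap_keeps_statistic_inverts_hr(self):
        rng = np.random.default_rng(1)
        n = 80
        clin = _clinical(rng.exponential(100, n), rng.random(n) < 0.8)
        groups = pd.Series(np.where(rng.random(n) < 0.5, "low", "high"), index=clin.index)
        swapped = groups.map({"low": "high", "high": "low"})
        f1, f2 = km_logrank(clin, groups), km_logrank(clin, swapped)
        assert f1.logrank_chi2 == pytest.approx(f2.logrank_chi2, rel=1e-8)
        assert f1.hr == pytest.approx(1 / f2.hr, rel=1e-6)


class TestCox:
    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(2)
        n = 600
        clin = _clinical(rng.exponential(100, n), np.ones(n, dtype=bool))
        cov = pd.DataFrame({"x": rng.normal(size=n)}, index=clin.index)
        fit = cox_fit(clin, cov)
        assert 0.85 < fit.hr < 1.15

    def test_planted_hr_recovered_within_3se(self, default_bundle):
        b = default_bundle
        clin = b.cohort
        cov = pd.DataFrame({"low_group": (clin["group"] == "low").astype(float)}, index=clin.index)
        fit = cox_fit(clin, cov)
        log_hr = np.log(fit.hr)
        se = float(fit.covariates["se"].iloc[0])
        assert abs(log_hr - np.log(b.config.planted_hr)) < 3 * se

    def test_tie_free_estimates_match_breslow_implementation(self):
        """With no tied event times, Efron and Breslow partial likelihoods
        coincide; cross-check against scikit-survival's Breslow fitter."""
        sksurv = pytest.importorskip("sksurv.linear_model")
        rng = np.random.default_rng(3)
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.7 * x) * 100)
        t = t + rng.uniform(0, 1e-6, n)  # enforce unique times
        clin = _clinical(t, np.ones(n, dtype=bool))
        cov = pd.DataFrame({"x": x}, index=clin.index)
        fit = cox_fit(clin, cov)
        y = np.array([(True, ti) for ti in t], dtype=[("e", bool), ("t", float)])
        sk = sksurv.CoxPHSurvivalAnalysis(alpha=0.0).fit(x.reshape(-1, 1), y)
        assert np.log(fit.hr) == pytest.approx(float(sk.coef_[0]), abs=1e-4)

    def test_too_few_events_raise(self):
        clin = _clinical([1, 2, 3], [False, False, True])
        with pytest.raises(ValueError, match="events"):
            cox_fit(clin, pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=clin.index))

    def test_degenerate_covariate_raises(self):
        clin = _clinical([1, 2, 3, 4], [True] * 4)
        with pytest.raises(ValueError, match="degenerate"):
            cox_fit(clin, pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]}, index=clin.index))


class TestLogistic:
    def test_null_covariate_or_near_one(self):
        rng = np.random.default_rng(4)
        n = 500
        resp = pd.Series(np.where(rng.random(n) < 0.5, "DCB", "NDB"), index=[f"s{i}" for i in range(n)])
        cov = pd.DataFrame({"x": rng.normal(size=n)}, index=resp.index)
        out = response_logistic(resp, cov)
        assert 0.8 < out.at["x", "odds_ratio"] < 1.25

    def test_planted_effect_recovered_within_3se(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.2 + 0.8 * x)))
        resp = pd.Series(np.where(rng.random(n) < p, "DCB", "NDB"), index=[f"s{i}" for i in range(n)])
        cov = pd.DataFrame({"x": x}, index=resp.index)
        out = response_logistic(resp, cov)
        assert abs(out.at["x", "coef"] - 0.8) < 3 * out.at["x", "se"]

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(6)
        n = 60
        resp = pd.Series(np.where(rng.random(n) < 0.5, "DCB", "NDB"), index=[f"s{i}" for i in range(n)])
        cov = pd.DataFrame({"x": rng.normal(size=n)}, index=resp.index)
        out1 = response_logistic(resp, cov)
        perm = rng.permutation(resp.index)
        out2 = response_logistic(resp.loc[perm], cov.loc[perm])
        assert out1.at["x", "coef"] == pytest.approx(out2.at["x", "coef"], abs=1e-10)

    def test_single_class_raises(self):
        resp = pd.Series(["DCB", "DCB", "DCB"], index=["a", "b", "c"])
        cov = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=resp.index)
        with pytest.raises(ValueError, match="single class"):
            response_logistic(resp, cov)
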