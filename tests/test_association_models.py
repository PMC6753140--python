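"""Per-gene regression, enrichment statistics, partial correlation, filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylink import (
    fit_gene_models,
    group_compare,
    immune_specific_genes,
    normalize_repeat_expression,
    partial_spearman,
    preranked_enrichment,
    ssgsea_score,
)
from methylink.association_models import enrichment_score, methylation_percentile_groups


def make_features(n, rng, stage=True):
    f = pd.DataFrame(
        {
            "global_methylation": rng.uniform(0.4, 0.8, n),
            "mutation_burden": rng.poisson(50, n),
            "aneuploidy": rng.exponential(0.1, n),
            "purity": rng.uniform(0.3, 0.9, n),
            "age": rng.normal(65, 8, n),
            "stage": rng.integers(1, 5, n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    return f


class TestRegression:
    def test_noiseless_coefficient_recovered(self):
        rng = np.random.default_rng(0)
        f = make_features(50, rng)
        y = 2.0 * f["global_methylation"]
        expr = pd.DataFrame([y.to_numpy()], index=["g1"], columns=f.index)
        fits = fit_gene_models(expr, f, include_stage=True)
        assert fits["coef"].at["g1", "global_methylation"] == pytest.approx(2.0, abs=1e-8)
        assert fits["p"].at["g1", "global_methylation"] < 1e-20

    def test_joint_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        f = make_features(40, rng)
        expr = pd.DataFrame(rng.normal(size=(5, 40)), index=[f"g{i}" for i in range(5)], columns=f.index)
        fits1 = fit_gene_models(expr, f)
        perm = rng.permutation(f.index)
        fits2 = fit_gene_models(expr[perm], f.loc[perm])
        pd.testing.assert_frame_equal(fits1["coef"], fits2["coef"])
        pd.testing.assert_frame_equal(fits1["p"], fits2["p"])

    def test_constant_predictor_named_in_error(self):
        rng = np.random.default_rng(2)
        f = make_features(30, rng)
        f["purity"] = 0.5
        expr = pd.DataFrame(rng.normal(size=(2, 30)), index=["g1", "g2"], columns=f.index)
        with pytest.raises(ValueError, match="purity"):
            fit_gene_models(expr, f)

    def test_z_sign_matches_coefficient_and_q_dominates_p(self):
        rng = np.random.default_rng(3)
        f = make_features(60, rng)
        expr = pd.DataFrame(rng.normal(size=(20, 60)), index=[f"g{i}" for i in range(20)], columns=f.index)
        fits = fit_gene_models(expr, f)
        assert np.all(np.sign(fits["z"].to_numpy()) == np.sign(fits["coef"].to_numpy()))
        assert np.all(fits["q"].to_numpy() >= fits["p"].to_numpy() - 1e-15)

    def test_bh_q_monotone_in_p(self):
        rng = np.random.default_rng(4)
        f = make_features(50, rng)
        expr = pd.DataFrame(rng.normal(size=(100, 50)), index=[f"g{i}" for i in range(100)], columns=f.index)
        fits = fit_gene_models(expr, f)
        p = fits["p"]["global_methylation"]
        q = fits["q"]["global_methylation"]
        order = np.argsort(p.to_numpy())
        assert np.all(np.diff(q.to_numpy()[order]) >= -1e-12)


class TestEnrichment:
    @staticmethod
    def brute_force_es(scores: pd.Series, gene_set: set[str]) -> float:
        """Independent running-sum: walk the ranking, track the extremum."""
        ranked = scores.sort_values(ascending=False, kind="stable")
        hits = sum(abs(v) for g, v in ranked.items() if g in gene_set)
        n_miss = sum(1 for g in ranked.index if g not in gene_set)
        run, best = 0.0, 0.0
        for g, v in ranked.items():
            if g in gene_set:
                run += abs(v) / hits
            else:
                run -= 1.0 / n_miss
            if abs(run) > abs(best):
                best = run
        return best

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(5, 21))
            genes = [f"g{i}" for i in range(n)]
            scores = pd.Series(rng.normal(size=n), index=genes)
            m = int(rng.integers(1, n))
            gene_set = set(rng.choice(genes, size=m, replace=False))
            ranked = scores.sort_values(ascending=False, kind="stable")
            assert enrichment_score(ranked, gene_set) == pytest.approx(
                self.brute_force_es(scores, gene_set), abs=1e-12
            )

    def test_top_block_with_positive_scores_reaches_one(self):
        scores = pd.Series([5.0, 4.0, 3.0, -1.0, -2.0], index=list("abcde"))
        ranked = scores.sort_values(ascending=False)
        assert enrichment_score(ranked, {"a", "b", "c"}) == pytest.approx(1.0)

    def test_reversed_ranking_negates_es(self):
        rng = np.random.default_rng(8)
        scores = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        gene_set = set(scores.index[:8])
        es_fwd = enrichment_score(scores.sort_values(ascending=False), gene_set)
        es_rev = enrichment_score((-scores).sort_values(ascending=False), gene_set)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_preranked_drops_small_sets_and_signs_nes(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(200)]
        scores = pd.Series(np.linspace(3, -3, 200), index=genes)
        sets = {"top": set(genes[:30]), "bottom": set(genes[-30:]), "tiny": set(genes[:3])}
        out = preranked_enrichment(scores, sets, n_perm=200, min_set_size=10, seed=0)
        assert "tiny" not in out.index
        assert out.at["top", "es"] > 0 and out.at["top", "nes"] > 0
        assert out.at["bottom", "es"] < 0 and out.at["bottom", "nes"] < 0
        assert out.at["top", "p_perm"] < 0.05 and out.at["bottom", "p_perm"] < 0.05

    def test_empty_ranking_raises(self):
        with pytest.raises(ValueError, match="empty"):
            preranked_enrichment(pd.Series(dtype=float), {"s": {"a"}})


class TestSsgsea:
    def test_top_ranked_set_attains_maximum(self):
        expr = pd.Series(np.arange(20, 0, -1, dtype=float), index=[f"g{i}" for i in range(20)])
        gene_set = {f"g{i}" for i in range(5)}
        top = ssgsea_score(expr, gene_set)
        for _ in range(20):
            rng = np.random.default_rng(_)
            other = set(rng.choice(expr.index, size=5, replace=False))
            assert ssgsea_score(expr, other) <= top + 1e-12

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        expr = pd.Series(rng.uniform(1, 100, 50), index=[f"g{i}" for i in range(50)])
        gene_set = set(expr.index[:10])
        assert ssgsea_score(expr, gene_set) == pytest.approx(ssgsea_score(np.log(expr), gene_set))
        assert ssgsea_score(expr, gene_set) == pytest.approx(ssgsea_score(expr**3, gene_set))

    def test_no_overlap_is_nan(self):
        expr = pd.Series([1.0, 2.0], index=["a", "b"])
        assert np.isnan(ssgsea_score(expr, {"zzz"}))

    def test_random_sets_distribution_roughly_symmetric(self):
        rng = np.random.default_rng(11)
        expr = pd.Series(rng.normal(size=300), index=[f"g{i}" for i in range(300)])
        scores = []
        for _ in range(200):
            s = set(rng.choice(expr.index, size=30, replace=False))
            scores.append(ssgsea_score(expr, s))
        scores = np.array(scores)
        assert abs(stats.skew(scores)) < 1.0


class TestPartialSpearman:
    def test_matches_closed_form(self):
        rng = np.random.default_rng(12)
        x, y, z = rng.normal(size=(3, 60))
        r, _ = partial_spearman(x, y, z)
        rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
        r_xy = stats.pearsonr(rx, ry).statistic
        r_xz = stats.pearsonr(rx, rz).statistic
        r_yz = stats.pearsonr(ry, rz).statistic
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_independent_z_approximates_marginal(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=500)
        y = x + rng.normal(size=500)
        z = rng.normal(size=500)
        r_partial, _ = partial_spearman(x, y, z)
        r_marg = stats.spearmanr(x, y).statistic
        assert r_partial == pytest.approx(r_marg, abs=0.05)

    def test_conditioning_on_y_itself_zeroes_correlation(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=100)
        y = x + rng.normal(size=100, scale=0.5)
        r, _ = partial_spearman(x, y, y)
        assert abs(r) < 1e-6

    def test_constant_input_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman([1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1])


class TestImmuneFilter:
    def _matrix(self, imm, others):
        cols = {"leukocyte": imm, "lymph_node": imm}
        for i, v in enumerate(others):
            cols[f"tissue{i}"] = v
        return pd.DataFrame(cols, index=["g"])

    def test_five_fold_boundary(self):
        assert immune_specific_genes(self._matrix(10.0, [1.9] * 14)) == {"g"}
        assert immune_specific_genes(self._matrix(10.0, [2.1] * 14)) == set()

    def test_zero_background_handled_by_pseudocount(self):
        out = immune_specific_genes(self._matrix(1e-6, [0.0] * 14), pseudocount=1e-8)
        assert out == {"g"}

    def test_missing_immune_tissue_raises(self):
        df = pd.DataFrame({"tissue0": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="leukocyte"):
            immune_specific_genes(df)


class TestRepeatNormalization:
    def test_rates_and_zscores(self):
        counts = pd.DataFrame({"s1": [10], "s2": [20], "s3": [40]}, index=["L1"])
        totals = pd.Series({"s1": 1e6, "s2": 2e6, "s3": 2e6})
        types = pd.Series({"s1": "LUAD", "s2": "LUAD", "s3": "LUAD"})
        out = normalize_repeat_expression(counts, totals, types)
        # rates: 1e-5, 1e-5, 2e-5 -> z-scores of {1,1,2}/1e5
        rates = np.array([1e-5, 1e-5, 2e-5])
        expected = (rates - rates.mean()) / rates.std(ddof=1)
        assert np.allclose(out.loc["L1"].to_numpy(), expected)

    def test_single_sample_type_is_nan(self):
        counts = pd.DataFrame({"s1": [10], "s2": [20], "s3": [30]}, index=["L1"])
        totals = pd.Series({"s1": 1e6, "s2": 1e6, "s3": 1e6})
        types = pd.Series({"s1": "A", "s2": "A", "s3": "B"})
        out = normalize_repeat_expression(counts, totals, types)
        assert np.isnan(out.at["L1", "s3"]) and not np.isnan(out.at["L1", "s1"])

    def test_total_rescaling_leaves_z_unchanged(self):
        rng = np.random.default_rng(15)
        counts = pd.DataFrame(rng.poisson(100, size=(2, 6)),
                              index=["L1", "ERV"], columns=[f"s{i}" for i in range(6)])
        totals = pd.Series(rng.uniform(1e6, 2e6, 6), index=counts.columns)
        types = pd.Series("T", index=counts.columns)
        out1 = normalize_repeat_expression(counts, totals, types)
        out2 = normalize_repeat_expression(counts, totals * 3.5, types)
        pd.testing.assert_frame_equal(out1, out2)

    def test_zero_total_raises(self):
        counts = pd.DataFrame({"s1": [1]}, index=["L1"])
        with pytest.raises(ValueError, match="positive"):
            normalize_repeat_expression(counts, pd.Series({"s1": 0.0}), pd.Series({"s1": "T"}))


class TestGroupCompare:
    def test_percentile_grouping_30_70(self):
        scores = pd.Series(np.arange(10, dtype=float), index=[f"s{i}" for i in range(10)])
        lab = methylation_percentile_groups(scores)
        assert (lab == "low").sum() == 3 and (lab == "high").sum() == 3
        assert lab.isna().sum() == 4

    def test_identical_distributions_nonsignificant(self):
        vals = pd.Series(list(range(10)) * 2, index=[f"s{i}" for i in range(20)], dtype=float)
        groups = pd.Series(["low"] * 10 + ["high"] * 10, index=vals.index)
        res = group_compare(vals, groups)
        assert res["p"] > 0.9

    def test_shifted_distributions_significant(self):
        rng = np.random.default_rng(16)
        vals = pd.Series(np.r_[rng.normal(0, 0.1, 15), rng.normal(5, 0.1, 15)],
                         index=[f"s{i}" for i in range(30)])
        groups = pd.Series(["low"] * 15 + ["high"] * 15, index=vals.index)
        assert group_compare(vals, groups)["p"] < 1e-4

    def test_u_statistic_matches_pair_counting(self):
        """Exhaustive pair counting oracle on small groups (ties counted half)."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            a = rng.integers(0, 10, size=int(rng.integers(2, 9))).astype(float)
            b = rng.integers(0, 10, size=int(rng.integers(2, 9))).astype(float)
            vals = pd.Series(np.r_[a, b], index=[f"s{i}" for i in range(a.size + b.size)])
            groups = pd.Series(["low"] * a.size + ["high"] * b.size, index=vals.index)
            u = group_compare(vals, groups)["statistic"]
            u_brute = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
            assert u == pytest.approx(u_brute)

    def test_empty_group_raises(self):
        vals = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        groups = pd.Series(["low", "low", "low"], index=vals.index)
        with pytest.raises(ValueError, match="at least 2"):
            group_compare(vals, groups)

    def test_paired_t_mode(self):
        low = pd.Series([0.1, 0.2, 0.3, 0.15])
        high = pd.Series([0.5, 0.6, 0.7, 0.55])
        res = group_compare(low, high, test="paired_t")
        t, p = stats.ttest_rel(low, high)
        assert res["statistic"] == pytest.approx(t) and res["p"] == pytest.approx(p)
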