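import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from pvatscope import (
    binormal_auc,
    compare_groups,
    multivariate_logistic,
    pooled_summary,
    roc_analysis,
    simulate_cohort,
    univariate_screen,
    vif_filter,
)
from pvatscope.cohort import OUTCOME


class TestPooledSummary:
    def test_matches_concatenated_sample_oracle(self, rng):
        samples = [rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n)
                   for n in (7, 13, 29)]
        groups = [(len(s), s.mean(), s.std(ddof=1)) for s in samples]
        mean, sd = pooled_summary(groups)
        allx = np.concatenate(samples)
        assert mean == pytest.approx(allx.mean(), abs=1e-9)
        assert sd == pytest.approx(allx.std(ddof=1), abs=1e-9)

    def test_equal_means_collapse(self):
        mean, sd = pooled_summary([(10, 4.0, 1.0), (30, 4.0, 1.0)])
        assert mean == pytest.approx(4.0)

    def test_requires_positive_n(self):
        with pytest.raises(ValueError):
            pooled_summary([(0, 1.0, 1.0)])


class TestCompareGroups:
    def _df(self, pos, neg, name="x"):
        return pd.DataFrame({
            OUTCOME: [1] * len(pos) + [0] * len(neg),
            name: np.concatenate([pos, neg]),
        })

    def test_heavy_tailed_variable_routed_to_rank_sum(self, rng):
        df = self._df(rng.lognormal(0, 1.5, 60), rng.lognormal(0, 1.5, 60))
        (res,) = compare_groups(df)
        assert res.method == "rank-sum"

    def test_gaussian_variable_routed_to_t_test(self, rng):
        df = self._df(rng.normal(0, 1, 60), rng.normal(0.5, 1, 60))
        (res,) = compare_groups(df)
        assert res.method == "t-test"

    def test_binary_variable_routed_to_chi_squared(self, rng):
        df = self._df(rng.integers(0, 2, 80), rng.integers(0, 2, 80))
        (res,) = compare_groups(df)
        assert res.method == "chi-squared"

    def test_constant_variable_flagged_untested(self):
        df = self._df(np.ones(10), np.ones(12))
        (res,) = compare_groups(df)
        assert res.method == "none"
        assert np.isnan(res.p_value)

    def test_table1_effect_detected(self):
        df = simulate_cohort(seed=2)
        res = {r.variable: r for r in compare_groups(df)}
        assert res["hu_delta"].p_value < 0.001
        assert res["hu_ratio"].p_value < 0.001

    def test_permuted_labels_mostly_non_significant(self, rng):
        # identical distributions in both groups: null p-values
        hits = 0
        trials = 40
        for s in range(trials):
            r = np.random.default_rng(s)
            df = self._df(r.normal(0, 1, 60), r.normal(0, 1, 60))
            (res,) = compare_groups(df)
            hits += res.p_value < 0.05
        assert hits <= 8  # ~5% expected; generous binomial envelope


class TestUnivariateScreen:
    def test_separation_flagged_and_not_advanced(self):
        df = pd.DataFrame({OUTCOME: [0] * 20 + [1] * 20})
        df["mirror"] = df[OUTCOME].astype(float)
        with pytest.warns(UserWarning, match="excluded"):
            fits, adv = univariate_screen(df)
        assert adv == []
        assert not fits[0].converged

    def test_table1_markers_advance(self):
        df = simulate_cohort(seed=4)
        _, adv = univariate_screen(df)
        assert "hu_delta" in adv and "hu_ratio" in adv

    def test_ci_brackets_coefficient(self):
        df = simulate_cohort(seed=4)
        fits, _ = univariate_screen(df, variables=["hu_delta", "age"])
        for f in fits:
            assert f.ci_low <= f.coef <= f.ci_high


class TestVIF:
    def test_closed_form_on_two_predictors(self, rng):
        x1 = rng.normal(0, 1, 400)
        x2 = 0.95 * x1 + np.sqrt(1 - 0.95**2) * rng.normal(0, 1, 400)
        df = pd.DataFrame({"x1": x1, "x2": x2})
        retained, vifs = vif_filter(df, ["x1", "x2"], limit=np.inf)
        r = np.corrcoef(x1, x2)[0, 1]
        expect = 1.0 / (1.0 - r**2)
        assert vifs["x1"] == pytest.approx(expect, abs=1e-8)
        assert vifs["x2"] == pytest.approx(expect, abs=1e-8)
        # at the default limit of 10 one of the pair is removed
        retained10, _ = vif_filter(df, ["x1", "x2"], limit=10)
        assert len(retained10) == 1

    def test_orthogonal_predictors_all_kept_with_unit_vif(self, rng):
        x = rng.normal(size=(50, 3))
        q, _ = np.linalg.qr(x - x.mean(axis=0))  # mean-zero orthogonal columns
        df = pd.DataFrame(q, columns=["a", "b", "c"])
        retained, vifs = vif_filter(df, ["a", "b", "c"])
        assert retained == ["a", "b", "c"]
        assert all(v == pytest.approx(1.0, abs=1e-8) for v in vifs.values())

    def test_duplicated_predictor_removed_first(self, rng):
        x = rng.normal(0, 1, 100)
        df = pd.DataFrame({"x": x, "x_copy": x.copy(), "y": rng.normal(0, 1, 100)})
        retained, vifs = vif_filter(df, ["x", "x_copy", "y"])
        assert "y" in retained
        assert len(retained) == 2
        assert all(np.isfinite(v) for v in vifs.values())


class TestROC:
    def test_perfect_separation_auc_one(self):
        roc = roc_analysis([4, 3, 2, 1], [1, 1, 0, 0], "greater")
        assert roc.auc == 1.0
        assert roc.youden_sensitivity == 1.0 and roc.youden_specificity == 1.0

    def test_ties_match_brute_force_concordance(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 6, n).astype(float)  # many ties
            roc = roc_analysis(scores, labels, "greater")
            pos, neg = scores[labels == 1], scores[labels == 0]
            conc = np.mean([
                1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg
            ])
            assert roc.auc == pytest.approx(conc, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        scores = rng.normal(0, 1, 200)
        labels = (rng.random(200) < 0.4).astype(int)
        roc = roc_analysis(scores, labels, "greater")
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 5), shift=st.floats(-10, 10))
    def test_auc_invariant_under_monotone_transform(self, seed, scale, shift):
        r = np.random.default_rng(seed)
        scores = r.normal(0, 1, 60)
        labels = np.concatenate([np.ones(25, int), np.zeros(35, int)])
        base = roc_analysis(scores, labels, "greater").auc
        affine = roc_analysis(scale * scores + shift, labels, "greater").auc
        expo = roc_analysis(np.exp(scores), labels, "greater").auc
        assert affine == pytest.approx(base, abs=1e-12)
        assert expo == pytest.approx(base, abs=1e-12)

    def test_direction_reversal_flips_auc(self, rng):
        scores = rng.normal(0, 1, 100)
        labels = (rng.random(100) < 0.5).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = roc_analysis(scores, labels, "greater").auc
        b = roc_analysis(scores, labels, "lesser").auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_youden_point_consistent_with_cutoff(self, rng):
        scores = rng.normal(0, 1, 150)
        labels = (scores + rng.normal(0, 1, 150) > 0).astype(int)
        roc = roc_analysis(scores, labels, "greater")
        pos, neg = scores[labels == 1], scores[labels == 0]
        assert roc.youden_sensitivity == pytest.approx((pos >= roc.youden_cutoff).mean())
        assert roc.youden_specificity == pytest.approx((neg < roc.youden_cutoff).mean())
        # maximality over all empirical operating points
        js = [
            (pos >= c).mean() + (neg < c).mean() - 1
            for c in np.concatenate([scores, [scores.min() - 1, scores.max() + 1]])
        ]
        assert roc.youden_index >= max(js) - 1e-12

    def test_lesser_direction_cutoff_semantics(self, rng):
        # low scores predict the event (as for HU_ratio)
        pos = rng.normal(-1, 1, 80)
        neg = rng.normal(1, 1, 80)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(80, int), np.zeros(80, int)])
        roc = roc_analysis(scores, labels, "lesser")
        assert roc.auc > 0.8
        assert roc.youden_sensitivity == pytest.approx((pos <= roc.youden_cutoff).mean())
        assert roc.youden_specificity == pytest.approx((neg > roc.youden_cutoff).mean())

    def test_one_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([1.0, 2.0], [1, 1], "greater")


class TestBinormalAUC:
    def test_symmetry_gives_half(self):
        assert binormal_auc(0, 1, 0, 1) == pytest.approx(0.5)

    def test_large_separation_tends_to_one(self):
        assert binormal_auc(100, 1, 0, 1) > 0.999999

    def test_agrees_with_large_empirical_binormal_sample(self, rng):
        mu_p, sd_p, mu_n, sd_n = 1.2, 1.5, 0.0, 1.0
        n = 200_000
        scores = np.concatenate([rng.normal(mu_p, sd_p, n), rng.normal(mu_n, sd_n, n)])
        labels = np.concatenate([np.ones(n, int), np.zeros(n, int)])
        emp = roc_analysis(scores, labels, "greater").auc
        ana = binormal_auc(mu_p, sd_p, mu_n, sd_n)
        # 3 SEs of the empirical AUC at this n
        assert abs(emp - ana) < 3 * 0.5 / np.sqrt(n)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            binormal_auc(0, 0, 0, 1)


class TestMultivariate:
    def test_ci_brackets_and_vif_reported(self):
        df = simulate_cohort(seed=6)
        fit = multivariate_logistic(df, ["hu_delta", "hu_ratio", "wbc"])
        t = fit.table()
        assert ((t["ci_low"] <= t["coef"]) & (t["coef"] <= t["ci_high"])).all()
        assert (t["vif"] >= 1).all()
        assert fit.converged

    def test_expected_sign_pattern_under_group_structure(self):
        # residual group: higher HU_delta, lower HU_ratio
        df = simulate_cohort(seed=6)
        fit = multivariate_logistic(df, ["hu_delta", "hu_ratio"])
        assert fit.coef["hu_delta"] > 0
        assert fit.coef["hu_ratio"] < 0

    def test_no_variables_rejected(self):
        df = simulate_cohort(seed=6)
        with pytest.raises(ValueError):
            multivariate_logistic(df, [])
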