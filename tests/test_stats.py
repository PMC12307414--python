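"""Inferential layer: ANOVA, correlations, regression, mediation, moderation,
bifactor scoring and omega reliability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from banditglx.stats import (
    BifactorLoadings,
    baron_kenny,
    bonferroni_posthoc,
    correlate,
    factor_scores,
    moderation,
    multiple_regression,
    omega_coefficients,
    rm_anova_gg,
)


class TestRmAnova:
    def test_two_conditions_reduce_to_paired_t(self, rng):
        X = rng.normal(0, 1, (15, 2))
        X[:, 1] += 0.5
        res = rm_anova_gg(X)
        t, p = sps.ttest_rel(X[:, 0], X[:, 1])
        assert res.gg_epsilon == pytest.approx(1.0)
        assert res.F == pytest.approx(t**2, rel=1e-10)
        assert res.p_gg == pytest.approx(p, rel=1e-9)

    def test_hand_computed_small_example(self):
        # 4 subjects x 3 conditions, integer entries
        X = np.array([[1, 2, 4], [2, 3, 5], [0, 1, 2], [3, 5, 6]], float)
        n, k = X.shape
        grand = X.mean()
        ss_cond = n * ((X.mean(0) - grand) ** 2).sum()
        resid = X - X.mean(1)[:, None] - X.mean(0)[None, :] + grand
        F_hand = (ss_cond / (k - 1)) / ((resid**2).sum() / ((n - 1) * (k - 1)))
        res = rm_anova_gg(X)
        assert res.F == pytest.approx(F_hand, rel=1e-12)
        assert res.df1 == 2 and res.df2 == 6
        assert res.df1_mv == 2 and res.df2_mv == 2

    def test_against_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        X = rng.normal(0, 1, (12, 4)) + rng.normal(0, 0.5, (12, 1))
        X[:, 2] += 0.8
        long = pd.DataFrame(
            {
                "y": X.ravel(),
                "subject": np.repeat(np.arange(12), 4),
                "cond": np.tile(np.arange(4), 12),
            }
        )
        aov = pg.rm_anova(
            data=long, dv="y", within="cond", subject="subject", correction=True
        )
        res = rm_anova_gg(X)
        assert res.F == pytest.approx(float(aov["F"].iloc[0]), rel=1e-6)
        assert res.gg_epsilon == pytest.approx(float(aov["eps"].iloc[0]), rel=1e-6)
        assert res.p_gg == pytest.approx(float(aov["p_GG_corr"].iloc[0]), rel=1e-5)

    def test_epsilon_bounds_random_data(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 15))
            k = int(rng.integers(2, 6))
            res = rm_anova_gg(rng.normal(0, 1, (n, k)))
            assert 1.0 / (k - 1) - 1e-12 <= res.gg_epsilon <= 1.0 + 1e-12

    def test_compound_symmetry_epsilon_near_one(self, rng):
        # equicorrelated conditions satisfy sphericity: expect eps near 1
        subj = rng.normal(0, 1.0, (300, 1))
        X = subj + rng.normal(0, 1.0, (300, 4))
        assert rm_anova_gg(X).gg_epsilon > 0.95

    def test_missing_cells_rejected(self):
        X = np.ones((5, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_gg(X)


class TestPosthoc:
    def test_rules(self, rng):
        X = rng.normal(0, 1, (10, 3))
        X[:, 2] = X[:, 0]  # identical pair
        names = ["a", "b", "c"]
        res = bonferroni_posthoc(X, names, [("a", "c")])
        assert res[0].t == 0.0 and res[0].p_adjusted == 1.0
        single = bonferroni_posthoc(X, names, [("a", "b")])
        assert single[0].p_adjusted == pytest.approx(single[0].p_raw)
        triple = bonferroni_posthoc(X, names, [("a", "b"), ("a", "c"), ("b", "c")])
        assert triple[0].p_adjusted == pytest.approx(min(1.0, 3 * triple[0].p_raw))
        with pytest.raises(ValueError):
            bonferroni_posthoc(X, names, [("a", "z")])


class TestCorrelate:
    def test_perfect_and_monotone(self):
        x = np.arange(10.0)
        assert correlate(x, x).r == pytest.approx(1.0)
        y = np.exp(x)
        res_s = correlate(x, y, method="spearman")
        res_p = correlate(x, y, method="pearson")
        assert res_s.r == pytest.approx(1.0)
        assert res_p.r < 1.0

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 7, 5])
        r_hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert correlate(x, y).r == pytest.approx(r_hand, abs=1e-12)

    def test_bonferroni_and_errors(self):
        x = np.arange(8.0)
        y = x + np.r_[0.1, -0.2, 0.3, 0.0, 0.2, -0.1, 0.05, 0.0]
        res = correlate(x, y, m=10)
        assert res.p_adjusted == pytest.approx(min(1.0, 10 * res.p_raw))
        assert res.p_adjusted >= res.p_raw
        with pytest.raises(ValueError):
            correlate(x, np.zeros(8))
        with pytest.raises(ValueError):
            correlate(x[:3], y[:3])


class TestRegression:
    def test_exact_fit(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        y = 2 + 3 * X["a"] - X["b"]
        res = multiple_regression(y, X)
        assert res.rsquared == pytest.approx(1.0)
        assert res.rsquared_adj == pytest.approx(1.0)
        assert res.params["a"] == pytest.approx(3.0)

    def test_single_predictor_f_equals_t_squared(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=25)})
        y = 0.5 * X["a"] + rng.normal(size=25)
        res = multiple_regression(y, X)
        t = res.params["a"] / res.bse["a"]
        assert res.F_overall == pytest.approx(t**2, rel=1e-10)

    def test_rank_deficiency_named(self, rng):
        a = rng.normal(size=20)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="b"):
            multiple_regression(rng.normal(size=20), X)

    def test_adjusted_r2_below_r2(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = X["a"] + rng.normal(size=40)
        res = multiple_regression(y, X)
        assert res.rsquared_adj <= res.rsquared


class TestMediation:
    def test_constructed_full_mediation(self, rng):
        n = 300
        x = rng.normal(size=n)
        m = x + rng.normal(size=n)
        y = m + 0.3 * rng.normal(size=n)
        res = baron_kenny(x, m, y)
        assert res.p_a < 0.05 and res.p_b < 0.05 and res.p_c < 0.05
        assert abs(res.c_prime) < abs(res.c)
        assert res.verdict in ("full", "partial")

    def test_independent_iv_gives_none(self, rng):
        hits = 0
        for _ in range(40):
            x = rng.normal(size=50)
            m = rng.normal(size=50)
            y = m + rng.normal(size=50)
            if baron_kenny(x, m, y).verdict == "none":
                hits += 1
        assert hits >= 34  # step 1 fails at ~rate 1 - alpha

    def test_affine_invariance(self, rng):
        x = rng.normal(size=80)
        m = 0.6 * x + rng.normal(size=80)
        y = 0.7 * m + rng.normal(size=80)
        r1 = baron_kenny(x, m, y)
        r2 = baron_kenny(5 + 2 * x, -3 * m, 100 * y - 7)
        assert r1.c == pytest.approx(abs(r2.c))
        assert r1.p_c == pytest.approx(r2.p_c)
        assert r1.p_c_prime == pytest.approx(r2.p_c_prime)

    def test_collinear_mediator_rejected(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(ValueError):
            baron_kenny(x, 2 * x, rng.normal(size=30))

    def test_bootstrap_ci_brackets_indirect(self, rng):
        n = 200
        x = rng.normal(size=n)
        m = 0.7 * x + rng.normal(size=n)
        y = 0.7 * m + rng.normal(size=n)
        res = baron_kenny(x, m, y, n_boot=200, seed=1)
        lo, hi = res.indirect_ci
        assert lo < res.indirect < hi
        assert lo > 0  # clearly positive indirect path


class TestModeration:
    def test_interaction_power(self, rng):
        hits = 0
        for _ in range(20):
            n = 200
            x = rng.normal(size=n)
            w = rng.normal(size=n)
            y = 0.3 * x + 0.3 * w + 0.5 * x * w + rng.normal(size=n)
            if moderation(x, w, y).p_interaction < 0.05:
                hits += 1
        assert hits >= 18

    def test_centering_invariance(self, rng):
        x = rng.normal(size=100)
        w = rng.normal(size=100)
        y = 0.4 * x + 0.2 * w + 0.3 * x * w + rng.normal(size=100)
        r1 = moderation(x, w, y)
        r2 = moderation(x + 10, w - 4, y)
        assert r1.b_interaction == pytest.approx(r2.b_interaction)
        assert r1.p_interaction == pytest.approx(r2.p_interaction)

    def test_constant_moderator_rejected(self, rng):
        with pytest.raises(ValueError):
            moderation(rng.normal(size=20), np.ones(20), rng.normal(size=20))

    def test_reduced_model_reported(self, rng):
        x = rng.normal(size=60)
        w = rng.normal(size=60)
        y = 0.8 * w + rng.normal(size=60)
        res = moderation(x, w, y)
        assert res.reduced is not None
        assert set(res.reduced.params.index) == {"const", "iv", "moderator"}


class TestBifactor:
    def test_single_perfect_item(self, rng):
        loadings = BifactorLoadings([1.0], np.zeros((1, 1)), [0.0])
        x = rng.normal(size=(50, 1))
        scores = factor_scores(x, loadings)
        z = (x[:, 0] - x[:, 0].mean()) / x[:, 0].std()
        np.testing.assert_allclose(scores, z, atol=1e-10)

    def test_zero_general_loadings_zero_scores(self, rng):
        loadings = BifactorLoadings(
            np.zeros(4), np.full((4, 1), 0.5), np.full(4, 0.75)
        )
        scores = factor_scores(rng.normal(size=(20, 4)), loadings)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_scores_match_direct_solve(self, rng):
        general = np.array([0.7, 0.6, 0.5, 0.6, 0.4, 0.55])
        group = np.zeros((6, 2))
        group[:3, 0] = 0.4
        group[3:, 1] = 0.35
        uniq = 1 - general**2 - (group**2).sum(axis=1)
        loadings = BifactorLoadings(general, group, uniq)
        X = rng.normal(size=(40, 6))
        scores = factor_scores(X, loadings)
        sigma = np.outer(general, general) + group @ group.T + np.diag(uniq)
        Z = (X - X.mean(0)) / X.std(0)
        expected = Z @ np.linalg.solve(sigma, general)
        np.testing.assert_allclose(scores, expected, atol=1e-10)

    def test_invalid_loadings(self):
        with pytest.raises(ValueError):
            BifactorLoadings([0.9], np.array([[0.9]]), [0.1])  # communality > 1
        with pytest.raises(ValueError):
            BifactorLoadings([0.5], np.zeros((1, 1)), [-0.1])


class TestOmega:
    def test_hand_computed_example(self):
        loadings = BifactorLoadings(
            np.full(8, 0.7), np.zeros((8, 1)), np.full(8, 0.51)
        )
        res = omega_coefficients(loadings)
        assert res.omega_hierarchical == pytest.approx(31.36 / 35.44, abs=1e-6)
        assert res.omega_hierarchical == pytest.approx(0.885, abs=1e-3)
        assert res.omega_total == res.omega_hierarchical  # no group factors

    def test_degenerate_cases(self):
        zero_gen = BifactorLoadings(np.zeros(5), np.full((5, 1), 0.5), np.full(5, 0.75))
        assert omega_coefficients(zero_gen).omega_hierarchical == 0.0
        perfect = BifactorLoadings(np.full(4, 1.0), np.zeros((4, 1)), np.zeros(4))
        res = omega_coefficients(perfect)
        assert res.omega_hierarchical == 1.0 and res.omega_total == 1.0

    def test_ordering_on_random_valid_loadings(self, rng):
        for _ in range(1000):
            p = int(rng.integers(3, 12))
            g = rng.uniform(0, 0.8, p)
            gr = np.zeros((p, 2))
            gr[: p // 2, 0] = rng.uniform(0, 0.5, p // 2)
            gr[p // 2 :, 1] = rng.uniform(0, 0.5, p - p // 2)
            max_u = 1 - g**2 - (gr**2).sum(axis=1)
            u = rng.uniform(0, 1, p) * max_u
            res = omega_coefficients(BifactorLoadings(g, gr, u))
            assert 0 <= res.omega_hierarchical <= res.omega_total <= 1 + 1e-12
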