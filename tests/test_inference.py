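"""Posterior sampling, PSIS-LOO and model comparison."""

import numpy as np
import pytest
from scipy.stats import norm

from banditglx.models import AgentParameters
from banditglx.inference import (
    BanditModel,
    LooResult,
    PriorSpec,
    SamplerConfig,
    compare_models,
    fit_subject,
    parameter_recovery,
    pointwise_loglik_matrix,
    psis_loo,
)
from banditglx.task import ChoiceDataset, TaskConfig, make_block_schedule, simulate_agent

FAST = SamplerConfig(chains=2, draws=500, warmup=400, seed=0)


class TestFitting:
    def test_convergence_contract_default_config(self, model4_dataset):
        res = BanditModel(model4_dataset, model=4).fit(seed=1)
        assert all(r <= 1.05 for r in res.rhat.values())
        assert all(e >= 200 for e in res.ess.values())
        assert res.converged
        summ = res.summary()
        assert set(summ.index) == {"epsilon", "tau", "decay"}
        assert ((summ["mean"] >= 0) & (summ["mean"] <= 1)).all()

    def test_seeded_fits_reproducible(self, model4_dataset):
        a = BanditModel(model4_dataset, 4).fit(config=FAST)
        b = BanditModel(model4_dataset, 4).fit(config=FAST)
        assert np.array_equal(a.draws, b.draws)

    def test_single_trial_posterior_is_prior(self):
        """The first choice carries no information about epsilon."""
        ds = ChoiceDataset("s", "gain", [0], [1])
        res = BanditModel(ds, model=2).fit(
            config=SamplerConfig(chains=2, draws=3000, warmup=500, seed=2)
        )
        eps = res.flat_draws[:, 0]
        assert eps.mean() == pytest.approx(0.5, abs=0.03)
        assert eps.std() == pytest.approx(np.sqrt(1 / 12), abs=0.03)

    def test_concentrated_prior_dominates(self):
        ds = ChoiceDataset("s", "gain", [0, 1, 0, 1], [1, 0, 1, 0])
        prior = PriorSpec({"epsilon": (300.0, 700.0)})  # sharply peaked at 0.3
        res = BanditModel(ds, model=2, prior=prior).fit(config=FAST)
        assert res.posterior_mean["epsilon"] == pytest.approx(0.3, abs=0.02)

    def test_epsilon_ordering_recovered(self):
        cfg = TaskConfig(n_trials=160)
        ordered = 0
        n_rep = 12
        for rep in range(n_rep):
            sched = make_block_schedule(cfg, 100 + rep)
            hi = simulate_agent(3, AgentParameters(epsilon=0.9, tau=1.0), sched, 200 + rep)
            lo = simulate_agent(3, AgentParameters(epsilon=0.1, tau=1.0), sched, 300 + rep)
            m_hi = BanditModel(hi, 3).fit(config=FAST).posterior_mean["epsilon"]
            m_lo = BanditModel(lo, 3).fit(config=FAST).posterior_mean["epsilon"]
            ordered += m_hi > m_lo
        assert ordered >= n_rep - 1

    def test_empty_data_refused(self):
        with pytest.raises(ValueError):
            BanditModel(ChoiceDataset("s", "gain", [], []), 2)

    def test_shared_fit_across_blocks(self, model4_dataset):
        two = BanditModel([model4_dataset, model4_dataset], model=4)
        assert two.n_obs == 2 * model4_dataset.n_trials
        assert two.resets.sum() == 2
        single_ll = BanditModel(model4_dataset, 4).loglike([0.5, 0.8, 0.7])
        assert two.loglike([0.5, 0.8, 0.7]) == pytest.approx(2 * single_ll)


class TestLoglikMatrix:
    def test_single_draw_delegates(self, model4_dataset):
        model = BanditModel(model4_dataset, 4)
        res = model.fit(config=FAST)
        theta = np.array([0.6, 0.8, 0.7])
        res.draws = theta[None, None, :].repeat(2, axis=0)
        mat = res.loglik_matrix()
        np.testing.assert_allclose(mat[0], model.loglike_pointwise(theta), atol=1e-12)
        assert (mat == mat[0]).all()

    def test_shape_check(self, model4_dataset, schedule80):
        res = BanditModel(model4_dataset, 4).fit(config=FAST)
        other = simulate_agent(2, AgentParameters(epsilon=0.3), schedule80, 99)
        mat = pointwise_loglik_matrix(res, model4_dataset)
        assert mat.shape == (2 * 500, 80)
        with pytest.raises(ValueError):
            pointwise_loglik_matrix(res, ChoiceDataset("s", "gain", [0], [1]))
        with pytest.raises(ValueError):
            pointwise_loglik_matrix(res, other)


class TestPsisLoo:
    def test_degenerate_posterior_identity(self, rng):
        ll_row = rng.normal(-0.7, 0.1, 40)
        mat = np.tile(ll_row, (500, 1))
        res = psis_loo(mat)
        assert res.elpd_loo == ll_row.sum()
        assert res.looic == -2.0 * ll_row.sum()
        np.testing.assert_array_equal(res.pointwise, ll_row)

    def test_looic_identity_and_pointwise_sum(self, model4_dataset):
        res = BanditModel(model4_dataset, 4).fit(config=FAST).loo()
        assert res.looic == -2.0 * res.elpd_loo
        assert res.pointwise.sum() == pytest.approx(res.elpd_loo, rel=1e-12)

    def test_conjugate_normal_toy(self, rng):
        """Exact leave-one-out for the normal-normal model with known variance."""
        n, prior_var, sigma2 = 30, 100.0, 1.0
        y = rng.normal(0.7, 1.0, n)

        def post(ys):
            prec = len(ys) / sigma2 + 1 / prior_var
            return (ys.sum() / sigma2) / prec, 1 / prec

        exact = 0.0
        for i in range(n):
            m_i, v_i = post(np.delete(y, i))
            exact += norm.logpdf(y[i], m_i, np.sqrt(v_i + sigma2))

        m, v = post(y)
        thetas = rng.normal(m, np.sqrt(v), 4000)
        loglik = norm.logpdf(y[None, :], thetas[:, None], np.sqrt(sigma2))
        res = psis_loo(loglik)
        assert res.elpd_loo == pytest.approx(exact, abs=0.1)
        assert (res.pareto_k <= 0.7).all()

    def test_nonfinite_rejected(self):
        mat = np.zeros((200, 5))
        mat[3, 2] = np.inf
        with pytest.raises(ValueError, match="observation 2"):
            psis_loo(mat)

    def test_few_draws_warns(self):
        with pytest.warns(UserWarning, match="draws"):
            psis_loo(np.random.default_rng(0).normal(-1, 0.1, (50, 4)))


class TestComparison:
    @staticmethod
    def _loo_from(pointwise):
        pointwise = np.asarray(pointwise, float)
        return LooResult(
            elpd_loo=pointwise.sum(),
            looic=-2 * pointwise.sum(),
            pointwise=pointwise,
            pareto_k=np.zeros_like(pointwise),
        )

    def test_identical_models_tie_with_zero_se(self):
        pw = [-0.7, -0.6, -0.65]
        res = compare_models({1: {"a": self._loo_from(pw)}, 2: {"a": self._loo_from(pw)}})
        t = res.table.set_index("model_id")
        assert t.loc[2, "d_looic"] == pytest.approx(0.0)
        assert t.loc[2, "se_d_elpd"] == pytest.approx(0.0)

    def test_subject_order_invariance(self):
        a, b = self._loo_from([-0.7, -0.6]), self._loo_from([-0.9, -0.8])
        r1 = compare_models({1: {"s1": a, "s2": b}, 2: {"s1": b, "s2": a}})
        r2 = compare_models({1: {"s2": b, "s1": a}, 2: {"s2": a, "s1": b}})
        assert r1.table.set_index("model_id")["looic"].equals(
            r2.table.set_index("model_id")["looic"]
        )

    def test_missing_cell_error(self):
        good = self._loo_from([-0.7])
        with pytest.raises(ValueError, match=r"\(2, 's2'\)"):
            compare_models({1: {"s1": good, "s2": good}, 2: {"s1": good}})

    def test_winner_is_argmin(self):
        res = compare_models(
            {
                1: {"s": self._loo_from([-1.0, -1.0])},
                2: {"s": self._loo_from([-0.5, -0.5])},
            }
        )
        assert res.winner_id == 2
        assert res.table.iloc[0]["model_id"] == 2


class TestRecovery:
    def test_report_fields_and_reproducibility(self):
        rng = np.random.default_rng(1)
        true = np.column_stack(
            [rng.uniform(0.1, 0.9, 10), rng.uniform(0.4, 1.0, 10), rng.uniform(0.4, 0.9, 10)]
        )
        kw = dict(
            task_config=TaskConfig(n_trials=60),
            seed=5,
            sampler_config=SamplerConfig(chains=2, draws=300, warmup=300, seed=0),
        )
        rep1 = parameter_recovery(4, true, **kw)
        rep2 = parameter_recovery(4, true, **kw)
        assert rep1.correlation == rep2.correlation
        assert set(rep1.correlation) == {"epsilon", "tau", "decay"}
        assert rep1.eps_tau_posterior_corr is not None
        assert rep1.n_subjects == 10

    def test_constant_truth_gives_nan_correlation(self):
        true = np.full((10, 1), 0.5)
        rep = parameter_recovery(
            2, true, task_config=TaskConfig(n_trials=20), seed=2,
            sampler_config=SamplerConfig(chains=2, draws=200, warmup=200, seed=0),
        )
        assert np.isnan(rep.correlation["epsilon"])

    def test_minimum_subjects(self):
        with pytest.raises(ValueError):
            parameter_recovery(2, np.full((5, 1), 0.4))
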