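"""Bayesian fitting of the bandit models and PSIS-LOO model comparison.

The central objects follow the Model/Results convention: :class:`BanditModel`
wraps one subject's choice data together with a model variant and priors, and
``fit()`` returns a :class:`BanditResults` carrying posterior draws,
convergence diagnostics, a ``summary()`` table, and ``loo()``.

The sampler is a random-walk Metropolis on logit-transformed parameters —
well suited here because every model has at most three parameters, each on a
bounded support.  Chains are independent, step sizes adapt during warmup
only, and all randomness is seeded.

PSIS-LOO: importance ratios for leaving out one observation are smoothed by a
generalized-Pareto fit of the largest ratios (the smoothing itself is
delegated to :func:`arviz.psislw`); ``LOOIC = -2 * elpd_loo``.  A Pareto
shape diagnostic k > 0.7 flags unreliable observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import _kernels
from .models import AgentParameters, ModelSpec, get_model
from .task import BlockSchedule, ChoiceDataset, TaskConfig, make_block_schedule, simulate_agent

__all__ = [
    "PriorSpec",
    "SamplerConfig",
    "BanditModel",
    "BanditResults",
    "LooResult",
    "ModelComparison",
    "RecoveryReport",
    "fit_subject",
    "fit_population",
    "pointwise_loglik_matrix",
    "psis_loo",
    "compare_models",
    "parameter_recovery",
    "model_recovery_study",
    "PARETO_K_THRESHOLD",
]

PARETO_K_THRESHOLD = 0.7
RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class PriorSpec:
    """Independent Beta priors on [0, 1] per parameter; default uniform.

    ``params`` maps a parameter name to a ``(alpha, beta)`` Beta shape pair.
    Unlisted parameters get the uniform Beta(1, 1).
    """

    params: dict = field(default_factory=dict)

    def shapes_for(self, model: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
        a = np.ones(model.n_params)
        b = np.ones(model.n_params)
        for j, name in enumerate(model.parameter_names):
            if name in self.params:
                aj, bj = self.params[name]
                if aj <= 0 or bj <= 0:
                    raise ValueError(f"Beta shapes for {name} must be positive")
                a[j], b[j] = aj, bj
        return a, b

    def logpdf(self, model: ModelSpec, theta: np.ndarray) -> float:
        from scipy.stats import beta as beta_dist

        a, b = self.shapes_for(model)
        return float(np.sum(beta_dist.logpdf(theta, a, b)))


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    draws: int = 2000  # kept iterations per chain, after warmup
    warmup: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("need at least 2 chains for split-R-hat diagnostics")


def _stack_blocks(data) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[ChoiceDataset]]:
    """Concatenate one or more blocks, marking value resets at block starts."""
    blocks = [data] if isinstance(data, ChoiceDataset) else list(data)
    if not blocks:
        raise ValueError("no data supplied")
    choices, outcomes, resets = [], [], []
    for ds in blocks:
        if ds.n_trials == 0:
            raise ValueError("empty block in data")
        choices.append(ds.choices)
        outcomes.append(ds.outcomes)
        r = np.zeros(ds.n_trials, dtype=np.bool_)
        r[0] = True
        resets.append(r)
    return (
        np.concatenate(choices).astype(np.int64),
        np.concatenate(outcomes).astype(np.int64),
        np.concatenate(resets),
        blocks,
    )


class BanditModel:
    """One subject's choices under one Rescorla-Wagner variant.

    Parameters
    ----------
    data : ChoiceDataset or sequence of ChoiceDataset
        Passing several blocks fits a single shared parameter vector, with
        option values re-initialized at each block start.
    model : int, str or ModelSpec
        Which of the six variants.
    prior : PriorSpec, optional
        Defaults to independent uniform priors.
    """

    def __init__(self, data, model=4, prior: PriorSpec | None = None):
        self.spec = get_model(model)
        self.prior = prior or PriorSpec()
        self.choices, self.outcomes, self.resets, self.blocks = _stack_blocks(data)
        self.subject_id = self.blocks[0].subject_id
        self._idx = _kernels.ACTIVE_IDX[self.spec.model_id]
        self._complement = _kernels.COMPLEMENT[self.spec.model_id]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, subject, model=4, block=None, **kw):
        """Build from a tidy choices table (columns subject/block/trial/choice/outcome)."""
        from .task import from_frame

        sub = df[df["subject"].astype(str) == str(subject)]
        if block is not None:
            sub = sub[sub["block"] == block]
        blocks = from_frame(sub)
        if not blocks:
            raise ValueError(f"no rows for subject {subject!r}")
        data = blocks[0] if len(blocks) == 1 else blocks
        return cls(data, model=model, **kw)

    @property
    def n_obs(self) -> int:
        return int(self.choices.size)

    def loglike(self, params) -> float:
        return float(np.sum(self.loglike_pointwise(params)))

    def loglike_pointwise(self, params) -> np.ndarray:
        theta = self._as_active_vector(params)
        full = _kernels.expand_params(self.spec.model_id, theta)
        out = np.empty(self.n_obs)
        _kernels.loglik_pointwise(
            self._complement, full[0], full[1], full[2], full[3],
            self.choices, self.outcomes, self.resets, out,
        )
        return out

    def _as_active_vector(self, params) -> np.ndarray:
        if isinstance(params, AgentParameters):
            return params.as_vector(self.spec)
        theta = np.asarray(params, float)
        if theta.shape != (self.spec.n_params,):
            raise ValueError(
                f"{self.spec.name} expects {self.spec.n_params} parameters"
            )
        if np.any(theta < 0) or np.any(theta > 1):
            raise ValueError("parameters must lie in [0, 1]")
        return theta

    def fit(
        self,
        chains: int = 4,
        draws: int = 2000,
        warmup: int = 1000,
        seed: int = 0,
        config: SamplerConfig | None = None,
    ) -> "BanditResults":
        """Sample the posterior; see :class:`SamplerConfig` for defaults."""
        cfg = config or SamplerConfig(chains=chains, draws=draws, warmup=warmup, seed=seed)
        a, b = self.prior.shapes_for(self.spec)
        chain_seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.chains).astype(np.int64)
        all_draws = np.empty((cfg.chains, cfg.draws, self.spec.n_params))
        accept = np.empty(cfg.chains)
        for c in range(cfg.chains):
            d, acc = _kernels.mh_chain(
                self._complement, self._idx, a, b,
                self.choices, self.outcomes, self.resets,
                cfg.warmup, cfg.draws, int(chain_seeds[c]),
            )
            all_draws[c] = d
            accept[c] = acc
        return BanditResults(self, all_draws, accept, cfg)


class BanditResults:
    """Posterior draws plus diagnostics for one fitted subject/model."""

    def __init__(self, model: BanditModel, draws: np.ndarray, accept_rates, config: SamplerConfig):
        self.model = model
        self.spec = model.spec
        self.subject_id = model.subject_id
        self.draws = draws  # (chains, draws, P)
        self.accept_rates = np.asarray(accept_rates)
        self.config = config
        self._rhat = None
        self._ess = None

    @property
    def parameter_names(self) -> tuple:
        return self.spec.parameter_names

    @property
    def flat_draws(self) -> np.ndarray:
        """All chains pooled, shape (S, P)."""
        return self.draws.reshape(-1, self.spec.n_params)

    @property
    def posterior_mean(self) -> dict[str, float]:
        means = self.flat_draws.mean(axis=0)
        return dict(zip(self.parameter_names, means.tolist()))

    @property
    def posterior_params(self) -> AgentParameters:
        return AgentParameters(**self.posterior_mean)

    def _diagnostics(self):
        if self._rhat is None:
            import arviz as az

            rhat, ess = {}, {}
            for j, name in enumerate(self.parameter_names):
                chains = self.draws[:, :, j]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rhat[name] = float(az.rhat(chains))
                    ess[name] = float(az.ess(chains))
            self._rhat, self._ess = rhat, ess
        return self._rhat, self._ess

    @property
    def rhat(self) -> dict[str, float]:
        return self._diagnostics()[0]

    @property
    def ess(self) -> dict[str, float]:
        return self._diagnostics()[1]

    @property
    def converged(self) -> bool:
        return all(r <= RHAT_THRESHOLD for r in self.rhat.values())

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, 95% credible interval and diagnostics per parameter."""
        flat = self.flat_draws
        rhat, ess = self._diagnostics()
        rows = []
        for j, name in enumerate(self.parameter_names):
            x = flat[:, j]
            lo, hi = np.percentile(x, [2.5, 97.5])
            rows.append(
                {
                    "parameter": name,
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    "hdi_2.5%": lo,
                    "hdi_97.5%": hi,
                    "r_hat": rhat[name],
                    "ess": ess[name],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def loglik_matrix(self) -> np.ndarray:
        """S x N pointwise log-likelihood over the pooled posterior draws."""
        return _kernels.loglik_matrix(
            self.model._complement,
            self.model._idx,
            self.flat_draws,
            self.model.choices,
            self.model.outcomes,
            self.model.resets,
        )

    def loo(self) -> "LooResult":
        return psis_loo(self.loglik_matrix())

    def simulate(self, schedule: BlockSchedule, seed: int = 0) -> ChoiceDataset:
        """Posterior-predictive play: simulate with the posterior-mean parameters."""
        return simulate_agent(self.spec, self.posterior_params, schedule, seed,
                              subject_id=self.subject_id)

    def plot_posterior(self, axes=None):
        """Histogram of each parameter's pooled posterior draws."""
        import matplotlib.pyplot as plt

        flat = self.flat_draws
        if axes is None:
            _, axes = plt.subplots(1, self.spec.n_params, figsize=(3 * self.spec.n_params, 2.5))
        axes = np.atleast_1d(axes)
        for ax, (j, name) in zip(axes, enumerate(self.parameter_names)):
            ax.hist(flat[:, j], bins=40, range=(0, 1), color="steelblue")
            ax.set_xlabel(name)
        return axes

    def to_dict(self) -> dict:
        rhat, ess = self._diagnostics()
        return {
            "model_id": self.spec.model_id,
            "subject_id": self.subject_id,
            "posterior_mean": self.posterior_mean,
            "r_hat": rhat,
            "ess": ess,
            "converged": self.converged,
            "accept_rates": self.accept_rates.tolist(),
            "sampler": {
                "chains": self.config.chains,
                "draws": self.config.draws,
                "warmup": self.config.warmup,
                "seed": self.config.seed,
            },
        }


# backwards-friendly functional surface -------------------------------------

def fit_subject(
    model, data, prior: PriorSpec | None = None, sampler_config: SamplerConfig | None = None
) -> BanditResults:
    """Fit one model to one subject's choices (functional wrapper)."""
    return BanditModel(data, model=model, prior=prior).fit(
        config=sampler_config or SamplerConfig()
    )


def pointwise_loglik_matrix(fit: BanditResults, data=None) -> np.ndarray:
    """S x N matrix of log p(choice_n | params_s, history).

    If ``data`` is given it must match the fitted data (shape check); the
    matrix always reuses the model's pointwise likelihood recursion.
    """
    if data is not None:
        choices, _, _, _ = _stack_blocks(data)
        if choices.size != fit.model.n_obs:
            raise ValueError(
                f"data has {choices.size} trials but fit used {fit.model.n_obs}"
            )
        if not np.array_equal(choices, fit.model.choices):
            raise ValueError("data does not match the fitted choice sequence")
    return fit.loglik_matrix()


def fit_population(
    datasets,
    model,
    sampler_config: SamplerConfig | None = None,
) -> tuple[PriorSpec, list]:
    """Two-stage empirical-Bayes hierarchical mode (non-default).

    Every subject is first fitted under uniform priors; a Beta population
    distribution per parameter is then moment-matched to the first-pass
    posterior means, and all subjects are refitted under that shared prior.
    Returns the estimated population prior and the refitted results.
    """
    spec = get_model(model)
    cfg = sampler_config or SamplerConfig()
    first = [fit_subject(spec, ds, sampler_config=cfg) for ds in datasets]
    means = np.array([r.flat_draws.mean(axis=0) for r in first])
    shapes = {}
    for j, name in enumerate(spec.parameter_names):
        m = float(np.clip(means[:, j].mean(), 1e-3, 1 - 1e-3))
        v = float(max(np.var(means[:, j], ddof=1), 1e-4))
        nu = max(m * (1 - m) / v - 1.0, 0.1)
        shapes[name] = (m * nu, (1 - m) * nu)
    prior = PriorSpec(shapes)
    refits = [
        BanditModel(ds, model=spec, prior=prior).fit(config=cfg) for ds in datasets
    ]
    return prior, refits


@dataclass
class LooResult:
    """PSIS-LOO estimate for one fitted model."""

    elpd_loo: float
    looic: float
    pointwise: np.ndarray
    pareto_k: np.ndarray

    @property
    def n_bad_k(self) -> int:
        return int(np.sum(self.pareto_k > PARETO_K_THRESHOLD))

    @property
    def warn(self) -> bool:
        return self.n_bad_k > 0


def psis_loo(loglik: np.ndarray) -> LooResult:
    """Pareto-smoothed importance-sampling leave-one-out from an S x N matrix.

    Per observation n, the leave-one-out importance ratios are 1/p(y_n|theta_s);
    the largest ratios are replaced by generalized-Pareto quantiles and
    elpd_n = log( sum_s w_s exp(l_sn) / sum_s w_s ).
    """
    import arviz as az

    loglik = np.asarray(loglik, float)
    if loglik.ndim != 2:
        raise ValueError("loglik must be an S x N matrix")
    bad = ~np.isfinite(loglik)
    if bad.any():
        s, n = np.argwhere(bad)[0]
        raise ValueError(f"non-finite log-likelihood at draw {s}, observation {n}")
    s_draws = loglik.shape[0]
    if s_draws < 100:
        warnings.warn(
            f"PSIS-LOO with only {s_draws} draws; results may be unstable", stacklevel=2
        )
    # smoothing wants shape (N, S) with samples on the last axis
    log_ratios = -loglik.T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lw, pareto_k = az.psislw(log_ratios)
    lw = np.asarray(lw)
    pareto_k = np.atleast_1d(np.asarray(pareto_k, float))
    # degenerate draws (zero-variance ratios) are exact: uniform weights, no tail
    degenerate = ~np.isfinite(pareto_k)
    pareto_k[degenerate] = 0.0
    pointwise = logsumexp(lw + loglik.T, axis=1)  # lw already normalized
    # constant columns have the exact answer; bypass logsumexp rounding
    const = np.ptp(loglik, axis=0) == 0.0
    pointwise[const] = loglik[0, const]
    elpd = float(pointwise.sum())
    return LooResult(elpd_loo=elpd, looic=-2.0 * elpd, pointwise=pointwise, pareto_k=pareto_k)


@dataclass
class ModelComparison:
    """Cohort-level LOOIC comparison across model variants."""

    table: pd.DataFrame  # per-model totals, sorted ascending by looic
    winner_id: int
    pointwise: dict[int, np.ndarray]  # concatenated per-observation elpd per model

    def __str__(self) -> str:
        return self.table.to_string()


def compare_models(loo_results: dict[int, dict]) -> ModelComparison:
    """Aggregate per-subject LOO into a model-comparison table.

    Parameters
    ----------
    loo_results : dict
        ``{model_id: {subject_id: LooResult}}``; every model must cover the
        same subjects.
    """
    model_ids = sorted(loo_results)
    subjects = {mid: set(loo_results[mid]) for mid in model_ids}
    union = set().union(*subjects.values())
    gaps = [
        (mid, sid) for mid in model_ids for sid in sorted(union) if sid not in subjects[mid]
    ]
    if gaps:
        raise ValueError(f"missing (model, subject) fits: {gaps}")
    order = sorted(union)

    pointwise = {
        mid: np.concatenate([loo_results[mid][sid].pointwise for sid in order])
        for mid in model_ids
    }
    totals = {mid: float(pointwise[mid].sum()) for mid in model_ids}
    looic = {mid: -2.0 * totals[mid] for mid in model_ids}
    winner = min(model_ids, key=lambda mid: looic[mid])

    rows = []
    for mid in model_ids:
        diff = pointwise[mid] - pointwise[winner]
        se = float(np.sqrt(diff.size * np.var(diff, ddof=0)))
        rows.append(
            {
                "model_id": mid,
                "parameters": ", ".join(get_model(mid).parameter_names),
                "elpd_loo": totals[mid],
                "looic": looic[mid],
                "d_looic": looic[mid] - looic[winner],
                "se_d_elpd": se,
                "n_subjects": len(order),
            }
        )
    table = pd.DataFrame(rows).sort_values("looic").reset_index(drop=True)
    return ModelComparison(table=table, winner_id=winner, pointwise=pointwise)


@dataclass
class RecoveryReport:
    """Generating-vs-recovered parameter agreement for one model."""

    model_id: int
    correlation: dict[str, float]
    bias: dict[str, float]
    rmse: dict[str, float]
    eps_tau_posterior_corr: float | None
    n_subjects: int
    n_trials: int
    n_excluded: int
    seed: int
    true_values: np.ndarray
    recovered: np.ndarray


@dataclass
class ModelRecoveryReport:
    """Which model wins LOOIC across replicate synthetic cohorts."""

    generating_model: int
    candidate_models: tuple
    winners: list
    n_cohorts: int
    n_subjects: int
    n_trials: int
    seed: int

    @property
    def win_rate(self) -> float:
        return float(np.mean([w == self.generating_model for w in self.winners]))


def model_recovery_study(
    generating_model: int = 4,
    candidate_models: tuple = (1, 2, 3, 4, 5, 6),
    n_cohorts: int = 20,
    n_subjects: int = 20,
    task_config: TaskConfig | None = None,
    param_range: tuple = (0.3, 0.7),
    sampler_config: SamplerConfig | None = None,
    seed: int = 0,
) -> ModelRecoveryReport:
    """Simulate cohorts from one model, fit all candidates, count LOOIC wins.

    Generating parameters are drawn uniformly from ``param_range`` (the
    mid-range by default) for every active parameter.
    """
    gen = get_model(generating_model)
    task_config = task_config or TaskConfig(n_trials=80)
    cfg = sampler_config or SamplerConfig(chains=2, draws=500, warmup=400, seed=0)
    winners = []
    for c in range(n_cohorts):
        root = np.random.SeedSequence([seed, c])
        states = root.generate_state(2 * n_subjects).astype(np.int64)
        rng = np.random.default_rng(root.spawn(1)[0])
        loo: dict[int, dict] = {int(m): {} for m in candidate_models}
        for i in range(n_subjects):
            theta = rng.uniform(param_range[0], param_range[1], gen.n_params)
            sched = make_block_schedule(task_config, int(states[2 * i]))
            data = simulate_agent(
                gen, AgentParameters.from_vector(gen, theta), sched,
                int(states[2 * i + 1]), subject_id=f"s{i}",
            )
            for m in candidate_models:
                res = BanditModel(data, model=int(m)).fit(
                    config=SamplerConfig(
                        cfg.chains, cfg.draws, cfg.warmup,
                        (seed * 131 + c * 977 + i * 13 + int(m)) % (2**31),
                    )
                )
                loo[int(m)][f"s{i}"] = res.loo()
        winners.append(compare_models(loo).winner_id)
    return ModelRecoveryReport(
        generating_model=gen.model_id,
        candidate_models=tuple(int(m) for m in candidate_models),
        winners=winners,
        n_cohorts=n_cohorts,
        n_subjects=n_subjects,
        n_trials=task_config.n_trials,
        seed=seed,
    )


def parameter_recovery(
    model,
    true_params: np.ndarray,
    task_config: TaskConfig | None = None,
    seed: int = 0,
    sampler_config: SamplerConfig | None = None,
    prior: PriorSpec | None = None,
    n_blocks: int = 1,
) -> RecoveryReport:
    """Simulate subjects at known parameters, refit, and score recovery.

    ``true_params`` is (n_subjects, P) on the model's active-parameter order.
    Each simulated subject gets fresh schedules seeded from ``seed``; with
    ``n_blocks > 1`` each subject plays several blocks (values re-initialized
    per block) fitted with one shared parameter vector, mirroring a session
    of consecutive task blocks.  Non-convergent fits are excluded (counted,
    never imputed).
    """
    spec = get_model(model)
    true_params = np.atleast_2d(np.asarray(true_params, float))
    n_subjects = true_params.shape[0]
    if n_subjects < 10:
        raise ValueError("parameter recovery needs at least 10 subjects")
    if true_params.shape[1] != spec.n_params:
        raise ValueError(f"{spec.name} expects {spec.n_params} parameters per subject")
    cfg = sampler_config or SamplerConfig()
    task_config = task_config or TaskConfig(n_trials=80)

    root = np.random.SeedSequence(seed)
    sub_seeds = root.generate_state(2 * n_subjects * n_blocks + 1) % (2**31)
    recovered = np.full_like(true_params, np.nan)
    eps_tau = []
    excluded = 0
    for i in range(n_subjects):
        params_i = AgentParameters.from_vector(spec, true_params[i])
        data = [
            simulate_agent(
                spec,
                params_i,
                make_block_schedule(task_config, int(sub_seeds[2 * (n_blocks * i + b)])),
                int(sub_seeds[2 * (n_blocks * i + b) + 1]),
                subject_id=f"s{i}",
            )
            for b in range(n_blocks)
        ]
        if n_blocks == 1:
            data = data[0]
        res = BanditModel(data, model=spec, prior=prior).fit(
            config=SamplerConfig(
                cfg.chains, cfg.draws, cfg.warmup,
                (cfg.seed * 65537 + int(sub_seeds[-1]) + i) % (2**31),
            )
        )
        if not res.converged:
            excluded += 1
            continue
        recovered[i] = res.flat_draws.mean(axis=0)
        if "tau" in spec.parameter_names:
            je = spec.parameter_names.index("epsilon")
            jt = spec.parameter_names.index("tau")
            eps_tau.append(np.corrcoef(res.flat_draws[:, je], res.flat_draws[:, jt])[0, 1])

    ok = ~np.isnan(recovered[:, 0])
    correlation, bias, rmse = {}, {}, {}
    for j, name in enumerate(spec.parameter_names):
        t, r = true_params[ok, j], recovered[ok, j]
        if np.std(t) == 0 or np.std(r) == 0:
            correlation[name] = float("nan")
        else:
            correlation[name] = float(np.corrcoef(t, r)[0, 1])
        bias[name] = float(np.mean(r - t))
        rmse[name] = float(np.sqrt(np.mean((r - t) ** 2)))

    return RecoveryReport(
        model_id=spec.model_id,
        correlation=correlation,
        bias=bias,
        rmse=rmse,
        eps_tau_posterior_corr=float(np.mean(eps_tau)) if eps_tau else None,
        n_subjects=n_subjects,
        n_trials=task_config.n_trials,
        n_excluded=excluded,
        seed=seed,
        true_values=true_params,
        recovered=recovered,
    )
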