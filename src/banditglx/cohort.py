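"""Synthetic study cohort: choices, metabolite panels, questionnaires.

The generator reproduces the statistical structure reported for the real
cohort so every downstream analysis can be exercised without access to the
data:

* a latent standard-normal factor drives each subject's baseline anterior
  insular cortex (AIC) Glx level;
* per-block error sensitivities are inverse-logit transforms of that latent
  plus noise, calibrated (by Gauss-Hermite quadrature, not trial and error)
  so the cohort-level Pearson correlation between measured baseline Glx and
  error sensitivity hits the configured targets (defaults 0.437 loss /
  0.408 gain);
* the general-psychopathology factor G is a linear function of standardized
  mean error sensitivity (default coefficient 0.762) plus an optional direct
  Glx path (default 0: full mediation);
* questionnaire items (PHQ-9, GAD-7, STAI-X1) arise from G through a single
  general factor plus an instrument factor, discretized by thresholds solved
  so expected sum scores match the configured means;
* AIC Glx drops during the gain block (default -2.21% of the preceding rest)
  and stays at the dropped level afterwards; the loss block and all mPFC
  series are null;
* choices are simulated from the winning model (error sensitivity, decision
  temperature, decay) on the 70/30 schedule, loss block before gain block.

Glx is produced in arbitrary institutional units; every downstream analysis
uses correlations or percent changes, so the scale is immaterial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .models import AgentParameters
from .task import (
    ChoiceDataset,
    TaskConfig,
    make_block_schedule,
    simulate_agent,
    to_frame,
    from_frame,
)

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "Cohort",
    "generate_cohort",
    "export_cohort",
    "load_cohort",
    "analysis_table",
]

REGIONS = ("AIC", "mPFC")
BLOCKS = ("rest1", "loss", "rest2", "gain", "rest3")

INSTRUMENTS = {
    # name: (n_items, min_score, max_score)
    "PHQ9": (9, 0, 3),
    "GAD7": (7, 0, 3),
    "STAIX1": (20, 1, 4),
}


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters for one synthetic cohort (defaults = study values)."""

    n_subjects: int = 52
    r_glx_epsilon_loss: float = 0.437
    r_glx_epsilon_gain: float = 0.408
    b_mediation: float = 0.762
    direct_effect: float = 0.0
    gain_task_glx_drop_pct: float = -2.21
    mpfc_null: bool = True
    # questionnaire sum-score targets (mean, sd) per instrument
    questionnaire_params: dict = field(
        default_factory=lambda: {
            "PHQ9": (1.7, 2.0),
            "GAD7": (2.2, 1.5),
            "STAIX1": (43.0, 9.1),
        }
    )
    crlb_range: tuple = (3.0, 25.0)
    # Glx scale (institutional units, arbitrary)
    aic_glx_mean: float = 10.0
    mpfc_glx_mean: float = 11.0
    glx_between_sd_frac: float = 0.06
    glx_measurement_sd_frac: float = 0.015
    # error-sensitivity marginal: epsilon = invlogit(a0 + scale * w), w ~ N(0,1)
    epsilon_logit_mean: float = -0.62
    epsilon_logit_scale: float = 0.9
    n_trials_per_block: int = 40
    generating_model: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        for r in (self.r_glx_epsilon_loss, self.r_glx_epsilon_gain, self.b_mediation):
            if not (-1.0 < r < 1.0):
                raise ValueError(f"target correlation/effect {r} must lie in (-1, 1)")


@dataclass
class SubjectRecord:
    """One synthetic participant."""

    subject_id: str
    true_params: dict  # block -> AgentParameters
    choices: dict  # block -> ChoiceDataset (may be empty if not simulated)
    metabolites: pd.DataFrame
    questionnaire_items: dict  # instrument -> int array
    g_true: float
    glx_latent: float
    age: int
    sex: str  # "F"/"M"


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def choices_frame(self) -> pd.DataFrame:
        datasets = [ds for s in self.subjects for ds in s.choices.values()]
        return to_frame(datasets)

    def metabolites_frame(self) -> pd.DataFrame:
        return pd.concat([s.metabolites for s in self.subjects], ignore_index=True)

    def questionnaires_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for inst, items in s.questionnaire_items.items():
                for i, v in enumerate(items, start=1):
                    rows.append((s.subject_id, inst, i, int(v)))
        return pd.DataFrame(rows, columns=["subject", "instrument", "item", "response"])


# --------------------------------------------------------------------------
# calibration helpers (deterministic quadrature, no Monte Carlo)

_GH_X, _GH_W = np.polynomial.hermite.hermgauss(80)
_GH_X = _GH_X * np.sqrt(2.0)
_GH_W = _GH_W / np.sqrt(np.pi)


def _epsilon_moments(a0: float, scale: float) -> tuple[float, float, float]:
    """Mean, sd and Cov(w, f(w)) for f(w) = invlogit(a0 + scale*w), w ~ N(0,1)."""
    f = expit(a0 + scale * _GH_X)
    mean = float(_GH_W @ f)
    var = float(_GH_W @ (f - mean) ** 2)
    cov_wf = float(_GH_W @ (_GH_X * (f - mean)))
    return mean, np.sqrt(var), cov_wf


def _epsilon_cross_cov(a0: float, scale: float, rho12: float) -> float:
    """Cov(f(w1), f(w2)) for bivariate standard normal (w1, w2) with corr rho12."""
    mean, _, _ = _epsilon_moments(a0, scale)
    x1 = _GH_X[:, None]
    x2 = _GH_X[None, :]
    w2 = rho12 * x1 + np.sqrt(max(0.0, 1.0 - rho12**2)) * x2
    f1 = expit(a0 + scale * x1)
    f2 = expit(a0 + scale * w2)
    joint = (_GH_W[:, None] * _GH_W[None, :]) * (f1 - mean) * (f2 - mean)
    return float(joint.sum())


def _calibrate_rho(target_r: float, attenuation: float, a0: float, scale: float) -> float:
    """Latent corr(glx_z, w) needed so corr(measured Glx, epsilon) == target."""
    _, sd_f, cov_wf = _epsilon_moments(a0, scale)
    k = cov_wf / sd_f  # corr(w, f(w))
    rho = target_r / (attenuation * k)
    if not (-0.999 < rho < 0.999):
        raise ValueError(
            f"correlation target {target_r} unsatisfiable: implied latent corr {rho:.3f}"
        )
    return rho


def _solve_thresholds(n_items: int, n_levels: int, target_item_mean: float,
                      spacing: float) -> np.ndarray:
    """Equally-spaced thresholds on the standard-normal item latent such that
    the expected item score (above its minimum) equals the target."""
    n_thresh = n_levels - 1

    def expected(t0: float) -> float:
        t = t0 + spacing * np.arange(n_thresh)
        return float(np.sum(norm.sf(t)))

    lo, hi = -8.0, 8.0
    return (lambda t0: t0 + spacing * np.arange(n_thresh))(
        brentq(lambda t0: expected(t0) - target_item_mean, lo, hi)
    )


# --------------------------------------------------------------------------


def generate_cohort(config: CohortConfig | None = None, simulate: bool = True) -> Cohort:
    """Draw one full synthetic cohort.

    Parameters
    ----------
    config : CohortConfig
    simulate : bool
        If False, skip the (comparatively costly) choice simulation — useful
        for replicate studies of the metabolite/questionnaire layers only.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    a0, sc = cfg.epsilon_logit_mean, cfg.epsilon_logit_scale

    atten = cfg.glx_between_sd_frac / np.hypot(
        cfg.glx_between_sd_frac, cfg.glx_measurement_sd_frac
    )
    rho_loss = _calibrate_rho(cfg.r_glx_epsilon_loss, atten, a0, sc)
    rho_gain = _calibrate_rho(cfg.r_glx_epsilon_gain, atten, a0, sc)

    # latent structure ------------------------------------------------------
    z = rng.standard_normal(n)  # drives baseline AIC Glx
    u_loss = rng.standard_normal(n)
    u_gain = rng.standard_normal(n)
    w_loss = rho_loss * z + np.sqrt(1 - rho_loss**2) * u_loss
    w_gain = rho_gain * z + np.sqrt(1 - rho_gain**2) * u_gain
    eps_loss = expit(a0 + sc * w_loss)
    eps_gain = expit(a0 + sc * w_gain)

    # standardized mean error sensitivity (population moments via quadrature)
    mean_f, sd_f, cov_wf = _epsilon_moments(a0, sc)
    cov_lg = _epsilon_cross_cov(a0, sc, rho_loss * rho_gain)
    var_mean_eps = (sd_f**2 + cov_lg) / 2.0
    eps_mean_z = ((eps_loss + eps_gain) / 2.0 - mean_f) / np.sqrt(var_mean_eps)

    b = cfg.b_mediation
    d = cfg.direct_effect
    corr_z_epsmean = (rho_loss + rho_gain) / 2.0 * cov_wf / np.sqrt(var_mean_eps)
    resid_var = 1.0 - b**2 - d**2 - 2.0 * b * d * corr_z_epsmean
    if resid_var <= 0:
        raise ValueError("effect sizes imply non-positive residual variance for G")
    g = b * eps_mean_z + d * z + np.sqrt(resid_var) * rng.standard_normal(n)

    # other generating parameters (independent of Glx by default)
    tau_loss = rng.uniform(0.5, 1.0, n)
    tau_gain = rng.uniform(0.5, 1.0, n)
    dec_loss = rng.uniform(0.6, 0.95, n)
    dec_gain = rng.uniform(0.6, 0.95, n)

    age = np.clip(np.round(rng.normal(22, 2, n)), 18, 30).astype(int)
    sex = np.where(rng.random(n) < 12 / 52, "F", "M")

    # questionnaire items ---------------------------------------------------
    lam_g, lam_inst = 0.6, 0.4
    item_resid_sd = np.sqrt(1.0 - lam_g**2 - lam_inst**2)
    items_by_inst = {}
    for inst, (n_items, lo, hi) in INSTRUMENTS.items():
        mean_sum, _sd_sum = cfg.questionnaire_params[inst]
        target_item_mean = mean_sum / n_items - lo
        spacing = 0.9 if hi - lo == 3 else 1.2
        thr = _solve_thresholds(n_items, hi - lo + 1, target_item_mean, spacing)
        inst_factor = rng.standard_normal(n)
        latent = (
            lam_g * g[:, None]
            + lam_inst * inst_factor[:, None]
            + item_resid_sd * rng.standard_normal((n, n_items))
        )
        items_by_inst[inst] = lo + (latent[:, :, None] > thr).sum(axis=2)

    # metabolite panels -----------------------------------------------------
    sd_b = cfg.aic_glx_mean * cfg.glx_between_sd_frac
    sd_m = cfg.aic_glx_mean * cfg.glx_measurement_sd_frac
    aic_base = cfg.aic_glx_mean + sd_b * z
    drop = 1.0 + cfg.gain_task_glx_drop_pct / 100.0
    # latent block series: drop appears in the gain block and persists
    aic_latent = np.column_stack(
        [aic_base, aic_base, aic_base, aic_base * drop, aic_base * drop]
    )
    mpfc_base = cfg.mpfc_glx_mean + cfg.mpfc_glx_mean * cfg.glx_between_sd_frac * (
        rng.standard_normal(n)
    )
    mpfc_latent = np.repeat(mpfc_base[:, None], len(BLOCKS), axis=1)
    if not cfg.mpfc_null:
        mpfc_latent = mpfc_latent * np.array([1, 1, 1, drop, drop])[None, :]

    other_metab = {"CrPCr": 8.0, "NAA": 12.0}

    subjects = []
    choice_seed_root = np.random.SeedSequence(cfg.seed)
    sub_states = choice_seed_root.generate_state(4 * n).astype(np.int64)
    width = len(str(n))
    for i in range(n):
        sid = f"s{i + 1:0{width}d}"
        rows = []
        for r_i, region in enumerate(REGIONS):
            latent = aic_latent[i] if region == "AIC" else mpfc_latent[i]
            scale_mean = cfg.aic_glx_mean if region == "AIC" else cfg.mpfc_glx_mean
            for b_i, block in enumerate(BLOCKS):
                conc = latent[b_i] + sd_m / cfg.aic_glx_mean * scale_mean * rng.standard_normal()
                rows.append((sid, region, block, "Glx", max(conc, 0.1),
                             rng.uniform(*cfg.crlb_range)))
                for met, met_mean in other_metab.items():
                    mconc = met_mean * (1 + 0.05 * rng.standard_normal())
                    rows.append((sid, region, block, met, max(mconc, 0.1),
                                 rng.uniform(*cfg.crlb_range)))
        panel = pd.DataFrame(
            rows,
            columns=["subject", "region", "block", "metabolite", "concentration", "crlb_pct"],
        )

        params = {
            "loss": AgentParameters(epsilon=float(eps_loss[i]), tau=float(tau_loss[i]),
                                    decay=float(dec_loss[i])),
            "gain": AgentParameters(epsilon=float(eps_gain[i]), tau=float(tau_gain[i]),
                                    decay=float(dec_gain[i])),
        }
        choices = {}
        if simulate:
            for b_i, block in enumerate(("loss", "gain")):  # loss precedes gain
                sched = make_block_schedule(
                    TaskConfig(block_type=block, n_trials=cfg.n_trials_per_block),
                    int(sub_states[4 * i + 2 * b_i]),
                )
                choices[block] = simulate_agent(
                    cfg.generating_model, params[block], sched,
                    int(sub_states[4 * i + 2 * b_i + 1]), subject_id=sid,
                )

        subjects.append(
            SubjectRecord(
                subject_id=sid,
                true_params=params,
                choices=choices,
                metabolites=panel,
                questionnaire_items={k: v[i] for k, v in items_by_inst.items()},
                g_true=float(g[i]),
                glx_latent=float(z[i]),
                age=int(age[i]),
                sex=str(sex[i]),
            )
        )
    return Cohort(config=cfg, subjects=subjects)


def analysis_table(cohort: Cohort) -> pd.DataFrame:
    """Per-subject table used by the inferential layer.

    Baseline Glx is the *measured* rest1 concentration per region; error
    sensitivities are the generating values (replace with posterior means
    after fitting for a full replica).
    """
    rows = []
    for s in cohort.subjects:
        m = s.metabolites
        glx = m[m.metabolite == "Glx"].set_index(["region", "block"]).concentration
        sums = {inst: int(items.sum()) for inst, items in s.questionnaire_items.items()}
        rows.append(
            {
                "subject": s.subject_id,
                "glx_aic_rest1": glx.loc[("AIC", "rest1")],
                "glx_aic_rest2": glx.loc[("AIC", "rest2")],
                "glx_aic_gain": glx.loc[("AIC", "gain")],
                "glx_aic_loss": glx.loc[("AIC", "loss")],
                "glx_aic_rest3": glx.loc[("AIC", "rest3")],
                "glx_mpfc_rest1": glx.loc[("mPFC", "rest1")],
                "eps_loss": s.true_params["loss"].epsilon,
                "eps_gain": s.true_params["gain"].epsilon,
                "eps_mean": (s.true_params["loss"].epsilon + s.true_params["gain"].epsilon) / 2,
                "g_true": s.g_true,
                "phq9": sums["PHQ9"],
                "gad7": sums["GAD7"],
                "staix1": sums["STAIX1"],
                "age": s.age,
                "sex": s.sex,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# export / import


def export_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write choices.csv, metabolites.csv, questionnaires.csv and truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "choices": directory / "choices.csv",
        "metabolites": directory / "metabolites.csv",
        "questionnaires": directory / "questionnaires.csv",
        "truth": directory / "truth.json",
    }
    cohort.choices_frame().to_csv(paths["choices"], index=False)
    cohort.metabolites_frame().to_csv(paths["metabolites"], index=False)
    cohort.questionnaires_frame().to_csv(paths["questionnaires"], index=False)

    truth = {
        "config": asdict(cohort.config),
        "subjects": {
            s.subject_id: {
                "true_params": {
                    blk: {k: v for k, v in asdict(p).items() if v is not None}
                    for blk, p in s.true_params.items()
                },
                "g_true": s.g_true,
                "glx_latent": s.glx_latent,
                "age": s.age,
                "sex": s.sex,
            }
            for s in cohort.subjects
        },
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths


def load_cohort(directory: str | Path) -> dict:
    """Read back an exported cohort (frames + truth); lossless round-trip."""
    directory = Path(directory)
    return {
        "choices": pd.read_csv(directory / "choices.csv"),
        "metabolites": pd.read_csv(directory / "metabolites.csv"),
        "questionnaires": pd.read_csv(directory / "questionnaires.csv"),
        "truth": json.loads((directory / "truth.json").read_text()),
    }
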