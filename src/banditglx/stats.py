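"""Inferential layer: rm-ANOVA with Greenhouse-Geisser correction, Bonferroni
post hocs, correlations, multiple regression, Baron-Kenny mediation,
moderation, bifactor scoring and omega reliability.

Conventions: two-tailed alpha = 0.05 throughout; Bonferroni family sizes are
always explicit arguments (never inferred); mediation and moderation fit on
standardized variables so coefficients are comparable across scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm

__all__ = [
    "RmAnovaResult",
    "PairwiseResult",
    "CorrelationResult",
    "RegressionResult",
    "MediationResult",
    "ModerationResult",
    "BifactorLoadings",
    "OmegaResult",
    "rm_anova_gg",
    "bonferroni_posthoc",
    "correlate",
    "multiple_regression",
    "baron_kenny",
    "moderation",
    "factor_scores",
    "omega_coefficients",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


@dataclass
class RmAnovaResult:
    F: float
    df1: int
    df2: int
    gg_epsilon: float
    p_uncorrected: float
    p_gg: float
    # multivariate-style df pair (k-1, n-k+1) for cross-reading
    df1_mv: int
    df2_mv: int
    grand_mean: float
    condition_means: np.ndarray

    @property
    def significant(self) -> bool:
        return self.p_gg < ALPHA


def rm_anova_gg(data) -> RmAnovaResult:
    """One-way within-subject ANOVA with Greenhouse-Geisser correction.

    ``data`` is a subjects x conditions matrix (no missing cells).  The
    univariate F uses df (k-1, (n-1)(k-1)); the sphericity estimate
    epsilon-hat comes from the double-centered condition covariance, and the
    GG-corrected p evaluates F at (eps*df1, eps*df2).
    """
    X = np.asarray(data, float)
    if isinstance(data, pd.DataFrame):
        X = data.to_numpy(float)
    if X.ndim != 2:
        raise ValueError("data must be a subjects x conditions matrix")
    n, k = X.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 conditions")
    if np.isnan(X).any():
        raise ValueError("missing cells are not allowed (no imputation)")

    grand = X.mean()
    cond = X.mean(axis=0)
    subj = X.mean(axis=1)
    ss_cond = n * np.sum((cond - grand) ** 2)
    resid = X - subj[:, None] - cond[None, :] + grand
    ss_err = np.sum(resid**2)
    df1, df2 = k - 1, (n - 1) * (k - 1)
    F = (ss_cond / df1) / (ss_err / df2)

    S = np.cov(X, rowvar=False)
    C = np.eye(k) - np.ones((k, k)) / k
    A = C @ S @ C
    eps = np.trace(A) ** 2 / ((k - 1) * np.sum(A * A))
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))

    return RmAnovaResult(
        F=float(F),
        df1=df1,
        df2=df2,
        gg_epsilon=eps,
        p_uncorrected=float(sps.f.sf(F, df1, df2)),
        p_gg=float(sps.f.sf(F, eps * df1, eps * df2)),
        df1_mv=k - 1,
        df2_mv=n - k + 1,
        grand_mean=float(grand),
        condition_means=cond,
    )


@dataclass
class PairwiseResult:
    pair: tuple
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    mean_diff: float


def bonferroni_posthoc(data, condition_names, family) -> list[PairwiseResult]:
    """Paired t-tests for the listed condition pairs, Bonferroni-adjusted by
    the family size (= number of pairs supplied)."""
    X = np.asarray(data, float)
    names = list(condition_names)
    if X.shape[1] != len(names):
        raise ValueError("condition_names must match the data columns")
    idx = {c: j for j, c in enumerate(names)}
    m = len(family)
    out = []
    for a, b in family:
        if a not in idx or b not in idx:
            raise ValueError(f"unknown condition in pair ({a}, {b})")
        xa, xb = X[:, idx[a]], X[:, idx[b]]
        if np.allclose(xa, xb):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = sps.ttest_rel(xa, xb)
        out.append(
            PairwiseResult(
                pair=(a, b),
                t=float(t_stat),
                df=X.shape[0] - 1,
                p_raw=float(p),
                p_adjusted=min(1.0, m * float(p)),
                mean_diff=float(np.mean(xa - xb)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# correlations


@dataclass
class CorrelationResult:
    r: float
    method: str
    p_raw: float
    p_adjusted: float
    m_comparisons: int
    n: int

    @property
    def significant(self) -> bool:
        return self.p_adjusted < ALPHA


def correlate(x, y, method: str = "pearson", m: int = 1) -> CorrelationResult:
    """Pearson or Spearman correlation with Bonferroni adjustment by m."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("x and y must have equal length >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return CorrelationResult(
        r=float(r), method=method, p_raw=float(p),
        p_adjusted=min(1.0, m * float(p)), m_comparisons=m, n=x.size,
    )


# ---------------------------------------------------------------------------
# regression


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    F_overall: float
    p_overall: float
    rsquared: float
    rsquared_adj: float
    n: int
    _sm_result: object = field(default=None, repr=False)

    def summary(self):
        return self._sm_result.summary()


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cols: list[int] = []
        for j in range(mat.shape[1]):
            if np.linalg.matrix_rank(mat[:, cols + [j]]) == len(cols):
                bad.append(X.columns[j])
            else:
                cols.append(j)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def multiple_regression(y, predictors) -> RegressionResult:
    """OLS of y on the named predictors (intercept added automatically)."""
    X = pd.DataFrame(predictors)
    y = np.asarray(y, float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    _check_rank(sm.add_constant(X))
    res = sm.OLS(y, sm.add_constant(X)).fit()
    return RegressionResult(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        F_overall=float(res.fvalue),
        p_overall=float(res.f_pvalue),
        rsquared=float(res.rsquared),
        rsquared_adj=float(res.rsquared_adj),
        n=n,
        _sm_result=res,
    )


# ---------------------------------------------------------------------------
# mediation and moderation


def _zscore(v) -> np.ndarray:
    v = np.asarray(v, float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance variable")
    return (v - v.mean()) / sd


@dataclass
class MediationResult:
    """Baron-Kenny step estimates on standardized variables.

    c: total IV->DV effect; a: IV->mediator; b: mediator->DV controlling IV;
    c_prime: IV->DV controlling mediator.
    """

    c: float
    p_c: float
    a: float
    p_a: float
    b: float
    p_b: float
    c_prime: float
    p_c_prime: float
    verdict: str  # full / partial / none
    alpha: float = ALPHA
    indirect: float = 0.0
    indirect_ci: tuple | None = None  # optional percentile bootstrap


def baron_kenny(iv, mediator, dv, alpha: float = ALPHA, n_boot: int = 0,
                seed: int = 0) -> MediationResult:
    """Baron-Kenny four-step mediation on standardized variables.

    Steps 1-3 are the regressions DV~IV, M~IV and DV~M+IV; step four is the
    verdict: *full* mediation when steps 1-3 are significant and the direct
    path c' is not; *partial* when c' stays significant but is attenuated;
    *none* when step 1 or 2 fails.  A percentile-bootstrap CI for the
    indirect effect a*b is computed when ``n_boot > 0`` (not part of the
    classic procedure).
    """
    x = _zscore(iv)
    mvar = _zscore(mediator)
    yvar = _zscore(dv)
    if np.allclose(abs(np.corrcoef(x, mvar)[0, 1]), 1.0):
        raise ValueError("mediator perfectly collinear with iv")

    s1 = sm.OLS(yvar, sm.add_constant(x)).fit()
    c, p_c = s1.params[1], s1.pvalues[1]
    s2 = sm.OLS(mvar, sm.add_constant(x)).fit()
    a, p_a = s2.params[1], s2.pvalues[1]
    X3 = sm.add_constant(np.column_stack([mvar, x]))
    s3 = sm.OLS(yvar, X3).fit()
    b, p_b = s3.params[1], s3.pvalues[1]
    c_prime, p_cp = s3.params[2], s3.pvalues[2]

    if p_c >= alpha or p_a >= alpha or p_b >= alpha:
        verdict = "none"
    elif p_cp >= alpha:
        verdict = "full"
    elif abs(c_prime) < abs(c):
        verdict = "partial"
    else:
        verdict = "none"

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = x.size
        ab = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n, n)
            xb, mb, yb = x[idx], mvar[idx], yvar[idx]
            a_i = sm.OLS(mb, sm.add_constant(xb)).fit().params[1]
            b_i = sm.OLS(yb, sm.add_constant(np.column_stack([mb, xb]))).fit().params[1]
            ab[i] = a_i * b_i
        ci = tuple(np.percentile(ab, [2.5, 97.5]))

    return MediationResult(
        c=float(c), p_c=float(p_c), a=float(a), p_a=float(p_a),
        b=float(b), p_b=float(p_b), c_prime=float(c_prime), p_c_prime=float(p_cp),
        verdict=verdict, alpha=alpha, indirect=float(a * b), indirect_ci=ci,
    )


@dataclass
class ModerationResult:
    b_interaction: float
    p_interaction: float
    b_iv: float
    p_iv: float
    b_moderator: float
    p_moderator: float
    F_overall: float
    p_overall: float
    reduced: RegressionResult | None = None


def moderation(iv, moderator, dv) -> ModerationResult:
    """DV ~ IV + moderator + IV x moderator on standardized inputs.

    Also fits the reduced model without the interaction, mirroring the usual
    follow-up when the interaction is not significant.
    """
    x = _zscore(iv)
    w = _zscore(moderator)
    if np.allclose(np.std(np.asarray(moderator, float)), 0):
        raise ValueError("constant moderator")
    yvar = _zscore(dv)
    X = pd.DataFrame({"iv": x, "moderator": w, "interaction": x * w})
    full = multiple_regression(yvar, X)
    reduced = multiple_regression(yvar, X[["iv", "moderator"]])
    return ModerationResult(
        b_interaction=float(full.params["interaction"]),
        p_interaction=float(full.pvalues["interaction"]),
        b_iv=float(full.params["iv"]),
        p_iv=float(full.pvalues["iv"]),
        b_moderator=float(full.params["moderator"]),
        p_moderator=float(full.pvalues["moderator"]),
        F_overall=full.F_overall,
        p_overall=full.p_overall,
        reduced=reduced,
    )


# ---------------------------------------------------------------------------
# bifactor scoring and omega reliability


@dataclass
class BifactorLoadings:
    """Orthogonal bifactor structure: every item loads on the general factor
    and on exactly one group factor; factors are mutually uncorrelated."""

    general: np.ndarray  # (p,)
    group: np.ndarray  # (p, G), one nonzero entry per row at most
    uniqueness: np.ndarray  # (p,)

    def __post_init__(self):
        self.general = np.asarray(self.general, float)
        self.group = np.atleast_2d(np.asarray(self.group, float))
        if self.group.shape[0] != self.general.size:
            self.group = self.group.T
        self.uniqueness = np.asarray(self.uniqueness, float)
        p = self.general.size
        if self.group.shape[0] != p or self.uniqueness.size != p:
            raise ValueError("loading shapes are inconsistent")
        if (self.uniqueness < 0).any():
            raise ValueError("negative uniqueness")
        communality = self.general**2 + (self.group**2).sum(axis=1)
        if (communality > 1 + 1e-9).any():
            raise ValueError("item communality exceeds 1")

    @property
    def n_items(self) -> int:
        return self.general.size

    def implied_covariance(self) -> np.ndarray:
        lam = np.column_stack([self.general, self.group])
        return lam @ lam.T + np.diag(self.uniqueness)


def factor_scores(item_responses, loadings: BifactorLoadings) -> np.ndarray:
    """Regression-method general-factor scores.

    Weights are Sigma^{-1} lambda_general applied to the standardized items,
    with Sigma the model-implied item covariance.
    """
    X = np.asarray(item_responses, float)
    if isinstance(item_responses, pd.DataFrame):
        X = item_responses.to_numpy(float)
    X = np.atleast_2d(X)
    if X.shape[1] != loadings.n_items:
        raise ValueError(
            f"expected {loadings.n_items} item columns, got {X.shape[1]}"
        )
    sigma = loadings.implied_covariance()
    try:
        weights = np.linalg.solve(sigma, loadings.general)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular implied covariance") from exc
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    return Z @ weights


@dataclass
class OmegaResult:
    omega_hierarchical: float
    omega_total: float


def omega_coefficients(loadings: BifactorLoadings) -> OmegaResult:
    """Omega reliability of the unit-weighted total score.

    omega_h = (sum lambda_g)^2 / Var(total); omega_t adds each group factor's
    (sum of loadings)^2 to the numerator.  Var(total) is the sum of all
    common-factor terms plus the uniquenesses.
    """
    gen2 = float(np.sum(loadings.general)) ** 2
    group2 = float(np.sum(loadings.group.sum(axis=0) ** 2))
    total_var = gen2 + group2 + float(np.sum(loadings.uniqueness))
    return OmegaResult(
        omega_hierarchical=gen2 / total_var,
        omega_total=(gen2 + group2) / total_var,
    )
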