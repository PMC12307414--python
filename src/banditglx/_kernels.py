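"""Numba-compiled inner loops: likelihood recursion, agent simulation, MCMC.

Every model variant is expressed through one scalar recursion by mapping the
inactive parameters to their neutral values (tau=1, lapse=0, decay=1), so a
single kernel serves models 1-6.  The complement rule (model 1) is the only
structural switch.  The pure-Python implementations in :mod:`banditglx.models`
are the readable reference; agreement between the two routes is enforced by
the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# full parameter vector layout: [epsilon, tau, lapse, decay]
NEUTRAL = np.array([0.5, 1.0, 0.0, 1.0])

# index of each model's active parameters within the full vector
ACTIVE_IDX = {
    1: np.array([0], dtype=np.int64),
    2: np.array([0], dtype=np.int64),
    3: np.array([0, 1], dtype=np.int64),
    4: np.array([0, 1, 3], dtype=np.int64),
    5: np.array([0, 2], dtype=np.int64),
    6: np.array([0, 2, 3], dtype=np.int64),
}

COMPLEMENT = {1: True, 2: False, 3: False, 4: False, 5: False, 6: False}


def expand_params(model_id: int, active: np.ndarray) -> np.ndarray:
    """Map an active-parameter vector onto the full [eps, tau, lapse, decay]."""
    full = NEUTRAL.copy()
    full[ACTIVE_IDX[model_id]] = active
    return full


@njit(cache=True)
def loglik_pointwise(
    is_complement: bool,
    eps: float,
    tau: float,
    lapse: float,
    decay: float,
    choices: np.ndarray,
    outcomes: np.ndarray,
    resets: np.ndarray,
    out: np.ndarray,
) -> float:
    """Per-trial log-probabilities of the observed choices; returns the sum.

    ``resets[t]`` marks the start of a new block: values are re-initialized to
    (0.5, 0.5) before that trial, so several blocks can share one parameter
    vector while learning starts afresh in each.
    """
    v_a = 0.5
    v_b = 0.5
    total = 0.0
    for t in range(choices.size):
        if resets[t]:
            v_a = 0.5
            v_b = 0.5
        x = tau * (v_a - v_b)
        p_a = 1.0 / (1.0 + np.exp(-x))
        p_a = p_a * (1.0 - lapse) + 0.5 * lapse
        c = choices[t]
        ll = np.log(p_a) if c == 0 else np.log(1.0 - p_a)
        out[t] = ll
        total += ll
        o = outcomes[t]
        if c == 0:
            v_a = v_a + eps * (o - v_a)
            if is_complement:
                v_b = 1.0 - v_a
            else:
                v_b = decay * v_b
        else:
            v_b = v_b + eps * (o - v_b)
            if is_complement:
                v_a = 1.0 - v_b
            else:
                v_a = decay * v_a
    return total


@njit(cache=True)
def loglik_total(
    is_complement: bool,
    eps: float,
    tau: float,
    lapse: float,
    decay: float,
    choices: np.ndarray,
    outcomes: np.ndarray,
    resets: np.ndarray,
) -> float:
    v_a = 0.5
    v_b = 0.5
    total = 0.0
    for t in range(choices.size):
        if resets[t]:
            v_a = 0.5
            v_b = 0.5
        x = tau * (v_a - v_b)
        p_a = 1.0 / (1.0 + np.exp(-x))
        p_a = p_a * (1.0 - lapse) + 0.5 * lapse
        c = choices[t]
        total += np.log(p_a) if c == 0 else np.log(1.0 - p_a)
        o = outcomes[t]
        if c == 0:
            v_a = v_a + eps * (o - v_a)
            if is_complement:
                v_b = 1.0 - v_a
            else:
                v_b = decay * v_b
        else:
            v_b = v_b + eps * (o - v_b)
            if is_complement:
                v_a = 1.0 - v_b
            else:
                v_a = decay * v_a
    return total


@njit(cache=True)
def simulate_choices(
    is_complement: bool,
    eps: float,
    tau: float,
    lapse: float,
    decay: float,
    outcome_draws: np.ndarray,  # (n_trials, 2) pre-drawn good/bad per option
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Play one agent through a pre-drawn schedule; returns (choices, outcomes)."""
    np.random.seed(seed)
    n = outcome_draws.shape[0]
    choices = np.empty(n, dtype=np.int64)
    outcomes = np.empty(n, dtype=np.int64)
    v_a = 0.5
    v_b = 0.5
    for t in range(n):
        x = tau * (v_a - v_b)
        p_a = 1.0 / (1.0 + np.exp(-x))
        p_a = p_a * (1.0 - lapse) + 0.5 * lapse
        c = 0 if np.random.random() < p_a else 1
        o = outcome_draws[t, c]
        choices[t] = c
        outcomes[t] = o
        if c == 0:
            v_a = v_a + eps * (o - v_a)
            if is_complement:
                v_b = 1.0 - v_a
            else:
                v_b = decay * v_b
        else:
            v_b = v_b + eps * (o - v_b)
            if is_complement:
                v_a = 1.0 - v_b
            else:
                v_a = decay * v_a
    return choices, outcomes


@njit(cache=True)
def _logpost(
    is_complement: bool,
    idx: np.ndarray,
    y: np.ndarray,
    prior_a: np.ndarray,
    prior_b: np.ndarray,
    choices: np.ndarray,
    outcomes: np.ndarray,
    resets: np.ndarray,
) -> float:
    """Log posterior on the logit scale.

    With theta = sigmoid(y) and a Beta(a, b) prior on theta, the density on y
    is proportional to theta^a * (1-theta)^b (the Jacobian contributes one
    extra power of each factor).
    """
    full = np.array([0.5, 1.0, 0.0, 1.0])
    lp = 0.0
    for j in range(idx.size):
        theta = 1.0 / (1.0 + np.exp(-y[j]))
        full[idx[j]] = theta
        lp += prior_a[j] * np.log(theta) + prior_b[j] * np.log(1.0 - theta)
    lp += loglik_total(
        is_complement, full[0], full[1], full[2], full[3], choices, outcomes, resets
    )
    return lp


@njit(cache=True)
def mh_chain(
    is_complement: bool,
    idx: np.ndarray,
    prior_a: np.ndarray,
    prior_b: np.ndarray,
    choices: np.ndarray,
    outcomes: np.ndarray,
    resets: np.ndarray,
    n_warmup: int,
    n_keep: int,
    seed: int,
) -> tuple[np.ndarray, float]:
    """Random-walk Metropolis on logit-transformed parameters.

    The proposal scale adapts toward a 20-50% acceptance rate during warmup
    only.  Returns draws on the constrained [0,1] scale, shape (n_keep, P),
    plus the post-warmup acceptance rate.
    """
    np.random.seed(seed)
    p = idx.size
    y = np.random.normal(0.0, 0.5, p)
    lp = _logpost(is_complement, idx, y, prior_a, prior_b, choices, outcomes, resets)
    step = 0.5
    draws = np.empty((n_keep, p))
    accepted = 0
    window_acc = 0
    for i in range(n_warmup + n_keep):
        y_prop = y + step * np.random.normal(0.0, 1.0, p)
        lp_prop = _logpost(
            is_complement, idx, y_prop, prior_a, prior_b, choices, outcomes, resets
        )
        if np.log(np.random.random()) < lp_prop - lp:
            y = y_prop
            lp = lp_prop
            if i >= n_warmup:
                accepted += 1
            else:
                window_acc += 1
        if i < n_warmup and (i + 1) % 50 == 0:
            rate = window_acc / 50.0
            if rate < 0.2:
                step *= 0.7
            elif rate > 0.5:
                step *= 1.4
            window_acc = 0
        if i >= n_warmup:
            k = i - n_warmup
            for j in range(p):
                draws[k, j] = 1.0 / (1.0 + np.exp(-y[j]))
    return draws, accepted / max(n_keep, 1)


@njit(cache=True)
def loglik_matrix(
    is_complement: bool,
    idx: np.ndarray,
    draws: np.ndarray,  # (S, P) constrained-scale draws
    choices: np.ndarray,
    outcomes: np.ndarray,
    resets: np.ndarray,
) -> np.ndarray:
    """S x N pointwise log-likelihood matrix across posterior draws."""
    s = draws.shape[0]
    n = choices.size
    out = np.empty((s, n))
    row = np.empty(n)
    full = np.array([0.5, 1.0, 0.0, 1.0])
    for i in range(s):
        for j in range(idx.size):
            full[idx[j]] = draws[i, j]
        loglik_pointwise(
            is_complement, full[0], full[1], full[2], full[3], choices, outcomes, resets, row
        )
        out[i, :] = row
    return out
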