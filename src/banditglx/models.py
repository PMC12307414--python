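"""The six Rescorla-Wagner learning models.

Each model describes a learner on a two-option bandit.  A value in [0, 1] is
kept per option; after each trial the chosen option's value moves toward the
observed binary outcome by a fraction epsilon (the *error sensitivity*)
of the prediction error ``PE_t = outcome_t - v_chosen``.  The variants differ
in how the unchosen option is treated and how values map to choice
probabilities:

=======  ====  ===================  ==========================
Model    arms  unchosen update      choice rule
=======  ====  ===================  ==========================
1        one   complement (1 - v)   softmax(v)
2        two   frozen               softmax(v)
3        two   frozen               softmax(tau * v)
4        two   frozen + decay       softmax(tau * v)
5        two   frozen               softmax(v)*(1-L) + L/2
6        two   frozen + decay       softmax(v)*(1-L) + L/2
=======  ====  ===================  ==========================

All parameters (epsilon, tau, lapse L, decay lambda) live on [0, 1].  Note the
decision temperature multiplies the values inside the exponent, so tau = 0
makes choice uniformly random and tau = 1 recovers the plain softmax.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ModelSpec",
    "AgentParameters",
    "ValueState",
    "MODELS",
    "get_model",
    "init_values",
    "update_values",
    "choice_probability",
    "log_likelihood",
]

OPTION_A = 0
OPTION_B = 1

_OPTION_CODES = {"A": OPTION_A, "B": OPTION_B, 0: OPTION_A, 1: OPTION_B}


def _as_option(choice) -> int:
    try:
        return _OPTION_CODES[choice]
    except KeyError:
        raise ValueError(f"choice must be 'A'/'B' or 0/1, got {choice!r}") from None


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of one model variant.

    Parameters
    ----------
    model_id : int
        Identifier 1..6.
    arms : str
        ``"one"`` (complement updating couples the two values) or ``"two"``.
    update_rule_unchosen : str
        ``"complement"``, ``"frozen"`` or ``"decay"``.
    choice_noise : str
        ``"plain_softmax"``, ``"temperature_softmax"`` or ``"lapse_softmax"``.
    """

    model_id: int
    arms: str
    update_rule_unchosen: str
    choice_noise: str
    parameter_names: tuple = field(default=("epsilon",))

    @property
    def name(self) -> str:
        return f"model{self.model_id}"

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    def __post_init__(self):
        if self.arms not in ("one", "two"):
            raise ValueError(f"arms must be 'one' or 'two', got {self.arms!r}")


MODELS: dict[int, ModelSpec] = {
    1: ModelSpec(1, "one", "complement", "plain_softmax", ("epsilon",)),
    2: ModelSpec(2, "two", "frozen", "plain_softmax", ("epsilon",)),
    3: ModelSpec(3, "two", "frozen", "temperature_softmax", ("epsilon", "tau")),
    4: ModelSpec(4, "two", "decay", "temperature_softmax", ("epsilon", "tau", "decay")),
    5: ModelSpec(5, "two", "frozen", "lapse_softmax", ("epsilon", "lapse")),
    6: ModelSpec(6, "two", "decay", "lapse_softmax", ("epsilon", "lapse", "decay")),
}

_NAME_TO_ID = {spec.name: mid for mid, spec in MODELS.items()}


def get_model(model) -> ModelSpec:
    """Resolve a model id (1-6), name (``"model4"``) or ModelSpec."""
    if isinstance(model, ModelSpec):
        return model
    if isinstance(model, str):
        if model in _NAME_TO_ID:
            return MODELS[_NAME_TO_ID[model]]
        raise KeyError(f"unknown model name {model!r}")
    mid = int(model)
    if mid not in MODELS:
        raise KeyError(f"model id must be 1..6, got {mid}")
    return MODELS[mid]


@dataclass
class AgentParameters:
    """Learner parameters, each bounded to [0, 1].

    Only the parameters active for a given model are used; the rest may be
    left as ``None``.
    """

    epsilon: float | None = None
    tau: float | None = None
    lapse: float | None = None
    decay: float | None = None

    def validate(self, model: ModelSpec) -> None:
        for name in model.parameter_names:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"{model.name} requires parameter {name!r}")
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name}={value} outside [0, 1]")

    def as_vector(self, model: ModelSpec) -> np.ndarray:
        self.validate(model)
        return np.array([getattr(self, n) for n in model.parameter_names], float)

    @classmethod
    def from_vector(cls, model: ModelSpec, vector: Sequence[float]) -> "AgentParameters":
        vector = np.asarray(vector, float)
        if vector.shape != (model.n_params,):
            raise ValueError(
                f"{model.name} expects {model.n_params} parameters, got shape {vector.shape}"
            )
        return cls(**dict(zip(model.parameter_names, vector.tolist())))


@dataclass
class ValueState:
    """Current option values (both in [0, 1])."""

    v_a: float
    v_b: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.v_a, self.v_b)


def init_values(model: ModelSpec | int = 2) -> ValueState:
    """Symmetric, choice-indifferent starting values (0.5, 0.5)."""
    get_model(model)
    return ValueState(0.5, 0.5)


def update_values(
    model: ModelSpec | int,
    state: ValueState,
    choice,
    outcome: int,
    params: AgentParameters,
) -> ValueState:
    """One Rescorla-Wagner update after observing ``outcome`` for ``choice``.

    The chosen value moves by ``epsilon * (outcome - v_chosen)``.  The unchosen
    value is complemented (model 1, using the post-update chosen value so that
    ``v_a + v_b == 1`` holds exactly), left frozen (models 2, 3, 5), or decayed
    multiplicatively by lambda (models 4, 6).
    """
    spec = get_model(model)
    params.validate(spec)
    if outcome not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1, got {outcome!r}")
    chosen = _as_option(choice)

    v = [state.v_a, state.v_b]
    other = 1 - chosen
    v[chosen] = v[chosen] + params.epsilon * (outcome - v[chosen])
    if spec.update_rule_unchosen == "complement":
        v[other] = 1.0 - v[chosen]
    elif spec.update_rule_unchosen == "decay":
        v[other] = params.decay * v[other]
    # "frozen": leave untouched
    return ValueState(v[0], v[1])


def choice_probability(
    model: ModelSpec | int, state: ValueState, params: AgentParameters | None = None
) -> tuple[float, float]:
    """Probability of choosing each option under the model's choice rule.

    Values are bounded to [0, 1] so the softmax cannot overflow, but the
    max-subtraction trick is applied anyway.
    """
    spec = get_model(model)
    v_a, v_b = state.v_a, state.v_b
    if spec.choice_noise == "temperature_softmax":
        if params is None:
            raise ValueError("temperature softmax needs params.tau")
        params.validate(spec)
        v_a, v_b = params.tau * v_a, params.tau * v_b
    m = max(v_a, v_b)
    ea, eb = math.exp(v_a - m), math.exp(v_b - m)
    p_a = ea / (ea + eb)
    if spec.choice_noise == "lapse_softmax":
        if params is None:
            raise ValueError("lapse softmax needs params.lapse")
        params.validate(spec)
        p_a = p_a * (1.0 - params.lapse) + params.lapse / 2.0
    return (p_a, 1.0 - p_a)


def log_likelihood(
    model: ModelSpec | int,
    params: AgentParameters,
    data,
) -> tuple[float, np.ndarray]:
    """Total and pointwise log-likelihood of an observed choice sequence.

    ``data`` may be a :class:`banditglx.task.ChoiceDataset` or any object with
    ``choices`` / ``outcomes`` integer arrays (choices coded 0 = A, 1 = B).
    Trials are visited in order: the choice probability is computed from the
    current values, its log accumulated, and only then are the values updated
    with the observed (choice, outcome) pair.
    """
    spec = get_model(model)
    params.validate(spec)
    choices, outcomes = _extract_arrays(data)
    if choices.size == 0:
        raise ValueError("empty dataset: cannot evaluate likelihood")

    state = init_values(spec)
    pointwise = np.empty(choices.size)
    for t, (c, o) in enumerate(zip(choices, outcomes)):
        p_a, p_b = choice_probability(spec, state, params)
        pointwise[t] = math.log(p_a if c == OPTION_A else p_b)
        state = update_values(spec, state, int(c), int(o), params)
    return float(pointwise.sum()), pointwise


def _extract_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(data, "choices") and hasattr(data, "outcomes"):
        choices = np.asarray(data.choices)
        outcomes = np.asarray(data.outcomes)
    else:
        choices, outcomes = data
        choices = np.asarray(choices)
        outcomes = np.asarray(outcomes)
    if choices.dtype.kind in "US":
        choices = np.array([_as_option(c) for c in choices])
    choices = choices.astype(np.int64)
    outcomes = outcomes.astype(np.int64)
    if choices.shape != outcomes.shape:
        raise ValueError("choices and outcomes differ in length")
    if not np.isin(outcomes, (0, 1)).all():
        raise ValueError("outcomes must be 0/1")
    return choices, outcomes
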