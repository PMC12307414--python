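"""Two-armed bandit task: schedules, agent simulation, behavioral summaries.

The task has one hidden correct option per block.  The correct option yields a
good outcome with probability 0.70 (and a bad outcome otherwise); the wrong
option has the reversed probabilities.  In a gain block a good outcome is
worth +1,000 points and a bad one 0; in a loss block a good outcome is 0 and a
bad one -1,000.  Outcomes are coded 1 = good, 0 = bad in both block types so a
single likelihood serves both.

Outcomes are pre-drawn per trial *and per option* when the schedule is built,
so that two agents run on the same schedule face the identical world — a
prerequisite for paired model comparisons and exact reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from . import _kernels
from .models import AgentParameters, ModelSpec, get_model

__all__ = [
    "TaskConfig",
    "BlockSchedule",
    "TrialRecord",
    "ChoiceDataset",
    "make_block_schedule",
    "simulate_agent",
    "correct_rate",
    "win_stay_lose_stay",
    "read_choices_csv",
    "write_choices_csv",
]

GAIN = "gain"
LOSS = "loss"
_OPTION_LABELS = ("A", "B")


@dataclass(frozen=True)
class TaskConfig:
    """Bandit block configuration (defaults reproduce the study task)."""

    block_type: str = GAIN
    n_trials: int = 40
    p_good_correct: float = 0.70
    p_good_wrong: float = 0.30
    points_magnitude: int = 1000
    correct_option: str = "A"

    def __post_init__(self):
        if self.block_type not in (GAIN, LOSS):
            raise ValueError(f"block_type must be 'gain' or 'loss', got {self.block_type!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0.0 <= self.p_good_wrong <= self.p_good_correct <= 1.0):
            raise ValueError(
                "need 0 <= p_good_wrong <= p_good_correct <= 1, got "
                f"({self.p_good_wrong}, {self.p_good_correct})"
            )
        if self.correct_option not in _OPTION_LABELS:
            raise ValueError("correct_option must be 'A' or 'B'")

    @property
    def correct_index(self) -> int:
        return _OPTION_LABELS.index(self.correct_option)


@dataclass(frozen=True)
class BlockSchedule:
    """Pre-drawn per-trial, per-option good/bad outcomes for one block."""

    config: TaskConfig
    outcome_draws: np.ndarray  # (n_trials, 2) of {0,1}; column i = option i
    seed: int

    def __post_init__(self):
        draws = np.asarray(self.outcome_draws, dtype=np.int64)
        if draws.shape != (self.config.n_trials, 2):
            raise ValueError(
                f"outcome_draws must have shape ({self.config.n_trials}, 2)"
            )
        if not np.isin(draws, (0, 1)).all():
            raise ValueError("outcome_draws entries must be 0/1")
        object.__setattr__(self, "outcome_draws", draws)


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int  # 1-based
    choice: str  # "A" or "B"
    outcome: int  # 1 good, 0 bad
    points: int


@dataclass
class ChoiceDataset:
    """Ordered trial sequence for one subject in one block.

    Internally stores integer arrays (choices 0 = A, 1 = B; outcomes 0/1);
    :attr:`trials` exposes the record view.
    """

    subject_id: str
    block_type: str
    choices: np.ndarray
    outcomes: np.ndarray
    points: np.ndarray | None = None
    points_magnitude: int = 1000

    def __post_init__(self):
        self.choices = np.asarray(self.choices, dtype=np.int64)
        self.outcomes = np.asarray(self.outcomes, dtype=np.int64)
        if self.choices.shape != self.outcomes.shape:
            raise ValueError("choices and outcomes differ in length")
        if not np.isin(self.outcomes, (0, 1)).all():
            raise ValueError("outcomes must be 0/1")
        if not np.isin(self.choices, (0, 1)).all():
            raise ValueError("choices must be coded 0 (A) / 1 (B)")
        if self.points is None:
            self.points = points_for_outcomes(
                self.block_type, self.outcomes, self.points_magnitude
            )
        else:
            self.points = np.asarray(self.points, dtype=np.int64)

    @property
    def n_trials(self) -> int:
        return int(self.choices.size)

    @property
    def trials(self) -> list[TrialRecord]:
        return [
            TrialRecord(
                t + 1, _OPTION_LABELS[c], int(o), int(p)
            )
            for t, (c, o, p) in enumerate(zip(self.choices, self.outcomes, self.points))
        ]

    def __len__(self) -> int:
        return self.n_trials

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.trials)


def points_for_outcomes(block_type: str, outcomes: np.ndarray, magnitude: int = 1000) -> np.ndarray:
    """Points implied by 0/1 outcomes: gain {bad: 0, good: +m}; loss {bad: -m, good: 0}."""
    outcomes = np.asarray(outcomes, dtype=np.int64)
    if block_type == GAIN:
        return outcomes * magnitude
    if block_type == LOSS:
        return (outcomes - 1) * magnitude
    raise ValueError(f"unknown block_type {block_type!r}")


def make_block_schedule(config: TaskConfig, seed: int) -> BlockSchedule:
    """Pre-draw each option's good/bad outcome independently for every trial."""
    rng = np.random.default_rng(seed)
    probs = np.full(2, config.p_good_wrong)
    probs[config.correct_index] = config.p_good_correct
    draws = (rng.random((config.n_trials, 2)) < probs).astype(np.int64)
    return BlockSchedule(config=config, outcome_draws=draws, seed=seed)


def simulate_agent(
    model: ModelSpec | int,
    params: AgentParameters,
    schedule: BlockSchedule,
    seed: int,
    subject_id: str = "sim",
) -> ChoiceDataset:
    """Run one learner through a schedule, sampling choices from the model.

    On each trial the choice is sampled from the model's choice probability
    given the current values; the outcome is then read off the pre-drawn
    schedule for the chosen option, and values are updated before the next
    trial.
    """
    spec = get_model(model)
    params.validate(spec)
    full = _kernels.expand_params(spec.model_id, params.as_vector(spec))
    choices, outcomes = _kernels.simulate_choices(
        _kernels.COMPLEMENT[spec.model_id],
        full[0],
        full[1],
        full[2],
        full[3],
        schedule.outcome_draws,
        int(seed) % (2**32),
    )
    return ChoiceDataset(
        subject_id=subject_id,
        block_type=schedule.config.block_type,
        choices=choices,
        outcomes=outcomes,
        points_magnitude=schedule.config.points_magnitude,
    )


def correct_rate(data: ChoiceDataset, config: TaskConfig) -> float:
    """Fraction of trials on which the hidden correct option was chosen."""
    if data.n_trials == 0:
        raise ValueError("empty dataset")
    return float(np.mean(data.choices == config.correct_index))


def win_stay_lose_stay(data: ChoiceDataset) -> tuple[float, float]:
    """Win-stay and lose-stay rates.

    Win-stay: of the trials following a good outcome, the fraction on which
    the same option was chosen again; lose-stay analogously after bad
    outcomes.  A rate with an empty denominator is returned as NaN.
    """
    if data.n_trials < 2:
        raise ValueError("need at least 2 trials for stay rates")
    stay = data.choices[1:] == data.choices[:-1]
    prev_good = data.outcomes[:-1] == 1
    ws = float(stay[prev_good].mean()) if prev_good.any() else float("nan")
    lose = ~prev_good
    ls = float(stay[lose].mean()) if lose.any() else float("nan")
    return ws, ls


# ---------------------------------------------------------------------------
# tidy CSV I/O: subject,block,trial,choice,outcome,points


def to_frame(datasets: list[ChoiceDataset]) -> pd.DataFrame:
    rows = []
    for ds in datasets:
        for rec in ds.trials:
            rows.append(
                (ds.subject_id, ds.block_type, rec.trial_index, rec.choice, rec.outcome, rec.points)
            )
    return pd.DataFrame(
        rows, columns=["subject", "block", "trial", "choice", "outcome", "points"]
    )


def write_choices_csv(datasets: list[ChoiceDataset], path: str | Path) -> None:
    to_frame(datasets).to_csv(path, index=False)


def from_frame(df: pd.DataFrame) -> list[ChoiceDataset]:
    datasets = []
    for (subject, block), grp in df.groupby(["subject", "block"], sort=False):
        grp = grp.sort_values("trial")
        trial = grp["trial"].to_numpy()
        if not np.array_equal(trial, np.arange(1, len(trial) + 1)):
            raise ValueError(
                f"subject {subject} block {block}: trial index must run 1..n without gaps"
            )
        choices = grp["choice"].map({"A": 0, "B": 1}).to_numpy()
        if np.isnan(choices.astype(float)).any():
            raise ValueError(f"subject {subject} block {block}: choices must be A/B")
        datasets.append(
            ChoiceDataset(
                subject_id=str(subject),
                block_type=str(block),
                choices=choices.astype(np.int64),
                outcomes=grp["outcome"].to_numpy(),
                points=grp["points"].to_numpy() if "points" in grp else None,
            )
        )
    return datasets


def read_choices_csv(path: str | Path) -> list[ChoiceDataset]:
    return from_frame(pd.read_csv(path))
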