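"""Generative task schedules for the advice-augmented two-option bandit.

The task is a probabilistic reversal-learning game: on every trial one of two
colours (green/blue) is "correct", with a latent probability ``p_green`` that
switches between blocks. Independently, a social partner recommends a colour;
the partner's fidelity (probability the advice is correct) follows its own
block structure. Reward magnitudes on the two options are drawn uniformly and
are independent of both probability processes, so a rational player sometimes
picks the less likely colour for a larger payoff.

The correct colour is revealed every trial regardless of the choice, so the
outcome sequences (and therefore any belief trajectory computed from them) do
not depend on the player's behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GREEN = "G"
BLUE = "B"

#: Default block structure for the latent reward probability: values alternate
#: between 0.8 and 0.2 across blocks of 40-80 trials, totalling 290.
DEFAULT_REWARD_BLOCKS: tuple[tuple[int, float], ...] = (
    (60, 0.8),
    (50, 0.2),
    (70, 0.8),
    (40, 0.2),
    (70, 0.8),
)

#: Default block structure for the advice-fidelity process; reversal points are
#: deliberately misaligned with the reward blocks so the two processes vary
#: independently.
DEFAULT_ADVICE_BLOCKS: tuple[tuple[int, float], ...] = (
    (45, 0.75),
    (65, 0.25),
    (55, 0.75),
    (75, 0.25),
    (50, 0.75),
)


class ScheduleConfigError(ValueError):
    """Raised when a schedule configuration violates its invariants."""


@dataclass(frozen=True)
class ScheduleConfig:
    """Configuration of a task session.

    Parameters
    ----------
    n_trials
        Number of trials in the session (default 290, the study length).
    reward_prob_blocks
        Sequence of ``(block_length, p_green)`` pairs; lengths must sum to
        ``n_trials``.
    advice_fidelity_blocks
        Sequence of ``(block_length, p_advice_correct)`` pairs; lengths must
        sum to ``n_trials``.
    magnitude_low, magnitude_high
        Inclusive bounds of the uniform integer reward magnitudes.
    seed
        Seed for the schedule's private random generator.
    """

    n_trials: int = 290
    reward_prob_blocks: tuple[tuple[int, float], ...] = DEFAULT_REWARD_BLOCKS
    advice_fidelity_blocks: tuple[tuple[int, float], ...] = DEFAULT_ADVICE_BLOCKS
    magnitude_low: int = 1
    magnitude_high: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ScheduleConfigError("n_trials must be positive")
        if self.magnitude_low < 1:
            raise ScheduleConfigError("magnitude_low must be >= 1")
        if self.magnitude_high < self.magnitude_low:
            raise ScheduleConfigError("magnitude_high must be >= magnitude_low")
        for name, blocks in (
            ("reward_prob_blocks", self.reward_prob_blocks),
            ("advice_fidelity_blocks", self.advice_fidelity_blocks),
        ):
            total = sum(int(length) for length, _ in blocks)
            if total != self.n_trials:
                raise ScheduleConfigError(
                    f"{name}: block lengths sum to {total}, expected {self.n_trials}"
                )
            for length, p in blocks:
                if length < 1:
                    raise ScheduleConfigError(f"{name}: block length {length} < 1")
                if not 0.0 <= p <= 1.0:
                    raise ScheduleConfigError(f"{name}: probability {p} outside [0, 1]")


def _expand_blocks(blocks: tuple[tuple[int, float], ...]) -> np.ndarray:
    return np.concatenate([np.full(int(n), p, dtype=float) for n, p in blocks])


@dataclass(frozen=True)
class TrialSchedule:
    """A fully realised task session.

    Arrays are per-trial (0-based indexing internally; serialised trial
    indices are 1-based). ``p_blue_true = 1 - p_green_true`` is implied and
    never stored.
    """

    p_green_true: np.ndarray
    p_social_true: np.ndarray
    r_green: np.ndarray
    r_blue: np.ndarray
    correct: np.ndarray  # "G"/"B"
    advice: np.ndarray  # "G"/"B"
    config: ScheduleConfig | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        n = len(self.p_green_true)
        for name in ("p_social_true", "r_green", "r_blue", "correct", "advice"):
            if len(getattr(self, name)) != n:
                raise ScheduleConfigError(f"field {name!r} has wrong length")

    @property
    def n_trials(self) -> int:
        return len(self.p_green_true)

    @property
    def advice_correct(self) -> np.ndarray:
        """1 on trials where the partner's recommendation matched the outcome."""
        return (self.advice == self.correct).astype(np.int8)


@dataclass(frozen=True)
class OutcomeSequences:
    """Binary feedback streams driving the two belief trajectories.

    ``reward_outcomes[i] = 1`` iff green was correct on trial *i*;
    ``advice_outcomes[i] = 1`` iff the advice was correct. Both are functions
    of the schedule only (full-information task).
    """

    reward_outcomes: np.ndarray
    advice_outcomes: np.ndarray

    def __post_init__(self) -> None:
        if len(self.reward_outcomes) != len(self.advice_outcomes):
            raise ScheduleConfigError("outcome sequences differ in length")


def generate_schedule(config: ScheduleConfig) -> TrialSchedule:
    """Draw a schedule from its configuration.

    The correct colour is Bernoulli(``p_green``) per trial; whether the advice
    is correct is an independent Bernoulli(``p_social``); the advised colour is
    then derived from those two draws. Magnitudes are uniform integers on
    ``[magnitude_low, magnitude_high]``. Reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    p_green = _expand_blocks(config.reward_prob_blocks)
    p_social = _expand_blocks(config.advice_fidelity_blocks)

    green_correct = rng.random(config.n_trials) < p_green
    advice_correct = rng.random(config.n_trials) < p_social
    correct = np.where(green_correct, GREEN, BLUE)
    # advice agrees with `correct` when correct, points the other way otherwise
    advice = np.where(advice_correct, correct, np.where(green_correct, BLUE, GREEN))
    r_green = rng.integers(config.magnitude_low, config.magnitude_high + 1, config.n_trials)
    r_blue = rng.integers(config.magnitude_low, config.magnitude_high + 1, config.n_trials)

    return TrialSchedule(
        p_green_true=p_green,
        p_social_true=p_social,
        r_green=r_green.astype(np.int64),
        r_blue=r_blue.astype(np.int64),
        correct=correct,
        advice=advice,
        config=config,
    )


def extract_outcomes(schedule: TrialSchedule) -> OutcomeSequences:
    """Derive the two binary feedback streams from a schedule."""
    reward = (schedule.correct == GREEN).astype(np.int8)
    return OutcomeSequences(reward_outcomes=reward, advice_outcomes=schedule.advice_correct)
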