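"""Subjective information-weighting choice model.

Two tracked probabilities — that green is the rewarded colour, and that the
partner's advice is truthful — are first passed through a logistic transform
centred at 0.5 whose slope is a per-subject weight γ: large γ amplifies a
probability's pull away from 0.5 (the information is used heavily), small γ
flattens it toward 0.5 (the information is ignored). The two subjective
probabilities are then fused by Bayes' rule into an overall probability that
green pays out given the advice, converted into expected values using the
trial's reward magnitudes, and passed through a softmax with inverse
temperature β to yield the choice probability.

A subject with small γ on both channels therefore ends up choosing mostly on
current reward magnitudes, while a subject with γ_social > γ_reward leans
toward the advised colour when the two channels conflict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedules import GREEN, TrialSchedule
from .learners import BeliefTrajectory

#: Clamp applied to probabilities before the odds-ratio fusion, to keep
#: degenerate beliefs (exactly 0 or 1) out of the division.
PROB_EPS = 1e-9


class ChoiceModelError(ValueError):
    """Invalid parameter or trace input."""


def _sigmoid(x: np.ndarray) -> np.ndarray:
    """Overflow-safe logistic: never exponentiates a positive argument."""
    x = np.asarray(x, dtype=float)
    e = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


@dataclass(frozen=True)
class ParameterVector:
    """Subject-level parameters: information weights and choice stochasticity.

    ``gamma_social`` and ``gamma_reward_history`` scale the influence of the
    advice-fidelity and reward-history beliefs; ``beta`` is the softmax
    inverse temperature (units: 1/points).
    """

    gamma_social: float
    gamma_reward_history: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("gamma_social", "gamma_reward_history", "beta"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val >= 0):
                raise ChoiceModelError(f"{name} must be finite and >= 0, got {val}")


@dataclass(frozen=True)
class ChoicePolicyTrace:
    """Per-trial intermediate quantities of the choice model."""

    p_hat_social: np.ndarray
    p_hat_green: np.ndarray
    q_hat: np.ndarray
    v_green: np.ndarray
    v_blue: np.ndarray
    p_choose_green: np.ndarray

    def __len__(self) -> int:
        return len(self.q_hat)


def subjective_probability(p, gamma):
    """Logistic amplification/attenuation of a probability around 0.5.

    ``1 / (1 + exp(-gamma * (p - 0.5)))``: the identity-like transform steepens
    as gamma grows and collapses to a constant 0.5 as gamma -> 0.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ChoiceModelError("probability outside [0, 1]")
    out = _sigmoid(np.asarray(gamma, dtype=float) * (p - 0.5))
    return out if out.ndim else float(out)

def combine(p_hat_social, p_hat_green, advice_is_green, *, as_printed: bool = False):
    """Fuse subjective advice-fidelity and reward-history probabilities.

    Bayes' rule over the advised colour: when the partner says green,

        q = ps*pg / (ps*pg + (1-ps)*(1-pg)),

    and when the partner says blue the roles of truthful/untruthful advice
    swap, giving the mirrored numerator ``(1-ps)*pg``. ``advice_is_green`` may
    be a boolean array for vectorised use.

    ``as_printed=True`` reproduces, for audit purposes, a published variant of
    the advice-blue branch whose numerator (``ps*pg``) is inconsistent with
    its own denominator; it is not Bayes-consistent and not the default.
    """
    ps = np.clip(np.asarray(p_hat_social, dtype=float), PROB_EPS, 1.0 - PROB_EPS)
    pg = np.clip(np.asarray(p_hat_green, dtype=float), PROB_EPS, 1.0 - PROB_EPS)
    green = np.asarray(advice_is_green, dtype=bool)

    num_g = ps * pg
    den_g = ps * pg + (1.0 - ps) * (1.0 - pg)
    num_b = (ps if as_printed else (1.0 - ps)) * pg
    den_b = (1.0 - ps) * pg + ps * (1.0 - pg)
    q = np.where(green, num_g / den_g, num_b / den_b)
    return q if q.ndim else float(q)


def expected_values(q_hat, r_green, r_blue):
    """Expected point value of each option: ``(q*r_green, (1-q)*r_blue)``."""
    q = np.asarray(q_hat, dtype=float)
    rg = np.asarray(r_green, dtype=float)
    rb = np.asarray(r_blue, dtype=float)
    if np.any(rg < 0) or np.any(rb < 0):
        raise ChoiceModelError("reward magnitudes must be >= 0")
    vg, vb = q * rg, (1.0 - q) * rb
    if vg.ndim:
        return vg, vb
    return float(vg), float(vb)


def choice_probability(v_green, v_blue, beta):
    """Softmax probability of choosing green given the two expected values.

    Computed through a signed formulation that never exponentiates a large
    positive argument, so it is overflow-safe for any beta.
    """
    d = np.asarray(beta, dtype=float) * (np.asarray(v_green, dtype=float)
                                         - np.asarray(v_blue, dtype=float))
    out = _sigmoid(d)
    return out if out.ndim else float(out)


def policy_trace(
    params: ParameterVector,
    schedule: TrialSchedule,
    beliefs_reward: BeliefTrajectory,
    beliefs_social: BeliefTrajectory,
    *,
    as_printed: bool = False,
) -> ChoicePolicyTrace:
    """Apply the full model trial-by-trial; deterministic given its inputs.

    ``beliefs_reward`` tracks P(green correct) and ``beliefs_social`` tracks
    P(advice truthful); both must be predictive (pre-feedback) and match the
    schedule's length.
    """
    n = schedule.n_trials
    if len(beliefs_reward) != n or len(beliefs_social) != n:
        raise ChoiceModelError("belief trajectories must match the schedule length")

    p_hat_social = subjective_probability(beliefs_social.estimates, params.gamma_social)
    p_hat_green = subjective_probability(beliefs_reward.estimates, params.gamma_reward_history)
    q_hat = combine(p_hat_social, p_hat_green, schedule.advice == GREEN,
                    as_printed=as_printed)
    v_green, v_blue = expected_values(q_hat, schedule.r_green, schedule.r_blue)
    p_green = choice_probability(v_green, v_blue, params.beta)

    return ChoicePolicyTrace(
        p_hat_social=np.atleast_1d(p_hat_social),
        p_hat_green=np.atleast_1d(p_hat_green),
        q_hat=np.atleast_1d(q_hat),
        v_green=np.atleast_1d(v_green),
        v_blue=np.atleast_1d(v_blue),
        p_choose_green=np.atleast_1d(p_green),
    )
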