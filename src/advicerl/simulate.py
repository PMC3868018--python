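"""Synthetic agents and cohorts with known ground truth.

This module is the generative counterpart of the fitting pipeline: it builds
agents whose choices are drawn from the subjective-weighting policy at known
parameters, and cohorts in which self-report trait scores are statistically
linked to the log-parameters through an explicit coefficient map. Every
downstream stage (parameter recovery, model comparison, trait association)
is validated against these ground truths.

Trait scores emulate the eight PPI subscales (4-point Likert sum scores);
default means/SDs resemble a community sample of young adults. Traits reach
the behaviour only through the parameter map — conditional on an agent's
parameters, its choices are independent of its trait scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedules import (GREEN, BLUE, ScheduleConfig, TrialSchedule,
                        generate_schedule, extract_outcomes)
from .learners import (BAYES_TAG, RW_TAG, LearnerGrid, RWParams,
                       track_bayes, track_rw)
from .choice_model import ParameterVector, policy_trace

#: Canonical subscale vocabulary (order is the canonical column order).
TRAIT_NAMES: tuple[str, ...] = (
    "Stress Immunity",
    "Social Potency",
    "Fearlessness",
    "Machiavellian Egocentricity",
    "Blame Externalization",
    "Carefree Non-planfulness",
    "Impulsive Non-conformity",
    "Coldheartedness",
)

#: Default per-subscale (mean, SD) pairs for the trait generator.
DEFAULT_TRAIT_MEANS_SDS: dict[str, tuple[float, float]] = {
    "Stress Immunity": (28.9, 5.4),
    "Social Potency": (56.6, 12.8),
    "Fearlessness": (41.3, 10.0),
    "Machiavellian Egocentricity": (54.6, 12.0),
    "Blame Externalization": (31.8, 6.9),
    "Carefree Non-planfulness": (40.4, 5.7),
    "Impulsive Non-conformity": (33.6, 6.3),
    "Coldheartedness": (46.4, 7.3),
}

#: Log-scale medians for generated parameters, resembling typical fitted
#: magnitudes (gamma_reward ~ 1.1, gamma_social ~ 2.2, beta ~ 0.5).
DEFAULT_LOG_MEDIANS: dict[str, float] = {
    "gamma_reward_history": float(np.log(1.1)),
    "gamma_social": float(np.log(2.2)),
    "beta": float(np.log(0.5)),
}

#: SD of log-parameters across subjects (total, loadings + noise).
DEFAULT_LOG_SD = 0.5

#: Default trait loadings on the log-parameters, in log units per trait SD.
#: With two loaded traits per parameter at coefficient rho*LOG_SD and residual
#: noise_sd = LOG_SD*sqrt(1 - 2*rho^2), each loaded trait correlates ~ rho
#: with the log-parameter. rho = -0.35 puts the association stage in the
#: realistic low-signal regime.
_RHO = -0.35
DEFAULT_GROUND_TRUTH_MAP: dict[str, dict[str, float]] = {
    "gamma_reward_history": {
        "Stress Immunity": _RHO * DEFAULT_LOG_SD,
        "Fearlessness": _RHO * DEFAULT_LOG_SD,
    },
    "gamma_social": {
        "Stress Immunity": _RHO * DEFAULT_LOG_SD,
        "Social Potency": _RHO * DEFAULT_LOG_SD,
    },
}

DEFAULT_NOISE_SD = float(DEFAULT_LOG_SD * np.sqrt(1.0 - 2.0 * _RHO**2))


class SimulationError(ValueError):
    """Invalid agent or cohort specification."""


@dataclass(frozen=True)
class AgentSpec:
    """Generative description of one agent."""

    params: ParameterVector
    learner_tag: str = BAYES_TAG
    rw_alpha_social: float = 0.3
    rw_alpha_reward: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learner_tag not in (BAYES_TAG, RW_TAG):
            raise SimulationError(f"unknown learner_tag {self.learner_tag!r}")
        for name in ("rw_alpha_social", "rw_alpha_reward"):
            a = getattr(self, name)
            if not 0.0 <= a <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class ChoiceRecord:
    """A sequence of observed (or simulated) choices with its task context."""

    choices: np.ndarray  # "G"/"B"
    schedule: TrialSchedule

    def __post_init__(self) -> None:
        if len(self.choices) != self.schedule.n_trials:
            raise SimulationError("choices must match the schedule length")
        if not np.isin(self.choices, (GREEN, BLUE)).all():
            raise SimulationError("choices must be 'G' or 'B'")

    def __len__(self) -> int:
        return len(self.choices)

    @property
    def chose_green(self) -> np.ndarray:
        return (self.choices == GREEN).astype(np.int8)


def agent_beliefs(spec: AgentSpec, schedule: TrialSchedule,
                  grid: LearnerGrid | None = None):
    """Belief trajectories (reward, social) implied by an agent's learner."""
    outcomes = extract_outcomes(schedule)
    if spec.learner_tag == BAYES_TAG:
        grid = grid or LearnerGrid()
        return (track_bayes(outcomes.reward_outcomes, grid),
                track_bayes(outcomes.advice_outcomes, grid))
    return (track_rw(outcomes.reward_outcomes, RWParams(spec.rw_alpha_reward)),
            track_rw(outcomes.advice_outcomes, RWParams(spec.rw_alpha_social)))


def simulate_agent(spec: AgentSpec, schedule: TrialSchedule,
                   grid: LearnerGrid | None = None) -> ChoiceRecord:
    """Draw one choice sequence from the agent's policy on a schedule."""
    beliefs_reward, beliefs_social = agent_beliefs(spec, schedule, grid)
    trace = policy_trace(spec.params, schedule, beliefs_reward, beliefs_social)
    rng = np.random.default_rng(spec.seed)
    green = rng.random(schedule.n_trials) < trace.p_choose_green
    return ChoiceRecord(choices=np.where(green, GREEN, BLUE), schedule=schedule)


@dataclass(frozen=True)
class SyntheticCohort:
    """A simulated study sample with recorded ground truth.

    ``traits`` is a subjects x 8 score table; ``true_params`` holds each
    subject's generative parameters; ``ground_truth_map`` records the linear
    coefficients (log units per trait SD) that produced the link.
    """

    specs: list[AgentSpec]
    records: list[ChoiceRecord]
    traits: pd.DataFrame
    true_params: pd.DataFrame
    ground_truth_map: dict[str, dict[str, float]]
    noise_sd: float
    trait_means_sds: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.specs)


def generate_cohort(
    n_subjects: int = 36,
    trait_means_sds: dict[str, tuple[float, float]] | None = None,
    ground_truth_map: dict[str, dict[str, float]] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    schedule_config: ScheduleConfig | None = None,
    seed: int = 0,
    *,
    trait_correlation: float = 0.0,
    log_medians: dict[str, float] | None = None,
    beta_log_sd: float = DEFAULT_LOG_SD,
    learner_grid: LearnerGrid | None = None,
    simulate_choices: bool = True,
) -> SyntheticCohort:
    """Generate a cohort with trait-linked parameters and simulated choices.

    Traits are multivariate normal with the given per-subscale means/SDs and a
    common inter-trait correlation (0 by default, for identifiability of the
    selection stage). Each gamma's log value is its log-median plus the mapped
    combination of z-scored traits plus ``noise_sd`` Gaussian noise; beta is
    log-normal and trait-independent. Each subject plays an independently
    seeded schedule. Fully reproducible from ``seed``.
    """
    if n_subjects < 2:
        raise SimulationError("n_subjects must be >= 2")
    trait_means_sds = dict(trait_means_sds or DEFAULT_TRAIT_MEANS_SDS)
    missing = set(TRAIT_NAMES) - set(trait_means_sds)
    if missing:
        raise SimulationError(f"missing trait distributions for {sorted(missing)}")
    if any(sd <= 0 for _, sd in trait_means_sds.values()):
        raise SimulationError("trait SDs must be > 0")
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    gt_map = {k: dict(v) for k, v in (ground_truth_map or DEFAULT_GROUND_TRUTH_MAP).items()}
    for param, loadings in gt_map.items():
        unknown = set(loadings) - set(TRAIT_NAMES)
        if unknown:
            raise SimulationError(f"{param}: unknown traits {sorted(unknown)}")
    log_medians = dict(log_medians or DEFAULT_LOG_MEDIANS)

    n_traits = len(TRAIT_NAMES)
    corr = np.full((n_traits, n_traits), trait_correlation)
    np.fill_diagonal(corr, 1.0)
    if np.linalg.eigvalsh(corr).min() <= 1e-10:
        raise SimulationError("inter-trait correlation matrix is singular")

    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(np.zeros(n_traits), corr, size=n_subjects,
                                method="cholesky")
    means = np.array([trait_means_sds[t][0] for t in TRAIT_NAMES])
    sds = np.array([trait_means_sds[t][1] for t in TRAIT_NAMES])
    traits = pd.DataFrame(means + sds * z, columns=list(TRAIT_NAMES))
    traits.index.name = "subject"

    # log-parameters from z-scored traits (population z, so noise_sd=0 gives
    # an exact monotone trait->parameter map)
    log_params = {}
    for param in ("gamma_reward_history", "gamma_social"):
        loadings = gt_map.get(param, {})
        signal = np.zeros(n_subjects)
        for trait, coef in loadings.items():
            signal += coef * z[:, TRAIT_NAMES.index(trait)]
        log_params[param] = (log_medians[param] + signal
                             + noise_sd * rng.standard_normal(n_subjects))
    log_params["beta"] = (log_medians["beta"]
                          + beta_log_sd * rng.standard_normal(n_subjects))
    true_params = pd.DataFrame({k: np.exp(v) for k, v in log_params.items()})
    true_params.index.name = "subject"

    schedule_config = schedule_config or ScheduleConfig()
    seed_seq = np.random.SeedSequence(seed)
    subject_seeds = seed_seq.spawn(n_subjects)
    specs: list[AgentSpec] = []
    records: list[ChoiceRecord] = []
    for j in range(n_subjects):
        sched_seed, choice_seed = subject_seeds[j].generate_state(2) >> np.uint32(1)
        spec = AgentSpec(
            params=ParameterVector(
                gamma_social=float(true_params.loc[j, "gamma_social"]),
                gamma_reward_history=float(true_params.loc[j, "gamma_reward_history"]),
                beta=float(true_params.loc[j, "beta"]),
            ),
            learner_tag=BAYES_TAG,
            seed=int(choice_seed),
        )
        specs.append(spec)
        if simulate_choices:
            cfg = ScheduleConfig(
                n_trials=schedule_config.n_trials,
                reward_prob_blocks=schedule_config.reward_prob_blocks,
                advice_fidelity_blocks=schedule_config.advice_fidelity_blocks,
                magnitude_low=schedule_config.magnitude_low,
                magnitude_high=schedule_config.magnitude_high,
                seed=int(sched_seed),
            )
            schedule = generate_schedule(cfg)
            records.append(simulate_agent(spec, schedule, learner_grid))

    return SyntheticCohort(
        specs=specs,
        records=records,
        traits=traits,
        true_params=true_params,
        ground_truth_map=gt_map,
        noise_sd=noise_sd,
        trait_means_sds=trait_means_sds,
    )
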