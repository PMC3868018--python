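"""Per-subject parameter estimation and model comparison.

Fitting is by direct numerical integration: the choice log-likelihood
``LL(gamma_social, gamma_reward_history, beta) = sum_i log P(C_i = c_i)`` is
evaluated at every node of a log-spaced grid over [0.01, 10] per parameter,
combined with a log-uniform prior, and normalised. Marginal posteriors give
both point estimates (posterior mean on the log scale, exponentiated) and
per-parameter posterior SDs, so the reliability of every fit is quantified
rather than assumed.

The fixed-learning-rate alternative adds two Rescorla-Wagner learning rates
(social and reward) as free parameters; it is fitted by profiling: an outer
grid over the two learning rates, an inner 3-D grid over (gammas, beta) for
each pair. Models are compared by BIC and AIC computed from the best
grid-node log-likelihood.

Because feedback is fully observable, belief trajectories depend only on the
schedule; they are computed once per subject and shared across all grid
nodes, which is what makes the dense grid evaluation affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .schedules import GREEN, extract_outcomes
from .learners import (BAYES_TAG, RW_TAG, BeliefTrajectory, LearnerGrid,
                       RWParams, track_bayes, track_rw)
from .choice_model import ParameterVector, PROB_EPS, policy_trace
from .simulate import ChoiceRecord

#: Probability floor inside the log-likelihood, keeping it finite.
LL_EPS = 1e-9


class FitError(ValueError):
    """Invalid fitting input or degenerate likelihood."""


@dataclass(frozen=True)
class FitGrid:
    """Log-spaced evaluation grid, one axis per parameter."""

    lower: float = 0.01
    upper: float = 10.0
    points_per_dim: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise FitError("grid bounds must satisfy 0 < lower < upper")
        if self.points_per_dim < 10:
            raise FitError("points_per_dim must be >= 10")

    @property
    def values(self) -> np.ndarray:
        return np.exp(self.log_values)

    @property
    def log_values(self) -> np.ndarray:
        return np.linspace(np.log(self.lower), np.log(self.upper), self.points_per_dim)


@dataclass(frozen=True)
class ParameterPosterior:
    """Gridded joint posterior over (gamma_social, gamma_reward_history, beta)."""

    grid: FitGrid
    joint_log_density: np.ndarray  # (Gs, Gr, B), normalised in probability
    marginals: dict[str, np.ndarray]  # each sums to 1
    point_estimates: ParameterVector
    posterior_sds: dict[str, float]  # natural scale
    posterior_log_sds: dict[str, float]  # log scale (the integration scale)
    log_evidence: float
    max_log_likelihood: float
    total_log_likelihood_at_estimate: float


@dataclass(frozen=True)
class ModelFit:
    """One model's fit summary for information-criterion comparison."""

    tag: str
    n_params: int
    n_trials: int
    max_log_likelihood: float
    bic: float
    aic: float
    point_estimates: ParameterVector
    extras: dict[str, float]


@dataclass(frozen=True)
class ModelComparison:
    fits: dict[str, ModelFit]
    preferred_by_bic: str
    preferred_by_aic: str


_PARAM_NAMES = ("gamma_social", "gamma_reward_history", "beta")


def log_likelihood(
    params: ParameterVector,
    record: ChoiceRecord,
    beliefs_reward: BeliefTrajectory,
    beliefs_social: BeliefTrajectory,
) -> float:
    """Choice log-likelihood of a record under the policy at ``params``."""
    trace = policy_trace(params, record.schedule, beliefs_reward, beliefs_social)
    sign = np.where(record.chose_green.astype(bool), 1.0, -1.0)
    # signed value gap toward the chosen option, through the same stable
    # sigmoid for either choice (avoids the 1-p cancellation at the clamp)
    x = sign * params.beta * (trace.v_green - trace.v_blue)
    p_chosen = 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))
    return float(np.log(np.clip(p_chosen, LL_EPS, 1.0 - LL_EPS)).sum())


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def _ll_grid(
    record: ChoiceRecord,
    beliefs_reward: BeliefTrajectory,
    beliefs_social: BeliefTrajectory,
    gammas_social: np.ndarray,
    gammas_reward: np.ndarray,
    betas: np.ndarray,
) -> np.ndarray:
    """Vectorised LL over a (gamma_s x gamma_r x beta) grid.

    Equivalent to calling :func:`log_likelihood` at every node; the per-trial
    subjective probabilities and value gaps are shared across the beta axis.
    """
    sched = record.schedule
    p_s = np.asarray(beliefs_social.estimates) - 0.5  # (T,)
    p_g = np.asarray(beliefs_reward.estimates) - 0.5
    advice_green = sched.advice == GREEN
    sign = np.where(record.chose_green.astype(bool), 1.0, -1.0)

    ps_hat = 1.0 / (1.0 + np.exp(-gammas_social[:, None] * p_s[None, :]))  # (Gs,T)
    pg_hat = 1.0 / (1.0 + np.exp(-gammas_reward[:, None] * p_g[None, :]))  # (Gr,T)
    ps_hat = np.clip(ps_hat, PROB_EPS, 1.0 - PROB_EPS)[:, None, :]  # (Gs,1,T)
    pg_hat = np.clip(pg_hat, PROB_EPS, 1.0 - PROB_EPS)[None, :, :]  # (1,Gr,T)

    num = np.where(advice_green, ps_hat * pg_hat, (1.0 - ps_hat) * pg_hat)
    den = np.where(
        advice_green,
        ps_hat * pg_hat + (1.0 - ps_hat) * (1.0 - pg_hat),
        (1.0 - ps_hat) * pg_hat + ps_hat * (1.0 - pg_hat),
    )
    q = num / den  # (Gs,Gr,T)
    dv = q * sched.r_green - (1.0 - q) * sched.r_blue
    x = sign * dv  # signed value gap toward the chosen option

    n_b = len(betas)
    ll = np.empty((len(gammas_social), len(gammas_reward), n_b))
    for b in range(n_b):
        # log sigma(beta*x) = -softplus(-beta*x); clamp matches LL_EPS floor
        p = 1.0 / (1.0 + np.exp(-np.clip(betas[b] * x, -700, 700)))
        ll[:, :, b] = np.log(np.clip(p, LL_EPS, 1.0 - LL_EPS)).sum(axis=-1)
    return ll


def fit_posterior(
    record: ChoiceRecord,
    beliefs_reward: BeliefTrajectory,
    beliefs_social: BeliefTrajectory,
    grid: FitGrid | None = None,
) -> ParameterPosterior:
    """Grid posterior over the three policy parameters (log-uniform prior).

    The point estimate of each parameter is its marginal posterior mean taken
    on the log scale and exponentiated. Spread is reported twice: as the
    marginal's natural-scale SD and as its log-scale SD. Both treat the grid
    posterior as a histogram density (each node represents a log-width cell),
    so the within-cell uniform variance is included; without it, a likelihood
    sharper than the node spacing would report a spuriously tiny SD.
    """
    grid = grid or FitGrid()
    vals = grid.values
    logs = grid.log_values
    ll = _ll_grid(record, beliefs_reward, beliefs_social, vals, vals, vals)
    if not np.isfinite(ll).any():
        raise FitError("likelihood is degenerate (no finite grid node)")

    log_norm = logsumexp(ll)
    log_joint = ll - log_norm
    joint = np.exp(log_joint)
    log_evidence = float(log_norm - np.log(ll.size))  # log-uniform prior mass

    marginals = {
        "gamma_social": joint.sum(axis=(1, 2)),
        "gamma_reward_history": joint.sum(axis=(0, 2)),
        "beta": joint.sum(axis=(0, 1)),
    }
    dlog = logs[1] - logs[0]  # uniform cell width on the log scale
    estimates = {}
    sds = {}
    log_sds = {}
    for name, marg in marginals.items():
        mean_log = marg @ logs
        estimates[name] = float(np.exp(mean_log))
        log_sds[name] = float(np.sqrt(marg @ (logs - mean_log) ** 2
                                      + dlog**2 / 12.0))
        mean_nat = marg @ vals
        cell_var = marg @ (vals * dlog) ** 2 / 12.0
        sds[name] = float(np.sqrt(max(marg @ (vals - mean_nat) ** 2 + cell_var,
                                      0.0)))

    point = ParameterVector(**estimates)
    ll_at_estimate = log_likelihood(point, record, beliefs_reward, beliefs_social)
    return ParameterPosterior(
        grid=grid,
        joint_log_density=log_joint,
        marginals=marginals,
        point_estimates=point,
        posterior_sds=sds,
        posterior_log_sds=log_sds,
        log_evidence=log_evidence,
        max_log_likelihood=float(ll.max()),
        total_log_likelihood_at_estimate=ll_at_estimate,
    )


def fit_subject(
    record: ChoiceRecord,
    grid: FitGrid | None = None,
    learner_grid: LearnerGrid | None = None,
) -> ParameterPosterior:
    """Convenience wrapper: Bayesian-tracker beliefs from the schedule, then fit."""
    outcomes = extract_outcomes(record.schedule)
    lg = learner_grid or LearnerGrid()
    beliefs_reward = track_bayes(outcomes.reward_outcomes, lg)
    beliefs_social = track_bayes(outcomes.advice_outcomes, lg)
    return fit_posterior(record, beliefs_reward, beliefs_social, grid)


def predictive_accuracy(record: ChoiceRecord, trace) -> float:
    """Fraction of trials where the model's preferred option was chosen.

    Trials where the model is exactly indifferent (p = 0.5) score half a hit.
    """
    p = np.asarray(trace.p_choose_green, dtype=float)
    chose_green = record.chose_green.astype(bool)
    hits = np.where(p == 0.5, 0.5, (p > 0.5) == chose_green)
    return float(np.mean(hits))


def _information_criteria(ll: float, n_params: int, n_trials: int) -> tuple[float, float]:
    bic = n_params * np.log(n_trials) - 2.0 * ll
    aic = 2.0 * n_params - 2.0 * ll
    return float(bic), float(aic)


def fit_rw_profile(
    record: ChoiceRecord,
    grid: FitGrid | None = None,
    alpha_points: int = 10,
    alpha_bounds: tuple[float, float] = (0.05, 0.95),
) -> tuple[ParameterVector, dict[str, float], float]:
    """Fit the fixed-learning-rate model by profiling the two learning rates.

    For each (alpha_reward, alpha_social) pair on an equispaced grid, the
    Rescorla-Wagner beliefs are rebuilt and the inner (gamma_s, gamma_r, beta)
    grid likelihood evaluated. Returns the posterior-mean point estimates of
    the three policy parameters (marginalised over everything), the best
    learning-rate pair, and the maximum log-likelihood over the full 5-D grid.
    """
    grid = grid or FitGrid(points_per_dim=20)
    vals, logs = grid.values, grid.log_values
    alphas = np.linspace(*alpha_bounds, alpha_points)
    outcomes = extract_outcomes(record.schedule)

    ll_stack = np.empty((alpha_points, alpha_points,
                         grid.points_per_dim, grid.points_per_dim, grid.points_per_dim))
    for i, a_r in enumerate(alphas):
        beliefs_r = track_rw(outcomes.reward_outcomes, RWParams(float(a_r)))
        for j, a_s in enumerate(alphas):
            beliefs_s = track_rw(outcomes.advice_outcomes, RWParams(float(a_s)))
            ll_stack[i, j] = _ll_grid(record, beliefs_r, beliefs_s, vals, vals, vals)

    flat = ll_stack - logsumexp(ll_stack)
    post = np.exp(flat)
    marg_s = post.sum(axis=(0, 1, 3, 4))
    marg_r = post.sum(axis=(0, 1, 2, 4))
    marg_b = post.sum(axis=(0, 1, 2, 3))
    point = ParameterVector(
        gamma_social=float(np.exp(marg_s @ logs)),
        gamma_reward_history=float(np.exp(marg_r @ logs)),
        beta=float(np.exp(marg_b @ logs)),
    )
    i, j = np.unravel_index(np.argmax(ll_stack.reshape(alpha_points**2, -1).max(axis=1)),
                            (alpha_points, alpha_points))
    best_alphas = {"alpha_reward": float(alphas[i]), "alpha_social": float(alphas[j])}
    return point, best_alphas, float(ll_stack.max())


def compare_models(
    record: ChoiceRecord,
    fit_grid: FitGrid | None = None,
    learner_grid: LearnerGrid | None = None,
    rw_grid: FitGrid | None = None,
    rw_alpha_points: int = 10,
) -> ModelComparison:
    """BIC/AIC comparison: volatility-adaptive learner vs fixed learning rate.

    The Bayesian-learner model has 3 free parameters (the two learning
    processes are parameter-free); the Rescorla-Wagner model has 5 (adds the
    two learning rates). Criteria use each model's best grid-node LL and
    ``n =`` number of choice trials.
    """
    n_trials = len(record)
    posterior = fit_subject(record, fit_grid, learner_grid)
    bic_b, aic_b = _information_criteria(posterior.max_log_likelihood, 3, n_trials)
    bayes_fit = ModelFit(
        tag=BAYES_TAG, n_params=3, n_trials=n_trials,
        max_log_likelihood=posterior.max_log_likelihood,
        bic=bic_b, aic=aic_b,
        point_estimates=posterior.point_estimates, extras={},
    )

    rw_point, rw_alphas, rw_ll = fit_rw_profile(record, rw_grid, rw_alpha_points)
    bic_r, aic_r = _information_criteria(rw_ll, 5, n_trials)
    rw_fit = ModelFit(
        tag=RW_TAG, n_params=5, n_trials=n_trials,
        max_log_likelihood=rw_ll, bic=bic_r, aic=aic_r,
        point_estimates=rw_point, extras=rw_alphas,
    )

    fits = {BAYES_TAG: bayes_fit, RW_TAG: rw_fit}
    return ModelComparison(
        fits=fits,
        preferred_by_bic=min(fits, key=lambda t: fits[t].bic),
        preferred_by_aic=min(fits, key=lambda t: fits[t].aic),
    )
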