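"""Probability trackers: volatility-adaptive Bayesian filter and Rescorla-Wagner.

Both learners consume a binary outcome sequence (e.g. "green was correct" or
"the advice was correct") and emit a trial-wise *predictive* probability
estimate — the belief held before that trial's feedback arrives — so the
choice model for trial *i* never sees trial *i*'s outcome.

The Bayesian tracker maintains a joint grid posterior over three latents:

* ``r``    — the outcome probability being tracked,
* ``v``    — log-volatility: how fast ``r`` drifts between trials,
* ``k``    — log-volatility-of-volatility: how fast ``v`` itself drifts
  (static per sequence).

Each trial the joint is propagated (``r`` through a mean-preserving beta
kernel whose dispersion grows with ``exp(v)``; ``v`` through a Gaussian random
walk with dispersion ``exp(k)``), then multiplied by the Bernoulli likelihood
of the observed outcome and renormalised. Because volatility is estimated
online, the filter's effective learning rate rises after reversals and decays
during stable stretches — the behaviour a fixed-learning-rate delta rule
cannot reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

BAYES_TAG = "bayes_volatility"
RW_TAG = "rw_fixed"

_MASS_FLOOR = 1e-300


class LearnerError(ValueError):
    """Invalid learner configuration or degenerate numerical state."""


@dataclass(frozen=True)
class LearnerGrid:
    """Discretisation of the tracker's latent space.

    ``r`` is equispaced strictly inside (0, 1); ``v`` and ``k`` are equispaced
    on the log scale. Defaults (30 points per axis, v in [-11, -2], k in
    [-8, 2]) balance resolution against runtime.
    """

    r_points: int = 30
    v_points: int = 30
    k_points: int = 30
    r_bounds: tuple[float, float] = (0.01, 0.99)
    v_bounds: tuple[float, float] = (-11.0, -2.0)
    k_bounds: tuple[float, float] = (-8.0, 2.0)

    def __post_init__(self) -> None:
        for name, n in (("r_points", self.r_points), ("v_points", self.v_points),
                        ("k_points", self.k_points)):
            if n < 5:
                raise LearnerError(f"{name} must be >= 5, got {n}")
        lo, hi = self.r_bounds
        if not (0.0 < lo < hi < 1.0):
            raise LearnerError("r_bounds must lie strictly inside (0, 1)")
        for name, (a, b) in (("v_bounds", self.v_bounds), ("k_bounds", self.k_bounds)):
            if not (np.isfinite(a) and np.isfinite(b) and a < b):
                raise LearnerError(f"{name} must be a finite increasing pair")

    @property
    def r_grid(self) -> np.ndarray:
        return np.linspace(*self.r_bounds, self.r_points)

    @property
    def v_grid(self) -> np.ndarray:
        return np.linspace(*self.v_bounds, self.v_points)

    @property
    def k_grid(self) -> np.ndarray:
        return np.linspace(*self.k_bounds, self.k_points)


@dataclass(frozen=True)
class RWParams:
    """Rescorla-Wagner delta rule: fixed learning rate, point-estimate belief."""

    alpha: float
    init: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise LearnerError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not 0.0 <= self.init <= 1.0:
            raise LearnerError(f"init must lie in [0, 1], got {self.init}")


@dataclass(frozen=True)
class BeliefTrajectory:
    """Per-trial predictive beliefs from one learner.

    ``estimates[i]`` is the probability estimate held going into trial *i*
    (before its feedback); ``spreads[i]`` is the SD of the marginal over the
    tracked probability (0 by convention for the point-estimate RW learner).
    """

    estimates: np.ndarray
    spreads: np.ndarray
    learner_tag: str

    def __post_init__(self) -> None:
        if len(self.estimates) != len(self.spreads):
            raise LearnerError("estimates and spreads differ in length")

    def __len__(self) -> int:
        return len(self.estimates)


def _validate_outcomes(outcomes) -> np.ndarray:
    arr = np.asarray(outcomes)
    if arr.ndim != 1 or arr.size == 0:
        raise LearnerError("outcomes must be a non-empty 1-D sequence")
    if not np.isin(arr, (0, 1)).all():
        raise LearnerError("outcomes must be binary (0/1)")
    return arr.astype(np.int8)


def _log_beta_pdf(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return ((a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x)
            + gammaln(a + b) - gammaln(a) - gammaln(b))


def r_transition_matrices(grid: LearnerGrid) -> np.ndarray:
    """Per-volatility transition kernels for the tracked probability.

    Returns an array of shape ``(v_points, r_points, r_points)`` where
    ``T[v, r_new, r_old]`` is the (column-normalised) probability of moving to
    ``r_new`` from ``r_old`` under log-volatility ``v``. The kernel is a beta
    density with mean ``r_old`` and total concentration ``exp(-v)``, so its
    dispersion grows with ``exp(v)`` while the mean is preserved.
    """
    r = grid.r_grid
    conc = np.exp(-grid.v_grid)  # (V,)
    a = conc[:, None] * r[None, :]  # (V, R_old)
    b = conc[:, None] * (1.0 - r[None, :])
    log_pdf = _log_beta_pdf(r[None, :, None], a[:, None, :], b[:, None, :])
    t = np.exp(log_pdf - log_pdf.max(axis=1, keepdims=True))
    t /= t.sum(axis=1, keepdims=True)
    return t


def v_transition_matrices(grid: LearnerGrid) -> np.ndarray:
    """Per-``k`` Gaussian random-walk kernels for log-volatility.

    Shape ``(k_points, v_points, v_points)``; ``W[k, v_new, v_old]`` columns
    sum to one.
    """
    v = grid.v_grid
    sd = np.exp(grid.k_grid)  # (K,)
    z = (v[None, :, None] - v[None, None, :]) / sd[:, None, None]
    w = np.exp(-0.5 * z**2)
    w /= w.sum(axis=1, keepdims=True)
    return w


def track_bayes(outcomes, grid: LearnerGrid | None = None) -> BeliefTrajectory:
    """Run the volatility-adaptive grid filter over a binary outcome sequence.

    Starts from a uniform joint prior (so the first predictive estimate is
    0.5), and per trial: propagate, record the predictive mean and SD of the
    ``r`` marginal, apply the Bernoulli likelihood, renormalise. The joint
    sums to one after every trial.
    """
    outcomes = _validate_outcomes(outcomes)
    grid = grid or LearnerGrid()
    r = grid.r_grid
    t_r = r_transition_matrices(grid)  # (V, R', R)
    t_v = v_transition_matrices(grid)  # (K, V', V)

    joint = np.full((grid.r_points, grid.v_points, grid.k_points), 1.0)
    joint /= joint.sum()

    n = len(outcomes)
    estimates = np.empty(n)
    spreads = np.empty(n)
    for i, outcome in enumerate(outcomes):
        # propagate: r given current v, then v given k (k static)
        a = np.matmul(t_r, joint.transpose(1, 0, 2))  # (V, R', K)
        joint = np.matmul(t_v, a.transpose(2, 0, 1)).transpose(2, 1, 0)  # (R', V', K)
        joint /= joint.sum()

        marg = joint.sum(axis=(1, 2))
        mean = float(marg @ r)
        estimates[i] = mean
        spreads[i] = float(np.sqrt(max(marg @ (r - mean) ** 2, 0.0)))

        lik = r if outcome == 1 else 1.0 - r
        joint = joint * lik[:, None, None]
        mass = joint.sum()
        if mass <= _MASS_FLOOR:
            raise LearnerError(f"posterior mass underflowed at trial {i}")
        joint /= mass

    return BeliefTrajectory(estimates=estimates, spreads=spreads, learner_tag=BAYES_TAG)


def track_rw(outcomes, params: RWParams) -> BeliefTrajectory:
    """Fixed-learning-rate delta rule: ``e[i+1] = e[i] + alpha*(o[i] - e[i])``."""
    outcomes = _validate_outcomes(outcomes)
    n = len(outcomes)
    estimates = np.empty(n)
    e = params.init
    for i, outcome in enumerate(outcomes):
        estimates[i] = e
        e = e + params.alpha * (outcome - e)
    return BeliefTrajectory(estimates=estimates, spreads=np.zeros(n), learner_tag=RW_TAG)


def effective_gain(trajectory: BeliefTrajectory, outcomes) -> np.ndarray:
    """Realised per-trial learning rate ``(e[i+1] - e[i]) / (o[i] - e[i])``.

    Length ``n - 1``; NaN where the outcome equals the estimate exactly (the
    update direction is undefined).
    """
    outcomes = _validate_outcomes(outcomes)
    e = trajectory.estimates
    if len(e) != len(outcomes):
        raise LearnerError("trajectory and outcomes differ in length")
    denom = outcomes[:-1] - e[:-1]
    gains = np.full(len(e) - 1, np.nan)
    ok = denom != 0
    gains[ok] = (e[1:] - e[:-1])[ok] / denom[ok]
    return gains


def adaptive_gain(outcomes, grid: LearnerGrid | None = None) -> np.ndarray:
    """Effective learning rate of the Bayesian tracker on an outcome sequence."""
    traj = track_bayes(outcomes, grid)
    return effective_gain(traj, outcomes)
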