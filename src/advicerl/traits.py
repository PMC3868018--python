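"""Trait-association stage: variable selection and bootstrap correlations.

Given a subjects x 8 trait-score table and one fitted model parameter per
subject, this stage answers which traits carry independent explanatory power
for the parameter:

1. every variable is optimally scaled at numeric level (z-score x 10);
2. a lasso path over 51 shrinkage levels (standardised sum of coefficients
   from 0.0 to 1.0 in steps of 0.02) traces how coefficients enter;
3. the level minimising the .632-bootstrap expected prediction error (100
   resamples, squared loss) defines the optimal model;
4. Pearson correlations between the selected traits and the parameter are
   tested by percentile bootstrap confidence intervals (10,000 resamples):
   significant iff the CI excludes zero;
5. one-sample Kolmogorov-Smirnov checks of normality are reported per score.

The lasso path is computed exactly via least-angle regression: the lasso
solution is piecewise linear in its L1 norm, so coefficients at any fraction
of the unconstrained fit's norm are obtained by interpolating between knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lars_path
from statsmodels.stats.diagnostic import lilliefors

from .simulate import TRAIT_NAMES

#: Shrinkage axis: fractions of the unconstrained L1 norm, 0.0 to 1.0 step 0.02.
SHRINKAGE_FRACTIONS: np.ndarray = np.round(np.arange(0, 51) * 0.02, 10)

_COEF_TOL = 1e-10


class TraitError(ValueError):
    """Invalid trait table or degenerate statistical input."""


def validate_trait_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the subjects x traits table against the fixed subscale vocabulary."""
    if table.isna().any().any():
        raise TraitError("trait table contains missing values")
    if len(table) < 3:
        raise TraitError("trait table needs at least 3 subjects")
    unknown = set(table.columns) - set(TRAIT_NAMES) - {"Total"}
    if unknown:
        raise TraitError(f"unknown trait columns: {sorted(unknown)}")
    return table


def optimal_scale(table: pd.DataFrame, *, ddof: int = 0) -> pd.DataFrame:
    """Numeric-level optimal scaling: z-score each column and multiply by 10.

    Population-SD convention by default (``ddof=0``); pass ``ddof=1`` for the
    sample-SD convention. Idempotent up to floating point.
    """
    means = table.mean(axis=0)
    sds = table.std(axis=0, ddof=ddof)
    bad = sds[sds <= 0]
    if len(bad):
        raise TraitError(f"constant column(s): {list(bad.index)}")
    return (table - means) / sds * 10.0


@dataclass(frozen=True)
class LassoPath:
    """Coefficients along the shrinkage axis.

    ``coefs[i]`` solves least squares subject to an L1 budget of
    ``fractions[i]`` times the unconstrained solution's L1 norm.
    """

    predictors: tuple[str, ...]
    fractions: np.ndarray  # (51,)
    coefs: np.ndarray  # (51, p)

    def nonzero_at(self, level: int) -> tuple[str, ...]:
        mask = np.abs(self.coefs[level]) > _COEF_TOL
        return tuple(p for p, m in zip(self.predictors, mask) if m)


def _path_coefs(x: np.ndarray, y: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Exact lasso coefficients at each L1-norm fraction, via LARS knots."""
    _, _, knot_coefs = lars_path(x, y, method="lasso")
    l1 = np.abs(knot_coefs).sum(axis=0)
    full_norm = l1[-1]
    out = np.zeros((len(fractions), x.shape[1]))
    if full_norm <= _COEF_TOL:
        return out
    targets = fractions * full_norm
    for i, t in enumerate(targets):
        k = int(np.searchsorted(l1, t, side="right")) - 1
        if k >= len(l1) - 1:
            out[i] = knot_coefs[:, -1]
        elif l1[k + 1] > l1[k]:
            w = (t - l1[k]) / (l1[k + 1] - l1[k])
            out[i] = (1 - w) * knot_coefs[:, k] + w * knot_coefs[:, k + 1]
        else:
            out[i] = knot_coefs[:, k]
    return out


def lasso_path_table(
    predictors: pd.DataFrame, response: pd.Series | np.ndarray
) -> LassoPath:
    """Lasso path of the (scaled, centred) response on the scaled predictors."""
    x = np.asarray(predictors, dtype=float)
    y = np.asarray(response, dtype=float)
    if y.std() <= 0:
        raise TraitError("response has zero variance")
    coefs = _path_coefs(x, y, SHRINKAGE_FRACTIONS)
    return LassoPath(
        predictors=tuple(predictors.columns),
        fractions=SHRINKAGE_FRACTIONS.copy(),
        coefs=coefs,
    )


@dataclass(frozen=True)
class OptimalModel:
    """Shrinkage level minimising .632-bootstrap expected prediction error."""

    path: LassoPath
    level: int  # index into path.fractions
    fraction: float
    coefficients: dict[str, float]
    selected: tuple[str, ...]
    expected_error: np.ndarray  # (51,) .632 estimate per level
    error_se: np.ndarray  # (51,) SE of the out-of-bag component
    n_redraws: int


def select_optimal(
    predictors: pd.DataFrame,
    response: pd.Series | np.ndarray,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> OptimalModel:
    """Pick the shrinkage level by the .632 bootstrap (squared-error loss).

    Expected error per level = 0.368 * apparent error (full-data fit scored on
    the full data) + 0.632 * out-of-bag error (path refitted on each bootstrap
    sample, scored on the subjects it missed, pooled over resamples). Ties go
    to the smaller (more parsimonious) level. Deterministic given ``seed``.
    """
    x = np.asarray(predictors, dtype=float)
    y = np.asarray(response, dtype=float)
    n = len(y)
    path = lasso_path_table(predictors, y)

    apparent = np.mean((y[None, :] - (x @ path.coefs.T).T) ** 2, axis=1)

    rng = np.random.default_rng(seed)
    n_levels = len(SHRINKAGE_FRACTIONS)
    oob_sse = np.zeros(n_levels)
    oob_count = 0
    per_sample_err = []
    redraws = 0
    b = 0
    while b < n_bootstrap:
        idx = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) == 0 or y[idx].std() <= 0:
            redraws += 1
            continue
        coefs_b = _path_coefs(x[idx], y[idx], SHRINKAGE_FRACTIONS)
        pred = x[oob] @ coefs_b.T  # (n_oob, 51)
        err = (y[oob, None] - pred) ** 2
        oob_sse += err.sum(axis=0)
        oob_count += len(oob)
        per_sample_err.append(err.mean(axis=0))
        b += 1

    oob_err = oob_sse / oob_count
    expected = 0.368 * apparent + 0.632 * oob_err
    error_se = np.std(np.asarray(per_sample_err), axis=0, ddof=1) / np.sqrt(n_bootstrap)
    level = int(np.argmin(expected))  # argmin takes the first (smallest) level on ties
    coefficients = {p: float(c) for p, c in zip(path.predictors, path.coefs[level])}
    return OptimalModel(
        path=path,
        level=level,
        fraction=float(SHRINKAGE_FRACTIONS[level]),
        coefficients=coefficients,
        selected=path.nonzero_at(level),
        expected_error=expected,
        error_se=error_se,
        n_redraws=redraws,
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_lower: float
    ci_upper: float
    significant: bool
    n_resamples: int
    n_redraws: int


def bootstrap_corr(x, y, n_bootstrap: int = 10_000, seed: int = 0,
                   ci_level: float = 95.0) -> CorrelationResult:
    """Pearson r with a percentile bootstrap CI over paired resamples.

    Significance means the CI excludes zero (both bounds on the same side).
    Resamples in which either variable is constant are redrawn and counted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise TraitError("x and y differ in length")
    n = len(x)
    if n < 3:
        raise TraitError("need at least 3 observations")
    if x.std() <= 0 or y.std() <= 0:
        raise TraitError("zero variance input")
    r = float(stats.pearsonr(x, y).statistic)

    rng = np.random.default_rng(seed)
    rs = np.empty(n_bootstrap)
    filled = 0
    redraws = 0
    while filled < n_bootstrap:
        chunk = min(n_bootstrap - filled, 2000)
        idx = rng.integers(0, n, (chunk, n))
        xb, yb = x[idx], y[idx]
        xc = xb - xb.mean(axis=1, keepdims=True)
        yc = yb - yb.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        ok = denom > 0
        redraws += int((~ok).sum())
        vals = (xc * yc).sum(axis=1)[ok] / denom[ok]
        rs[filled:filled + len(vals)] = vals
        filled += len(vals)

    half = (100.0 - ci_level) / 2.0
    lo, hi = np.percentile(rs, [half, 100.0 - half])
    significant = bool(lo > 0.0 or hi < 0.0)
    return CorrelationResult(r=r, ci_lower=float(lo), ci_upper=float(hi),
                             significant=significant,
                             n_resamples=n_bootstrap, n_redraws=redraws)


def ks_normality(x, method: str = "lilliefors", n_boot: int = 2000,
                 seed: int = 0) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample's mean and SD.

    Because the reference distribution's parameters are estimated from the
    same sample, the classical KS p-value (``method='asymptotic'``) is
    conservative; the default corrects for this with the Lilliefors table,
    and ``method='bootstrap'`` draws a parametric-bootstrap null of the
    statistic instead.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise TraitError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd <= 0:
        raise TraitError("constant input")
    if method == "lilliefors":
        stat, p = lilliefors(x, dist="norm", pvalmethod="table")
        return float(stat), float(p)
    mean = x.mean()
    stat, p = stats.kstest(x, "norm", args=(mean, sd))
    if method == "asymptotic":
        return float(stat), float(p)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        sims = rng.standard_normal((n_boot, len(x)))
        d_null = np.empty(n_boot)
        for i, s in enumerate(sims):
            d_null[i] = stats.kstest(s, "norm", args=(s.mean(), s.std(ddof=1))).statistic
        p_boot = (1 + np.sum(d_null >= stat)) / (n_boot + 1)
        return float(stat), float(p_boot)
    raise TraitError(f"unknown method {method!r}")


@dataclass(frozen=True)
class AssociationResult:
    """Selection + correlation report for one fitted parameter."""

    target: str
    optimal_model: OptimalModel
    correlations: dict[str, CorrelationResult]
    normality: dict[str, tuple[float, float]] = field(default_factory=dict)


def associate(
    traits: pd.DataFrame,
    param_values,
    target: str,
    n_bootstrap_select: int = 100,
    n_bootstrap_corr: int = 10_000,
    seed: int = 0,
) -> AssociationResult:
    """Full association pipeline for one parameter.

    Scales traits and parameter (z x 10), selects traits by lasso + .632
    bootstrap, then reports bootstrap-CI Pearson correlations for the
    selected traits and KS normality for every trait score.
    """
    validate_trait_table(traits)
    param_values = np.asarray(param_values, dtype=float)
    if len(param_values) != len(traits):
        raise TraitError("parameter vector must match the trait table length")
    scaled_x = optimal_scale(traits)
    scaled_y = optimal_scale(pd.DataFrame({"y": param_values}))["y"].to_numpy()

    optimal = select_optimal(scaled_x, scaled_y, n_bootstrap=n_bootstrap_select,
                             seed=seed)
    correlations = {
        trait: bootstrap_corr(traits[trait].to_numpy(), param_values,
                              n_bootstrap=n_bootstrap_corr,
                              seed=seed + 1 + i)
        for i, trait in enumerate(optimal.selected)
    }
    normality = {col: ks_normality(traits[col].to_numpy()) for col in traits.columns}
    return AssociationResult(target=target, optimal_model=optimal,
                             correlations=correlations, normality=normality)
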