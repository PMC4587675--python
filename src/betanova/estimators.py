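"""Per-group Gaussian estimation: MLE, minimum beta-divergence, and the hybrid rule.

Each group of log-scale expression values is modelled as ``x_k ~ N(mu, sigma^2)``.
Two estimator families are provided:

* the classical maximum-likelihood estimates (sample mean; variance with
  divisor ``n``), which are efficient for clean Gaussian data but break down
  under a single extreme value;
* the minimum beta-divergence estimates, computed by an iteratively
  reweighted scheme in which each observation carries the weight
  ``W_beta(x | mu, sigma^2) = exp{-beta (x - mu)^2 / (2 sigma^2)}``.
  Outlying observations receive weights near 0 and therefore barely
  influence the fit; the ``(beta + 1)`` factor in the variance update makes
  the scale estimate approximately unbiased for Gaussian data.

The weight function doubles as an outlier detector.  Under the fitted
Gaussian, ``-2/beta * log W`` is a chi-square(1) pivot, so the p-th quantile
of the null weight distribution has the closed form

    delta = exp(-(beta / 2) * Q_chi2_1(1 - p)),

and an observation is declared outlying when its weight is <= delta.  The
hybrid rule then uses the MLE whenever no observation in the group is
flagged, and the beta-divergence estimate otherwise, combining the
efficiency of the former with the robustness of the latter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BetaConfig",
    "DegenerateVarianceError",
    "GaussianParams",
    "GroupSample",
    "WeightVector",
    "beta_estimate",
    "beta_estimate_batch",
    "beta_weight",
    "detect_outliers",
    "hybrid_estimate",
    "hybrid_estimate_batch",
    "mle_estimate",
    "mle_estimate_batch",
    "pooled_robust_scale",
    "predicted_weight_quantile",
]

# MAD -> sigma consistency factor for the Gaussian.
_MAD_SCALE = 1.4826


class DegenerateVarianceError(ValueError):
    """Raised when a group's variance collapses below the configured floor."""


@dataclass(frozen=True)
class BetaConfig:
    """Tuning parameters of the beta-divergence estimator and outlier rule.

    Parameters
    ----------
    beta
        Non-negative divergence tuning parameter.  ``beta = 0`` recovers
        maximum likelihood exactly; ``0.2`` is the default working value for
        outlier detection.
    tail_prob
        Null tail probability ``p`` defining the weight threshold
        ``delta`` (an observation whose weight falls in the lower ``p``
        tail of the null weight distribution is called an outlier).
    tol
        Convergence tolerance on ``max(|d mu|, |d sigma^2|)``.
    max_iter
        Iteration cap for the reweighting scheme.
    init
        ``"median_mad"`` (robust; default) or ``"mean_var"`` initialisation.
    variance_floor
        Variances at or below this value are treated as degenerate.
    """

    beta: float = 0.2
    tail_prob: float = 1e-5
    tol: float = 1e-6
    max_iter: int = 100
    init: str = "median_mad"
    variance_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 < self.tail_prob < 1.0:
            raise ValueError("tail_prob must lie in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init not in ("median_mad", "mean_var"):
            raise ValueError("init must be 'median_mad' or 'mean_var'")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")


@dataclass(frozen=True)
class GaussianParams:
    """A per-group (mean, variance) estimate with its provenance.

    ``source`` is ``"mle"`` or ``"beta"``; ``iterations`` is 0 for the MLE.
    """

    mean: float
    variance: float
    source: str
    iterations: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if self.source not in ("mle", "beta"):
            raise ValueError("source must be 'mle' or 'beta'")
        if self.source == "mle" and self.iterations != 0:
            raise ValueError("MLE params carry iterations = 0")


@dataclass(frozen=True)
class GroupSample:
    """Expression values of one gene within one condition."""

    values: np.ndarray
    group_label: str = ""
    n: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "n", vals.size)


@dataclass(frozen=True)
class WeightVector:
    """Beta-weights of a group's observations and the null threshold delta."""

    weights: np.ndarray
    threshold: float


def _as_values(sample) -> np.ndarray:
    """Coerce a GroupSample or array-like to a validated 1-D float array."""
    if isinstance(sample, GroupSample):
        x = sample.values
    else:
        x = np.asarray(sample, dtype=float)
    if x.ndim != 1:
        raise ValueError("a group sample must be one-dimensional")
    if x.size < 2:
        raise ValueError("a group sample needs at least two observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("group sample contains non-finite values")
    return x


def mle_estimate_batch(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise MLE mean and variance (divisor n) of a (G, n) matrix."""
    X = np.asarray(X, dtype=float)
    return X.mean(axis=1), X.var(axis=1)


def mle_estimate(sample, variance_floor: float = 1e-12) -> GaussianParams:
    """Maximum-likelihood (mean, variance) estimate for one group.

    The variance uses divisor ``n`` so that ``n * variance`` equals the
    group's within-sum-of-squares.  An (all but) constant sample raises
    :class:`DegenerateVarianceError`.
    """
    x = _as_values(sample)
    mean = float(x.mean())
    variance = float(x.var())
    if variance <= variance_floor:
        raise DegenerateVarianceError(
            f"sample variance {variance:g} at or below floor {variance_floor:g}"
        )
    return GaussianParams(mean=mean, variance=variance, source="mle")


def beta_weight(x, mean: float, variance: float, beta: float):
    """Evaluate ``exp{-beta (x - mean)^2 / (2 variance)}`` elementwise.

    Equals 1 exactly at ``x = mean`` and for ``beta = 0``; decays towards 0
    as ``x`` moves away from the mean on the scale of ``sqrt(variance)``.
    """
    if variance <= 0:
        raise ValueError("variance must be positive")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    x = np.asarray(x, dtype=float)
    w = np.exp(-beta * (x - mean) ** 2 / (2.0 * variance))
    return w if w.ndim else float(w)


def pooled_robust_scale(
    X: np.ndarray, group_indices: Sequence[np.ndarray], variance_floor: float = 1e-12
) -> np.ndarray:
    """Per-row robust variance pooled over a gene's groups.

    Residuals are taken from each group's median and pooled across all n
    samples; the squared scaled MAD of the pooled residuals estimates the
    common error variance of the one-way layout.  With only two or three
    observations per group, a single group carries almost no scale
    information of its own, so this pooled estimate is the natural starting
    value for the per-group reweighting iteration (rows whose MAD degenerates
    fall back to the pooled residual variance).
    """
    X = np.asarray(X, dtype=float)
    resid = np.empty_like(X)
    for idx in group_indices:
        med = np.median(X[:, idx], axis=1)
        resid[:, idx] = X[:, idx] - med[:, None]
    abs_resid = np.abs(resid)
    # odd-sized groups put their median on a data point, leaving an exact
    # zero residual that would bias the MAD low; ignore those atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mad = np.nanmedian(np.where(abs_resid > 0, abs_resid, np.nan), axis=1)
    scale = (_MAD_SCALE * np.where(np.isnan(mad), 0.0, mad)) ** 2
    flat = scale <= variance_floor
    if np.any(flat):
        scale = np.where(flat, resid.var(axis=1), scale)
    return scale


def _initial_params(
    X: np.ndarray, config: BetaConfig, init_scale: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    if config.init == "median_mad":
        mu = np.median(X, axis=1)
    else:
        mu = X.mean(axis=1)
    if init_scale is not None:
        var = np.broadcast_to(np.asarray(init_scale, dtype=float), mu.shape).copy()
    elif config.init == "median_mad":
        mad = np.median(np.abs(X - mu[:, None]), axis=1)
        var = (_MAD_SCALE * mad) ** 2
        # a tied-at-the-median group has MAD 0 even when the data vary
        flat = var <= config.variance_floor
        if np.any(flat):
            var = np.where(flat, X.var(axis=1), var)
    else:
        var = X.var(axis=1)
    if np.any(var <= config.variance_floor):
        bad = int(np.flatnonzero(var <= config.variance_floor)[0])
        raise DegenerateVarianceError(
            f"row {bad}: initial variance at or below floor "
            f"{config.variance_floor:g} (constant sample?)"
        )
    return mu, var


def beta_estimate_batch(
    X: np.ndarray,
    config: BetaConfig,
    init_scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Minimum beta-divergence estimates for every row of a (G, n) matrix.

    Runs the iteratively reweighted updates

        mu'     = sum(w x) / sum(w)
        sigma2' = (beta + 1) * sum(w (x - mu)^2) / sum(w)

    with ``w = W_beta(x | mu, sigma2)`` evaluated at the current iterate,
    freezing each row once ``max(|d mu|, |d sigma2|) < tol``.

    Returns
    -------
    (mu, var, iterations, converged, degenerate) arrays of length G.
        ``degenerate`` marks rows whose variance collapsed to the floor
        (e.g. two effectively-weighted, numerically identical points); their
        estimates are the last iterate with the variance clamped at the
        floor and should not be trusted.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be (G, n) with n >= 2")
    if config.beta <= 0:
        raise ValueError("beta_estimate requires beta > 0")
    n_rows = X.shape[0]
    mu, var = _initial_params(X, config, init_scale)
    iterations = np.zeros(n_rows, dtype=int)
    converged = np.zeros(n_rows, dtype=bool)
    degenerate = np.zeros(n_rows, dtype=bool)
    active = np.ones(n_rows, dtype=bool)
    for _ in range(config.max_iter):
        idx = np.flatnonzero(active)
        sub = X[idx]
        m = mu[idx][:, None]
        v = var[idx][:, None]
        resid2 = (sub - m) ** 2
        w = np.exp(-config.beta * resid2 / (2.0 * v))
        sw = w.sum(axis=1)
        mu_new = (w * sub).sum(axis=1) / sw
        var_new = (config.beta + 1.0) * (w * resid2).sum(axis=1) / sw
        collapsed = var_new <= config.variance_floor
        if np.any(collapsed):
            bad = idx[collapsed]
            degenerate[bad] = True
            active[bad] = False
            var_new = np.maximum(var_new, config.variance_floor)
        delta = np.maximum(np.abs(mu_new - mu[idx]), np.abs(var_new - var[idx]))
        mu[idx] = mu_new
        var[idx] = var_new
        iterations[idx] += 1
        done = idx[(delta < config.tol) & ~collapsed]
        converged[done] = True
        active[done] = False
        if not active.any():
            break
    if active.any():
        warnings.warn(
            f"beta estimation did not converge for {int(active.sum())} "
            f"group(s) within {config.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return mu, var, iterations, converged, degenerate


def beta_estimate(
    sample, config: BetaConfig, init_scale: float | None = None
) -> GaussianParams:
    """Minimum beta-divergence (mean, variance) estimate for one group.

    ``init_scale`` optionally overrides the starting variance of the
    iteration (used by the gene-level tests to start every group of a gene
    at the pooled robust scale of the one-way layout).
    """
    x = _as_values(sample)
    scale = None if init_scale is None else np.asarray([init_scale], dtype=float)
    mu, var, iters, conv, degen = beta_estimate_batch(x[None, :], config, scale)
    if degen[0]:
        raise DegenerateVarianceError(
            "variance collapsed below the floor during iteration"
        )
    return GaussianParams(
        mean=float(mu[0]),
        variance=float(var[0]),
        source="beta",
        iterations=int(iters[0]),
        converged=bool(conv[0]),
    )


def predicted_weight_quantile(beta: float, tail_prob: float) -> float:
    """The p-th quantile ``delta`` of the null beta-weight distribution.

    For ``x ~ N(mu, sigma^2)`` evaluated at its own parameters,
    ``U = (x - mu)^2 / sigma^2`` is chi-square(1) and ``W = exp(-beta U / 2)``
    is a decreasing transform of U, so

        P(W <= delta) = p  <=>  delta = exp(-(beta/2) * Q_chi2_1(1 - p)).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not 0.0 < tail_prob < 1.0:
        raise ValueError("tail_prob must lie in (0, 1)")
    return float(np.exp(-(beta / 2.0) * stats.chi2.ppf(1.0 - tail_prob, df=1)))


def detect_outliers(
    sample, params: GaussianParams, config: BetaConfig
) -> tuple[WeightVector, np.ndarray]:
    """Flag observations whose beta-weight falls at or below delta.

    ``params`` should be the converged beta-divergence estimate for the
    sample.  Ties with the threshold count as outliers.
    """
    x = _as_values(sample)
    weights = beta_weight(x, params.mean, params.variance, config.beta)
    threshold = predicted_weight_quantile(config.beta, config.tail_prob)
    mask = weights <= threshold
    return WeightVector(weights=np.asarray(weights), threshold=threshold), mask


def hybrid_estimate(
    sample, config: BetaConfig, init_scale: float | None = None
) -> tuple[GaussianParams, np.ndarray]:
    """Hybrid (mean, variance) estimate: MLE unless the group holds outliers.

    The beta-divergence fit is computed first and its weights screened
    against the null threshold; when nothing is flagged the exact MLE is
    returned (``source = "mle"``), otherwise the robust fit is kept.  With
    ``beta = 0`` the MLE is returned directly.
    """
    x = _as_values(sample)
    if config.beta == 0:
        return mle_estimate(x, config.variance_floor), np.zeros(x.size, dtype=bool)
    robust = beta_estimate(x, config, init_scale)
    _, mask = detect_outliers(x, robust, config)
    if not mask.any():
        return mle_estimate(x, config.variance_floor), mask
    return robust, mask


def hybrid_estimate_batch(
    X: np.ndarray,
    config: BetaConfig,
    init_scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised hybrid estimates for every row of a (G, n) matrix.

    Returns
    -------
    mu, var : (G,) arrays
        Hybrid estimates per row.
    mask : (G, n) bool array
        Outlier flags (all False when ``beta = 0``).
    used_beta : (G,) bool array
        True where the robust estimate was kept (``source = "beta"``).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be (G, n) with n >= 2")
    mle_mu, mle_var = mle_estimate_batch(X)
    if np.any(mle_var <= config.variance_floor):
        bad = int(np.flatnonzero(mle_var <= config.variance_floor)[0])
        raise DegenerateVarianceError(f"row {bad}: degenerate (constant) sample")
    if config.beta == 0:
        mask = np.zeros(X.shape, dtype=bool)
        used_beta = np.zeros(X.shape[0], dtype=bool)
        return mle_mu, mle_var, mask, used_beta
    b_mu, b_var, _, _, degen = beta_estimate_batch(X, config, init_scale)
    weights = np.exp(-config.beta * (X - b_mu[:, None]) ** 2 / (2.0 * b_var[:, None]))
    threshold = predicted_weight_quantile(config.beta, config.tail_prob)
    mask = weights <= threshold
    # a degenerate robust fit (collapsed variance) is unusable; keep the MLE
    mask[degen] = False
    used_beta = mask.any(axis=1) & ~degen
    mu = np.where(used_beta, b_mu, mle_mu)
    var = np.where(used_beta, b_var, mle_var)
    return mu, var, mask, used_beta
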