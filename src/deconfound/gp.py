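"""Gaussian-process regression with homogeneous and heterogeneous noise.

Model
-----
A zero-mean GP prior over latent function values, ``f ~ N(0, K(theta))``,
with a Gaussian observation likelihood.  Two noise conventions:

* homogeneous: ``y_i = f_i + eps_i``, ``eps_i ~ N(0, sigma^2)``;
* heterogeneous (instance-weighted): ``eps_i ~ N(0, sigma^2 / w_i)`` for
  positive per-subject weights ``w_i``.  Writing ``W = diag(1/w_i)`` the two
  cases share one algebra with noise covariance ``sigma^2 W`` (``W = I``
  when unweighted).

The posterior predictive at ``x*`` is closed form:

    mean  = k* (K + sigma^2 W)^{-1} y
    var   = k(x*, x*) - k* (K + sigma^2 W)^{-1} k*^T + sigma^2

The mean is exactly (weighted) kernel ridge regression: a training point with
weight ``w_i`` contributes ``w_i`` times the squared loss of a unit-weight
point, so an integer weight is equivalent to replicating the point.

Hyperparameters ``(theta, sigma)`` are estimated by maximising the log
marginal likelihood

    log Z = -1/2 y^T A^{-1} y - 1/2 log|A| - n/2 log(2 pi),   A = K + sigma^2 W

with analytic gradients in log space,
``d log Z / d p = 1/2 tr((alpha alpha^T - A^{-1}) dA/dp)`` where
``alpha = A^{-1} y``, using L-BFGS-B from a small set of dispersed restarts.
Initial values are data driven: the linear scale ``l`` from the mean squared
feature norm, ``b`` and ``sigma`` from the target standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg as sla
from scipy import optimize

from .exceptions import FitError, NumericalError, ValidationError
from .kernels import Kernel

__all__ = [
    "GPFit",
    "Prediction",
    "log_marginal_likelihood",
    "fit_gp",
    "gp_from_params",
    "predict_gp",
]

_LOG_BOUND = 15.0  # optimisation box on log hyperparameters
_RESTART_OFFSETS = (0.0, 1.5, -1.5)  # dispersed log-space restarts


def _chol_jitter(A: np.ndarray):
    """Cholesky with adaptive jitter: start at 1e-10 * mean diag, double <= 10x."""
    if A.shape[0] == 0:
        return np.zeros((0, 0)), 0.0
    base = 1e-10 * float(np.mean(np.diag(A)))
    base = base if base > 0 else 1e-10
    jitter = 0.0
    for attempt in range(11):
        try:
            L = sla.cholesky(A + jitter * np.eye(A.shape[0]), lower=True)
            return L, jitter
        except sla.LinAlgError:
            jitter = base * (2.0 ** attempt)
    raise NumericalError(
        "covariance matrix not positive definite after maximum jitter "
        f"({jitter:.3e}); check kernel hyperparameters and weights"
    )


def _noise_diag(n, sigma, weights):
    if weights is None:
        return np.full(n, 1.0)
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.shape[0] != n:
        raise ValidationError(f"weights length {weights.shape[0]} != n = {n}")
    if np.any(~np.isfinite(weights)) or np.any(weights <= 0):
        raise ValidationError("weights must be positive and finite")
    return 1.0 / weights


@dataclass
class Prediction:
    """Posterior predictive mean and variance (includes the sigma^2 noise term)."""

    mean: np.ndarray
    variance: np.ndarray


@dataclass
class GPFit:
    """A fitted GP: kernel with hyperparameters, noise scale, and solve state.

    ``alpha`` solves ``(K + sigma^2 W) alpha = y``; ``L`` is the lower
    Cholesky factor of that system (with any jitter applied).  ``weights`` is
    None for the homogeneous likelihood.
    """

    kernel: Kernel
    sigma: float
    X_train: np.ndarray
    y_train: np.ndarray
    alpha: np.ndarray
    L: np.ndarray
    log_evidence: float
    weights: Optional[np.ndarray] = None

    @property
    def W_diag(self) -> np.ndarray:
        return _noise_diag(self.X_train.shape[0], self.sigma, self.weights)

    @property
    def n(self) -> int:
        return self.X_train.shape[0]


def log_marginal_likelihood(kernel, X, y, sigma, weights=None, eval_gradient=False,
                            _cache=None):
    """Log evidence of the (possibly weighted) Gaussian-likelihood GP.

    With ``eval_gradient=True`` also returns d log Z with respect to
    ``[kernel.theta..., log sigma]`` (all in log space).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValidationError("X and y have different numbers of rows")
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    wdiag = _noise_diag(n, sigma, weights)
    cache = _cache if _cache is not None else kernel.precompute(X)
    if eval_gradient:
        K, Kgrads = kernel.eval_cache(cache, eval_gradient=True)
    else:
        K = kernel.eval_cache(cache)
    A = K + (sigma**2) * np.diag(wdiag)
    L, _ = _chol_jitter(A)
    alpha = sla.cho_solve((L, True), y)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    lml = -0.5 * float(y @ alpha) - 0.5 * logdet - 0.5 * n * np.log(2.0 * np.pi)
    if not eval_gradient:
        return lml
    Ainv = sla.cho_solve((L, True), np.eye(n))
    M = np.outer(alpha, alpha) - Ainv
    grad = np.empty(len(Kgrads) + 1)
    for i, dK in enumerate(Kgrads):
        grad[i] = 0.5 * np.sum(M * dK)
    # dA/d(log sigma) = 2 sigma^2 W (diagonal)
    grad[-1] = 0.5 * np.sum(np.diag(M) * (2.0 * sigma**2 * wdiag))
    return lml, grad


def gp_from_params(kernel, X, y, sigma, weights=None) -> GPFit:
    """Build a :class:`GPFit` at fixed hyperparameters (no optimisation)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    wdiag = _noise_diag(n, sigma, weights)
    if n == 0:
        return GPFit(kernel=kernel.clone(), sigma=float(sigma), X_train=X, y_train=y,
                     alpha=np.zeros(0), L=np.zeros((0, 0)), log_evidence=0.0,
                     weights=None)
    K = kernel(X)
    A = K + (sigma**2) * np.diag(wdiag)
    L, _ = _chol_jitter(A)
    alpha = sla.cho_solve((L, True), y)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    lml = -0.5 * float(y @ alpha) - 0.5 * logdet - 0.5 * n * np.log(2.0 * np.pi)
    w = None if weights is None else np.asarray(weights, dtype=float).ravel()
    return GPFit(kernel=kernel.clone(), sigma=float(sigma), X_train=X, y_train=y,
                 alpha=alpha, L=L, log_evidence=lml, weights=w)


def fit_gp(
    kernel: Kernel,
    X,
    y,
    weights=None,
    *,
    optimize_hyperparameters: bool = True,
    initialize: bool = True,
    n_restarts: int = 3,
    maxiter: int = 200,
    sigma0: Optional[float] = None,
) -> GPFit:
    """Fit a GP by evidence maximisation; returns the best of all restarts.

    The passed kernel is cloned, never mutated.  With
    ``optimize_hyperparameters=False`` the (data-initialized or passed-in)
    hyperparameters are used as-is, which gives a fully deterministic,
    optimisation-free fit -- used for fixed-hyperparameter protocols and for
    identities that hold at given ``(theta, sigma)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y have different numbers of rows")
    if X.shape[0] < 2:
        raise ValidationError("GP fitting requires at least 2 observations")
    kernel = kernel.clone()
    if initialize:
        kernel.init_from_data(X, y)
    if sigma0 is None:
        sd = float(np.std(y))
        sigma0 = sd / 2.0 if sd > 0 else 0.1

    if not optimize_hyperparameters:
        return gp_from_params(kernel, X, y, sigma0, weights=weights)

    cache = kernel.precompute(X)
    x0 = np.concatenate([kernel.theta, [np.log(sigma0)]])

    def objective(x):
        x = np.clip(x, -_LOG_BOUND, _LOG_BOUND)
        kernel.theta = x[:-1]
        sigma = float(np.exp(x[-1]))
        try:
            lml, grad = log_marginal_likelihood(
                kernel, X, y, sigma, weights=weights, eval_gradient=True, _cache=cache
            )
        except NumericalError:
            return 1e25, np.zeros_like(x)
        return -lml, -grad

    offsets = list(_RESTART_OFFSETS)[:max(1, n_restarts)]
    bounds = [(-_LOG_BOUND, _LOG_BOUND)] * len(x0)
    best_x, best_f = None, np.inf
    errors = []
    for off in offsets:
        start = np.clip(x0 + off, -_LOG_BOUND, _LOG_BOUND)
        f_start, _ = objective(start)
        try:
            res = optimize.minimize(
                objective, start, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter},
            )
        except Exception as exc:  # pragma: no cover - scipy failures are rare
            errors.append(f"restart at offset {off}: {exc}")
            continue
        # monotone-evidence guard: never accept a point worse than the start
        x_fin, f_fin = (res.x, res.fun) if res.fun <= f_start else (start, f_start)
        if np.isfinite(f_fin) and f_fin < best_f:
            best_x, best_f = x_fin, f_fin
    if best_x is None:
        raise FitError("all optimiser restarts failed: " + "; ".join(errors))
    best_x = np.clip(best_x, -_LOG_BOUND, _LOG_BOUND)
    kernel.theta = best_x[:-1]
    sigma = float(np.exp(best_x[-1]))
    return gp_from_params(kernel, X, y, sigma, weights=weights)


def predict_gp(fit: GPFit, X_star) -> Prediction:
    """Closed-form posterior predictive at test inputs.

    With no training points this is the prior predictive: mean 0 and
    variance ``k(x*, x*) + sigma^2``.
    """
    X_star = np.atleast_2d(np.asarray(X_star, dtype=float))
    if fit.n and X_star.shape[1] != fit.X_train.shape[1]:
        raise ValidationError(
            f"test inputs have {X_star.shape[1]} columns, training had "
            f"{fit.X_train.shape[1]}"
        )
    kdiag = fit.kernel.diag(X_star)
    if fit.n == 0:
        return Prediction(mean=np.zeros(X_star.shape[0]),
                          variance=kdiag + fit.sigma**2)
    kstar = fit.kernel(X_star, fit.X_train)  # m x n
    mean = kstar @ fit.alpha
    V = sla.solve_triangular(fit.L, kstar.T, lower=True)
    var = kdiag - np.sum(V**2, axis=0) + fit.sigma**2
    return Prediction(mean=mean, variance=np.maximum(var, 1e-12))
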