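"""Confound-handling computations.

Three independent tools live here:

* **Feature adjustment (residualization).**  Each feature column is
  regressed on the intercept-augmented confounds ``C_hat`` by ordinary least
  squares and replaced by its residual:
  ``G_A = G - C_hat (C_hat_S^T C_hat_S)^{-1} C_hat_S^T G_S`` where ``S`` is
  the (optionally restricted) fitting subset.  With ``S`` = all rows this is
  the orthogonal projection onto the complement of the confound span.

* **Density-ratio instance weights.**  Each training subject receives
  ``w_i = P_hat(y_i) / P_hat(y_i | c_i)``, the ratio of the estimated
  marginal target density to the conditional density given the confounds.
  Both densities are posterior predictive densities of GPs fitted by
  evidence maximisation: a bias-only kernel for the marginal (equivalent to
  fitting a normal distribution), and bias + linear-ARD-on-confounds for the
  conditional (a linear confound->target model with per-confound relevance
  scales).  Weighted empirical risk with these weights approximates risk
  under a population in which target and confounds are independent.

* **Balance diagnostics.**  The weighted standardized difference of the
  target across the two levels of a discrete confound,
  ``(m0 - m1) / sqrt((s0^2 + s1^2) / 2)`` with frequency-weighted means and
  unbiased weighted sample variances; it reduces exactly to the classical
  standardized difference under equal weights.  A drop in its absolute value
  after weighting indicates the weighted pseudo-sample is better balanced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats as sstats

from .data import augment_confounds
from .exceptions import SingularMatrixError, ValidationError, WeightingError
from .gp import GPFit, fit_gp, predict_gp
from .kernels import ARDLinear, BiasOnly, SumKernel

__all__ = [
    "AdjustmentModel",
    "InstanceWeights",
    "BalanceReport",
    "fit_adjustment",
    "apply_adjustment",
    "adjust_features",
    "estimate_target_density",
    "estimate_conditional_density",
    "compute_instance_weights",
    "weighted_standardized_difference",
]


# ---------------------------------------------------------------------------
# adjustment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdjustmentModel:
    """Per-feature OLS coefficients of features on augmented confounds.

    ``beta`` has shape ``(dC + 1, dG)``; column j holds the intercept and
    confound coefficients for feature j, fitted on rows ``fit_subset``.
    """

    beta: np.ndarray
    fit_subset: np.ndarray


def fit_adjustment(G, C_hat, subset=None) -> AdjustmentModel:
    """Least-squares fit of every feature column on the augmented confounds.

    ``subset`` restricts the fitting rows (default: all rows); the model can
    then adjust any rows with the same confound layout.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    C_hat = np.atleast_2d(np.asarray(C_hat, dtype=float))
    if G.shape[0] != C_hat.shape[0]:
        raise ValidationError("G and C_hat have different numbers of rows")
    subset = np.arange(G.shape[0]) if subset is None else np.asarray(subset)
    Cs, Gs = C_hat[subset], G[subset]
    rank = np.linalg.matrix_rank(Cs)
    if rank < Cs.shape[1]:
        # identify offending columns by dropping each in turn
        bad = [
            j for j in range(Cs.shape[1])
            if np.linalg.matrix_rank(np.delete(Cs, j, axis=1)) == rank
        ]
        raise SingularMatrixError(
            f"augmented confounds are rank deficient on the fitting subset "
            f"(rank {rank} of {Cs.shape[1]}); linearly dependent columns: {bad}"
        )
    beta, *_ = np.linalg.lstsq(Cs, Gs, rcond=None)
    return AdjustmentModel(beta=beta, fit_subset=subset)


def apply_adjustment(G, C_hat, model: AdjustmentModel) -> np.ndarray:
    """Residualize: ``G_A = G - C_hat @ beta``."""
    G = np.atleast_2d(np.asarray(G, dtype=float))
    C_hat = np.atleast_2d(np.asarray(C_hat, dtype=float))
    if C_hat.shape[1] != model.beta.shape[0]:
        raise ValidationError(
            f"C_hat has {C_hat.shape[1]} columns but model expects {model.beta.shape[0]}"
        )
    if G.shape[1] != model.beta.shape[1]:
        raise ValidationError(
            f"G has {G.shape[1]} features but model expects {model.beta.shape[1]}"
        )
    return G - C_hat @ model.beta


def adjust_features(G, C, subset=None) -> Tuple[np.ndarray, AdjustmentModel]:
    """Convenience: augment confounds, fit on ``subset``, adjust all rows."""
    C_hat = augment_confounds(C)
    model = fit_adjustment(G, C_hat, subset=subset)
    return apply_adjustment(G, C_hat, model), model


# ---------------------------------------------------------------------------
# density estimation and instance weights
# ---------------------------------------------------------------------------

def _posterior_densities(fit: GPFit, X_eval, y_eval):
    pred = predict_gp(fit, X_eval)
    return sstats.norm.pdf(y_eval, loc=pred.mean, scale=np.sqrt(pred.variance))


def estimate_target_density(y, **fit_kwargs):
    """Marginal density ``P_hat(y_i)`` at each training point via a bias-only GP.

    The kernel has no input dependence, so the posterior predictive is one
    normal distribution shared by all points; evaluating its pdf at each
    ``y_i`` gives the per-point marginal density estimates.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] < 3:
        raise ValidationError("density estimation requires n >= 3")
    X = np.zeros((y.shape[0], 1))
    fit = fit_gp(BiasOnly(), X, y, **fit_kwargs)
    return _posterior_densities(fit, X, y), fit


def estimate_conditional_density(y, C, **fit_kwargs):
    """Conditional density ``P_hat(y_i | c_i)`` via a bias + linear-ARD GP.

    The kernel ``b^2 + c Lambda_ARD c'^T`` learns a linear relationship
    between confounds and target, with the contribution of each confound
    controlled by its ARD scale.
    """
    y = np.asarray(y, dtype=float).ravel()
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != y.shape[0]:
        raise ValidationError("C and y have different numbers of rows")
    if y.shape[0] < 3:
        raise ValidationError("density estimation requires n >= 3")
    if C.shape[1] < 1:
        raise ValidationError("conditional density requires at least one confound")
    kernel = SumKernel([BiasOnly(), ARDLinear(np.ones(C.shape[1]))])
    fit = fit_gp(kernel, C, y, **fit_kwargs)
    return _posterior_densities(fit, C, y), fit


@dataclass(frozen=True)
class InstanceWeights:
    """Per-subject density-ratio weights and the estimates that formed them.

    ``ratio`` holds the raw ``p_marginal / p_conditional`` values; ``w`` is
    the working weight vector (rescaled to mean one unless normalisation was
    disabled, in which case ``w`` equals ``ratio``).
    """

    w: np.ndarray
    ratio: np.ndarray
    p_marginal: np.ndarray
    p_conditional: np.ndarray
    marginal_fit: GPFit
    conditional_fit: GPFit


def compute_instance_weights(
    y,
    C,
    normalize: bool = True,
    clip_quantile: Optional[float] = None,
    **fit_kwargs,
) -> InstanceWeights:
    """Density-ratio instance weights ``w_i = P_hat(y_i) / P_hat(y_i | c_i)``.

    ``normalize=True`` (default) rescales weights to mean 1, which keeps the
    fitted noise scale comparable with the unweighted model.
    ``clip_quantile`` optionally winsorizes the raw ratios at the given upper
    quantile (and its complement below) before normalisation; off by default.
    """
    p_marg, fit_m = estimate_target_density(y, **fit_kwargs)
    p_cond, fit_c = estimate_conditional_density(y, C, **fit_kwargs)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p_marg / p_cond
    bad = np.flatnonzero(~np.isfinite(ratio) | (ratio <= 0))
    if bad.size:
        raise WeightingError(
            f"non-finite or non-positive weight ratios at indices {bad[:10].tolist()}"
        )
    w = ratio.copy()
    if clip_quantile is not None:
        lo, hi = np.quantile(w, [1.0 - clip_quantile, clip_quantile])
        w = np.clip(w, lo, hi)
    if normalize:
        w = w / w.mean()
    return InstanceWeights(
        w=w, ratio=ratio, p_marginal=p_marg, p_conditional=p_cond,
        marginal_fit=fit_m, conditional_fit=fit_c,
    )


# ---------------------------------------------------------------------------
# balance diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BalanceReport:
    """Standardized difference of the target across a two-level confound."""

    std_diff_weighted: float
    std_diff_unweighted: float
    levels: np.ndarray
    weighted_means: Tuple[float, float]
    weighted_variances: Tuple[float, float]

    @property
    def improved(self) -> bool:
        return abs(self.std_diff_weighted) < abs(self.std_diff_unweighted)


def _weighted_moments(y, w):
    sw = w.sum()
    m = float((w * y).sum() / sw)
    denom = sw**2 - (w**2).sum()
    if denom <= 0:
        raise ValidationError("weighted variance undefined (single effective subject)")
    s2 = float(sw / denom * (w * (y - m) ** 2).sum())
    return m, s2


def _std_diff(y, group_mask, w):
    m0, s0 = _weighted_moments(y[group_mask], w[group_mask])
    m1, s1 = _weighted_moments(y[~group_mask], w[~group_mask])
    return (m0 - m1) / np.sqrt((s0 + s1) / 2.0), (m0, m1), (s0, s1)


def weighted_standardized_difference(y, group, weights=None) -> BalanceReport:
    """Weighted (and unweighted) standardized difference of ``y`` across groups.

    ``group`` must take exactly two distinct values; the difference is
    level-0 minus level-1 (levels in sorted order).  With equal weights the
    weighted value equals the classical standardized difference exactly.
    """
    y = np.asarray(y, dtype=float).ravel()
    group = np.asarray(group).ravel()
    levels = np.unique(group)
    if levels.size != 2:
        raise ValidationError(
            f"group labels must have exactly two levels, got {levels.size}"
        )
    mask0 = group == levels[0]
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != y.shape:
            raise ValidationError("weights and y have different lengths")
        if np.any(w <= 0):
            raise ValidationError("weights must be positive")
        if np.ptp(w) == 0:
            # constant weights reduce to the classical formula *exactly*
            w = np.ones_like(y)
    sd_w, means, variances = _std_diff(y, mask0, w)
    sd_u, _, _ = _std_diff(y, mask0, np.ones_like(y))
    return BalanceReport(
        std_diff_weighted=float(sd_w),
        std_diff_unweighted=float(sd_u),
        levels=levels,
        weighted_means=means,
        weighted_variances=variances,
    )
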