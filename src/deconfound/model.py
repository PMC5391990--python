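"""Confound-handling regression strategies behind one Model/Results interface.

:class:`ConfoundRegression` is constructed from a :class:`~deconfound.data.Dataset`
and a strategy name; ``fit()`` returns a :class:`ConfoundRegressionResults`
carrying the fitted GP, any auxiliary models (adjustment, instance weights),
transformation statistics, and ``predict`` / ``weight_map`` / ``summary``.

Strategies
----------
``images_only``
    GP on the standardized features with a linear-plus-bias kernel; the
    baseline that ignores the confounds.
``adjusted_images``
    Features residualized on the intercept-augmented confounds first (by
    default transductively: the adjustment OLS is fitted on training and
    test rows pooled, when test features are supplied), then standardized
    and modelled as in ``images_only``.
``images_confounds``
    Confounds appended to the features; kernel is the sum of linear-plus-bias
    on the feature block and a linear ARD kernel on the confound block, so
    each confound's contribution is controlled by its own relevance scale.
``instance_weighted``
    Density-ratio instance weights ``w_i = P_hat(y_i)/P_hat(y_i|c_i)``
    estimated from the training sample, then a heterogeneous-likelihood GP
    (noise variance ``sigma^2 / w_i``) on the standardized features.  The
    predictive function does not depend on the confounds; the weighting
    alone refocuses training on the confound-free population.

For bounded integer scores (e.g. a 0-30 dementia screening scale) the
``rounding`` option rounds predictions to the nearest whole number clamped
to the given bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .confounds import (
    AdjustmentModel,
    InstanceWeights,
    apply_adjustment,
    compute_instance_weights,
    fit_adjustment,
    weighted_standardized_difference,
)
from .data import Dataset, StandardizationStats, augment_confounds, standardize
from .exceptions import ValidationError
from .gp import GPFit, fit_gp, gp_from_params, predict_gp
from .kernels import ARDLinear, LinearBias, SumKernel, kernel_from_dict

__all__ = [
    "STRATEGIES",
    "StrategySpec",
    "ConfoundRegression",
    "ConfoundRegressionResults",
    "save_results",
    "load_results",
]

STRATEGIES = ("images_only", "adjusted_images", "images_confounds", "instance_weighted")


@dataclass(frozen=True)
class StrategySpec:
    """Named strategy plus prediction-side options."""

    name: str
    rounding: Optional[Tuple[int, int]] = None
    standardize: bool = True

    def __post_init__(self):
        if self.name not in STRATEGIES:
            raise ValidationError(
                f"unknown strategy '{self.name}'; valid strategies: {', '.join(STRATEGIES)}"
            )
        if self.rounding is not None and self.rounding[0] > self.rounding[1]:
            raise ValidationError("rounding bounds must be ordered (lower, upper)")


def _standardize_confounds(C_train, C_other=None):
    """Standardize continuous confound columns; leave two-level columns as-is."""
    C_train = np.atleast_2d(np.asarray(C_train, dtype=float))
    continuous = np.array(
        [np.unique(C_train[:, j]).size > 2 for j in range(C_train.shape[1])]
    )
    mean = np.where(continuous, C_train.mean(axis=0), 0.0)
    sd = C_train.std(axis=0, ddof=1) if C_train.shape[0] > 1 else np.ones(C_train.shape[1])
    scale = np.where(continuous & (sd > 1e-12), sd, 1.0)
    stats = StandardizationStats(mean=mean, scale=scale, ddof=1)

    def tf(C):
        C = np.atleast_2d(np.asarray(C, dtype=float))
        return (C - mean) / scale

    return tf(C_train), (None if C_other is None else tf(C_other)), stats


class ConfoundRegression:
    """Confound-aware GP regression model for a training :class:`Dataset`.

    Parameters
    ----------
    data
        Training data (features, confounds, target).
    strategy
        One of ``images_only``, ``adjusted_images``, ``images_confounds``,
        ``instance_weighted``, or a :class:`StrategySpec`.
    rounding
        Optional ``(lower, upper)`` integer bounds; predictions are rounded
        to the nearest integer within them.
    adjustment_data
        Optional ``(G_test, C_test)`` block pooled with the training rows
        when fitting the adjustment OLS (the transductive mode used in the
        evaluated protocol).  Ignored by the other strategies.
    weight_options
        Keyword arguments for instance-weight computation
        (``normalize``, ``clip_quantile``, or a precomputed ``weights``
        vector to bypass estimation).
    """

    def __init__(
        self,
        data: Dataset,
        strategy="images_only",
        *,
        rounding: Optional[Tuple[int, int]] = None,
        standardize_features: bool = True,
        adjustment_data: Optional[Tuple[np.ndarray, np.ndarray]] = None,
        weight_options: Optional[dict] = None,
    ):
        if isinstance(strategy, StrategySpec):
            spec = strategy
            if rounding is not None:
                spec = StrategySpec(spec.name, rounding, spec.standardize)
        else:
            spec = StrategySpec(str(strategy), rounding, standardize_features)
        self.spec = spec
        self.data = data
        self.adjustment_data = adjustment_data
        self.weight_options = dict(weight_options or {})
        if spec.name in ("adjusted_images", "images_confounds", "instance_weighted"):
            if data.d_confounds == 0:
                raise ValidationError(f"strategy '{spec.name}' requires confounds")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        target: str,
        confounds: Sequence[str],
        features: Optional[Sequence[str]] = None,
        **kwargs,
    ) -> "ConfoundRegression":
        """Build the model from a single tidy DataFrame.

        ``features`` defaults to every numeric column that is neither the
        target nor a confound; the DataFrame index supplies subject ids.
        """
        confounds = list(confounds)
        if features is None:
            numeric = df.select_dtypes(include=[np.number]).columns
            features = [c for c in numeric if c != target and c not in confounds]
        data = Dataset(
            G=df[list(features)].to_numpy(dtype=float),
            C=df[confounds].to_numpy(dtype=float),
            y=df[target].to_numpy(dtype=float),
            subject_ids=df.index.astype(str).to_numpy(),
            feature_names=list(features),
            confound_names=confounds,
        )
        return cls(data, **kwargs)

    # ------------------------------------------------------------------
    def fit(
        self,
        *,
        optimize_hyperparameters: bool = True,
        n_restarts: int = 3,
        maxiter: int = 200,
    ) -> "ConfoundRegressionResults":
        """Estimate hyperparameters (and any auxiliary models) and return results."""
        data, spec = self.data, self.spec
        adjustment = None
        instance_weights = None
        gp_weights = None
        confound_stats = None

        G_model = data.G
        if spec.name == "adjusted_images":
            if self.adjustment_data is not None:
                G_extra, C_extra = self.adjustment_data
                G_pool = np.vstack([data.G, np.atleast_2d(G_extra)])
                C_pool = np.vstack(
                    [data.C, np.atleast_2d(np.asarray(C_extra, dtype=float))]
                )
            else:
                G_pool, C_pool = data.G, data.C
            C_hat_pool = augment_confounds(C_pool)
            adjustment = fit_adjustment(G_pool, C_hat_pool)
            G_model = apply_adjustment(
                data.G, augment_confounds(data.C), adjustment
            )

        if spec.standardize:
            G_std, _, feature_stats = standardize(G_model)
        else:
            feature_stats = StandardizationStats(
                mean=np.zeros(G_model.shape[1]), scale=np.ones(G_model.shape[1])
            )
            G_std = G_model

        if spec.name == "images_confounds":
            C_std, _, confound_stats = _standardize_confounds(data.C)
            X = np.hstack([G_std, C_std])
            dG, dC = G_std.shape[1], C_std.shape[1]
            kernel = SumKernel(
                [LinearBias(), ARDLinear(np.ones(dC))],
                slices=[slice(0, dG), slice(dG, dG + dC)],
            )
        else:
            X = G_std
            kernel = LinearBias()

        if spec.name == "instance_weighted":
            opts = dict(self.weight_options)
            forced = opts.pop("weights", None)
            if forced is not None:
                gp_weights = np.asarray(forced, dtype=float).ravel()
                if gp_weights.shape[0] != data.n:
                    raise ValidationError("forced weight vector has wrong length")
            else:
                instance_weights = compute_instance_weights(
                    data.y, data.C,
                    optimize_hyperparameters=optimize_hyperparameters,
                    n_restarts=n_restarts, maxiter=maxiter, **opts,
                )
                gp_weights = instance_weights.w

        gp = fit_gp(
            kernel, X, data.y, weights=gp_weights,
            optimize_hyperparameters=optimize_hyperparameters,
            n_restarts=n_restarts, maxiter=maxiter,
        )
        return ConfoundRegressionResults(
            model=self,
            spec=spec,
            gp=gp,
            adjustment=adjustment,
            instance_weights=instance_weights,
            feature_stats=feature_stats,
            confound_stats=confound_stats,
        )


class ConfoundRegressionResults:
    """Fitted strategy: GP state, auxiliary models, and prediction methods."""

    def __init__(self, model, spec, gp: GPFit, adjustment, instance_weights,
                 feature_stats, confound_stats):
        self.model = model
        self.spec = spec
        self.gp = gp
        self.adjustment = adjustment
        self.instance_weights = instance_weights
        self.feature_stats = feature_stats
        self.confound_stats = confound_stats

    # -- prediction -----------------------------------------------------
    def _inputs(self, G, C):
        G = np.atleast_2d(np.asarray(G, dtype=float))
        if self.spec.name == "adjusted_images":
            if C is None:
                raise ValidationError("adjusted_images prediction requires confounds")
            G = apply_adjustment(G, augment_confounds(C), self.adjustment)
        X = self.feature_stats.transform(G)
        if self.spec.name == "images_confounds":
            if C is None:
                raise ValidationError("images_confounds prediction requires confounds")
            C = np.atleast_2d(np.asarray(C, dtype=float))
            Cs = (C - self.confound_stats.mean) / self.confound_stats.scale
            X = np.hstack([X, Cs])
        return X

    def predict(self, data=None, *, G=None, C=None, raw: bool = False) -> np.ndarray:
        """Posterior-mean predictions for new subjects.

        Pass either a :class:`Dataset` or explicit ``G`` (and ``C`` where
        the strategy needs confounds).  ``raw=True`` skips the configured
        integer rounding.
        """
        if data is not None:
            G, C = data.G, data.C
        if G is None:
            raise ValidationError("predict requires a Dataset or a feature matrix G")
        pred = predict_gp(self.gp, self._inputs(G, C))
        yhat = pred.mean
        if self.spec.rounding is not None and not raw:
            lo, hi = self.spec.rounding
            yhat = np.clip(np.rint(yhat), lo, hi)
        return yhat

    def predict_frame(self, data: Dataset, **kwargs) -> pd.DataFrame:
        """Predictions as a table with columns subject_id, y_true, y_pred."""
        return pd.DataFrame({
            "subject_id": data.subject_ids,
            "y_true": data.y,
            "y_pred": self.predict(data, **kwargs),
        })

    # -- interpretation -------------------------------------------------
    def _linear_child(self):
        kernel = self.gp.kernel
        if isinstance(kernel, LinearBias):
            return kernel, slice(0, self.gp.X_train.shape[1])
        if isinstance(kernel, SumKernel):
            for child, sl in zip(kernel.children, kernel.slices):
                if isinstance(child, LinearBias):
                    return child, sl
        raise ValidationError(
            "weight-map extraction requires a kernel linear in the features"
        )

    def weight_map(self) -> np.ndarray:
        """Primal weights over the feature block (standardized scale).

        For the linear kernel the posterior mean is
        ``f(x*) = x* . v + intercept`` with ``v = X^T alpha / l^2``; a
        positive weight at a feature means predictions increase with that
        feature, all else held fixed.
        """
        child, sl = self._linear_child()
        Xblock = self.gp.X_train[:, sl]
        return Xblock.T @ self.gp.alpha / child.scale**2

    @property
    def intercept(self) -> float:
        """Bias-kernel contribution ``b^2 * sum(alpha)`` to every prediction."""
        child, _ = self._linear_child()
        return float(child.bias**2 * self.gp.alpha.sum())

    def confound_weights(self) -> np.ndarray:
        """Primal weights on the (standardized) confound block (images_confounds)."""
        kernel = self.gp.kernel
        if self.spec.name != "images_confounds" or not isinstance(kernel, SumKernel):
            raise ValidationError("confound weights exist only for images_confounds")
        ard = kernel.children[1]
        sl = kernel.slices[1]
        Cblock = self.gp.X_train[:, sl]
        return (Cblock / ard.scales**2).T @ self.gp.alpha

    def balance(self, column: int = 0):
        """Balance report before/after weighting (instance_weighted only)."""
        if self.instance_weights is None:
            raise ValidationError("balance diagnostics require estimated instance weights")
        data = self.model.data
        return weighted_standardized_difference(
            data.y, data.C[:, column], self.instance_weights.w
        )

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        data = self.model.data
        lines = [
            "Confound-aware GP regression results",
            "=" * 44,
            f"strategy:          {self.spec.name}",
            f"n subjects:        {data.n}",
            f"n features:        {data.d_features}",
            f"n confounds:       {data.d_confounds}",
            f"log evidence:      {self.gp.log_evidence:.4f}",
            f"noise scale sigma: {self.gp.sigma:.6g}",
        ]
        for name, val in zip(self.gp.kernel.param_names,
                             np.exp(self.gp.kernel.theta)):
            lines.append(f"kernel {name}: {val:.6g}")
        if self.spec.rounding is not None:
            lines.append(f"rounding bounds:   {self.spec.rounding}")
        if self.instance_weights is not None:
            w = self.instance_weights.w
            lines.append(
                f"instance weights:  min {w.min():.3g}, max {w.max():.3g}, "
                f"max/min {w.max() / w.min():.3g}"
            )
            rep = self.balance()
            lines.append(
                f"std. difference:   {rep.std_diff_unweighted:+.3f} unweighted -> "
                f"{rep.std_diff_weighted:+.3f} weighted"
            )
        return "\n".join(lines)

    def __repr__(self):
        return (f"<ConfoundRegressionResults strategy={self.spec.name} "
                f"n={self.gp.n} logZ={self.gp.log_evidence:.2f}>")


# ---------------------------------------------------------------------------
# serialisation (arrays in an .npz, structure in an embedded JSON header)
# ---------------------------------------------------------------------------

def save_results(results: ConfoundRegressionResults, path):
    """Persist everything needed for prediction and weight maps."""
    gp = results.gp
    header = {
        "strategy": results.spec.name,
        "rounding": results.spec.rounding,
        "kernel": gp.kernel.to_dict(),
        "sigma": gp.sigma,
        "log_evidence": gp.log_evidence,
        "has_adjustment": results.adjustment is not None,
        "has_confound_stats": results.confound_stats is not None,
    }
    arrays = {
        "header": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        "X_train": gp.X_train,
        "y_train": gp.y_train,
        "alpha": gp.alpha,
        "L": gp.L,
        "feat_mean": results.feature_stats.mean,
        "feat_scale": results.feature_stats.scale,
    }
    if gp.weights is not None:
        arrays["gp_weights"] = gp.weights
    if results.adjustment is not None:
        arrays["adj_beta"] = results.adjustment.beta
        arrays["adj_subset"] = results.adjustment.fit_subset
    if results.confound_stats is not None:
        arrays["conf_mean"] = results.confound_stats.mean
        arrays["conf_scale"] = results.confound_stats.scale
    np.savez(path, **arrays)


def load_results(path) -> ConfoundRegressionResults:
    """Reload a saved fit for prediction (no training data re-attached)."""
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(bytes(z["header"].tobytes()).decode())
        kernel = kernel_from_dict(header["kernel"])
        weights = z["gp_weights"] if "gp_weights" in z.files else None
        gp = gp_from_params(kernel, z["X_train"], z["y_train"], header["sigma"],
                            weights=weights)
        adjustment = None
        if header["has_adjustment"]:
            adjustment = AdjustmentModel(beta=z["adj_beta"], fit_subset=z["adj_subset"])
        confound_stats = None
        if header["has_confound_stats"]:
            confound_stats = StandardizationStats(
                mean=z["conf_mean"], scale=z["conf_scale"]
            )
        feature_stats = StandardizationStats(mean=z["feat_mean"], scale=z["feat_scale"])
    rounding = None if header["rounding"] is None else tuple(header["rounding"])
    spec = StrategySpec(header["strategy"], rounding)
    return ConfoundRegressionResults(
        model=None, spec=spec, gp=gp, adjustment=adjustment,
        instance_weights=None, feature_stats=feature_stats,
        confound_stats=confound_stats,
    )
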