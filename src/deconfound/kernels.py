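"""Covariance functions for the GP models.

Three kernels cover every model in the framework:

* :class:`LinearBias` — ``k(x, x') = x.x' / l^2 + b^2``, the dot-product
  kernel over (standardized) image features whose posterior mean is a linear
  model of the features (kernel ridge regression in the dual),
* :class:`ARDLinear` — ``k(x, x') = sum_m x_m x'_m / l_m^2``, a linear kernel
  with one automatic-relevance-determination scale per input column, applied
  to confounds,
* :class:`BiasOnly` — ``k(x, x') = b^2``, input-independent; fitting a GP
  with this kernel and a Gaussian likelihood is essentially fitting a normal
  distribution to the marginal target density.

:class:`SumKernel` combines children over column blocks (e.g. linear-plus-bias
on the feature block plus ARD-linear on the appended confound block).  A
squared-exponential ARD kernel over one-hot encodings (:class:`SEARDOneHot`)
is provided for discrete confounds with more than two levels.

All scale hyperparameters are strictly positive and exposed in log space via
``theta`` so evidence maximisation is unconstrained.  Gradients returned with
``eval_gradient=True`` are with respect to the *log* hyperparameters.
"""

from __future__ import annotations

import copy
from abc import ABC, abstractmethod
from typing import List, Optional, Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "Kernel",
    "LinearBias",
    "ARDLinear",
    "BiasOnly",
    "SumKernel",
    "SEARDOneHot",
    "gram",
    "gram_gradients",
    "kernel_from_dict",
]


def _check_positive(value, name):
    value = float(value)
    if not np.isfinite(value) or value <= 0:
        raise ValidationError(f"kernel hyperparameter '{name}' must be positive, got {value!r}")
    return value


def _as2d(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


class Kernel(ABC):
    """Covariance function with log-space hyperparameter vector ``theta``."""

    param_names: Sequence[str]

    @property
    @abstractmethod
    def theta(self) -> np.ndarray:
        """Log hyperparameters, in ``param_names`` order."""

    @theta.setter
    @abstractmethod
    def theta(self, value):
        ...

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @abstractmethod
    def precompute(self, X, X2=None):
        """Hyperparameter-independent cache for repeated Gram evaluation."""

    @abstractmethod
    def eval_cache(self, cache, eval_gradient: bool = False):
        ...

    @abstractmethod
    def diag(self, X) -> np.ndarray:
        """``k(x_i, x_i)`` for each row of ``X``."""

    @abstractmethod
    def init_from_data(self, X, y) -> None:
        """Set data-driven initial hyperparameter values (see gp module)."""

    def __call__(self, X, X2=None, eval_gradient: bool = False):
        return self.eval_cache(self.precompute(X, X2), eval_gradient=eval_gradient)

    def clone(self) -> "Kernel":
        return copy.deepcopy(self)

    @abstractmethod
    def to_dict(self) -> dict:
        ...


def _pair(X, X2):
    X = _as2d(X)
    X2 = X if X2 is None else _as2d(X2)
    if X.shape[1] != X2.shape[1]:
        raise ValidationError(
            f"input dimensionality mismatch: {X.shape[1]} vs {X2.shape[1]} columns"
        )
    return X, X2


class LinearBias(Kernel):
    """Linear kernel plus bias: ``k = x.x'/l^2 + b^2``."""

    param_names = ("scale", "bias")

    def __init__(self, scale: float = 1.0, bias: float = 1.0):
        self.scale = _check_positive(scale, "scale")
        self.bias = _check_positive(bias, "bias")

    @property
    def theta(self):
        return np.log([self.scale, self.bias])

    @theta.setter
    def theta(self, value):
        self.scale, self.bias = np.exp(np.asarray(value, dtype=float))

    def precompute(self, X, X2=None):
        X, X2 = _pair(X, X2)
        return {"S": X @ X2.T}

    def eval_cache(self, cache, eval_gradient=False):
        S = cache["S"]
        K = S / self.scale**2 + self.bias**2
        if not eval_gradient:
            return K
        grads = [
            -2.0 * S / self.scale**2,                      # d/d log l
            np.full_like(S, 2.0 * self.bias**2),           # d/d log b
        ]
        return K, grads

    def diag(self, X):
        X = _as2d(X)
        return (X**2).sum(axis=1) / self.scale**2 + self.bias**2

    def init_from_data(self, X, y):
        X = _as2d(X)
        msn = float(np.sqrt(np.mean((X**2).sum(axis=1)))) if X.size else 0.0
        self.scale = msn if msn > 0 else 1.0
        sd = float(np.std(y)) if len(y) else 0.0
        self.bias = sd if sd > 0 else 1.0

    def to_dict(self):
        return {"kind": "linear_bias", "scale": self.scale, "bias": self.bias}


class ARDLinear(Kernel):
    """Linear ARD kernel: ``k = sum_m x_m x'_m / l_m^2`` (one scale per column)."""

    def __init__(self, scales):
        scales = np.atleast_1d(np.asarray(scales, dtype=float))
        for s in scales:
            _check_positive(s, "ard scale")
        self.scales = scales

    @property
    def param_names(self):
        return tuple(f"ard_scale_{m}" for m in range(len(self.scales)))

    @property
    def theta(self):
        return np.log(self.scales)

    @theta.setter
    def theta(self, value):
        self.scales = np.exp(np.asarray(value, dtype=float))

    def precompute(self, X, X2=None):
        X, X2 = _pair(X, X2)
        if X.shape[1] != len(self.scales):
            raise ValidationError(
                f"ARD kernel expects {len(self.scales)} columns, got {X.shape[1]}"
            )
        return {"X": X, "X2": X2}

    def eval_cache(self, cache, eval_gradient=False):
        X, X2 = cache["X"], cache["X2"]
        inv = 1.0 / self.scales**2
        K = (X * inv) @ X2.T
        if not eval_gradient:
            return K
        grads = [
            -2.0 * inv[m] * np.outer(X[:, m], X2[:, m]) for m in range(len(self.scales))
        ]
        return K, grads

    def diag(self, X):
        X = _as2d(X)
        return (X**2 / self.scales**2).sum(axis=1)

    def init_from_data(self, X, y):
        X = _as2d(X)
        rms = np.sqrt(np.mean(X**2, axis=0)) if X.shape[0] else np.ones(X.shape[1])
        self.scales = np.where(rms > 0, rms, 1.0)

    def to_dict(self):
        return {"kind": "ard_linear", "scales": self.scales.tolist()}


class BiasOnly(Kernel):
    """Constant kernel ``k = b^2``; ignores its inputs entirely."""

    param_names = ("bias",)

    def __init__(self, bias: float = 1.0):
        self.bias = _check_positive(bias, "bias")

    @property
    def theta(self):
        return np.log([self.bias])

    @theta.setter
    def theta(self, value):
        (self.bias,) = np.exp(np.asarray(value, dtype=float))

    def precompute(self, X, X2=None):
        X, X2 = _pair(X, X2)
        return {"shape": (X.shape[0], X2.shape[0])}

    def eval_cache(self, cache, eval_gradient=False):
        K = np.full(cache["shape"], self.bias**2)
        if not eval_gradient:
            return K
        return K, [np.full(cache["shape"], 2.0 * self.bias**2)]

    def diag(self, X):
        return np.full(_as2d(X).shape[0], self.bias**2)

    def init_from_data(self, X, y):
        sd = float(np.std(y)) if len(y) else 0.0
        self.bias = sd if sd > 0 else 1.0

    def to_dict(self):
        return {"kind": "bias_only", "bias": self.bias}


class SEARDOneHot(Kernel):
    """Squared-exponential ARD kernel, intended for one-hot encoded levels.

    ``k = exp(-1/2 sum_m (x_m - x'_m)^2 / l_m^2)``.  Offered for discrete
    confounds with more than two levels; not part of the evaluated model
    family.
    """

    def __init__(self, scales):
        scales = np.atleast_1d(np.asarray(scales, dtype=float))
        for s in scales:
            _check_positive(s, "se scale")
        self.scales = scales

    @property
    def param_names(self):
        return tuple(f"se_scale_{m}" for m in range(len(self.scales)))

    @property
    def theta(self):
        return np.log(self.scales)

    @theta.setter
    def theta(self, value):
        self.scales = np.exp(np.asarray(value, dtype=float))

    def precompute(self, X, X2=None):
        X, X2 = _pair(X, X2)
        if X.shape[1] != len(self.scales):
            raise ValidationError(
                f"SE-ARD kernel expects {len(self.scales)} columns, got {X.shape[1]}"
            )
        d2 = [
            (X[:, m][:, None] - X2[:, m][None, :]) ** 2 for m in range(X.shape[1])
        ]
        return {"d2": d2}

    def eval_cache(self, cache, eval_gradient=False):
        d2 = cache["d2"]
        expo = sum(d2[m] / self.scales[m] ** 2 for m in range(len(self.scales)))
        K = np.exp(-0.5 * expo)
        if not eval_gradient:
            return K
        grads = [K * (d2[m] / self.scales[m] ** 2) for m in range(len(self.scales))]
        return K, grads

    def diag(self, X):
        return np.ones(_as2d(X).shape[0])

    def init_from_data(self, X, y):
        self.scales = np.ones(len(self.scales))

    def to_dict(self):
        return {"kind": "se_ard_onehot", "scales": self.scales.tolist()}


class SumKernel(Kernel):
    """Sum of child kernels, each applied to a column block of the input.

    ``slices`` gives one column slice per child; ``None`` entries mean "all
    columns".  The hyperparameter vector is the concatenation of the
    children's, and gradients concatenate in the same order.
    """

    def __init__(self, children: List[Kernel], slices: Optional[Sequence] = None):
        if len(children) < 2:
            raise ValidationError("sum kernel requires at least two children")
        self.children = list(children)
        self.slices = list(slices) if slices is not None else [None] * len(children)
        if len(self.slices) != len(self.children):
            raise ValidationError("one slice per child kernel required")

    @property
    def param_names(self):
        names = []
        for i, child in enumerate(self.children):
            names.extend(f"k{i}.{p}" for p in child.param_names)
        return tuple(names)

    @property
    def theta(self):
        return np.concatenate([c.theta for c in self.children])

    @theta.setter
    def theta(self, value):
        value = np.asarray(value, dtype=float)
        pos = 0
        for child in self.children:
            k = child.n_params
            child.theta = value[pos:pos + k]
            pos += k

    def _block(self, X, sl):
        X = _as2d(X)
        return X if sl is None else X[:, sl]

    def precompute(self, X, X2=None):
        return [
            c.precompute(self._block(X, sl), None if X2 is None else self._block(X2, sl))
            for c, sl in zip(self.children, self.slices)
        ]

    def eval_cache(self, cache, eval_gradient=False):
        if not eval_gradient:
            return sum(c.eval_cache(cc) for c, cc in zip(self.children, cache))
        K = None
        grads = []
        for child, cc in zip(self.children, cache):
            Kc, gc = child.eval_cache(cc, eval_gradient=True)
            K = Kc if K is None else K + Kc
            grads.extend(gc)
        return K, grads

    def diag(self, X):
        return sum(c.diag(self._block(X, sl)) for c, sl in zip(self.children, self.slices))

    def init_from_data(self, X, y):
        for child, sl in zip(self.children, self.slices):
            child.init_from_data(self._block(X, sl), y)

    def to_dict(self):
        return {
            "kind": "sum",
            "children": [c.to_dict() for c in self.children],
            "slices": [
                None if sl is None else [sl.start, sl.stop] for sl in self.slices
            ],
        }


def gram(kernel: Kernel, X, X2=None) -> np.ndarray:
    """Gram matrix ``K[i, j] = k(x_i, x2_j)``."""
    return kernel(X, X2)


def gram_gradients(kernel: Kernel, X, X2=None):
    """Per-hyperparameter matrices ``dK / d(log h)``, in ``theta`` order."""
    _, grads = kernel(X, X2, eval_gradient=True)
    return grads


_KINDS = {
    "linear_bias": lambda d: LinearBias(d.get("scale", 1.0), d.get("bias", 1.0)),
    "ard_linear": lambda d: ARDLinear(d["scales"]),
    "bias_only": lambda d: BiasOnly(d.get("bias", 1.0)),
    "se_ard_onehot": lambda d: SEARDOneHot(d["scales"]),
}


def kernel_from_dict(spec: dict) -> Kernel:
    """Reconstruct a kernel from its ``to_dict`` serialisation."""
    kind = spec.get("kind")
    if kind == "sum":
        children = [kernel_from_dict(c) for c in spec["children"]]
        slices = [None if s is None else slice(s[0], s[1]) for s in spec["slices"]]
        return SumKernel(children, slices)
    if kind not in _KINDS:
        raise ValidationError(f"unknown kernel kind '{kind}'")
    return _KINDS[kind](spec)
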