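"""Biased-train / unbiased-test evaluation protocol.

The protocol takes a pool in which the target and a two-level confound are
independent (the "population of interest"), half-splits it into folds
``F_1, F_2``, draws ``J`` training samples ``B_j^k`` from each fold --
either *biased* (drawn non-uniformly so that the target and confound become
significantly associated) or *unbiased* (uniform draws) -- trains each
strategy on each sample, and predicts the opposite fold, which remains an
unbiased sample of the population.  Per-run metrics are averaged over the
``2 J`` runs.

Metrics
-------
* plain test MSE;
* group-balanced MSE: folds are partitioned at the pool median of the
  target into a low subset ``R_1`` (``y <= threshold``) and a high subset
  ``R_2``; within each subset the two group-specific MSEs are averaged with
  equal weight, and subsets are recombined weighted by their size;
* signed group-difference errors: per subset, MSE of group level 0 minus
  MSE of group level 1 -- a diagnostic of *which* stratum a model predicts
  better, not of accuracy -- summarised by the size-weighted mean of their
  absolute values.

Biased sampling
---------------
Selection probabilities follow an exponential tilt
``p_i ∝ exp(lambda * z(y_i) * c_tilde_i)`` with ``z`` the within-fold
standardized target and ``c_tilde in {-1, +1}`` the group sign; ``lambda=0``
recovers uniform sampling.  A draw is accepted when a two-sided equal-variance
two-sample t-test of the target across groups satisfies the acceptance rule
(``p < 0.05`` for biased draws, ``p >= 0.05`` for unbiased draws), redrawing
up to ``max_tries`` times.

A restricted permutation test assesses whether a model learns feature
information beyond the confound: targets are permuted only *within* confound
levels (within each fold), which preserves the confound-target association
while breaking any feature-target link, i.e. it tests conditional
independence of features and target given the confound.  The unpermuted
labelling is counted, so p-values are at least ``1 / n_perm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .data import Dataset
from .exceptions import MetricError, SamplingError, ValidationError
from .model import ConfoundRegression, StrategySpec

__all__ = [
    "DrawnSample",
    "SplitScheme",
    "TargetPartition",
    "StrategyReport",
    "ProtocolConfig",
    "ProtocolResult",
    "PermutationResult",
    "half_split",
    "draw_biased_sample",
    "mse",
    "partition_by_target",
    "balanced_mse",
    "signed_group_difference",
    "build_split_scheme",
    "run_protocol",
    "restricted_permutation_test",
]


# ---------------------------------------------------------------------------
# splitting and sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrawnSample:
    indices: np.ndarray          # absolute row indices into the pool
    p_value: float               # achieved group t-test p for the target
    lam: float
    direction: int
    n_tries: int


@dataclass(frozen=True)
class SplitScheme:
    folds: Tuple[np.ndarray, np.ndarray]
    samples: Dict[Tuple[int, int], DrawnSample] = field(default_factory=dict)


def half_split(n: int, rng) -> Tuple[np.ndarray, np.ndarray]:
    """Random disjoint halves of ``range(n)`` (sizes differ by <= 1)."""
    rng = np.random.default_rng(rng)
    perm = rng.permutation(n)
    half = n // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


def _group_pvalue(y, c) -> float:
    levels = np.unique(c)
    if levels.size != 2:
        return np.nan
    a, b = y[c == levels[0]], y[c == levels[1]]
    if len(a) < 2 or len(b) < 2:
        return np.nan
    return float(sstats.ttest_ind(a, b, equal_var=True).pvalue)


def draw_biased_sample(
    y,
    c,
    size: int,
    lam: float,
    *,
    direction: int = 1,
    accept_p: Optional[float] = 0.05,
    rng=None,
    max_tries: int = 500,
    ratio: Optional[float] = None,
    indices: Optional[np.ndarray] = None,
) -> DrawnSample:
    """Draw a without-replacement sample with an exponential selection tilt.

    ``direction=+1`` makes the higher confound level (level 1 in sorted
    order) preferentially sampled at high target values.  With ``lam != 0``
    the draw is accepted when the two-sided Student's t-test of the target
    across levels gives ``p < accept_p``; with ``lam == 0`` when
    ``p >= accept_p``.  ``accept_p=None`` accepts the first draw.  ``ratio``
    optionally fixes the level-0 : level-1 count ratio by drawing per-level
    counts (off by default).  ``indices`` maps positions to
    absolute pool rows in the returned sample.
    """
    rng = np.random.default_rng(rng)
    y = np.asarray(y, dtype=float).ravel()
    c = np.asarray(c).ravel()
    n = y.shape[0]
    if size >= n:
        raise ValidationError(f"sample size {size} must be below the fold size {n}")
    levels = np.unique(c)
    if levels.size != 2:
        raise ValidationError("biased sampling requires a two-level confound")
    c_sign = np.where(c == levels[0], -1.0, 1.0)
    sd = y.std()
    z = (y - y.mean()) / sd if sd > 0 else np.zeros_like(y)
    logits = lam * direction * z * c_sign
    probs = np.exp(logits - logits.max())
    probs = probs / probs.sum()
    indices = np.arange(n) if indices is None else np.asarray(indices)

    if ratio is not None:
        # stratified draw with fixed per-level counts matching the ratio
        n0 = int(round(size * ratio / (1.0 + ratio)))
        n0 = min(max(n0, 1), size - 1)
        lev_rows = [np.flatnonzero(c == lev) for lev in levels]
        counts = (n0, size - n0)
        if counts[0] > len(lev_rows[0]) or counts[1] > len(lev_rows[1]):
            raise SamplingError(
                f"fold cannot supply {counts} subjects per level for ratio {ratio}"
            )

    best_p, best = np.inf, None
    for attempt in range(1, max_tries + 1):
        if ratio is None:
            pick = rng.choice(n, size=size, replace=False, p=probs)
        else:
            parts = []
            for rows, cnt in zip(lev_rows, counts):
                pr = probs[rows] / probs[rows].sum()
                parts.append(rng.choice(rows, size=cnt, replace=False, p=pr))
            pick = np.concatenate(parts)
        p = _group_pvalue(y[pick], c[pick])
        if accept_p is None:
            ok = True
        elif lam == 0:
            ok = np.isfinite(p) and p >= accept_p
        else:
            ok = np.isfinite(p) and p < accept_p
        if ok:
            return DrawnSample(indices=np.sort(indices[pick]), p_value=p,
                               lam=lam, direction=direction, n_tries=attempt)
        crit = p if lam != 0 else (1 - p)
        if np.isfinite(crit) and crit < best_p:
            best_p, best = crit, p
    raise SamplingError(
        f"acceptance rule not met within {max_tries} draws "
        f"(best achieved p = {best})"
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def mse(y, yhat) -> float:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValidationError("y and yhat have different lengths")
    return float(np.mean((y - yhat) ** 2))


@dataclass(frozen=True)
class TargetPartition:
    """Low/high split of the target at a threshold (ties fall in the low set)."""

    threshold: float

    def masks(self, y) -> Tuple[np.ndarray, np.ndarray]:
        y = np.asarray(y, dtype=float).ravel()
        low = y <= self.threshold
        return low, ~low


def partition_by_target(pool_y, threshold: Optional[float] = None) -> TargetPartition:
    """Partition threshold from the *pool* median (not per fold)."""
    pool_y = np.asarray(pool_y, dtype=float).ravel()
    if np.unique(pool_y).size < 2:
        raise MetricError("all targets identical; target partition is degenerate")
    if threshold is None:
        threshold = float(np.median(pool_y))
    return TargetPartition(threshold=threshold)


def _subset_masks(y, partition: TargetPartition):
    low, high = partition.masks(y)
    if not low.any() or not high.any():
        raise MetricError(
            f"target partition at {partition.threshold} leaves an empty subset"
        )
    return low, high


def balanced_mse(y, yhat, group, partition: TargetPartition):
    """Group-balanced MSE per target subset and its size-weighted overall value.

    Within each subset the squared errors are averaged per group level and
    the two group means are averaged with weight 1/2 each, so the value is
    insensitive to group imbalance; subsets recombine weighted by
    ``n_subset / n_total``.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    group = np.asarray(group).ravel()
    levels = np.unique(group)
    if levels.size != 2:
        raise ValidationError("balanced MSE requires a two-level group variable")
    sq = (y - yhat) ** 2
    per_subset = []
    for l, mask in enumerate(_subset_masks(y, partition), start=1):
        vals = []
        for q, lev in enumerate(levels):
            cell = mask & (group == lev)
            if not cell.any():
                raise MetricError(f"empty cell: subset R_{l} x group level {lev}")
            vals.append(sq[cell].mean())
        per_subset.append(0.5 * (vals[0] + vals[1]))
    low, high = _subset_masks(y, partition)
    weights = np.array([low.sum(), high.sum()]) / len(y)
    overall = float(weights @ np.asarray(per_subset))
    return np.asarray(per_subset), overall


def signed_group_difference(y, yhat, group, partition: TargetPartition):
    """Signed per-subset difference of group MSEs and its absolute summary.

    Per subset: (MSE of group level 0) minus (MSE of group level 1); the
    summary is the subset-size-weighted mean of the absolute values, which
    prevents opposite-signed subsets cancelling.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    group = np.asarray(group).ravel()
    levels = np.unique(group)
    if levels.size != 2:
        raise ValidationError("group-difference errors require a two-level group")
    sq = (y - yhat) ** 2
    signed = []
    for l, mask in enumerate(_subset_masks(y, partition), start=1):
        cells = []
        for lev in levels:
            cell = mask & (group == lev)
            if not cell.any():
                raise MetricError(f"empty cell: subset R_{l} x group level {lev}")
            cells.append(sq[cell].mean())
        signed.append(cells[0] - cells[1])
    low, high = _subset_masks(y, partition)
    weights = np.array([low.sum(), high.sum()]) / len(y)
    summary = float(weights @ np.abs(signed))
    return np.asarray(signed), summary


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

@dataclass
class ProtocolConfig:
    """Sizes, bias specification and fitting options for one protocol run."""

    sample_size: int
    J: int = 4
    lam: float = 1.5
    direction: int = 1
    accept_p: Optional[float] = 0.05
    biased: bool = True
    max_tries: int = 500
    rounding: Optional[Tuple[int, int]] = None
    transductive_adjustment: bool = True
    ratio: Optional[float] = None
    check_population: bool = False
    fit_options: dict = field(default_factory=dict)
    weight_options: dict = field(default_factory=dict)


@dataclass(frozen=True)
class StrategyReport:
    """Per-run and averaged metrics for one strategy."""

    strategy: str
    per_run: pd.DataFrame
    mse: float
    balanced_mse: float
    group_difference_mse: float

    def summary(self) -> str:
        return (
            f"{self.strategy}: MSE={self.mse:.4f}  balanced MSE="
            f"{self.balanced_mse:.4f}  |group-difference| MSE="
            f"{self.group_difference_mse:.4f}  (over {len(self.per_run)} runs)"
        )


@dataclass(frozen=True)
class ProtocolResult:
    reports: Dict[str, StrategyReport]
    scheme: SplitScheme
    partition: TargetPartition

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for name, rep in self.reports.items():
            df = rep.per_run.copy()
            df.insert(0, "strategy", name)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def build_split_scheme(pool: Dataset, config: ProtocolConfig, seed) -> SplitScheme:
    """Half-split the pool and draw the ``2 J`` training samples."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    split_rng, draw_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    f1, f2 = half_split(pool.n, split_rng)
    samples = {}
    lam = config.lam if config.biased else 0.0
    for k, fold in enumerate((f1, f2), start=1):
        for j in range(1, config.J + 1):
            samples[(k, j)] = draw_biased_sample(
                pool.y[fold], pool.C[fold, 0], config.sample_size, lam,
                direction=config.direction, accept_p=config.accept_p,
                rng=draw_rng, max_tries=config.max_tries,
                ratio=config.ratio, indices=fold,
            )
    return SplitScheme(folds=(f1, f2), samples=samples)


def _run_one(pool, scheme, partition, spec: StrategySpec, config: ProtocolConfig):
    rows = []
    preds = {}
    for (k, j), sample in sorted(scheme.samples.items()):
        test_fold = scheme.folds[2 - k]  # predict the opposite fold
        train = pool.take(sample.indices)
        test = pool.take(test_fold)
        adjustment_data = None
        if spec.name == "adjusted_images" and config.transductive_adjustment:
            adjustment_data = (test.G, test.C)
        model = ConfoundRegression(
            train, spec, adjustment_data=adjustment_data,
            weight_options=config.weight_options,
        )
        results = model.fit(**config.fit_options)
        yhat = results.predict(test)
        preds[(k, j)] = yhat
        try:
            bal_subsets, bal = balanced_mse(test.y, yhat, test.C[:, 0], partition)
            signed, gd = signed_group_difference(test.y, yhat, test.C[:, 0], partition)
        except MetricError:
            # stratified metrics undefined for this fold (empty subset x group
            # cell); keep the run with NaNs rather than aborting plain MSE
            bal_subsets = signed = (np.nan, np.nan)
            bal = gd = np.nan
        rows.append({
            "k": k, "j": j, "n_train": train.n, "sample_p": sample.p_value,
            "mse": mse(test.y, yhat),
            "balanced_mse_low": bal_subsets[0], "balanced_mse_high": bal_subsets[1],
            "balanced_mse": bal,
            "signed_diff_low": signed[0], "signed_diff_high": signed[1],
            "group_difference_mse": gd,
        })
    per_run = pd.DataFrame(rows)
    report = StrategyReport(
        strategy=spec.name,
        per_run=per_run,
        mse=float(per_run["mse"].mean()),
        balanced_mse=float(per_run["balanced_mse"].mean(skipna=True)),
        group_difference_mse=float(per_run["group_difference_mse"].mean(skipna=True)),
    )
    return report, preds


def _as_specs(strategies, config) -> Sequence[StrategySpec]:
    specs = []
    for s in strategies:
        if isinstance(s, StrategySpec):
            specs.append(s if s.rounding is not None or config.rounding is None
                         else StrategySpec(s.name, config.rounding, s.standardize))
        else:
            specs.append(StrategySpec(str(s), config.rounding))
    return specs


def run_protocol(pool: Dataset, strategies, config: ProtocolConfig, seed=0,
                 scheme: Optional[SplitScheme] = None) -> ProtocolResult:
    """Full evaluation: split, draw samples, train every strategy, average metrics.

    A precomputed ``scheme`` may be supplied to evaluate further strategies
    on identical splits and draws.
    """
    if config.check_population:
        p = _group_pvalue(pool.y, pool.C[:, 0])
        if np.isfinite(p) and p < 0.05:
            raise ValidationError(
                f"pool shows a significant confound-target association (p={p:.4g}); "
                "not a valid population of interest"
            )
    if scheme is None:
        scheme = build_split_scheme(pool, config, seed)
    partition = partition_by_target(pool.y)
    reports = {}
    for spec in _as_specs(strategies, config):
        report, _ = _run_one(pool, scheme, partition, spec, config)
        reports[spec.name] = report
    return ProtocolResult(reports=reports, scheme=scheme, partition=partition)


# ---------------------------------------------------------------------------
# restricted permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    observed: Dict[str, float]
    permuted: pd.DataFrame
    p_values: Dict[str, float]
    n_perm: int


def _permute_within_levels(pool: Dataset, folds, rng) -> Dataset:
    """Permute targets within each confound level, separately per fold."""
    y_new = pool.y.copy()
    for fold in folds:
        c = pool.C[fold, 0]
        for lev in np.unique(c):
            rows = fold[c == lev]
            y_new[rows] = y_new[rng.permutation(rows)]
    return pool.with_target(y_new)


def restricted_permutation_test(
    pool: Dataset,
    strategy,
    config: ProtocolConfig,
    n_perm: int = 500,
    seed=0,
    metrics: Sequence[str] = ("mse", "balanced_mse"),
) -> PermutationResult:
    """Permutation test of predictive information beyond the confound.

    The split and the training draws are built once; each of the
    ``n_perm - 1`` non-identity permutations shuffles the targets within
    confound level (within each fold), re-trains on the same subject indices
    and recomputes the averaged metrics.  For each metric the p-value is the
    fraction of permutations (the identity included) with a value less than
    or equal to the observed one.
    """
    if n_perm < 2:
        raise ValidationError("n_perm must be at least 2")
    ss = np.random.SeedSequence(seed)
    scheme_seed, perm_seed = ss.spawn(2)
    scheme = build_split_scheme(pool, config, scheme_seed)
    partition = partition_by_target(pool.y)
    (spec,) = _as_specs([strategy], config)

    obs_report, _ = _run_one(pool, scheme, partition, spec, config)
    observed = {m: getattr(obs_report, m) for m in metrics}

    rng = np.random.default_rng(perm_seed)
    rows = []
    for _ in range(n_perm - 1):
        permuted_pool = _permute_within_levels(pool, scheme.folds, rng)
        rep, _ = _run_one(permuted_pool, scheme, partition, spec, config)
        rows.append({m: getattr(rep, m) for m in metrics})
    permuted = pd.DataFrame(rows)
    p_values = {
        m: (1 + int((permuted[m] <= observed[m]).sum())) / n_perm for m in metrics
    }
    return PermutationResult(observed=observed, permuted=permuted,
                             p_values=p_values, n_perm=n_perm)
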