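"""Subject-level data containers and I/O.

The central container is :class:`Dataset`, holding a subjects-by-features
matrix ``G`` (e.g. voxelwise grey-matter values flattened under a mask),
a subjects-by-confounds matrix ``C`` (continuous, or two-level discrete
encoded as a single {0, 1} column) and a target vector ``y`` (e.g. a
clinical score or age).  All downstream modules consume this container.

Supported feature sources:

* a delimited table (header row of feature names, one row per subject,
  plus a subject-identifier column),
* a column-major float64 binary matrix with a JSON sidecar header,
* a list of NIfTI volumes flattened under a binary NIfTI mask, in mask
  scan order (C order of the mask array).

Metadata (targets + confounds) always comes from a delimited table with a
header and a subject-identifier column.  Missing values are rejected, not
imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ValidationError

__all__ = [
    "Dataset",
    "StandardizationStats",
    "load_dataset",
    "write_dataset",
    "standardize",
    "augment_confounds",
    "read_features_table",
    "write_features_table",
    "read_features_binary",
    "write_features_binary",
    "flatten_masked_volumes",
]

# Columns whose training-set standard deviation falls below this are treated
# as constant and mapped to all-zero columns (kept, not dropped, so feature
# indexing stays stable for weight-map extraction).
_SD_TOL = 1e-12


@dataclass(frozen=True)
class Dataset:
    """Aligned subject-level data: features ``G``, confounds ``C``, target ``y``.

    Invariants enforced at construction: equal row counts, no missing or
    non-finite values, and two-level discrete confounds encoded in a single
    column (any number of continuous confound columns is allowed).
    """

    G: np.ndarray
    C: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray = None
    feature_names: Sequence[str] = None
    confound_names: Sequence[str] = None

    def __post_init__(self):
        G = np.atleast_2d(np.asarray(self.G, dtype=float))
        y = np.asarray(self.y, dtype=float).ravel()
        C = np.asarray(self.C, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.size == 0:
            C = C.reshape(len(y), 0)
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "y", y)
        n = G.shape[0]
        if not (C.shape[0] == n and y.shape[0] == n):
            raise ValidationError(
                f"row counts differ: G has {n}, C has {C.shape[0]}, y has {y.shape[0]}"
            )
        ids = self.subject_ids
        if ids is None:
            ids = np.array([f"s{i:05d}" for i in range(n)])
        else:
            ids = np.asarray(ids).astype(str)
            if ids.shape[0] != n:
                raise ValidationError("subject_ids length does not match G")
        object.__setattr__(self, "subject_ids", ids)
        for name, arr in (("G", G), ("C", C), ("y", y)):
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains missing or non-finite values")
        fnames = self.feature_names
        if fnames is None:
            fnames = [f"f{j:05d}" for j in range(G.shape[1])]
        if len(fnames) != G.shape[1]:
            raise ValidationError("feature_names length does not match G")
        object.__setattr__(self, "feature_names", list(map(str, fnames)))
        cnames = self.confound_names
        if cnames is None:
            cnames = [f"c{j}" for j in range(C.shape[1])]
        if len(cnames) != C.shape[1]:
            raise ValidationError("confound_names length does not match C")
        object.__setattr__(self, "confound_names", list(map(str, cnames)))

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def d_features(self) -> int:
        return self.G.shape[1]

    @property
    def d_confounds(self) -> int:
        return self.C.shape[1]

    def __len__(self) -> int:
        return self.n

    # -- derived views ---------------------------------------------------
    def take(self, indices) -> "Dataset":
        """Row subset (copy) preserving order of ``indices``."""
        idx = np.asarray(indices)
        return Dataset(
            G=self.G[idx],
            C=self.C[idx],
            y=self.y[idx],
            subject_ids=self.subject_ids[idx],
            feature_names=self.feature_names,
            confound_names=self.confound_names,
        )

    def with_target(self, y_new: np.ndarray) -> "Dataset":
        """Same subjects/features with a replacement target vector."""
        return replace(self, y=np.asarray(y_new, dtype=float))

    def confound_levels(self, column: int = 0) -> np.ndarray:
        """Sorted distinct values of a confound column; errors unless exactly two."""
        levels = np.unique(self.C[:, column])
        if levels.size != 2:
            raise ValidationError(
                f"confound column {column} has {levels.size} distinct values; "
                "expected a two-level discrete confound"
            )
        return levels


@dataclass(frozen=True)
class StandardizationStats:
    """Per-feature mean/sd computed on a designated training set.

    ``ddof`` records the variance convention (sample, n-1, by default).
    Constant training columns carry ``scale == 0`` and are mapped to zero.
    """

    mean: np.ndarray
    scale: np.ndarray
    ddof: int = 1

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean.shape[0]:
            raise ValidationError(
                f"feature count {X.shape[1]} does not match stats ({self.mean.shape[0]})"
            )
        safe = np.where(self.scale > _SD_TOL, self.scale, 1.0)
        out = (X - self.mean) / safe
        out[:, self.scale <= _SD_TOL] = 0.0
        return out


def standardize(
    train_G: np.ndarray,
    other_G: Optional[np.ndarray] = None,
    ddof: int = 1,
):
    """Zero-mean/unit-variance scaling with statistics from the training set only.

    Returns ``(train_std, other_std, stats)``; ``other_std`` is None when no
    second matrix is given.  Sample (n-1) variance is used; constant training
    columns map to all-zero columns in both outputs.
    """
    train_G = np.atleast_2d(np.asarray(train_G, dtype=float))
    if train_G.shape[0] == 0:
        raise ValidationError("training matrix is empty")
    mean = train_G.mean(axis=0)
    sd = train_G.std(axis=0, ddof=ddof) if train_G.shape[0] > ddof else np.zeros(train_G.shape[1])
    stats = StandardizationStats(mean=mean, scale=sd, ddof=ddof)
    train_s = stats.transform(train_G)
    other_s = None
    if other_G is not None:
        other_G = np.atleast_2d(np.asarray(other_G, dtype=float))
        if other_G.shape[1] != train_G.shape[1]:
            raise ValidationError(
                f"feature count mismatch: train has {train_G.shape[1]}, other has {other_G.shape[1]}"
            )
        other_s = stats.transform(other_G)
    return train_s, other_s, stats


def augment_confounds(C: np.ndarray, idempotent: bool = False) -> np.ndarray:
    """Prepend an all-ones intercept column to the confound matrix.

    A matrix that already contains a constant column is rejected (double
    augmentation would make the design singular); with ``idempotent=True`` a
    matrix whose first column is all ones is returned unchanged instead.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n = C.shape[0]
    if C.shape[1] > 0:
        constant = np.ptp(C, axis=0) == 0
        if constant.any():
            if idempotent and np.allclose(C[:, 0], 1.0):
                return C.copy()
            raise ValidationError(
                "confound matrix already contains a constant column "
                f"(columns {np.flatnonzero(constant).tolist()}); refusing to augment"
            )
    return np.column_stack([np.ones(n), C])


# ---------------------------------------------------------------------------
# feature-matrix formats
# ---------------------------------------------------------------------------

def read_features_table(path, subject_col: str = "subject_id") -> pd.DataFrame:
    """Delimited feature table -> DataFrame indexed by subject id."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if subject_col not in df.columns:
        raise ValidationError(f"{path} has no subject column '{subject_col}'")
    return df.set_index(df[subject_col].astype(str)).drop(columns=[subject_col])


def write_features_table(path, matrix, subject_ids, feature_names, subject_col="subject_id"):
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(np.asarray(matrix, dtype=float), columns=list(feature_names))
    df.insert(0, subject_col, np.asarray(subject_ids).astype(str))
    df.to_csv(path, sep=sep, index=False)


def write_features_binary(path, matrix, subject_ids, feature_names):
    """Raw column-major float64 matrix + JSON sidecar; round-trips bit-exactly."""
    path = Path(path)
    matrix = np.asarray(matrix, dtype="<f8")
    with open(path, "wb") as fh:
        fh.write(np.asfortranarray(matrix).tobytes(order="F"))
    sidecar = {
        "n": int(matrix.shape[0]),
        "d": int(matrix.shape[1]),
        "dtype": "<f8",
        "order": "F",
        "subject_ids": [str(s) for s in subject_ids],
        "feature_names": [str(f) for f in feature_names],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_features_binary(path) -> pd.DataFrame:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    raw = np.fromfile(path, dtype=sidecar["dtype"])
    mat = raw.reshape((sidecar["n"], sidecar["d"]), order=sidecar["order"])
    return pd.DataFrame(mat, index=sidecar["subject_ids"], columns=sidecar["feature_names"])


def flatten_masked_volumes(volume_paths, mask_path) -> pd.DataFrame:
    """Flatten NIfTI volumes under a binary NIfTI mask.

    Voxels are taken in mask scan order (C order of the mask array); feature
    names are ``vox<flat-index>``.  Subject ids come from the file stems.
    """
    import nibabel as nib

    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    flat_idx = np.flatnonzero(mask.ravel(order="C"))
    rows, ids = [], []
    for p in volume_paths:
        p = Path(p)
        img = nib.load(str(p))
        vol = np.asarray(img.dataobj, dtype=float)
        if vol.shape != mask.shape:
            raise ValidationError(
                f"volume {p.name} shape {vol.shape} does not match mask shape {mask.shape}"
            )
        rows.append(vol.ravel(order="C")[flat_idx])
        ids.append(p.name.split(".")[0])
    return pd.DataFrame(np.asarray(rows), index=ids, columns=[f"vox{i}" for i in flat_idx])


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

FeatureSource = Union[str, Path, pd.DataFrame, tuple]


def _load_features(source, subject_col) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    if isinstance(source, tuple) and len(source) == 2:
        return flatten_masked_volumes(*source)
    path = Path(source)
    if path.suffix.lower() == ".bin":
        return read_features_binary(path)
    return read_features_table(path, subject_col=subject_col)


def load_dataset(
    features_source: FeatureSource,
    meta_source,
    target_name: str,
    confound_names: Sequence[str],
    subject_col: str = "subject_id",
) -> Dataset:
    """Assemble a validated :class:`Dataset` from feature and metadata sources.

    Row order follows the feature source; the metadata table is aligned to it
    by subject identifier.  A subject present in one source but not the other
    raises :class:`AlignmentError`; missing values raise
    :class:`ValidationError`.
    """
    feats = _load_features(features_source, subject_col)
    if isinstance(meta_source, pd.DataFrame):
        meta = meta_source.copy()
    else:
        path = Path(meta_source)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        meta = pd.read_csv(path, sep=sep)
    if subject_col not in meta.columns:
        raise ValidationError(f"metadata has no subject column '{subject_col}'")
    meta = meta.set_index(meta[subject_col].astype(str))
    feats.index = feats.index.astype(str)

    missing = [s for s in feats.index if s not in meta.index]
    extra = [s for s in meta.index if s not in feats.index]
    if missing or extra:
        raise AlignmentError(
            f"subject sets differ: {len(missing)} subjects missing from metadata "
            f"(e.g. {missing[:3]}), {len(extra)} extra in metadata (e.g. {extra[:3]})"
        )
    meta = meta.loc[feats.index]

    for col in [target_name, *confound_names]:
        if col not in meta.columns:
            raise ValidationError(f"metadata has no column '{col}'")
    if feats.isna().any().any() or meta[[target_name, *confound_names]].isna().any().any():
        raise ValidationError("input contains missing values")

    return Dataset(
        G=feats.to_numpy(dtype=float),
        C=meta[list(confound_names)].to_numpy(dtype=float),
        y=meta[target_name].to_numpy(dtype=float),
        subject_ids=feats.index.to_numpy(),
        feature_names=list(feats.columns),
        confound_names=list(confound_names),
    )


def write_dataset(
    dataset: Dataset,
    directory,
    fmt: str = "csv",
    target_name: str = "y",
    subject_col: str = "subject_id",
):
    """Write features + metadata tables; returns (features_path, meta_path)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        fpath = directory / "features.csv"
        write_features_table(fpath, dataset.G, dataset.subject_ids, dataset.feature_names,
                             subject_col=subject_col)
    elif fmt == "bin":
        fpath = directory / "features.bin"
        write_features_binary(fpath, dataset.G, dataset.subject_ids, dataset.feature_names)
    else:
        raise ValueError(f"unknown feature format '{fmt}'")
    meta = pd.DataFrame({subject_col: dataset.subject_ids})
    for j, name in enumerate(dataset.confound_names):
        meta[name] = dataset.C[:, j]
    meta[target_name] = dataset.y
    mpath = directory / "meta.csv"
    meta.to_csv(mpath, index=False)
    return fpath, mpath
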