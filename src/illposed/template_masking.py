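"""Template thresholding, vectorization and voxel-wise standardization.

Turns cohorts of volumes into the ``(X, y)`` matrices the classifiers
consume: threshold a probability template into a binary mask, extract
masked voxels into an ``n x d`` matrix (lexicographic voxel order), and
standardize each voxel column using training-set statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_cohort import GMVolume, ProbabilityTemplate, VolumeGrid

__all__ = [
    "BinaryMask",
    "FeatureMatrix",
    "LabelVector",
    "StandardizationParams",
    "threshold_mask",
    "vectorize",
    "fit_standardizer",
    "apply_standardizer",
    "invert_standardizer",
]

LABEL_CODES = {"CN": 0, "AD": 1}


class EmptyMaskError(ValueError):
    pass


@dataclass(frozen=True)
class BinaryMask:
    grid: VolumeGrid
    flags: np.ndarray  # 3D booleans
    voxel_index_map: np.ndarray  # (d, 3) int coords, lexicographic

    @property
    def voxel_count(self) -> int:
        return len(self.voxel_index_map)

    def contains(self, other: "BinaryMask") -> bool:
        return bool(np.all(self.flags[other.flags]))


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (n, d)
    subject_ids: list[str]
    mask_ref: BinaryMask | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class LabelVector:
    labels: np.ndarray  # values in {0, 1}; 0 = CN, 1 = AD

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if not np.isin(lab, (0, 1)).all():
            raise ValueError("labels must be 0 (CN) or 1 (AD)")
        object.__setattr__(self, "labels", lab)

    def require_both_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present")


@dataclass(frozen=True)
class StandardizationParams:
    mean: np.ndarray  # (d,)
    sd: np.ndarray  # (d,) — 1.0 substituted where the column was constant
    constant_columns: np.ndarray  # (d,) bool flags


def threshold_mask(template: ProbabilityTemplate, t: float) -> BinaryMask:
    """Binary mask of voxels whose template probability exceeds ``t``.

    Voxel order is fixed lexicographic by (x, y, z) coordinate so that
    feature columns align deterministically across calls.
    """
    flags = template.values > t
    coords = np.argwhere(flags)  # argwhere is already lexicographic
    if coords.size == 0:
        raise EmptyMaskError(f"threshold {t} yields an empty mask")
    return BinaryMask(grid=template.grid, flags=flags, voxel_index_map=coords)


def vectorize(cohort: list[GMVolume], mask: BinaryMask) -> tuple[FeatureMatrix, LabelVector]:
    """Extract masked voxels of each subject into rows of an ``n x d`` matrix."""
    idx = tuple(mask.voxel_index_map.T)
    rows, ids, labels = [], [], []
    for vol in cohort:
        if vol.grid != mask.grid:
            raise ValueError(f"subject {vol.subject_id} grid does not match mask grid")
        rows.append(vol.values[idx])
        ids.append(vol.subject_id)
        labels.append(LABEL_CODES[vol.label])
    X = FeatureMatrix(values=np.asarray(rows), subject_ids=ids, mask_ref=mask)
    return X, LabelVector(labels=np.asarray(labels))


def fit_standardizer(X_train: FeatureMatrix | np.ndarray) -> StandardizationParams:
    """Per-voxel mean and sample (n-1) standard deviation over training rows.

    Constant columns are flagged; their sd is replaced by 1 so that
    applying the standardizer maps them to all-zeros instead of NaN.
    """
    V = X_train.values if isinstance(X_train, FeatureMatrix) else np.asarray(X_train, float)
    if V.shape[0] < 2:
        raise ValueError("standardizer needs at least 2 training rows")
    mean = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1)
    # rounding in the mean can leave a ~eps-sized sd on a constant column
    tol = 100 * np.finfo(V.dtype).eps * np.maximum(np.abs(mean), 1.0)
    constant = sd <= tol
    sd = np.where(constant, 1.0, sd)
    return StandardizationParams(mean=mean, sd=sd, constant_columns=constant)


def apply_standardizer(params: StandardizationParams, X: FeatureMatrix | np.ndarray) -> FeatureMatrix:
    if isinstance(X, FeatureMatrix):
        V, ids, mask = X.values, X.subject_ids, X.mask_ref
    else:
        V = np.asarray(X, float)
        ids, mask = [f"row-{i}" for i in range(V.shape[0])], None
    if V.shape[1] != params.mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: X has {V.shape[1]} columns, params expect {params.mean.shape[0]}"
        )
    Z = (V - params.mean) / params.sd
    Z[:, params.constant_columns] = 0.0
    return FeatureMatrix(values=Z, subject_ids=list(ids), mask_ref=mask, standardized=True)


def invert_standardizer(params: StandardizationParams, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Undo :func:`apply_standardizer` (constant columns return their mean)."""
    Z = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    return Z * params.sd + params.mean


def save_mask(mask: BinaryMask, path) -> None:
    """Write a mask as a binary NIfTI volume."""
    import nibabel as nib

    img = nib.Nifti1Image(mask.flags.astype("uint8"), mask.grid.affine)
    nib.save(img, str(path))
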