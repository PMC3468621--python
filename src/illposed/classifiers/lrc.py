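"""Linear regression classifier in dual form.

Labels are regressed on features by least squares; the minimum-norm
solution is obtained through the Moore-Penrose pseudo-inverse of the
linear kernel matrix: ``a = K^+ y`` with primal weights ``w = X^T a``.
Singular values below ``n * eps * sigma_max`` are filtered out, so the
fit is defined (and stable) even when ``K`` is rank deficient.

There is no intercept and no tuned hyperparameter; standardized features
make the missing intercept benign.  The decision threshold is 0.5 on the
{0, 1} label scale, ties going to class 1 (AD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..kernel_conditioning import LinearKernel, cross_kernel
from ..template_masking import FeatureMatrix, LabelVector

__all__ = ["LRCModel", "fit_lrc", "predict_lrc"]


@dataclass
class LRCModel:
    dual_coefficients: np.ndarray  # a = K^+ y, length n
    training_features: np.ndarray  # (n, d); needed to expand w = X^T a
    decision_threshold: float = 0.5
    trained_on_standardized: bool = True
    primal_weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.primal_weights = self.training_features.T @ self.dual_coefficients


def _as_array(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)


def fit_lrc(
    K: LinearKernel | np.ndarray,
    y: LabelVector | np.ndarray,
    X_train: FeatureMatrix | np.ndarray,
    rcond: float | None = None,
) -> LRCModel:
    """Fit ``a = K^+ y`` with a documented singular-value cutoff.

    ``rcond`` is the relative cutoff passed to the pseudo-inverse;
    defaults to ``n * machine eps``.  When ``K`` is invertible the fit
    interpolates the training labels exactly (``K a = y``).
    """
    Km = K.K if isinstance(K, LinearKernel) else np.asarray(K, float)
    yv = y.labels if isinstance(y, LabelVector) else np.asarray(y, float)
    Xv = _as_array(X_train)
    n = Km.shape[0]
    if yv.shape[0] != n or Xv.shape[0] != n:
        raise ValueError("K, y and X_train must agree on the number of subjects")
    if rcond is None:
        rcond = n * np.finfo(float).eps
    a = np.linalg.pinv(Km, rcond=rcond, hermitian=True) @ yv.astype(float)
    standardized = X_train.standardized if isinstance(X_train, FeatureMatrix) else True
    return LRCModel(
        dual_coefficients=a,
        training_features=Xv,
        trained_on_standardized=standardized,
    )


def predict_lrc(
    model: LRCModel,
    X_new: FeatureMatrix | np.ndarray,
    path: str = "primal",
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted {0, 1} labels and decision values ``f(x) = <x, w>``.

    ``path`` selects the equivalent primal (``<x, X^T a>``) or dual
    (``<k(x, .), a>``) evaluation route; both agree to rounding error.
    """
    Xv = _as_array(X_new)
    if isinstance(X_new, FeatureMatrix) and model.trained_on_standardized and not X_new.standardized:
        warnings.warn("model was trained on standardized features but input is not standardized")
    if Xv.shape[1] != model.training_features.shape[1]:
        raise ValueError("feature dimension mismatch with training data")
    if path == "primal":
        f = Xv @ model.primal_weights
    elif path == "dual":
        f = cross_kernel(Xv, model.training_features) @ model.dual_coefficients
    else:
        raise ValueError(f"unknown path {path!r}")
    labels = (f >= model.decision_threshold).astype(int)  # tie -> class 1
    return labels, f
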