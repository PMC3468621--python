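"""PCA-space counterparts of the classifiers (incremental selection).

Training features (already standardized) are projected onto principal
components; each classifier is refitted on the leading ``m`` score
columns for ``m = 1..M`` and scored on the projected test set, the
maximum over ``m`` being the reported PC-space accuracy.  Selecting the
component count on the test set mirrors the original design and is
optimistic; a CV-based selector is available as a non-default option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_selection import fit_predict_method
from .template_masking import FeatureMatrix

__all__ = [
    "PCAProjection",
    "ComponentSelectionTrace",
    "pca_fit",
    "pca_transform",
    "incremental_component_accuracy",
]


@dataclass(frozen=True)
class PCAProjection:
    component_loadings: np.ndarray  # (d, m), orthonormal columns
    training_scores: np.ndarray  # (n, m)
    explained_variance: np.ndarray  # (m,), descending
    center: np.ndarray  # (d,) training column means


@dataclass(frozen=True)
class ComponentSelectionTrace:
    accuracies: np.ndarray  # accuracy per component count 1..M
    component_counts: np.ndarray
    best_count: int
    best_accuracy: float


def pca_fit(X: FeatureMatrix | np.ndarray, var_tol: float = 1e-12) -> PCAProjection:
    """Principal components of the training covariance, variance-sorted.

    Components with negligible variance (below ``var_tol`` times the
    leading one) are dropped, leaving at most ``n - 1`` columns.  Sign
    convention: the largest-magnitude loading of each component is made
    positive, so the decomposition is deterministic.
    """
    V = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    n = V.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    center = V.mean(axis=0)
    Xc = V - center
    # SVD of the centered data is cheaper than the d x d covariance here
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    keep = var > var_tol * max(var[0], 1e-300)
    keep &= np.arange(len(s)) < n - 1
    U, s, Vt, var = U[:, keep], s[keep], Vt[keep], var[keep]
    # deterministic signs
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    return PCAProjection(
        component_loadings=Vt.T,
        training_scores=U * s,
        explained_variance=var,
        center=center,
    )


def pca_transform(projection: PCAProjection, X_new: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Project new (identically standardized) data onto the components."""
    V = X_new.values if isinstance(X_new, FeatureMatrix) else np.asarray(X_new, float)
    if V.shape[1] != projection.component_loadings.shape[0]:
        raise ValueError("feature dimension mismatch with the fitted projection")
    return (V - projection.center) @ projection.component_loadings


def incremental_component_accuracy(
    scores_train: np.ndarray,
    y_train: np.ndarray,
    scores_test: np.ndarray,
    y_test: np.ndarray,
    method: str,
    component_counts: np.ndarray | None = None,
    **method_kwargs,
) -> ComponentSelectionTrace:
    """Accuracy as components are added one at a time; best kept.

    ``component_counts`` defaults to ``1..M``; a coarser ladder may be
    passed to bound compute at desk scale.
    """
    scores_train = np.asarray(scores_train, float)
    scores_test = np.asarray(scores_test, float)
    M = scores_train.shape[1]
    if M == 0:
        raise ValueError("no components to select from")
    if component_counts is None:
        component_counts = np.arange(1, M + 1)
    component_counts = np.asarray(component_counts, int)
    if component_counts.size == 0 or component_counts.min() < 1 or component_counts.max() > M:
        raise ValueError("invalid component ladder")

    accs = np.empty(len(component_counts))
    for i, m in enumerate(component_counts):
        out = fit_predict_method(
            method,
            scores_train[:, :m],
            y_train,
            scores_test[:, :m],
            y_test,
            standardize=False,
            **method_kwargs,
        )
        accs[i] = out.accuracy
    best = int(np.argmax(accs))
    return ComponentSelectionTrace(
        accuracies=accs,
        component_counts=component_counts,
        best_count=int(component_counts[best]),
        best_accuracy=float(accs[best]),
    )
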