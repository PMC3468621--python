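"""Soft/hard-margin linear SVM on a precomputed kernel.

The dual soft-margin problem with box constraint ``C`` is solved by the
LIBSVM SMO solver (via scikit-learn) on a precomputed Gram matrix; the
model is kept in dual form (signed coefficients ``y_i * alpha_i`` and
bias).  Hard margin is not a separate formulation: it is the soft margin
with ``C = 1e6``.  KKT satisfaction is a contract, checkable through
:func:`kkt_residual_svm`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from ..kernel_conditioning import LinearKernel
from ..template_masking import FeatureMatrix, LabelVector
from .labels import to_pm1

__all__ = ["SVMModel", "HARD_MARGIN_C", "fit_svm", "predict_svm", "kkt_residual_svm", "primal_weights"]

HARD_MARGIN_C = 1e6

_PSD_TOL = 1e-8


@dataclass
class SVMModel:
    dual_coefficients: np.ndarray  # signed, length n: y_i * alpha_i, |.| <= C
    bias: float
    C: float
    mode: str  # "soft" | "hard"
    y_train_pm1: np.ndarray


def _kernel_array(K) -> np.ndarray:
    return K.K if isinstance(K, LinearKernel) else np.asarray(K, float)


def _labels_pm1(y) -> np.ndarray:
    yv = y.labels if isinstance(y, LabelVector) else np.asarray(y)
    if np.isin(yv, (0, 1)).all():
        return to_pm1(yv)
    if np.isin(yv, (-1, 1)).all():
        return yv.astype(int)
    raise ValueError("labels must be coded {0,1} or {-1,+1}")


def fit_svm(
    K: LinearKernel | np.ndarray,
    y: LabelVector | np.ndarray,
    C: float = 1.0,
    mode: str = "soft",
    tol: float = 1e-10,
    max_iter: int = -1,
    check_psd: bool = True,
) -> SVMModel:
    """Solve the box-constrained soft-margin dual on a precomputed kernel.

    ``mode='hard'`` overrides ``C`` with ``1e6``.  The kernel must be
    PSD within tolerance; a substantially negative eigenvalue is an
    error rather than something to silently clip (``check_psd=False``
    skips the eigenvalue check when the kernel is PSD by construction).
    ``max_iter`` caps SMO iterations — rank-deficient kernels at large C
    can otherwise spin for hundreds of millions of steps.
    """
    Km = _kernel_array(K)
    ypm = _labels_pm1(y)
    if mode == "hard":
        C = HARD_MARGIN_C
    elif mode != "soft":
        raise ValueError(f"mode must be 'soft' or 'hard', got {mode!r}")
    if C <= 0:
        raise ValueError("C must be positive")
    if check_psd:
        eigmin = float(np.linalg.eigvalsh(Km).min())
        scale = max(float(np.abs(Km).max()), 1.0)
        if eigmin < -_PSD_TOL * scale:
            raise ValueError(f"kernel is not PSD: min eigenvalue {eigmin:.3e}")

    svc = SVC(
        kernel="precomputed", C=C, tol=tol, shrinking=False, cache_size=64,
        max_iter=max_iter,
    )
    with warnings.catch_warnings():
        if max_iter > 0:  # hitting the cap is expected and handled
            warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(Km, ypm)
    n = Km.shape[0]
    dual = np.zeros(n)
    dual[svc.support_] = svc.dual_coef_[0]  # already signed y_i alpha_i
    dual, bias = _polish_kkt(Km, ypm, dual, float(svc.intercept_[0]), C)
    return SVMModel(
        dual_coefficients=dual,
        bias=bias,
        C=C,
        mode=mode,
        y_train_pm1=ypm,
    )


def _polish_kkt(
    Km: np.ndarray, ypm: np.ndarray, dual: np.ndarray, bias: float, C: float
) -> tuple[np.ndarray, float]:
    """Refine the SMO solution to machine-precision KKT satisfaction.

    Margin equalities ``y_i f_i = 1`` on the free support vectors plus
    the equality constraint form a linear system in the free signed
    duals and the bias; solving it removes the solver's O(tol) residual.
    Reverts to the unpolished solution if the refit leaves the box.
    """
    alpha = ypm * dual
    slack = 1e-7 * C
    free = (alpha > slack) & (alpha < C - slack)
    if not free.any():
        return dual, bias
    at_C = alpha >= C - slack
    u_B = np.where(at_C, ypm * C, 0.0)
    nF = int(free.sum())
    A = np.zeros((nF + 1, nF + 1))
    A[:nF, :nF] = Km[np.ix_(free, free)]
    A[:nF, nF] = 1.0
    A[nF, :nF] = 1.0
    rhs = np.empty(nF + 1)
    rhs[:nF] = ypm[free] - Km[free] @ u_B
    rhs[nF] = -u_B.sum()
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    u_F, b = sol[:nF], float(sol[nF])
    alpha_F = ypm[free] * u_F
    if alpha_F.min() < -1e-3 * C or alpha_F.max() > C * (1 + 1e-3):
        return dual, bias
    new_dual = u_B.copy()
    new_dual[free] = u_F
    return new_dual, b


def decision_values(model: SVMModel, K_cross: np.ndarray) -> np.ndarray:
    """``f(x) = sum_i dual_i K(x, x_i) + b`` for rows of ``K_cross``."""
    K_cross = np.asarray(K_cross, float)
    if K_cross.shape[1] != model.dual_coefficients.shape[0]:
        raise ValueError("K_cross columns must index the training subjects")
    return K_cross @ model.dual_coefficients + model.bias


def predict_svm(model: SVMModel, K_cross: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted {0, 1} labels and decision values (``f = 0`` -> class 1)."""
    f = decision_values(model, K_cross)
    return (f >= 0.0).astype(int), f


def primal_weights(model: SVMModel, X_train: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Expand the dual solution into primal weights ``w = X^T dual``."""
    Xv = X_train.values if isinstance(X_train, FeatureMatrix) else np.asarray(X_train, float)
    return Xv.T @ model.dual_coefficients


def kkt_residual_svm(model: SVMModel, K: LinearKernel | np.ndarray, bound_tol: float = 1e-8) -> float:
    """Max violation of the dual KKT conditions on the training set.

    With ``alpha_i = y_i * dual_i`` and margins ``m_i = y_i f(x_i)``:
    ``alpha = 0`` requires ``m >= 1``, ``0 < alpha < C`` requires
    ``m = 1``, and ``alpha = C`` requires ``m <= 1``.
    """
    Km = _kernel_array(K)
    f = decision_values(model, Km)
    m = model.y_train_pm1 * f
    alpha = model.y_train_pm1 * model.dual_coefficients
    if alpha.min() < -1e-9 or alpha.max() > model.C * (1 + 1e-9):
        return float("inf")
    scale = model.C * bound_tol
    at_zero = alpha <= scale
    at_C = alpha >= model.C - scale
    interior = ~(at_zero | at_C)
    res = 0.0
    if at_zero.any():
        res = max(res, float(np.maximum(1.0 - m[at_zero], 0.0).max()))
    if interior.any():
        res = max(res, float(np.abs(1.0 - m[interior]).max()))
    if at_C.any():
        res = max(res, float(np.maximum(m[at_C] - 1.0, 0.0).max()))
    return res
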