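"""Linear kernel (Gram) matrices and SVD-based conditioning diagnostics.

The degree of ill-posedness of the ``n << d`` classification problem is
quantified through the singular values of ``K = X X^T``: numerical rank,
condition number (largest over smallest singular value; infinite for a
singular matrix) and its reciprocal, plus median aggregation of spectra
across Monte-Carlo iterations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .template_masking import FeatureMatrix

__all__ = [
    "LinearKernel",
    "ConditioningReport",
    "SpectrumSummary",
    "linear_kernel",
    "cross_kernel",
    "svd_conditioning",
    "aggregate_spectra",
]


@dataclass(frozen=True)
class LinearKernel:
    K: np.ndarray  # (n, n) symmetric PSD
    n: int
    d: int

    def __post_init__(self) -> None:
        K = np.asarray(self.K, float)
        if K.shape != (self.n, self.n):
            raise ValueError("kernel shape does not match n")
        scale = max(np.abs(K).max(), 1.0)
        if np.abs(K - K.T).max() > 1e-10 * scale:
            raise ValueError("kernel is not symmetric")
        object.__setattr__(self, "K", K)


@dataclass(frozen=True)
class ConditioningReport:
    singular_values: np.ndarray  # nonincreasing, nonnegative, length n
    rank: int
    condition_number: float  # sigma_max / sigma_min; inf when singular
    reciprocal_condition: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["singular_values"] = self.singular_values.tolist()
        payload["condition_number"] = (
            "inf" if np.isinf(self.condition_number) else self.condition_number
        )
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class SpectrumSummary:
    median_singular_values: np.ndarray  # per-index median over iterations
    n_iterations: int
    median_condition: float
    iqr_condition: tuple[float, float]


def linear_kernel(X: FeatureMatrix | np.ndarray) -> LinearKernel:
    """Gram matrix of inner products between subject feature vectors.

    Exact symmetry is enforced by averaging with the transpose, which
    removes floating-point asymmetry from the BLAS product.
    """
    if isinstance(X, FeatureMatrix):
        if not X.standardized:
            warnings.warn("building a linear kernel from unstandardized features")
        V = X.values
    else:
        V = np.asarray(X, float)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite feature values")
    K = V @ V.T
    K = (K + K.T) / 2.0
    return LinearKernel(K=K, n=V.shape[0], d=V.shape[1])


def cross_kernel(X_new: FeatureMatrix | np.ndarray, X_train: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Inner products of new subjects (rows) against training subjects (columns)."""
    A = X_new.values if isinstance(X_new, FeatureMatrix) else np.asarray(X_new, float)
    B = X_train.values if isinstance(X_train, FeatureMatrix) else np.asarray(X_train, float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature dimension mismatch between new and training data")
    return A @ B.T


def svd_conditioning(K: LinearKernel | np.ndarray, rank_tol: float | None = None) -> ConditioningReport:
    """Singular values, numerical rank and condition number of a kernel.

    ``rank_tol`` defaults to ``n * eps * sigma_max`` (standard numerical
    rank convention).  The condition number is ``sigma_max / sigma_min``
    with the *smallest* singular value in the denominator — +inf when it
    is exactly zero — matching the singular/ill-conditioned reading.
    """
    M = K.K if isinstance(K, LinearKernel) else np.asarray(K, float)
    n = M.shape[0]
    sigma = np.linalg.svd(M, compute_uv=False)
    sigma = np.sort(sigma)[::-1]
    smax = sigma[0] if n else 0.0
    if smax == 0.0:
        warnings.warn("all-zero kernel: rank 0, condition number undefined")
        return ConditioningReport(
            singular_values=sigma, rank=0, condition_number=np.inf, reciprocal_condition=0.0
        )
    if rank_tol is None:
        rank_tol = n * np.finfo(float).eps
    rank = int(np.sum(sigma > rank_tol * smax))
    smin = sigma[-1]
    cond = np.inf if smin == 0.0 else float(smax / smin)
    rcond = 0.0 if np.isinf(cond) else 1.0 / cond
    return ConditioningReport(
        singular_values=sigma, rank=rank, condition_number=cond, reciprocal_condition=rcond
    )


def spectra_to_csv(reports: list[ConditioningReport], path: str | Path) -> None:
    """Long-format spectrum export: iteration, index, sigma."""
    with open(path, "w") as fh:
        fh.write("iteration,index,sigma\n")
        for it, rep in enumerate(reports):
            for idx, sigma in enumerate(rep.singular_values):
                fh.write(f"{it},{idx},{sigma!r}\n")


def aggregate_spectra(reports: list[ConditioningReport]) -> SpectrumSummary:
    """Element-wise median spectrum plus median/IQR of condition numbers."""
    if not reports:
        raise ValueError("no reports to aggregate")
    sizes = {len(r.singular_values) for r in reports}
    if len(sizes) != 1:
        raise ValueError(f"reports have mixed kernel sizes: {sorted(sizes)}")
    spectra = np.vstack([r.singular_values for r in reports])
    conds = np.array([r.condition_number for r in reports])
    q1, q3 = np.quantile(conds, [0.25, 0.75])
    return SpectrumSummary(
        median_singular_values=np.median(spectra, axis=0),
        n_iterations=len(reports),
        median_condition=float(np.median(conds)),
        iqr_condition=(float(q1), float(q3)),
    )
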