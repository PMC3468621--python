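"""Held-out evaluation, 10-fold CV grid search, and the accuracy metric.

The evaluation design: a fixed, balanced test set is drawn once per
study seed; balanced training sets of varying size are redrawn from the
remaining subjects on each iteration.  Regularization parameters of RLR
(lambda) and SM-SVM (C) are chosen by stratified 10-fold CV + grid
search maximizing mean fold accuracy, ties going to the more regularized
value.  The LRC takes no grid and is fitted on the whole training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classifiers import fit_lrc, fit_rlr, fit_svm, predict_lrc, predict_rlr, predict_svm
from .classifiers.rlr import ConvergenceError, DEFAULT_ALPHA
from .kernel_conditioning import cross_kernel, linear_kernel
from .template_masking import (
    FeatureMatrix,
    LabelVector,
    apply_standardizer,
    fit_standardizer,
)

__all__ = [
    "SplitPlan",
    "CVResult",
    "ConfusionCounts",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_C_GRID",
    "make_split",
    "draw_training_ids",
    "accuracy",
    "confusion_counts",
    "kfold_grid_search",
    "evaluate_on_test",
    "fit_predict_method",
]

# the study's grids are typographically lost; these span the null-model
# to the near-unregularized regime
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 1, 25))
DEFAULT_C_GRID = tuple(2.0 ** np.arange(-10, 11))


@dataclass(frozen=True)
class SplitPlan:
    test_ids: tuple[int, ...]  # indices into the cohort, fixed & balanced
    train_pool_ids: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.test_ids) & set(self.train_pool_ids):
            raise ValueError("test and training pool overlap")


@dataclass(frozen=True)
class CVResult:
    grid: tuple[float, ...]
    fold_accuracies: np.ndarray  # (len(grid), k)
    selected_value: float
    mean_accuracy_at_selected: float


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN); AD is the positive class."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return (c.TP + c.TN) / c.total


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape:
        raise ValueError("label length mismatch")
    return ConfusionCounts(
        TP=int(np.sum((yt == 1) & (yp == 1))),
        TN=int(np.sum((yt == 0) & (yp == 0))),
        FP=int(np.sum((yt == 0) & (yp == 1))),
        FN=int(np.sum((yt == 1) & (yp == 0))),
    )


def make_split(labels: np.ndarray, n_test_per_class: int, seed: int) -> SplitPlan:
    """Draw the fixed balanced test set; everyone else is the training pool."""
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    test: list[int] = []
    for cls in (0, 1):
        ids = np.flatnonzero(y == cls)
        if len(ids) < n_test_per_class + 1:
            raise ValueError(
                f"class {cls} has {len(ids)} subjects; need > {n_test_per_class}"
            )
        test.extend(rng.choice(ids, size=n_test_per_class, replace=False).tolist())
    test_set = set(test)
    pool = [i for i in range(len(y)) if i not in test_set]
    return SplitPlan(test_ids=tuple(sorted(test)), train_pool_ids=tuple(pool), seed=seed)


def draw_training_ids(
    plan: SplitPlan, labels: np.ndarray, sample_size: int, iteration_seed: int
) -> np.ndarray:
    """Balanced training draw of ``sample_size`` subjects from the pool."""
    if sample_size % 2 != 0:
        raise ValueError("sample_size must be even for balanced classes")
    y = np.asarray(labels).astype(int)
    per_class = sample_size // 2
    rng = np.random.default_rng(iteration_seed)
    chosen: list[int] = []
    pool = np.asarray(plan.train_pool_ids)
    for cls in (0, 1):
        ids = pool[y[pool] == cls]
        if len(ids) < per_class:
            raise ValueError(f"training pool has only {len(ids)} of class {cls}")
        chosen.extend(rng.choice(ids, size=per_class, replace=False).tolist())
    return np.array(sorted(chosen))


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified k-fold assignment; every fold sees both classes."""
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        ids = np.flatnonzero(y == cls)
        rng.shuffle(ids)
        fold_of[ids] = np.arange(len(ids)) % k
    folds = [np.flatnonzero(fold_of == f) for f in range(k)]
    for f, held in enumerate(folds):
        if len(np.unique(y[held])) < 2:
            raise ValueError(f"fold {f} lacks both classes; reduce k or enlarge n")
    return folds


_CV_RLR_TOL = 1e-5  # CV fits are scored, not reported; final refit uses 1e-7


def _fold_accuracies(method, X_tr, y_tr, X_va, y_va, grid, alpha) -> np.ndarray:
    """Accuracy at every grid point for one fold, reusing shared work.

    RLR fits warm-start along the descending-lambda path; the SVM kernel
    blocks are computed once per fold and shared across the C grid.
    """
    acc = np.zeros(len(grid))
    if method == "rlr":
        order = np.argsort(grid)[::-1]  # large lambda first: cheap, good warm start
        model = None
        for g in order:
            try:
                model = fit_rlr(
                    X_tr, y_tr, lam=grid[g], alpha=alpha,
                    tol=_CV_RLR_TOL, warm_start=model,
                )
            except ConvergenceError:
                model = None  # non-converged grid point scores 0
                continue
            pred, _ = predict_rlr(model, X_va)
            acc[g] = float(np.mean(pred == y_va))
    elif method == "svm":
        K = linear_kernel(X_tr)
        K_va = cross_kernel(X_va, X_tr)
        for g, C in enumerate(grid):
            # iteration cap: scoring a slightly unconverged fold fit is
            # preferable to SMO spinning on rank-deficient kernels
            model = fit_svm(K, y_tr, C=C, tol=1e-6, max_iter=50_000, check_psd=False)
            pred, _ = predict_svm(model, K_va)
            acc[g] = float(np.mean(pred == y_va))
    else:
        raise ValueError(f"no grid search for method {method!r}")
    return acc


def kfold_grid_search(
    X_train: FeatureMatrix | np.ndarray,
    y_train: LabelVector | np.ndarray,
    method: str,
    grid: tuple[float, ...] | None = None,
    k: int = 10,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> CVResult:
    """Stratified k-fold grid search maximizing mean fold accuracy.

    Tie rule: among tied grid points the more regularized one wins —
    the larger lambda for RLR, the smaller C for the SVM.
    """
    Xv = X_train.values if isinstance(X_train, FeatureMatrix) else np.asarray(X_train, float)
    yv = (y_train.labels if isinstance(y_train, LabelVector) else np.asarray(y_train)).astype(int)
    if len(yv) < k:
        raise ValueError(f"n={len(yv)} < k={k}")
    if grid is None:
        grid = DEFAULT_LAMBDA_GRID if method == "rlr" else DEFAULT_C_GRID
    grid = tuple(float(g) for g in grid)
    folds = _stratified_folds(yv, k, seed)

    acc = np.zeros((len(grid), k))
    for f, held in enumerate(folds):
        tr = np.setdiff1d(np.arange(len(yv)), held)
        acc[:, f] = _fold_accuracies(
            method, Xv[tr], yv[tr], Xv[held], yv[held], grid, alpha
        )

    mean_acc = acc.mean(axis=1)
    best = mean_acc.max()
    tied = np.flatnonzero(np.isclose(mean_acc, best, rtol=0, atol=1e-12))
    values = np.array(grid)
    if method == "rlr":
        selected = float(values[tied].max())  # stronger regularization = larger lambda
    else:
        selected = float(values[tied].min())  # stronger regularization = smaller C
    return CVResult(
        grid=grid,
        fold_accuracies=acc,
        selected_value=selected,
        mean_accuracy_at_selected=float(best),
    )


def evaluate_on_test(
    y_test: np.ndarray, y_pred: np.ndarray, train_ids=None, test_ids=None
) -> tuple[ConfusionCounts, float]:
    """Confusion counts + accuracy with AD (label 1) as the positive class.

    Passing ``train_ids``/``test_ids`` arms a leakage guard that refuses
    test subjects that were seen in training.
    """
    if train_ids is not None and test_ids is not None:
        overlap = set(map(int, train_ids)) & set(map(int, test_ids))
        if overlap:
            raise ValueError(f"leakage: test subjects {sorted(overlap)} were in training")
    counts = confusion_counts(y_test, y_pred)
    return counts, accuracy(counts)


@dataclass
class MethodOutcome:
    predictions: np.ndarray
    accuracy: float
    counts: ConfusionCounts
    selected_hyperparameter: float | None = None
    cv: CVResult | None = None


def fit_predict_method(
    method: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    rlr_grid=None,
    svm_grid=None,
    cv_k: int = 10,
    cv_seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    standardize: bool = True,
) -> MethodOutcome:
    """Standardize on train, run the method end to end, score on test.

    ``method`` is one of ``lrc``, ``rlr``, ``svm_soft``, ``svm_hard``.
    Standardization parameters are fitted on the training rows only.
    """
    X_train = np.asarray(X_train, float)
    X_test = np.asarray(X_test, float)
    y_train = np.asarray(y_train).astype(int)
    y_test = np.asarray(y_test).astype(int)
    if standardize:
        params = fit_standardizer(X_train)
        Xtr = apply_standardizer(params, X_train).values
        Xte = apply_standardizer(params, X_test).values
    else:
        Xtr, Xte = X_train, X_test

    selected: float | None = None
    cv: CVResult | None = None
    if method == "lrc":
        K = linear_kernel(Xtr)
        model = fit_lrc(K, y_train, Xtr)
        pred, _ = predict_lrc(model, Xte)
    elif method == "rlr":
        cv = kfold_grid_search(
            Xtr, y_train, "rlr", grid=rlr_grid, k=cv_k, seed=cv_seed, alpha=alpha
        )
        selected = cv.selected_value
        model = fit_rlr(Xtr, y_train, lam=selected, alpha=alpha)
        pred, _ = predict_rlr(model, Xte)
    elif method in ("svm_soft", "svm_hard"):
        K = linear_kernel(Xtr)
        if method == "svm_soft":
            cv = kfold_grid_search(Xtr, y_train, "svm", grid=svm_grid, k=cv_k, seed=cv_seed)
            selected = cv.selected_value
            model = fit_svm(
                K, y_train, C=selected, tol=1e-6, max_iter=5_000_000, check_psd=False
            )
        else:
            model = fit_svm(
                K, y_train, mode="hard", tol=1e-6, max_iter=5_000_000, check_psd=False
            )
        pred, _ = predict_svm(model, cross_kernel(Xte, Xtr))
    else:
        raise ValueError(f"unknown method {method!r}")

    counts, acc = evaluate_on_test(y_test, pred)
    return MethodOutcome(
        predictions=pred,
        accuracy=acc,
        counts=counts,
        selected_hyperparameter=selected,
        cv=cv,
    )


def save_split_plan(plan: SplitPlan, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "test_ids": list(plan.test_ids),
                "train_pool_ids": list(plan.train_pool_ids),
                "seed": plan.seed,
            },
            indent=2,
        )
    )
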