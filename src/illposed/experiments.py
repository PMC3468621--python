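"""Orchestration of the sample-size x dimension experiment grid.

Experiment 1 measures test accuracy of the linear classifiers across
training sample sizes and mask dimensions; Experiment 2 collects SVD
conditioning diagnostics of the corresponding training kernels;
Experiment 3 compares voxel-space and PC-space accuracy at the largest
dimension and sample size; the supplementary run compares hard- and
soft-margin SVM.

Every cell is keyed by (experiment, size index, threshold index,
iteration) and seeded from the master seed through ``SeedSequence``
tuple entropy, so results are independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kernel_conditioning import ConditioningReport, linear_kernel, svd_conditioning
from .model_selection import draw_training_ids, fit_predict_method, make_split
from .pca_space import incremental_component_accuracy, pca_fit, pca_transform
from .synthetic_cohort import (
    DEFAULT_MASK_RATIOS,
    DEFAULT_THRESHOLDS,
    CohortConfig,
    VolumeGrid,
    default_effect_region,
    make_template,
    simulate_cohort,
)
from .template_masking import apply_standardizer, fit_standardizer, threshold_mask, vectorize

__all__ = [
    "ExperimentConfig",
    "ExperimentCell",
    "StudyContext",
    "desk_config",
    "small_config",
    "build_study",
    "run_experiment1",
    "run_experiment2",
    "run_experiment3",
    "run_supplementary",
    "aggregate",
    "cells_to_frame",
]

METHODS = ("lrc", "rlr", "svm_soft", "svm_hard")


@dataclass(frozen=True)
class ExperimentConfig:
    grid_dims: tuple[int, int, int] = (32, 32, 32)
    sample_sizes: tuple[int, ...] = (20, 30, 40, 50, 60, 90, 120, 150, 180, 210)
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    mask_size_ratios: tuple[float, ...] = DEFAULT_MASK_RATIOS
    n_iterations: int = 20
    methods: tuple[str, ...] = ("lrc", "rlr", "svm_soft")
    n_test_per_class: int = 50
    n_per_class: int = 160  # cohort size per class (pool + test)
    effect_size: float = 0.2
    noise_sd: float = 0.5
    smoothing_fwhm_vox: float = 1.0
    effect_heterogeneity: float = 0.09
    effect_fraction: float = 0.75
    # the C grid reaches far below 1: with a precomputed linear kernel of
    # scale ~d, the margin constraint only binds for C ~ 1/(n d)
    rlr_grid: tuple[float, ...] | None = tuple(float(g) for g in np.logspace(-3, 1, 9))
    svm_grid: tuple[float, ...] | None = tuple(float(g) for g in 2.0 ** np.arange(-26.0, 5.0, 2.0))
    cv_k: int = 10
    # "train": per-draw training-set-only parameters applied to the test
    # set (no leakage; default); "pooled": voxel-wise standardization over
    # the whole cohort once — the reading under which training kernels
    # are full rank, used by the conditioning experiment
    standardization: str = "train"
    conditioning_standardization: str = "pooled"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(s % 2 for s in self.sample_sizes):
            raise ValueError("sample sizes must be even (balanced classes)")
        if any(not 0 <= t <= 1 for t in self.thresholds):
            raise ValueError("thresholds must lie in [0, 1]")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        for attr in ("standardization", "conditioning_standardization"):
            if getattr(self, attr) not in ("pooled", "train"):
                raise ValueError(f"{attr} must be 'pooled' or 'train'")
        need = self.n_test_per_class + max(self.sample_sizes) // 2
        if self.n_per_class < need:
            raise ValueError(
                f"n_per_class={self.n_per_class} too small; need >= {need} "
                "(test set + largest training draw)"
            )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("grid_dims", "sample_sizes", "thresholds", "mask_size_ratios",
                    "methods", "rlr_grid", "svm_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def desk_config(master_seed: int = 0, **overrides) -> ExperimentConfig:
    """Desk-scale default: 32^3 grid, the full size ladder, 20 iterations."""
    return ExperimentConfig(master_seed=master_seed, **overrides)


def small_config(master_seed: int = 0, **overrides) -> ExperimentConfig:
    """Fast configuration on a 16^3 grid with reduced CV grids."""
    defaults = dict(
        grid_dims=(16, 16, 16),
        n_iterations=10,
        rlr_grid=tuple(float(g) for g in np.logspace(-3, 1, 7)),
        svm_grid=tuple(float(g) for g in 2.0 ** np.arange(-22.0, 5.0, 3.0)),
        cv_k=5,
    )
    defaults.update(overrides)
    return ExperimentConfig(master_seed=master_seed, **defaults)


@dataclass
class ExperimentCell:
    experiment: str
    sample_size: int
    threshold: float
    dimension: int  # mask voxel count
    method: str
    iteration: int
    accuracy: float
    selected_hyperparameter: float | None = None
    kernel_rank: int | None = None
    condition_number: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0 and not np.isnan(self.accuracy):
            raise ValueError("accuracy outside [0, 1]")


@dataclass
class StudyContext:
    """Cohort realized once per study: features per mask + fixed split."""

    config: ExperimentConfig
    labels: np.ndarray  # (N,) in {0, 1}
    features: list[np.ndarray]  # one raw (N, d_t) matrix per threshold
    dimensions: list[int]
    test_ids: np.ndarray
    plan: object
    _pooled: dict = field(default_factory=dict)

    def pooled_features(self, ti: int) -> np.ndarray:
        """Whole-cohort voxel-wise standardized features for mask ``ti``."""
        if ti not in self._pooled:
            V = self.features[ti]
            self._pooled[ti] = apply_standardizer(fit_standardizer(V), V).values
        return self._pooled[ti]

    def classifier_features(self, ti: int) -> np.ndarray:
        if self.config.standardization == "pooled":
            return self.pooled_features(ti)
        return self.features[ti]


def _cell_seed(master: int, experiment: int, size_i: int, thr_i: int, iteration: int) -> int:
    ss = np.random.SeedSequence((master, experiment, size_i, thr_i, iteration))
    return int(ss.generate_state(1)[0])


def build_study(config: ExperimentConfig) -> StudyContext:
    """Simulate the cohort and precompute per-mask feature matrices."""
    ss = np.random.SeedSequence((config.master_seed, 0))
    tmpl_seed, cohort_seed, split_seed = (int(s) for s in ss.generate_state(3))
    grid = VolumeGrid(dims=config.grid_dims)
    template = make_template(grid, config.mask_size_ratios, seed=tmpl_seed)
    region = default_effect_region(template, fraction=config.effect_fraction)
    cohort_cfg = CohortConfig(
        n_cn=config.n_per_class,
        n_ad=config.n_per_class,
        effect_region=region,
        effect_size=config.effect_size,
        noise_sd=config.noise_sd,
        smoothing_fwhm_vox=config.smoothing_fwhm_vox,
        effect_heterogeneity=config.effect_heterogeneity,
        seed=cohort_seed,
    )
    cohort = simulate_cohort(template, cohort_cfg)
    features, dims = [], []
    labels = None
    for t in config.thresholds:
        mask = threshold_mask(template, t)
        X, y = vectorize(cohort, mask)
        features.append(X.values)
        dims.append(mask.voxel_count)
        labels = y.labels
    plan = make_split(labels, config.n_test_per_class, seed=split_seed)
    return StudyContext(
        config=config,
        labels=labels,
        features=features,
        dimensions=dims,
        test_ids=np.asarray(plan.test_ids),
        plan=plan,
    )


def _iter_cells(config: ExperimentConfig):
    for si, size in enumerate(config.sample_sizes):
        for ti in range(len(config.thresholds)):
            for it in range(config.n_iterations):
                yield si, size, ti, it


def run_experiment1(
    config: ExperimentConfig,
    study: StudyContext | None = None,
    methods: tuple[str, ...] | None = None,
    experiment_tag: str = "exp1",
    experiment_id: int = 1,
) -> list[ExperimentCell]:
    """Accuracy of each method over the (size x dimension) grid."""
    study = study if study is not None else build_study(config)
    methods = methods if methods is not None else config.methods
    y = study.labels
    cells: list[ExperimentCell] = []
    for si, size, ti, it in _iter_cells(config):
        seed = _cell_seed(config.master_seed, experiment_id, si, ti, it)
        train_ids = draw_training_ids(study.plan, y, size, seed)
        X = study.classifier_features(ti)
        X_tr, y_tr = X[train_ids], y[train_ids]
        X_te, y_te = X[study.test_ids], y[study.test_ids]
        for method in methods:
            out = fit_predict_method(
                method,
                X_tr,
                y_tr,
                X_te,
                y_te,
                rlr_grid=config.rlr_grid,
                svm_grid=config.svm_grid,
                cv_k=min(config.cv_k, size // 2),
                cv_seed=seed,
                standardize=(config.standardization == "train"),
            )
            cells.append(
                ExperimentCell(
                    experiment=experiment_tag,
                    sample_size=size,
                    threshold=config.thresholds[ti],
                    dimension=study.dimensions[ti],
                    method=method,
                    iteration=it,
                    accuracy=out.accuracy,
                    selected_hyperparameter=out.selected_hyperparameter,
                )
            )
    return cells


def run_experiment2(
    config: ExperimentConfig, study: StudyContext | None = None
) -> tuple[list[ExperimentCell], dict[tuple[int, int, int], ConditioningReport]]:
    """Conditioning diagnostics of every training kernel in the grid.

    Training draws use the same per-cell seeds as Experiment 1.  The
    features are standardized per ``config.conditioning_standardization``
    ("pooled" by default: under per-draw training-only standardization
    every kernel carries a structural zero singular value from the
    column centering, which would mask the conditioning patterns).
    """
    study = study if study is not None else build_study(config)
    y = study.labels
    cells: list[ExperimentCell] = []
    reports: dict[tuple[int, int, int], ConditioningReport] = {}
    for si, size, ti, it in _iter_cells(config):
        seed = _cell_seed(config.master_seed, 1, si, ti, it)
        train_ids = draw_training_ids(study.plan, y, size, seed)
        if config.conditioning_standardization == "pooled":
            X_tr = study.pooled_features(ti)[train_ids]
        else:
            X_raw = study.features[ti][train_ids]
            X_tr = apply_standardizer(fit_standardizer(X_raw), X_raw).values
        report = svd_conditioning(linear_kernel(X_tr))
        reports[(si, ti, it)] = report
        cells.append(
            ExperimentCell(
                experiment="exp2",
                sample_size=size,
                threshold=config.thresholds[ti],
                dimension=study.dimensions[ti],
                method="kernel",
                iteration=it,
                accuracy=float("nan"),
                kernel_rank=report.rank,
                condition_number=report.condition_number,
            )
        )
    return cells, reports


def run_experiment3(
    config: ExperimentConfig,
    study: StudyContext | None = None,
    methods: tuple[str, ...] | None = None,
    component_step: int = 1,
) -> list[ExperimentCell]:
    """Voxel- vs PC-space accuracy at the largest dimension and size.

    ``component_step`` coarsens the component ladder (1 = add one
    component at a time, as in the original design).
    """
    study = study if study is not None else build_study(config)
    methods = methods if methods is not None else config.methods
    size = max(config.sample_sizes)
    si = config.sample_sizes.index(size)
    ti = int(np.argmax(study.dimensions))
    y = study.labels
    X = study.classifier_features(ti)
    cells: list[ExperimentCell] = []
    for it in range(config.n_iterations):
        seed = _cell_seed(config.master_seed, 3, si, ti, it)
        train_ids = draw_training_ids(study.plan, y, size, seed)
        X_tr, y_tr = X[train_ids], y[train_ids]
        X_te, y_te = X[study.test_ids], y[study.test_ids]
        if config.standardization == "train":
            params = fit_standardizer(X_tr)
            Z_tr = apply_standardizer(params, X_tr).values
            Z_te = apply_standardizer(params, X_te).values
        else:
            Z_tr, Z_te = X_tr, X_te  # features are pooled-standardized already
        proj = pca_fit(Z_tr)
        S_tr = proj.training_scores
        S_te = pca_transform(proj, Z_te)
        M = S_tr.shape[1]
        ladder = np.unique(np.r_[np.arange(1, M + 1, component_step), M])
        for method in methods:
            kwargs = dict(
                rlr_grid=config.rlr_grid,
                svm_grid=config.svm_grid,
                cv_k=min(config.cv_k, size // 2),
                cv_seed=seed,
            )
            vox = fit_predict_method(
                method, X_tr, y_tr, X_te, y_te,
                standardize=(config.standardization == "train"), **kwargs,
            )
            trace = incremental_component_accuracy(
                S_tr, y_tr, S_te, y_te, method, component_counts=ladder, **kwargs
            )
            cells.append(
                ExperimentCell(
                    experiment="exp3_voxel",
                    sample_size=size,
                    threshold=config.thresholds[ti],
                    dimension=study.dimensions[ti],
                    method=method,
                    iteration=it,
                    accuracy=vox.accuracy,
                    selected_hyperparameter=vox.selected_hyperparameter,
                )
            )
            cells.append(
                ExperimentCell(
                    experiment="exp3_pc",
                    sample_size=size,
                    threshold=config.thresholds[ti],
                    dimension=study.dimensions[ti],
                    method=method,
                    iteration=it,
                    accuracy=trace.best_accuracy,
                    selected_hyperparameter=float(trace.best_count),
                )
            )
    return cells


def run_supplementary(
    config: ExperimentConfig, study: StudyContext | None = None
) -> list[ExperimentCell]:
    """Hard- vs soft-margin SVM over the grid (same cells as Experiment 1)."""
    return run_experiment1(
        config,
        study=study,
        methods=("svm_soft", "svm_hard"),
        experiment_tag="supp",
        experiment_id=1,  # reuse exp1 training draws for paired comparison
    )


def cells_to_frame(cells: list[ExperimentCell]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in cells])


def aggregate(cells: list[ExperimentCell], n_iterations: int | None = None) -> pd.DataFrame:
    """Mean/sd/quartiles of accuracy per (size, dimension, method) cell.

    Raises if any (size, dimension, method) combination is incomplete.
    """
    df = cells_to_frame(cells)
    if df.empty:
        raise ValueError("no cells to aggregate")
    counts = df.groupby(["experiment", "sample_size", "dimension", "method"]).size()
    expected = n_iterations if n_iterations is not None else counts.max()
    short = counts[counts != expected]
    if len(short):
        raise ValueError(f"incomplete cells: {short.to_dict()}")
    has_acc = df[~df["accuracy"].isna()]
    out = []
    if len(has_acc):
        acc = (
            has_acc.groupby(["experiment", "sample_size", "dimension", "method"])["accuracy"]
            .agg(
                mean="mean",
                sd=lambda a: a.std(ddof=1) if len(a) > 1 else 0.0,
                q25=lambda a: a.quantile(0.25),
                median="median",
                q75=lambda a: a.quantile(0.75),
                n_iterations="size",
            )
            .reset_index()
        )
        out.append(acc)
    cond = df[df["condition_number"].notna()]
    if len(cond):
        ksum = (
            cond.groupby(["experiment", "sample_size", "dimension", "method"])
            .agg(
                median_condition=("condition_number", "median"),
                min_rank=("kernel_rank", "min"),
                max_rank=("kernel_rank", "max"),
                n_iterations=("condition_number", "size"),
            )
            .reset_index()
        )
        out.append(ksum)
    return pd.concat(out, ignore_index=True)
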