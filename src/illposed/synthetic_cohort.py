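"""Seeded synthetic gray-matter cohort generator.

Produces 3D GM density volumes with the statistical structure the
voxel-space classification experiments assume: a smooth probability
template whose thresholds carve out nested analysis masks, two subject
classes separated by a spatially localized atrophy effect, and spatially
smoothed additive noise that induces correlated voxels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "ProbabilityTemplate",
    "GMVolume",
    "CohortConfig",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_MASK_RATIOS",
    "make_template",
    "simulate_subject",
    "simulate_cohort",
    "default_effect_region",
    "save_cohort",
    "load_cohort",
]

#: template thresholds used throughout the experiments (descending)
DEFAULT_THRESHOLDS = (0.86, 0.65, 0.2, 0.0021)

#: target mask sizes proportional to 50:150:310:750, as fractions of the
#: brain region (largest mask ~= 93.75% of in-brain voxels)
DEFAULT_MASK_RATIOS = tuple(float(r) for r in np.array([50.0, 150.0, 310.0, 750.0]) / 800.0)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class ConfigurationError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


@dataclass(frozen=True)
class VolumeGrid:
    """Regular voxel grid: dimensions and physical voxel size in mm."""

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 8 for d in self.dims):
            raise ConfigurationError(f"all grid dims must be >= 8, got {self.dims}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ConfigurationError("voxel size must be strictly positive")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        return aff


@dataclass(frozen=True)
class ProbabilityTemplate:
    """Voxel-wise tissue-probability map in [0, 1] on a grid."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.dims:
            raise ConfigurationError("template shape does not match grid dims")
        if not np.all(np.isfinite(v)) or v.min() < 0 or v.max() > 1:
            raise ConfigurationError("template values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class GMVolume:
    """One subject's gray-matter density volume with its class label."""

    grid: VolumeGrid
    values: np.ndarray
    subject_id: str
    label: str  # "CN" or "AD"

    def __post_init__(self) -> None:
        if self.label not in ("CN", "AD"):
            raise ConfigurationError(f"label must be CN or AD, got {self.label!r}")
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.dims:
            raise ConfigurationError("volume shape does not match grid dims")
        if not np.all(np.isfinite(v)):
            raise ConfigurationError("volume contains non-finite values")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation parameters.

    ``effect_size`` is the mean GM reduction in the AD class over
    ``effect_region``, expressed in units of ``noise_sd``.

    ``effect_heterogeneity`` (same units) is the standard deviation of a
    per-subject atrophy severity drawn in *both* classes (mean 0 for CN,
    ``effect_size`` for AD).  A nonzero value bounds the achievable
    accuracy away from 1 regardless of voxel count — mimicking the
    irreducible class overlap of real cohorts.  The default 0 gives the
    deterministic effect.
    """

    n_cn: int
    n_ad: int
    effect_region: frozenset = field(default_factory=frozenset)
    effect_size: float = 1.0
    noise_sd: float = 1.0
    smoothing_fwhm_vox: float = 1.0
    effect_heterogeneity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cn < 1 or self.n_ad < 1 or self.n_cn + self.n_ad < 4:
            raise ConfigurationError("need n_cn, n_ad >= 1 and n_cn + n_ad >= 4")
        if self.noise_sd < 0 or self.smoothing_fwhm_vox < 0 or self.effect_heterogeneity < 0:
            raise ConfigurationError("noise_sd, smoothing and heterogeneity must be nonnegative")
        object.__setattr__(self, "effect_region", frozenset(self.effect_region))


def _smooth(vol: np.ndarray, fwhm_vox: float) -> np.ndarray:
    if fwhm_vox <= 0:
        return vol
    return ndimage.gaussian_filter(vol, sigma=fwhm_vox * _FWHM_TO_SIGMA)


def _brain_region(grid: VolumeGrid) -> np.ndarray:
    """Ellipsoidal 'brain' footprint; mask-size ratios refer to it."""
    centers = [(d - 1) / 2.0 for d in grid.dims]
    radii = [0.45 * d for d in grid.dims]
    coords = np.ogrid[: grid.dims[0], : grid.dims[1], : grid.dims[2]]
    r2 = sum(((c - m) / r) ** 2 for c, m, r in zip(coords, centers, radii))
    return r2 <= 1.0


def make_template(
    grid: VolumeGrid,
    mask_size_ratios: tuple[float, float, float, float] = DEFAULT_MASK_RATIOS,
    seed: int = 0,
    thresholds: tuple[float, float, float, float] = DEFAULT_THRESHOLDS,
    smoothing_fwhm_vox: float = 3.0,
) -> ProbabilityTemplate:
    """Build a smooth probability template with calibrated mask sizes.

    A smoothed uniform random field inside an ellipsoidal brain region is
    monotonically rescaled so that thresholding at ``thresholds`` (given
    in descending order) yields nested masks containing approximately
    ``mask_size_ratios`` x (brain voxel count) voxels each.  Monotone
    rescaling guarantees nesting exactly; quantile calibration puts each
    count within the contracted +-10%.
    """
    ratios = tuple(float(r) for r in mask_size_ratios)
    if len(ratios) != 4 or any(b <= a for a, b in zip(ratios, ratios[1:])):
        raise ConfigurationError(f"mask_size_ratios must be strictly increasing, got {ratios}")
    if min(ratios) <= 0:
        raise ConfigurationError("mask_size_ratios must be positive")
    thr = tuple(float(t) for t in thresholds)
    if any(b >= a for a, b in zip(thr, thr[1:])):
        raise ConfigurationError("thresholds must be strictly decreasing")

    brain = _brain_region(grid)
    n_brain = int(brain.sum())
    if ratios[-1] > 1.0:
        raise ConfigurationError(
            f"largest ratio {ratios[-1]} exceeds brain region ({n_brain} voxels)"
        )

    rng = np.random.default_rng(seed)
    field_ = _smooth(rng.uniform(size=grid.dims), smoothing_fwhm_vox)

    inside = field_[brain]
    # map the field through a piecewise-linear monotone transform so the
    # (1 - ratio) quantile of in-brain values lands exactly on each threshold
    quantiles = [np.quantile(inside, 1.0 - r) for r in ratios]
    lo, hi = inside.min(), inside.max()
    xs = np.array([lo, *quantiles[::-1], hi])  # increasing field values
    ys = np.array([0.001, *thr[::-1], 1.0])  # increasing probabilities
    if np.any(np.diff(xs) <= 0):
        raise ConfigurationError("degenerate field quantiles; increase grid or smoothing")
    values = np.zeros(grid.dims)
    values[brain] = np.interp(inside, xs, ys)
    return ProbabilityTemplate(grid=grid, values=values)


def default_effect_region(
    template: ProbabilityTemplate,
    highest_threshold: float = DEFAULT_THRESHOLDS[0],
    fraction: float = 0.5,
) -> frozenset:
    """Voxels with the highest template probability: a localized region
    guaranteed to survive every analysis threshold."""
    vals = template.values
    core = np.argwhere(vals > highest_threshold)
    if core.size == 0:
        raise ConfigurationError("template has no voxels above the highest threshold")
    k = max(1, int(round(fraction * len(core))))
    order = np.argsort(vals[tuple(core.T)])[::-1]
    chosen = core[order[:k]]
    return frozenset(map(tuple, chosen.tolist()))


def _baseline(template: ProbabilityTemplate) -> np.ndarray:
    # mean GM density proportional to tissue probability
    return template.values.copy()


def _region_indexer(region: frozenset, dims: tuple[int, int, int]) -> tuple:
    idx = np.array(sorted(region), dtype=int)
    if idx.size and (idx.min() < 0 or np.any(idx >= np.array(dims))):
        raise ConfigurationError("effect_region outside grid")
    return tuple(idx.T) if idx.size else (np.array([], int),) * 3


def simulate_subject(
    template: ProbabilityTemplate,
    cfg: CohortConfig,
    label: str,
    seed: int,
    subject_id: str | None = None,
) -> GMVolume:
    """Simulate one GM volume: baseline - atrophy (AD only) + smoothed noise,
    clipped at zero."""
    grid = template.grid
    vol = _baseline(template)
    rng = np.random.default_rng(seed)
    if cfg.effect_region:
        # effect sizes are in noise-sd units; unit scale in the noiseless case
        unit = cfg.noise_sd if cfg.noise_sd > 0 else 1.0
        severity = cfg.effect_size if label == "AD" else 0.0
        if cfg.effect_heterogeneity > 0:
            severity += cfg.effect_heterogeneity * rng.standard_normal()
        vol[_region_indexer(cfg.effect_region, grid.dims)] -= severity * unit
    if cfg.noise_sd > 0:
        noise = rng.normal(scale=cfg.noise_sd, size=grid.dims)
        noise = _smooth(noise, cfg.smoothing_fwhm_vox)
        vol = vol + noise
    np.clip(vol, 0.0, None, out=vol)
    sid = subject_id if subject_id is not None else f"{label}_{seed}"
    return GMVolume(grid=grid, values=vol, subject_id=sid, label=label)


def simulate_cohort(template: ProbabilityTemplate, cfg: CohortConfig) -> list[GMVolume]:
    """Simulate ``n_cn`` CN and ``n_ad`` AD volumes with per-subject seeds
    derived deterministically from ``cfg.seed``."""
    if cfg.effect_region and not all(
        template.values[r] > DEFAULT_THRESHOLDS[0] for r in cfg.effect_region
    ):
        raise ConfigurationError(
            "effect_region must lie inside the highest-threshold template mask"
        )
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = ss.generate_state(cfg.n_cn + cfg.n_ad).tolist()
    cohort = []
    labels = ["CN"] * cfg.n_cn + ["AD"] * cfg.n_ad
    for i, (label, s) in enumerate(zip(labels, child_seeds)):
        cohort.append(
            simulate_subject(template, cfg, label, int(s), subject_id=f"sub-{i:04d}")
        )
    return cohort


# ---------------------------------------------------------------------------
# NIfTI + sidecar CSV I/O


def save_cohort(cohort: list[GMVolume], out_dir: str | Path) -> None:
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for vol in cohort:
        img = nib.Nifti1Image(vol.values.astype(np.float32), vol.grid.affine)
        nib.save(img, out / f"{vol.subject_id}.nii.gz")
        rows.append((vol.subject_id, vol.label))
    with open(out / "participants.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "label"])
        w.writerows(rows)


def load_cohort(in_dir: str | Path) -> list[GMVolume]:
    import nibabel as nib

    src = Path(in_dir)
    cohort = []
    with open(src / "participants.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            img = nib.load(src / f"{row['subject_id']}.nii.gz")
            data = np.asarray(img.dataobj, dtype=float)
            vox = tuple(float(abs(img.affine[i, i])) for i in range(3))
            grid = VolumeGrid(dims=data.shape, voxel_size_mm=vox)
            cohort.append(
                GMVolume(
                    grid=grid,
                    values=data,
                    subject_id=row["subject_id"],
                    label=row["label"],
                )
            )
    return cohort
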