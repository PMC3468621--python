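"""Model serialization helpers: JSON dumps and NIfTI coefficient maps."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..template_masking import BinaryMask
from .lrc import LRCModel
from .rlr import ElasticNetModel
from .svm import SVMModel

__all__ = ["model_to_json", "coefficients_to_nifti"]


def model_to_json(model, path: str | Path | None = None) -> str:
    """Serialize a fitted model (coefficients + hyperparameters) to JSON."""
    if isinstance(model, LRCModel):
        payload = {
            "type": "lrc",
            "dual_coefficients": model.dual_coefficients.tolist(),
            "decision_threshold": model.decision_threshold,
        }
    elif isinstance(model, ElasticNetModel):
        payload = {
            "type": "rlr",
            "intercept": model.intercept,
            "coefficients": model.coefficients.tolist(),
            "lambda": model.lam,
            "alpha": model.alpha,
            "converged": model.converged,
            "n_outer_iterations": model.n_outer_iterations,
            "objective": model.objective,
        }
    elif isinstance(model, SVMModel):
        payload = {
            "type": "svm",
            "dual_coefficients": model.dual_coefficients.tolist(),
            "bias": model.bias,
            "C": model.C,
            "mode": model.mode,
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def coefficients_to_nifti(coefficients: np.ndarray, mask: BinaryMask, path: str | Path) -> None:
    """Scatter a per-voxel coefficient vector back into a NIfTI volume."""
    import nibabel as nib

    coefficients = np.asarray(coefficients, float)
    if coefficients.shape[0] != mask.voxel_count:
        raise ValueError("coefficient length does not match mask voxel count")
    vol = np.zeros(mask.grid.dims, dtype=np.float32)
    vol[tuple(mask.voxel_index_map.T)] = coefficients
    nib.save(nib.Nifti1Image(vol, mask.grid.affine), str(path))
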