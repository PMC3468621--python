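"""Centralized label conversions.

LRC and RLR work on {0, 1} labels (0 = CN, 1 = AD); the SVM dual works
on {-1, +1}.  All conversions go through these two functions so the
convention is defined — and tested — exactly once.
"""

from __future__ import annotations

import numpy as np


def to_pm1(y01: np.ndarray) -> np.ndarray:
    """{0, 1} -> {-1, +1}."""
    y = np.asarray(y01)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("expected labels in {0, 1}")
    return (2 * y - 1).astype(int)


def to_01(ypm: np.ndarray) -> np.ndarray:
    """{-1, +1} -> {0, 1}."""
    y = np.asarray(ypm)
    if not np.isin(y, (-1, 1)).all():
        raise ValueError("expected labels in {-1, +1}")
    return ((y + 1) // 2).astype(int)
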