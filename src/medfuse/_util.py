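"""Shared validation helpers for image-valued arguments."""

from __future__ import annotations

import numpy as np


def as_image(f, name: str = "image") -> np.ndarray:
    """Validate a 2-D intensity image in [0, 1] and return it as float64."""
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {f.shape}")
    if not np.all(np.isfinite(f)):
        raise ValueError(f"{name} contains non-finite values")
    if f.min() < -1e-9 or f.max() > 1 + 1e-9:
        raise ValueError(f"{name} values must lie in [0, 1]")
    return np.clip(f, 0.0, 1.0)


def as_band(f, name: str = "band") -> np.ndarray:
    """Validate a 2-D real-valued sub-band (no range restriction)."""
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {f.shape}")
    if not np.all(np.isfinite(f)):
        raise ValueError(f"{name} contains non-finite values")
    return f


def check_same_shape(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"arrays must share a shape, got {sorted(shapes)}")


def rescale01(f: np.ndarray) -> np.ndarray:
    """Affine min-max rescale to [0, 1]; constant input maps to 0."""
    f = np.asarray(f, dtype=np.float64)
    lo, hi = float(f.min()), float(f.max())
    if hi - lo < 1e-12:
        return np.zeros_like(f)
    return (f - lo) / (hi - lo)
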