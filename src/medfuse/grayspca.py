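"""PCA-based decolorization (gray-PCA).

RGB inputs are mapped to YCbCr (ITU-R BT.601, full range), the per-channel
mean is removed, and a 3x3 PCA over the pixel population yields eigenpairs
(lambda_1 >= lambda_2 >= lambda_3, orthonormal eigenvectors).  The grayscale
output is the weighted sum of the three eigenvector projections with weights
proportional to sqrt(lambda_k): the first projection carries the main
luminance mapping, the remaining two restore chromatic texture detail.
Eigenvector signs are fixed by positive correlation with luminance so the
result is deterministic; the output is affinely rescaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import rescale01

__all__ = ["PcaBasis", "decolorize", "to_gray"]

# ITU-R BT.601 full-range RGB -> YCbCr (Cb/Cr centered at 0 here)
_BT601 = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)


@dataclass(frozen=True)
class PcaBasis:
    eigenvalues: np.ndarray  # (3,) descending, nonnegative
    eigenvectors: np.ndarray  # (3, 3), rows orthonormal

    def __post_init__(self):
        ev, V = self.eigenvalues, self.eigenvectors
        if np.any(np.diff(ev) > 1e-12) or np.any(ev < -1e-12):
            raise ValueError("eigenvalues must be nonnegative and sorted descending")
        if not np.allclose(V @ V.T, np.eye(3), atol=1e-8):
            raise ValueError("eigenvectors must be orthonormal")


def _validate_color(img) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) color image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("color image contains non-finite values")
    return img


def pca_basis(ycc_zero_mean: np.ndarray) -> PcaBasis:
    """PCA of the zero-mean YCbCr pixel population (rows = pixels)."""
    cov = ycc_zero_mean.T @ ycc_zero_mean / max(1, ycc_zero_mean.shape[0])
    w, V = np.linalg.eigh(cov)  # ascending
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order].T  # rows = eigenvectors
    # deterministic sign: positive correlation with the luminance channel,
    # falling back to the largest-magnitude component for chroma-only axes
    y = ycc_zero_mean[:, 0]
    for k in range(3):
        c = float(ycc_zero_mean @ V[k] @ y) if y.any() else 0.0
        if abs(c) < 1e-12:
            j = int(np.argmax(np.abs(V[k])))
            c = V[k, j]
        if c < 0:
            V = V.copy()
            V[k] = -V[k]
    return PcaBasis(eigenvalues=w, eigenvectors=V)


def decolorize(img) -> np.ndarray:
    """Decolorize an RGB image to a single gray channel via YCbCr PCA.

    Returns a float64 image in [0, 1].  A constant input (zero covariance)
    returns its constant luminance.
    """
    img = _validate_color(img)
    h, w, _ = img.shape
    ycc = img.reshape(-1, 3) @ _BT601.T
    mean = ycc.mean(axis=0)
    x = ycc - mean

    total_var = float((x**2).sum()) / x.shape[0]
    if total_var < 1e-15:
        return np.full((h, w), np.clip(mean[0], 0.0, 1.0))

    basis = pca_basis(x)
    wts = np.sqrt(basis.eigenvalues)
    wts = wts / wts.sum()
    proj = x @ basis.eigenvectors.T  # (n, 3) projections
    combined = proj @ wts
    return rescale01(combined.reshape(h, w))


def to_gray(img) -> np.ndarray:
    """Dispatch: gray images pass through, 3-channel images are decolorized."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 1:
        return img[:, :, 0]
    if img.ndim == 3 and img.shape[2] == 3:
        return decolorize(img)
    raise ValueError(f"unsupported channel layout for shape {img.shape}")
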