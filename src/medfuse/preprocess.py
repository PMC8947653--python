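"""Morphological bottom-hat / top-hat preprocessing.

Non-uniform illumination and background noise in CT/MRI slices are corrected
with flat grayscale morphology: the bottom-hat residue closing(f) - f picks
up dark pits (noise, shading troughs), the top-hat residue f - opening(f)
picks up bright peaks.  The enhancement step adds the top-hat to and
subtracts the bottom-hat from the image, boosting bright structures while
suppressing dark artifacts; a literal "top-hat minus bottom-hat" variant is
selectable for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, footprint_rectangle

from ._util import as_image

__all__ = ["StructuringElement", "bottom_hat", "top_hat", "enhance"]


@dataclass(frozen=True)
class StructuringElement:
    """Flat structuring element: a centered binary mask, disk or square."""

    shape: str = "disk"
    radius: int = 9
    mask: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.shape == "disk":
            m = disk(self.radius)
        elif self.shape == "square":
            m = footprint_rectangle((2 * self.radius + 1,) * 2)
        else:
            raise ValueError(f"unknown structuring element shape {self.shape!r}")
        object.__setattr__(self, "mask", m.astype(bool))

    @staticmethod
    def auto_radius(height: int, width: int) -> int:
        # radius 9 at 256 px, scaled with the smaller image side
        return max(2, round(9 * min(height, width) / 256))


def _check_fits(f: np.ndarray, b: StructuringElement) -> None:
    if b.mask.shape[0] > f.shape[0] or b.mask.shape[1] > f.shape[1]:
        raise ValueError("structuring element is larger than the image")


def bottom_hat(f, b: StructuringElement) -> np.ndarray:
    """Bottom-hat residue closing(f, b) - f; nonnegative everywhere."""
    f = as_image(f)
    _check_fits(f, b)
    closed = ndimage.grey_closing(f, footprint=b.mask, mode="reflect")
    return closed - f


def top_hat(f, b: StructuringElement) -> np.ndarray:
    """Top-hat residue f - opening(f, b); nonnegative everywhere."""
    f = as_image(f)
    _check_fits(f, b)
    opened = ndimage.grey_opening(f, footprint=b.mask, mode="reflect")
    return f - opened


def enhance(f, b: StructuringElement, variant: str = "classic") -> np.ndarray:
    """Contrast-enhance ``f`` with the combined hat residues.

    variant="classic": clip(f + top_hat - bottom_hat, 0, 1) — the standard
    enhancement that keeps the image and boosts bright / suppresses dark
    features.  variant="residue": clip(top_hat - bottom_hat, 0, 1),
    the bare residue difference.
    """
    f = as_image(f)
    th = top_hat(f, b)
    bh = bottom_hat(f, b)
    if variant == "classic":
        out = f + th - bh
    elif variant == "residue":
        out = th - bh
    else:
        raise ValueError(f"unknown enhance variant {variant!r}")
    return np.clip(out, 0.0, 1.0)
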