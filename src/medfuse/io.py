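"""Reading and writing image files (8/16-bit PNG, float TIFF)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["read_image", "write_png", "write_tiff"]


def read_image(path) -> np.ndarray:
    """Read a gray or RGB image and scale intensities to float64 in [0, 1].

    Integer images are divided by their dtype maximum; float images are
    assumed to already be in [0, 1].  RGBA alpha is dropped.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError(f"{path}: float image values must lie in [0, 1]")
    return arr


def write_png(path, img: np.ndarray) -> None:
    """Write an image in [0, 1] as 8-bit PNG."""
    img = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), (np.round(img * 255)).astype(np.uint8))


def write_tiff(path, img: np.ndarray) -> None:
    """Write a float32 TIFF (unquantized, for metric-stable storage)."""
    tifffile.imwrite(Path(path), np.asarray(img, dtype=np.float32))
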