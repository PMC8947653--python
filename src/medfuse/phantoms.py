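"""Synthetic co-registered CT/MRI-like phantoms and sharp/blur training patches.

CT and MRI slices of the same anatomy carry complementary content: CT shows
bone (a bright skull ring) at high contrast with a flat soft-tissue interior,
while MRI shows textured soft tissue with dark bone.  The generators here
emulate exactly that structure on a deterministic elliptical head phantom so
every downstream fusion stage can be exercised offline: the two modalities
share one anatomy layout (perfectly co-registered), differ in which
structures are bright, and are corrupted by additive Gaussian noise and a
smooth multiplicative illumination ramp.

The patch generator produces labeled (sharp, blurred) pairs of textured
crops, the training corpus for the clarity classifier used in high-frequency
fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PatchPairSet",
    "generate_phantom_pair",
    "phantom_masks",
    "generate_patch_pairs",
]

# Fixed anatomy layout in normalized [-1, 1] coordinates:
# skull ring = outer ellipse minus inner ellipse; interior blobs (cx, cy, a, b).
_OUTER = (0.88, 0.94)
_INNER = (0.74, 0.80)
_BLOBS = (
    (-0.30, -0.25, 0.22, 0.30),
    (0.32, -0.20, 0.18, 0.24),
    (0.05, 0.30, 0.28, 0.20),
    (-0.02, -0.05, 0.10, 0.12),
)


@dataclass
class PatchPairSet:
    """Labeled pairs of square patches for clarity classification.

    ``label[i] == 1`` means ``patch_a[i]`` is the sharp member of pair *i*.
    """

    patch_a: np.ndarray  # (n, p, p) float64
    patch_b: np.ndarray  # (n, p, p) float64
    label: np.ndarray  # (n,) int, in {0, 1}
    patch_size: int

    def __len__(self) -> int:
        return len(self.label)


def _grid(size: int):
    c = np.linspace(-1.0, 1.0, size)
    return np.meshgrid(c, c, indexing="xy")


def _ellipse(x, y, cx, cy, a, b):
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0


def phantom_masks(size: int) -> dict:
    """Boolean anatomy masks shared by both modalities of a phantom pair.

    Keys: ``ring`` (skull), ``interior`` (soft tissue inside the skull),
    ``blobs`` (lesion-like interior structures), ``background``.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    x, y = _grid(size)
    outer = _ellipse(x, y, 0.0, 0.0, *_OUTER)
    inner = _ellipse(x, y, 0.0, 0.0, *_INNER)
    ring = outer & ~inner
    blobs = np.zeros_like(ring)
    for cx, cy, a, b in _BLOBS:
        blobs |= _ellipse(x, y, cx, cy, a, b)
    blobs &= inner
    return {
        "ring": ring,
        "interior": inner & ~blobs,
        "blobs": blobs,
        "background": ~outer,
    }


def illumination_field(size: int, illum_strength: float) -> np.ndarray:
    """Multiplicative illumination ramp L(u, v) = 1 + s*((u + v)/2 - 1/2).

    u, v are pixel coordinates normalized to [0, 1]; the field is a first-order
    polynomial ramp whose mean over the grid is exactly 1.
    """
    u = np.linspace(0.0, 1.0, size)
    uu, vv = np.meshgrid(u, u, indexing="xy")
    return 1.0 + illum_strength * ((uu + vv) / 2.0 - 0.5)


def _smooth_texture(shape, rng, corr_sigma: float) -> np.ndarray:
    """Band-limited Gaussian texture: white noise smoothed to a correlation
    length of ``corr_sigma`` pixels, renormalized to unit standard deviation."""
    t = ndimage.gaussian_filter(rng.standard_normal(shape), corr_sigma, mode="wrap")
    sd = t.std()
    return t / sd if sd > 0 else t


def generate_phantom_pair(
    size: int,
    noise_sd: float = 0.02,
    illum_strength: float = 0.3,
    seed: int = 0,
):
    """Generate a co-registered (ct_like, mri_like) phantom pair.

    Parameters
    ----------
    size:
        Image side length in pixels (>= 64).
    noise_sd:
        Standard deviation of the additive Gaussian noise, in intensity units.
    illum_strength:
        Amplitude of the multiplicative illumination ramp, in [0, 1).
    seed:
        Seed for noise and texture; identical arguments give bit-identical
        output.

    Returns
    -------
    (ct_like, mri_like):
        Two float64 images in [0, 1] with identical anatomy masks: the CT has
        a bright skull ring and dark interior, the MRI a dark ring and bright
        textured interior.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not (0.0 <= illum_strength < 1.0):
        raise ValueError("illum_strength must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    masks = phantom_masks(size)
    edge_sigma = max(0.8, size / 160.0)  # soften mask boundaries slightly

    def soft(mask):
        return ndimage.gaussian_filter(mask.astype(np.float64), edge_sigma)

    ring, interior, blobs = soft(masks["ring"]), soft(masks["interior"]), soft(
        masks["blobs"]
    )

    ct = 0.02 + 0.93 * ring + 0.13 * interior + 0.30 * blobs
    mri_tex = _smooth_texture((size, size), rng, corr_sigma=max(1.0, size / 96.0))
    mri = (
        0.02
        + 0.06 * ring
        + (0.55 + 0.12 * mri_tex) * interior
        + (0.78 + 0.06 * mri_tex) * blobs
    )

    illum = illumination_field(size, illum_strength)
    ct = ct * illum + rng.normal(0.0, noise_sd, (size, size)) if noise_sd > 0 else ct * illum
    mri = mri * illum + rng.normal(0.0, noise_sd, (size, size)) if noise_sd > 0 else mri * illum
    return np.clip(ct, 0.0, 1.0), np.clip(mri, 0.0, 1.0)


def generate_patch_pairs(
    n: int,
    patch_size: int = 16,
    blur_sd_range=(1.0, 3.0),
    seed: int = 0,
) -> PatchPairSet:
    """Generate ``n`` labeled (sharp, blurred) patch pairs.

    Patches are textured crops from random smooth-noise canvases; the blurred
    member is a Gaussian-blurred copy (sigma uniform in ``blur_sd_range``).
    The (a, b) order of each pair is randomized; ``label == 1`` iff
    ``patch_a`` is the sharp member.  Labels are exactly balanced up to
    rounding of n/2.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if patch_size < 8:
        raise ValueError("patch_size must be >= 8")
    lo, hi = float(blur_sd_range[0]), float(blur_sd_range[1])
    if not (0 < lo <= hi):
        raise ValueError("blur_sd_range must be a nonempty positive interval")

    rng = np.random.default_rng(seed)
    p = patch_size
    canvas_size = max(4 * p, 64)
    sharp = np.empty((n, p, p))
    blurred = np.empty((n, p, p))
    made = 0
    while made < n:
        # each canvas mixes two correlation lengths so crops carry both
        # edges and fine texture
        canvas = 0.5 + 0.22 * _smooth_texture(
            (canvas_size, canvas_size), rng, 1.2
        ) + 0.12 * _smooth_texture((canvas_size, canvas_size), rng, 4.0)
        canvas = np.clip(canvas, 0.0, 1.0)
        for _ in range(32):
            if made == n:
                break
            i = rng.integers(0, canvas_size - p + 1)
            j = rng.integers(0, canvas_size - p + 1)
            crop = canvas[i : i + p, j : j + p]
            if crop.std() < 0.02:  # reject near-flat crops
                continue
            sigma = rng.uniform(lo, hi)
            sharp[made] = crop
            blurred[made] = ndimage.gaussian_filter(crop, sigma, mode="reflect")
            made += 1

    # exactly balanced labels, randomly permuted from the seeded stream
    label = np.zeros(n, dtype=np.int64)
    label[: (n + 1) // 2] = 1
    label = label[rng.permutation(n)]
    swap = label == 0
    patch_a = np.where(swap[:, None, None], blurred, sharp)
    patch_b = np.where(swap[:, None, None], sharp, blurred)
    return PatchPairSet(patch_a=patch_a, patch_b=patch_b, label=label, patch_size=p)
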