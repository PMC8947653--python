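"""Local shift-invariant shearlet transform (LSIST).

The transform has two stages, both fully undecimated so every band keeps the
input's size:

1. Multi-scale split with non-subsampled pyramid filters: an a-trous scheme
   built on the CDF 9/7 analysis/synthesis low-pass pair (DC gain normalized
   to 1).  With analysis low-pass h0 and synthesis low-pass h1, scale s uses
   the dilated responses H0(2^s w), H1(2^s w) and defines

       low_{s+1} = H0 * f_s,      g_{s+1} = f_s - H1 * low_{s+1},

   so the Bezout identity H0*H1 + G*1 = 1 holds exactly and synthesis
   f_s = H1 * low_{s+1} + g_{s+1} reconstructs perfectly.

2. Directional localization: each high band is analyzed in the 2-D DFT
   domain with Meyer-window wedge filters defined on the pseudo-polar grid
   (uniform in slope on concentric squares) and mapped to the Cartesian DFT
   grid.  The squared windows of each scale form a partition of unity, so
   the adjoint recombination is exact and the whole transform is a tight
   frame up to floating-point error.

Everything is diagonal in the DFT (periodic boundaries), which makes the
transform exactly equivariant to circular shifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.fft import fft2, ifft2

__all__ = [
    "SubbandPyramid",
    "ShearFilterBank",
    "build_shear_filter_bank",
    "decompose",
    "reconstruct",
]

# CDF 9/7 low-pass pair, normalized to DC gain 1 (analysis 9 taps, synthesis 7)
_H0 = np.array(
    [
        0.026748757410810054,
        -0.016864118442875895,
        -0.07822326652898785,
        0.2668641184428723,
        0.6029490182363579,
        0.2668641184428723,
        -0.07822326652898785,
        -0.016864118442875895,
        0.026748757410810054,
    ]
)
_H1 = np.array(
    [
        -0.09127176311424948,
        -0.057543526228499726,
        0.5912717631142470,
        1.115087052456994,
        0.5912717631142470,
        -0.057543526228499726,
        -0.09127176311424948,
    ]
)
_H0 = _H0 / _H0.sum()
_H1 = _H1 / _H1.sum()


def _filter_response_1d(taps: np.ndarray, n: int, dilation: int) -> np.ndarray:
    """DFT response of a centered symmetric FIR filter dilated a-trous by
    ``dilation`` (zeros inserted), evaluated on the length-``n`` DFT grid."""
    half = len(taps) // 2
    w = 2.0 * np.pi * np.fft.fftfreq(n)
    k = np.arange(-half, half + 1)
    # symmetric taps -> real response: sum_k taps[k] * cos(dilation * k * w)
    return np.cos(np.outer(w, k) * dilation) @ taps


def _pyramid_responses(h: int, w: int, scales: int):
    """Per-scale 2-D separable responses (H0_s, H1_s), finest scale first."""
    out = []
    for s in range(scales):
        d = 2**s
        h0 = np.outer(_filter_response_1d(_H0, h, d), _filter_response_1d(_H0, w, d))
        h1 = np.outer(_filter_response_1d(_H1, h, d), _filter_response_1d(_H1, w, d))
        out.append((h0, h1))
    return out


def _meyer_nu(x: np.ndarray) -> np.ndarray:
    """Meyer auxiliary polynomial: 0 at 0, 1 at 1, C^3-smooth transitions."""
    x = np.clip(x, 0.0, 1.0)
    return x**4 * (35.0 - 84.0 * x + 70.0 * x**2 - 20.0 * x**3)


def _pseudo_polar_coord(h: int, w: int) -> np.ndarray:
    """Orientation coordinate u on the pseudo-polar grid, period 4.

    On the horizontal cone (|w2| <= |w1|) u = w2/w1 in [-1, 1]; on the
    vertical cone u = 2 - w1/w2 in [1, 3].  u is constant along rays and
    symmetric under point reflection, and uniform steps in u correspond to
    uniform steps in slope on concentric squares.  DC is assigned u = 0 and
    handled separately by the window builder.
    """
    fy = np.fft.fftfreq(h)[:, None] * np.ones((1, w))
    fx = np.ones((h, 1)) * np.fft.fftfreq(w)[None, :]
    # On Nyquist lines (even sizes) the bin stands for both +1/2 and -1/2;
    # use magnitudes there so the windows stay symmetric under point
    # reflection and real bands lose no energy to the discarded imaginary part.
    ny = np.zeros((h, w), dtype=bool)
    if h % 2 == 0:
        ny[h // 2, :] = True
    if w % 2 == 0:
        ny[:, w // 2] = True
    fy = np.where(ny, np.abs(fy), fy)
    fx = np.where(ny, np.abs(fx), fx)
    horiz = np.abs(fy) <= np.abs(fx)
    u = np.zeros((h, w))
    with np.errstate(divide="ignore", invalid="ignore"):
        u_h = fy / fx
        u_v = 2.0 - fx / fy
    u[horiz] = u_h[horiz]
    u[~horiz] = u_v[~horiz]
    u[0, 0] = 0.0
    return u


def _validate_directions(directions_per_scale) -> tuple:
    dps = tuple(int(d) for d in directions_per_scale)
    for d in dps:
        if d < 2 or (d & (d - 1)) != 0:
            raise ValueError(f"direction count {d} must be a power of 2, >= 2")
    return dps


@dataclass(frozen=True)
class ShearFilterBank:
    """Meyer-window wedge filters on the Cartesian DFT grid, one set per scale.

    ``frequency_windows[s]`` has shape (D_s, H, W); the squared windows of
    each scale sum to 1 at every frequency (partition of unity).
    """

    height: int
    width: int
    scales: int
    directions_per_scale: tuple
    frequency_windows: tuple  # per scale: (D_s, H, W) real arrays

    def partition_deviation(self) -> float:
        """Max |sum_d W_d^2 - 1| over all scales and frequencies."""
        dev = 0.0
        for wins in self.frequency_windows:
            dev = max(dev, float(np.abs((wins**2).sum(axis=0) - 1.0).max()))
        return dev


def _build_windows(h: int, w: int, d: int) -> np.ndarray:
    u = _pseudo_polar_coord(h, w)
    delta = 4.0 / d
    wins = np.empty((d, h, w))
    for k in range(d):
        t = (u - k * delta + 2.0) % 4.0 - 2.0  # wrapped distance to center
        t = np.abs(t) / delta
        wins[k] = np.where(t < 1.0, np.cos(0.5 * np.pi * _meyer_nu(t)), 0.0)
        wins[k, 0, 0] = 1.0 / np.sqrt(d)  # DC split evenly, keeps the partition
    return wins


@lru_cache(maxsize=16)
def _cached_bank(h: int, w: int, scales: int, dps: tuple) -> ShearFilterBank:
    wins = tuple(_build_windows(h, w, d) for d in dps)
    return ShearFilterBank(
        height=h,
        width=w,
        scales=scales,
        directions_per_scale=dps,
        frequency_windows=wins,
    )


def build_shear_filter_bank(
    height: int, width: int, scales: int, directions_per_scale
) -> ShearFilterBank:
    """Build (or fetch from cache) the wedge filter bank for an image size."""
    if height < 8 or width < 8:
        raise ValueError("image dimensions must be >= 8")
    dps = _validate_directions(directions_per_scale)
    if len(dps) != scales:
        raise ValueError("directions_per_scale must list one count per scale")
    return _cached_bank(height, width, scales, dps)


@dataclass
class SubbandPyramid:
    """Undecimated shearlet coefficients: one low band plus, per scale
    (coarse to fine), a list of directional high bands, all input-sized."""

    low: np.ndarray
    high: list  # high[s][d] -> (H, W) array, s coarse -> fine
    scales: int
    directions_per_scale: tuple

    @property
    def shape(self):
        return self.low.shape

    def _check(self):
        if len(self.high) != self.scales:
            raise ValueError("pyramid scale count mismatch")
        for s, bands in enumerate(self.high):
            if len(bands) != self.directions_per_scale[s]:
                raise ValueError("pyramid direction count mismatch")
            for b in bands:
                if b.shape != self.low.shape:
                    raise ValueError("pyramid band shapes mismatch")


def decompose(img, scales: int = 3, directions_per_scale=(8, 8, 16)) -> SubbandPyramid:
    """Decompose an image into one low band and per-scale directional bands.

    ``directions_per_scale`` is ordered coarse to fine.  All bands have the
    input's size; the transform is linear, shift-equivariant (circular), and
    inverted exactly by :func:`reconstruct`.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if scales < 1:
        raise ValueError("scales must be >= 1")
    dps = _validate_directions(directions_per_scale)
    if len(dps) != scales:
        raise ValueError("directions_per_scale must list one count per scale")
    h, w = img.shape
    if min(h, w) < 2**scales:
        raise ValueError("image dimensions must be >= 2**scales")

    bank = build_shear_filter_bank(h, w, scales, dps)
    pyr_resp = _pyramid_responses(h, w, scales)

    spectrum = fft2(img)
    high: list = []
    for s in range(scales):  # finest split first
        h0, h1 = pyr_resp[s]
        low_spec = spectrum * h0
        g_spec = spectrum - h1 * low_spec
        wins = bank.frequency_windows[scales - 1 - s]  # fine scale -> last entry
        bands = [np.real(ifft2(g_spec * win)) for win in wins]
        high.append(bands)
        spectrum = low_spec
    low = np.real(ifft2(spectrum))
    high.reverse()  # present coarse -> fine, matching directions_per_scale
    return SubbandPyramid(low=low, high=high, scales=scales, directions_per_scale=dps)


def reconstruct(pyr: SubbandPyramid) -> np.ndarray:
    """Invert :func:`decompose`: adjoint wedge recombination per scale, then
    pyramid synthesis with the low band.  Output is real-valued, unclipped."""
    pyr._check()
    h, w = pyr.low.shape
    scales = pyr.scales
    bank = build_shear_filter_bank(h, w, scales, pyr.directions_per_scale)
    pyr_resp = _pyramid_responses(h, w, scales)

    spectrum = fft2(pyr.low)
    for s in range(scales - 1, -1, -1):  # coarsest first
        _, h1 = pyr_resp[s]
        wins = bank.frequency_windows[scales - 1 - s]
        g_spec = np.zeros((h, w), dtype=complex)
        for band, win in zip(pyr.high[scales - 1 - s], wins):
            g_spec += fft2(band) * win
        spectrum = h1 * spectrum + g_spec
    return np.real(ifft2(spectrum))
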