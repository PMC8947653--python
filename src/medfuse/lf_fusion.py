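"""Low-pass sub-band fusion by local energy with salience-gated rules.

For each pixel, the local energy of a low-pass band L is the weighted sum of
squared coefficients over a 3x3 template Wc,

    En(x, y) = sum_{m,n} L(x+m, y+n)^2 Wc(m, n),

and the salience (match) factor between the two bands is the normalized
cross term

    S(x, y) = 2 sum_{m,n} LC(x+m, y+n) LD(x+m, y+n) Wc(m, n)
              / (EnC(x, y) + EnD(x, y)),

which lies in [-1, 1] and equals 1 where the bands agree.  Where S exceeds a
threshold T the bands are averaged with majority weight alpha_max on the
higher-energy band (alpha_min on the other, alpha_min + alpha_max = 1);
where S <= T the higher-energy coefficient is selected outright.  Energy
ties go to the first band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._util import as_band, check_same_shape

__all__ = ["EnergyConfig", "local_energy", "salience", "fuse_lf"]


@dataclass(frozen=True)
class EnergyConfig:
    """Tunables of the low-pass fusion rule."""

    template: np.ndarray = field(default_factory=lambda: np.ones((3, 3)))
    threshold: float = 0.5
    alpha_min: float = 0.3
    alpha_max: float = 0.7

    def __post_init__(self):
        t = np.asarray(self.template, dtype=np.float64)
        if t.shape != (3, 3) or np.any(t < 0):
            raise ValueError("template must be a nonnegative 3x3 grid")
        object.__setattr__(self, "template", t)
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if not (0.0 <= self.alpha_min <= 0.5 <= self.alpha_max <= 1.0):
            raise ValueError("alpha_min must be in [0, 0.5], alpha_max in [0.5, 1]")
        if abs(self.alpha_min + self.alpha_max - 1.0) > 1e-12:
            raise ValueError("alpha_min + alpha_max must equal 1")


def _window_sum(x: np.ndarray, template: np.ndarray) -> np.ndarray:
    # correlate with the 3x3 template, reflect-padded borders
    return ndimage.correlate(x, template, mode="reflect")


def local_energy(L, cfg: EnergyConfig = EnergyConfig()) -> np.ndarray:
    """Windowed energy of a band; nonnegative everywhere."""
    L = as_band(L)
    if L.shape[0] < 3 or L.shape[1] < 3:
        raise ValueError("band must be at least 3x3")
    return _window_sum(L * L, cfg.template)


def salience(LC, LD, EnC, EnD, cfg: EnergyConfig = EnergyConfig()) -> np.ndarray:
    """Match measure in [-1, 1]; defined as 1 where both energies vanish."""
    LC, LD = as_band(LC), as_band(LD)
    EnC, EnD = np.asarray(EnC, float), np.asarray(EnD, float)
    check_same_shape(LC, LD, EnC, EnD)
    cross = 2.0 * _window_sum(LC * LD, cfg.template)
    denom = EnC + EnD
    s = np.where(denom < 1e-12, 1.0, cross / np.where(denom < 1e-12, 1.0, denom))
    return np.clip(s, -1.0, 1.0)


def fuse_lf(LC, LD, cfg: EnergyConfig = EnergyConfig()) -> np.ndarray:
    """Fuse two low-pass bands: salience-gated averaging or selection."""
    LC, LD = as_band(LC), as_band(LD)
    check_same_shape(LC, LD)
    enc = local_energy(LC, cfg)
    end = local_energy(LD, cfg)
    s = salience(LC, LD, enc, end, cfg)

    c_dominant = enc >= end  # ties go to the first band
    alpha_c = np.where(c_dominant, cfg.alpha_max, cfg.alpha_min)
    averaged = alpha_c * LC + (1.0 - alpha_c) * LD
    selected = np.where(c_dominant, LC, LD)
    return np.where(s > cfg.threshold, averaged, selected)
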