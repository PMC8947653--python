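"""Objective fusion-quality metrics.

Four standard measures compare a fused image F against its sources A and B:

* ``qfab`` — gradient-based edge-information transfer (Xydeas–Petrović
  style Q^{AB/F}): Sobel edge strength and orientation preservation are
  scored with sigmoids, combined multiplicatively, and averaged with the
  source edge strengths as weights.  1 means all source edges survive.
* ``crr`` — mean of the Pearson correlations corr(A, F) and corr(B, F).
* ``avg_gradient`` — mean gradient magnitude sqrt((dFx^2 + dFy^2) / 2) over
  interior pixels (forward differences); a sharpness proxy.
* ``nfab`` — fusion-artifact (noise) measure: the fraction of fused edge
  energy not explained by either source's edges, using the same
  preservation sigmoids as ``qfab``.  0 means every fused edge has a source
  counterpart; lower is better.

The sigmoid constants are exposed; they are normalized so that perfect
preservation scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._util import as_image, check_same_shape

__all__ = [
    "MetricsReport",
    "EdgeMetricConstants",
    "UndefinedMetricError",
    "qfab",
    "crr",
    "avg_gradient",
    "nfab",
    "evaluate",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


@dataclass(frozen=True)
class EdgeMetricConstants:
    """Sigmoid constants of the edge strength/orientation preservation model."""

    kappa_g: float = -10.0
    sigma_g: float = 0.5
    kappa_a: float = -20.0
    sigma_a: float = 0.75
    weight_power: float = 1.0  # exponent L on the edge-strength weights


@dataclass(frozen=True)
class MetricsReport:
    qfab: float
    crr: float
    ag: float
    nfab: float

    def as_dict(self) -> dict:
        return {"qfab": self.qfab, "crr": self.crr, "ag": self.ag, "nfab": self.nfab}


def _sobel(img: np.ndarray):
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    g = np.hypot(gx, gy)
    alpha = np.arctan2(gy, gx)
    # fold orientation to (-pi/2, pi/2]
    alpha = np.where(alpha > np.pi / 2, alpha - np.pi, alpha)
    alpha = np.where(alpha <= -np.pi / 2, alpha + np.pi, alpha)
    return g, alpha


def _preservation(g_s, a_s, g_f, a_f, c: EdgeMetricConstants):
    """Per-pixel edge preservation Q in [0, 1] of source (g_s, a_s) in F."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(g_s > g_f, g_f / g_s, g_s / g_f)
    both_zero = (g_s == 0) & (g_f == 0)
    ratio = np.where(both_zero, 1.0, np.where(np.isfinite(ratio), ratio, 0.0))
    angle = 1.0 - np.abs(a_s - a_f) / (np.pi / 2)
    # normalized so a perfectly preserved edge (ratio=1, angle=1) scores 1
    qg = (1.0 + np.exp(c.kappa_g * (1.0 - c.sigma_g))) / (
        1.0 + np.exp(c.kappa_g * (ratio - c.sigma_g))
    )
    qa = (1.0 + np.exp(c.kappa_a * (1.0 - c.sigma_a))) / (
        1.0 + np.exp(c.kappa_a * (angle - c.sigma_a))
    )
    return qg * qa


def qfab(A, B, F, constants: EdgeMetricConstants = EdgeMetricConstants()) -> float:
    """Edge-information transfer from sources A, B to fused F, in [0, 1]."""
    A, B, F = as_image(A, "A"), as_image(B, "B"), as_image(F, "F")
    check_same_shape(A, B, F)
    ga, aa = _sobel(A)
    gb, ab = _sobel(B)
    gf, af = _sobel(F)
    q_af = _preservation(ga, aa, gf, af, constants)
    q_bf = _preservation(gb, ab, gf, af, constants)
    wa = ga**constants.weight_power
    wb = gb**constants.weight_power
    denom = float((wa + wb).sum())
    if denom <= 0:
        raise UndefinedMetricError("both sources are constant; qfab undefined")
    return float((q_af * wa + q_bf * wb).sum() / denom)


def crr(A, B, F) -> float:
    """Mean Pearson correlation of F with each source, in [-1, 1]."""
    A, B, F = as_image(A, "A"), as_image(B, "B"), as_image(F, "F")
    check_same_shape(A, B, F)
    for name, img in (("A", A), ("B", B), ("F", F)):
        if img.std() < 1e-12:
            raise UndefinedMetricError(f"{name} is constant; correlation undefined")
    ca = np.corrcoef(A.ravel(), F.ravel())[0, 1]
    cb = np.corrcoef(B.ravel(), F.ravel())[0, 1]
    return float((ca + cb) / 2.0)


def avg_gradient(F) -> float:
    """Mean gradient magnitude sqrt((dx^2 + dy^2)/2), forward differences."""
    F = as_image(F, "F")
    if F.shape[0] < 2 or F.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    dx = F[:-1, 1:] - F[:-1, :-1]
    dy = F[1:, :-1] - F[:-1, :-1]
    return float(np.mean(np.sqrt((dx**2 + dy**2) / 2.0)))


def nfab(
    A,
    B,
    F,
    constants: EdgeMetricConstants = EdgeMetricConstants(),
    mode: str = "unexplained",
) -> float:
    """Fusion-artifact (noise) measure in [0, 1]; lower is better.

    mode="unexplained" (default): fraction of fused edge energy carried by
    edges poorly explained by both sources,
    sum g_F (1-Q^AF)(1-Q^BF) / sum g_F.  mode="masked" restricts the sum to
    artifact sites where the fused gradient strictly exceeds both source
    gradients.
    """
    A, B, F = as_image(A, "A"), as_image(B, "B"), as_image(F, "F")
    check_same_shape(A, B, F)
    ga, aa = _sobel(A)
    gb, ab = _sobel(B)
    gf, af = _sobel(F)
    q_af = _preservation(ga, aa, gf, af, constants)
    q_bf = _preservation(gb, ab, gf, af, constants)
    unexplained = (1.0 - q_af) * (1.0 - q_bf)
    if mode == "masked":
        unexplained = unexplained * ((gf > ga) & (gf > gb))
    elif mode != "unexplained":
        raise ValueError(f"unknown nfab mode {mode!r}")
    denom = float(gf.sum())
    if denom <= 0:
        return 0.0  # a constant fused image has no artificial edges
    return float(np.clip((gf * unexplained).sum() / denom, 0.0, 1.0))


def evaluate(A, B, F, constants: EdgeMetricConstants = EdgeMetricConstants()) -> MetricsReport:
    """Compute the full metric report for a fusion result."""
    return MetricsReport(
        qfab=qfab(A, B, F, constants),
        crr=crr(A, B, F),
        ag=avg_gradient(F),
        nfab=nfab(A, B, F, constants),
    )
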