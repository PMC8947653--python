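"""Edge-preserving guided image filter.

The filter fits, in every (2r+1)x(2r+1) window w_k, a local linear model
q = a_k * I + b_k between the guide I and the input p, with

    a_k = (mean(I p) - mean(I) mean(p)) / (var(I) + eps),
    b_k = mean(p) - a_k * mean(I),

and outputs q_i = mean over windows containing i of (a_k I_i + b_k).
Window means near the border are taken over the window's intersection with
the image (exact counts), the standard formulation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["guided_filter"]


def _box_sum(x: np.ndarray, r: int) -> np.ndarray:
    """Sum of x over the (2r+1)^2 window clipped to the image, via cumsums."""
    h, w = x.shape
    c = np.zeros((h + 1, w + 1))
    c[1:, 1:] = np.cumsum(np.cumsum(x, axis=0), axis=1)
    y0 = np.clip(np.arange(h) - r, 0, h)
    y1 = np.clip(np.arange(h) + r + 1, 0, h)
    x0 = np.clip(np.arange(w) - r, 0, w)
    x1 = np.clip(np.arange(w) + r + 1, 0, w)
    return c[np.ix_(y1, x1)] - c[np.ix_(y0, x1)] - c[np.ix_(y1, x0)] + c[np.ix_(y0, x0)]


def guided_filter(p: np.ndarray, guide: np.ndarray, r: int = 4, eps: float = 0.1) -> np.ndarray:
    """Filter ``p`` using ``guide`` as the edge reference.

    Parameters
    ----------
    p, guide:
        Same-shape 2-D arrays; the guide supplies the edges along which the
        output follows ``p``.
    r:
        Window radius in pixels.
    eps:
        Regularization; larger values mean stronger smoothing.
    """
    p = np.asarray(p, dtype=np.float64)
    guide = np.asarray(guide, dtype=np.float64)
    if p.shape != guide.shape or p.ndim != 2:
        raise ValueError("p and guide must be 2-D arrays of the same shape")
    if r < 1:
        raise ValueError("radius must be >= 1")

    n = _box_sum(np.ones_like(p), r)
    mean_i = _box_sum(guide, r) / n
    mean_p = _box_sum(p, r) / n
    corr_ii = _box_sum(guide * guide, r) / n
    corr_ip = _box_sum(guide * p, r) / n
    var_i = corr_ii - mean_i * mean_i
    cov_ip = corr_ip - mean_i * mean_p

    a = cov_ip / (var_i + eps)
    b = mean_p - a * mean_i
    mean_a = _box_sum(a, r) / n
    mean_b = _box_sum(b, r) / n
    return mean_a * guide + mean_b
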