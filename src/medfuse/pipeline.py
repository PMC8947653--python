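"""End-to-end CT/MRI fusion pipeline.

Stages, for each co-registered source pair (C, D):

1. Morphological enhancement (per channel for color inputs).
2. Decolorization to a single gray channel (PCA-based) when needed.
3. Undecimated shearlet decomposition of both images.
4. Per-band high-frequency fusion via the Siamese decision-map procedure;
   low-frequency fusion via the local-energy rule.
5. Inverse transform of (fused low band, fused high bands) — the
   transform-domain linear superposition — followed by display
   normalization to [0, 1].

The fused image is returned together with the objective quality metrics
computed against the (by default preprocessed) sources.  The pipeline is a
pure function of its inputs, the configuration and the network weights.
"""

from __future__ import annotations

import numpy as np

from . import hf_fusion, lf_fusion, lsist, metrics, preprocess
from .config import FusionConfig
from .grayspca import to_gray
from .hf_fusion import NetworkWeights
from .preprocess import StructuringElement

__all__ = ["preprocess_source", "fuse_images", "average_baseline", "normalize_output"]


def _as_float(img) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim not in (2, 3):
        raise ValueError(f"expected a 2-D or 3-channel image, got shape {img.shape}")
    return img


def preprocess_source(img, cfg: FusionConfig) -> np.ndarray:
    """Morphological enhancement followed by gray conversion."""
    img = _as_float(img)
    h, w = img.shape[:2]
    radius = cfg.preprocess.radius or StructuringElement.auto_radius(h, w)
    se = StructuringElement(shape=cfg.preprocess.shape, radius=radius)
    if img.ndim == 3:
        img = np.dstack(
            [preprocess.enhance(img[..., c], se, cfg.preprocess.variant) for c in range(img.shape[2])]
        )
        if cfg.grayspca_enabled:
            img = to_gray(img)
        else:
            img = img.mean(axis=2)
    else:
        img = preprocess.enhance(img, se, cfg.preprocess.variant)
    return img


def normalize_output(img: np.ndarray, mode: str) -> np.ndarray:
    """Display normalization of the reconstructed image.

    "anchored" (default): affine rescale over the window
    [min(0, min), max(1, max)] — the identity whenever the reconstruction
    already lies in [0, 1], a pure contraction on overshoot.  "minmax":
    strict min-max rescale.  "clip": clamp.  "none": raw values.
    """
    if mode == "none":
        return img
    if mode == "clip":
        return np.clip(img, 0.0, 1.0)
    if mode == "minmax":
        lo, hi = float(img.min()), float(img.max())
        return np.zeros_like(img) if hi - lo < 1e-12 else (img - lo) / (hi - lo)
    if mode == "anchored":
        lo = min(0.0, float(img.min()))
        hi = max(1.0, float(img.max()))
        return (img - lo) / (hi - lo)
    raise ValueError(f"unknown normalization mode {mode!r}")


def _fuse_high_bands(pyr_c, pyr_d, guide, weights, cfg: FusionConfig):
    """Decision-map fusion of every (scale, direction) high-band pair."""
    hfc = cfg.hf
    fused = []
    for s in range(pyr_c.scales):
        bands_c = np.stack(pyr_c.high[s])
        bands_d = np.stack(pyr_d.high[s])
        maps = hf_fusion.score_maps(weights, bands_c, bands_d, chunk=hfc.chunk)
        if not hfc.per_band:  # one shared map per scale: average over directions
            maps = np.repeat(maps.mean(axis=0, keepdims=True), maps.shape[0], axis=0)
        out_scale = []
        for m, ch, dh in zip(maps, bands_c, bands_d):
            b = hf_fusion.initial_segment(m, hfc.segment_threshold)
            bv = hf_fusion.consistency_verify(b, hfc.consistency_window)
            dm = hf_fusion.refine_decision(bv, guide, r=hfc.guided_r, eps=hfc.guided_eps)
            out_scale.append(hf_fusion.fuse_hf(dm, ch, dh))
        fused.append(out_scale)
    return fused


def fuse_images(img_c, img_d, cfg: FusionConfig = FusionConfig(), weights: NetworkWeights = None):
    """Fuse a co-registered image pair; returns (fused, MetricsReport)."""
    if weights is None:
        raise RuntimeError("trained network weights are required for fusion")
    img_c, img_d = _as_float(img_c), _as_float(img_d)
    if img_c.shape[:2] != img_d.shape[:2]:
        raise ValueError("source images must share spatial dimensions")

    pre_c = preprocess_source(img_c, cfg)
    pre_d = preprocess_source(img_d, cfg)

    pad = cfg.lsist.pad if cfg.lsist.boundary == "symmetric" else 0
    wc = np.pad(pre_c, pad, mode="symmetric") if pad else pre_c
    wd = np.pad(pre_d, pad, mode="symmetric") if pad else pre_d

    pyr_c = lsist.decompose(wc, cfg.lsist.scales, cfg.lsist.directions)
    pyr_d = lsist.decompose(wd, cfg.lsist.scales, cfg.lsist.directions)

    fused_high = _fuse_high_bands(pyr_c, pyr_d, wc, weights, cfg)
    fused_low = lf_fusion.fuse_lf(pyr_c.low, pyr_d.low, cfg.lf)

    fused_pyr = lsist.SubbandPyramid(
        low=fused_low,
        high=fused_high,
        scales=cfg.lsist.scales,
        directions_per_scale=tuple(cfg.lsist.directions),
    )
    fused = lsist.reconstruct(fused_pyr)
    if pad:
        fused = fused[pad:-pad, pad:-pad]
    fused = normalize_output(fused, cfg.normalization)

    ref_c, ref_d = (pre_c, pre_d) if cfg.metrics_on == "preprocessed" else (
        to_gray(img_c),
        to_gray(img_d),
    )
    report = metrics.evaluate(ref_c, ref_d, np.clip(fused, 0.0, 1.0))
    return fused, report


def average_baseline(img_c, img_d, cfg: FusionConfig = FusionConfig()):
    """Pixelwise-average fusion of the preprocessed sources (reference
    baseline for comparisons); returns (fused, MetricsReport)."""
    pre_c = preprocess_source(_as_float(img_c), cfg)
    pre_d = preprocess_source(_as_float(img_d), cfg)
    fused = normalize_output((pre_c + pre_d) / 2.0, cfg.normalization)
    ref_c, ref_d = (pre_c, pre_d) if cfg.metrics_on == "preprocessed" else (
        to_gray(_as_float(img_c)),
        to_gray(_as_float(img_d)),
    )
    report = metrics.evaluate(ref_c, ref_d, np.clip(fused, 0.0, 1.0))
    return fused, report
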