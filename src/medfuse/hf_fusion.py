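"""High-frequency sub-band fusion with a Siamese clarity classifier.

Each pair of corresponding high-pass bands (Ch from source C, Dh from source
D) is fused in four steps:

1. *Feature detection* — the two-branch shared-weight CNN scores every
   16x16 block pair with the probability that the C-side block is the
   clearer one; block scores are redistributed to pixel resolution by
   averaging over overlapping blocks, giving a feature map M in [0, 1].
2. *Initial segmentation* — choose-max threshold: B = 1 where M > 0.5.
3. *Consistency verification* — 8x8 sliding-window majority vote removes
   isolated misclassified pixels ("singularity points").
4. *Refinement and compositing* — a guided filter (r = 4, eps = 0.1, guided
   by the preprocessed source image) turns the binary map into a smooth
   decision map Dm, and the fused band is the convex combination
   Fh = Dm*Ch + (1 - Dm)*Dh on the raw coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import _cnn
from ._util import as_band, check_same_shape
from .guided import guided_filter
from .phantoms import PatchPairSet

__all__ = [
    "NetworkConfig",
    "NetworkWeights",
    "train_network",
    "feature_detect",
    "score_maps",
    "initial_segment",
    "consistency_verify",
    "refine_decision",
    "fuse_hf",
]

_BLOCK = 16  # receptive field of one score, in pixels
_STRIDE = 2  # score-map stride in input pixels (one 2x2 pool stage)


@dataclass(frozen=True)
class NetworkConfig:
    """Training configuration; the architecture constants are fixed."""

    learning_rate: float = 0.01
    epochs: int = 10
    batch_size: int = 128
    weight_decay: float = 1e-5
    momentum: float = 0.9
    seed: int = 0
    holdout_fraction: float = 0.2

    # fixed architecture (read-only, for introspection)
    conv_filters: tuple = (64, 128, 256)
    kernel: int = 3
    stride: int = 1
    pool: int = 2

    def __post_init__(self):
        if self.conv_filters != (64, 128, 256) or self.kernel != 3 or self.stride != 1 or self.pool != 2:
            raise ValueError("architecture constants are fixed")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid epochs/batch_size")


@dataclass
class NetworkWeights:
    """Shared-branch and head parameters plus training provenance."""

    params: dict
    training_seed: int
    training_metrics: dict = field(default_factory=dict)

    def save(self, path) -> None:
        meta = json.dumps(
            {"training_seed": self.training_seed, "training_metrics": self.training_metrics}
        )
        np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path) -> "NetworkWeights":
        with np.load(path) as z:
            meta = json.loads(bytes(z["_meta"]).decode())
            params = {k: z[k] for k in z.files if k != "_meta"}
        return cls(
            params=params,
            training_seed=meta["training_seed"],
            training_metrics=meta["training_metrics"],
        )


def _softmax_loss_grad(logits: np.ndarray, labels: np.ndarray):
    p = _cnn.softmax(logits)
    n = len(labels)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(_cnn.F32)


def _accuracy(params: dict, xa, xb, labels, batch: int = 256) -> float:
    hits = 0
    for i in range(0, len(labels), batch):
        logits, _ = _cnn.pair_logits(params, xa[i : i + batch], xb[i : i + batch], need_cache=False)
        hits += int((logits.argmax(axis=1) == labels[i : i + batch]).sum())
    return hits / len(labels)


def train_network(patches: PatchPairSet, cfg: NetworkConfig = NetworkConfig()) -> NetworkWeights:
    """Train the clarity classifier on labeled (sharp, blurred) patch pairs.

    SGD with momentum and weight decay on the soft-max cross-entropy;
    deterministic under ``cfg.seed`` (fixed initialization and shuffling
    streams).  A ``cfg.holdout_fraction`` split is held out and its accuracy
    recorded in ``training_metrics``.
    """
    if patches.patch_size < 16:
        raise ValueError("patch size must be >= 16 (one pooling stage, 16x16 protocol)")
    if len(patches) < 500:
        raise ValueError("need at least 500 patch pairs")

    xa = patches.patch_a[:, :, :, None].astype(_cnn.F32)
    xb = patches.patch_b[:, :, :, None].astype(_cnn.F32)
    labels = np.asarray(patches.label, dtype=np.int64)

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(labels))
    n_val = max(1, int(round(cfg.holdout_fraction * len(labels))))
    val, train = order[:n_val], order[n_val:]

    params = _cnn.init_params(rng)
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    final_loss = float("nan")
    for _ in range(cfg.epochs):
        perm = train[rng.permutation(len(train))]
        losses = []
        for i in range(0, len(perm), cfg.batch_size):
            idx = perm[i : i + cfg.batch_size]
            logits, cache = _cnn.pair_logits(params, xa[idx], xb[idx])
            loss, dlogits = _softmax_loss_grad(logits, labels[idx])
            grads = _cnn.pair_backward(params, dlogits, cache)
            _cnn.sgd_step(params, grads, velocity, cfg.learning_rate, cfg.momentum, cfg.weight_decay)
            losses.append(loss)
        final_loss = float(np.mean(losses))

    metrics = {
        "final_loss": final_loss,
        "holdout_accuracy": _accuracy(params, xa[val], xb[val], labels[val]),
        "n_train": int(len(train)),
        "n_holdout": int(len(val)),
    }
    return NetworkWeights(params=params, training_seed=cfg.seed, training_metrics=metrics)


def _normalize01(band: np.ndarray) -> np.ndarray:
    lo, hi = band.min(), band.max()
    return (band - lo) / (hi - lo + 1e-12)


def _anchored_sum(u: np.ndarray, k: int) -> np.ndarray:
    """out[.., x, y] = sum of u over the kxk block whose bottom-right corner
    is (x, y), clipped at the array edge."""
    c = np.cumsum(np.cumsum(u, axis=-2), axis=-1)
    c = np.pad(c, [(0, 0)] * (u.ndim - 2) + [(1, 0), (1, 0)])
    h, w = u.shape[-2:]
    y1 = np.arange(h) + 1
    y0 = np.clip(y1 - k, 0, None)
    x1 = np.arange(w) + 1
    x0 = np.clip(x1 - k, 0, None)
    return (
        c[..., y1[:, None], x1[None, :]]
        - c[..., y0[:, None], x1[None, :]]
        - c[..., y1[:, None], x0[None, :]]
        + c[..., y0[:, None], x0[None, :]]
    )


def score_maps(weights: NetworkWeights, bands_c: np.ndarray, bands_d: np.ndarray, chunk: int = 4) -> np.ndarray:
    """Dense feature maps for a stack of band pairs.

    ``bands_c``/``bands_d`` have shape (K, H, W); returns (K, H, W) maps in
    [0, 1], the per-pixel probability that the C band's 16x16 neighborhood
    is the clearer one, averaged over overlapping blocks.
    """
    bands_c = np.asarray(bands_c, dtype=np.float64)
    bands_d = np.asarray(bands_d, dtype=np.float64)
    if bands_c.shape != bands_d.shape or bands_c.ndim != 3:
        raise ValueError("band stacks must share a (K, H, W) shape")
    k_total, h, w = bands_c.shape
    if h < _BLOCK or w < _BLOCK:
        raise ValueError("bands must be at least 16x16")

    params = weights.params
    out = np.empty((k_total, h, w))
    for i0 in range(0, k_total, chunk):
        xc = np.stack([_normalize01(b) for b in bands_c[i0 : i0 + chunk]])[..., None].astype(_cnn.F32)
        xd = np.stack([_normalize01(b) for b in bands_d[i0 : i0 + chunk]])[..., None].astype(_cnn.F32)
        nb = xc.shape[0]
        feats = _cnn.branch_infer(params, np.concatenate([xc, xd]))
        feat = np.concatenate([feats[:nb], feats[nb:]], axis=3)
        logits = _cnn.conv_infer(feat, params["head_w"], params["head_b"])
        z = logits - logits.max(axis=3, keepdims=True)
        e = np.exp(z)
        prob = e[..., 1] / e.sum(axis=3)  # (n, Hs, Ws), class 1 = C clearer

        n, hs, ws = prob.shape
        up = np.zeros((n, h, w))
        up[:, : _STRIDE * hs : _STRIDE, : _STRIDE * ws : _STRIDE] = prob
        acc = _anchored_sum(up, _BLOCK)
        ones = np.zeros((1, h, w))
        ones[:, : _STRIDE * hs : _STRIDE, : _STRIDE * ws : _STRIDE] = 1.0
        cnt = _anchored_sum(ones, _BLOCK)
        m = np.where(cnt > 0, acc / np.where(cnt > 0, cnt, 1.0), 0.0)
        # trailing rows/cols without coverage (odd sizes): replicate nearest
        covered_y = np.flatnonzero(cnt[0].max(axis=1) > 0)
        covered_x = np.flatnonzero(cnt[0].max(axis=0) > 0)
        if len(covered_y) < h:
            m[:, covered_y[-1] + 1 :, :] = m[:, covered_y[-1] : covered_y[-1] + 1, :]
        if len(covered_x) < w:
            m[:, :, covered_x[-1] + 1 :] = m[:, :, covered_x[-1] : covered_x[-1] + 1]
        out[i0 : i0 + chunk] = m
    return np.clip(out, 0.0, 1.0)


def feature_detect(weights: NetworkWeights, Ch, Dh) -> np.ndarray:
    """Feature map M in [0, 1] for one band pair (see :func:`score_maps`)."""
    Ch, Dh = as_band(Ch, "Ch"), as_band(Dh, "Dh")
    check_same_shape(Ch, Dh)
    return score_maps(weights, Ch[None], Dh[None])[0]


def initial_segment(M, threshold: float = 0.5) -> np.ndarray:
    """Choose-max binary map: 1 where M > threshold (strict), else 0."""
    M = np.asarray(M, dtype=np.float64)
    if M.min() < 0 or M.max() > 1:
        raise ValueError("feature map values must lie in [0, 1]")
    return (M > threshold).astype(np.float64)


def consistency_verify(B, window: int = 8) -> np.ndarray:
    """Majority vote over a sliding ``window`` x ``window`` neighborhood.

    For even windows the extra row/column lies toward lower indices; exact
    50/50 ties keep the original pixel.  Borders are reflect-padded.
    """
    B = np.asarray(B, dtype=np.float64)
    if not np.isin(B, (0.0, 1.0)).all():
        raise ValueError("binary map must contain only 0 and 1")
    counts = ndimage.correlate(B, np.ones((window, window)), mode="reflect")
    half = window * window / 2.0
    out = np.where(counts > half, 1.0, np.where(counts < half, 0.0, B))
    return out


def refine_decision(B_v, guide, r: int = 4, eps: float = 0.1) -> np.ndarray:
    """Guided-filter refinement of the verified map into a decision map Dm.

    The guide is the preprocessed source intensity image, which supplies the
    edges along which the decision boundary is smoothed; output in [0, 1].
    """
    B_v = np.asarray(B_v, dtype=np.float64)
    guide = np.asarray(guide, dtype=np.float64)
    if B_v.shape != guide.shape:
        raise ValueError("decision map and guide must share a shape")
    if guide.min() < 0 or guide.max() > 1:
        raise ValueError("guide must lie in [0, 1]")
    return np.clip(guided_filter(B_v, guide, r=r, eps=eps), 0.0, 1.0)


def fuse_hf(Dm, Ch, Dh) -> np.ndarray:
    """Convex compositing Fh = Dm*Ch + (1 - Dm)*Dh on raw coefficients."""
    Dm = np.asarray(Dm, dtype=np.float64)
    Ch, Dh = as_band(Ch, "Ch"), as_band(Dh, "Dh")
    check_same_shape(Dm, Ch, Dh)
    if Dm.min() < 0 or Dm.max() > 1:
        raise ValueError("decision map must lie in [0, 1]")
    return Dm * Ch + (1.0 - Dm) * Dh
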