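"""Minimal convolutional network engine (NumPy + BLAS, NHWC layout).

Implements exactly the two-branch clarity classifier used for high-frequency
fusion: three 3x3 stride-1 valid convolutions with 64, 128 and 256 filters,
ReLU activations, one 2x2 stride-2 max-pool after the second convolution,
and a 2-way soft-max head applied to the 512 concatenated feature maps of
the two (weight-shared) branches.  The head is a 4x4 convolution, which on
16x16 patches reduces to a fully-connected layer and on full-size inputs
produces a dense score map with a 16x16 receptive field and stride 2.

Convolutions are evaluated as im2col + GEMM in float32.  Arrays are NHWC and
the patch matrix is assembled from k*k contiguous block copies, so the run
time is dominated by BLAS.  Kernels are stored as (k, k, C_in, C_out).
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H-k+1, W-k+1, k*k*C) patch matrix."""
    n, h, w, c = x.shape
    ho, wo = h - k + 1, w - k + 1
    cols = np.empty((n, ho, wo, k * k * c), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[..., (i * k + j) * c : (i * k + j + 1) * c] = x[:, i : i + ho, j : j + wo, :]
    return cols


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid convolution; w has shape (k, k, C_in, C_out)."""
    k = w.shape[0]
    cols = im2col(x, k)
    n, ho, wo, ck = cols.shape
    out = cols.reshape(-1, ck) @ w.reshape(ck, w.shape[3])
    out += b
    return out.reshape(n, ho, wo, w.shape[3]), (cols, x.shape, w)


def conv_backward(dout: np.ndarray, cache, need_dx: bool = True):
    cols, x_shape, w = cache
    k, _, c, f = w.shape
    n, ho, wo, _ = dout.shape
    dflat = dout.reshape(-1, f)
    dw = (cols.reshape(-1, k * k * c).T @ dflat).reshape(w.shape)
    db = dflat.sum(axis=0)
    if not need_dx:
        return None, dw, db
    # input gradient: full correlation of dout with 180-degree-flipped kernels
    pad = k - 1
    dpad = np.zeros((n, ho + 2 * pad, wo + 2 * pad, f), dtype=dout.dtype)
    dpad[:, pad : pad + ho, pad : pad + wo, :] = dout
    cols_d = im2col(dpad, k)  # N, H, W, k*k*F
    wflip = w[::-1, ::-1].transpose(0, 1, 3, 2).reshape(k * k * f, c)
    dx = cols_d.reshape(-1, k * k * f) @ wflip
    return dx.reshape(x_shape), dw, db


def conv_infer(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid convolution without the patch-matrix buffer (inference only):
    nine accumulated batched GEMMs on shifted views."""
    k = w.shape[0]
    n, h, wid, _ = x.shape
    ho, wo = h - k + 1, wid - k + 1
    out = np.empty((n, ho, wo, w.shape[3]), dtype=x.dtype)
    out[:] = b
    for i in range(k):
        for j in range(k):
            out += np.matmul(x[:, i : i + ho, j : j + wo, :], w[i, j])
    return out


def branch_infer(params: dict, x: np.ndarray) -> np.ndarray:
    """Memory-lean forward pass of one branch (no caches, in-place ReLU)."""
    x = conv_infer(x, params["conv1_w"], params["conv1_b"])
    np.maximum(x, 0, out=x)
    x = conv_infer(x, params["conv2_w"], params["conv2_b"])
    np.maximum(x, 0, out=x)
    x, _ = maxpool_forward(x)
    x = conv_infer(x, params["conv3_w"], params["conv3_b"])
    np.maximum(x, 0, out=x)
    return x


def relu_forward(x):
    out = np.maximum(x, 0)
    return out, x > 0


def relu_backward(dout, mask):
    return dout * mask


def maxpool_forward(x: np.ndarray):
    """2x2 stride-2 max-pool on NHWC (odd trailing row/col truncated)."""
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    v = x[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
    v = np.ascontiguousarray(v.transpose(0, 1, 3, 5, 2, 4)).reshape(n, h2, w2, c, 4)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool_backward(dout: np.ndarray, cache):
    idx, x_shape = cache
    n, h, w, c = x_shape
    h2, w2 = h // 2, w // 2
    dv = np.zeros((n, h2, w2, c, 4), dtype=dout.dtype)
    np.put_along_axis(dv, idx[..., None], dout[..., None], axis=-1)
    dv = dv.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, : h2 * 2, : w2 * 2, :] = dv.reshape(n, h2 * 2, w2 * 2, c)
    return dx


ARCH = {"filters": (64, 128, 256), "kernel": 3, "head_kernel": 4, "classes": 2}


def init_params(rng: np.random.Generator) -> dict:
    """He-normal initialization of all shared-branch and head parameters."""
    f1, f2, f3 = ARCH["filters"]
    k, hk = ARCH["kernel"], ARCH["head_kernel"]

    def he(shape):
        fan_in = shape[0] * shape[1] * shape[2]
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)

    return {
        "conv1_w": he((k, k, 1, f1)),
        "conv1_b": np.zeros(f1, dtype=F32),
        "conv2_w": he((k, k, f1, f2)),
        "conv2_b": np.zeros(f2, dtype=F32),
        "conv3_w": he((k, k, f2, f3)),
        "conv3_b": np.zeros(f3, dtype=F32),
        "head_w": he((hk, hk, 2 * f3, ARCH["classes"])),
        "head_b": np.zeros(ARCH["classes"], dtype=F32),
    }


def branch_forward(params: dict, x: np.ndarray, need_cache: bool = True):
    """One shared-weight branch: conv-relu, conv-relu, pool, conv-relu.

    ``x`` is NHWC with one channel; output is NHWC with 256 channels.
    """
    c1, cc1 = conv_forward(x, params["conv1_w"], params["conv1_b"])
    r1, m1 = relu_forward(c1)
    c2, cc2 = conv_forward(r1, params["conv2_w"], params["conv2_b"])
    r2, m2 = relu_forward(c2)
    p, cp = maxpool_forward(r2)
    c3, cc3 = conv_forward(p, params["conv3_w"], params["conv3_b"])
    r3, m3 = relu_forward(c3)
    cache = (cc1, m1, cc2, m2, cp, cc3, m3) if need_cache else None
    return r3, cache


def branch_backward(params: dict, dout: np.ndarray, cache):
    cc1, m1, cc2, m2, cp, cc3, m3 = cache
    grads = {}
    d = relu_backward(dout, m3)
    d, grads["conv3_w"], grads["conv3_b"] = conv_backward(d, cc3)
    d = maxpool_backward(d, cp)
    d = relu_backward(d, m2)
    d, grads["conv2_w"], grads["conv2_b"] = conv_backward(d, cc2)
    d = relu_backward(d, m1)
    _, grads["conv1_w"], grads["conv1_b"] = conv_backward(d, cc1, need_dx=False)
    return grads


def head_forward(params: dict, feat: np.ndarray):
    """4x4 soft-max head as a convolution over concatenated features."""
    return conv_forward(feat, params["head_w"], params["head_b"])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def pair_logits(params: dict, xa: np.ndarray, xb: np.ndarray, need_cache=True):
    """Logits (N, 2) for NHWC patch batches; class 1 = first patch sharper.

    Both branches share weights, so the two batches run as one stacked pass.
    """
    n = xa.shape[0]
    feats, cache_b = branch_forward(params, np.concatenate([xa, xb]), need_cache)
    feat = np.concatenate([feats[:n], feats[n:]], axis=3)
    out, ch = head_forward(params, feat)
    logits = out.reshape(n, -1)
    cache = (cache_b, ch, feats.shape[3], n) if need_cache else None
    return logits, cache


def pair_backward(params: dict, dlogits: np.ndarray, cache):
    cache_b, ch, n_ch, n = cache
    dout = dlogits.reshape(dlogits.shape[0], 1, 1, -1).astype(F32)
    dfeat, dw_h, db_h = conv_backward(dout, ch)
    dstack = np.concatenate([dfeat[..., :n_ch], dfeat[..., n_ch:]])
    grads = branch_backward(params, dstack, cache_b)
    grads["head_w"], grads["head_b"] = dw_h, db_h
    return grads


def sgd_step(params, grads, velocity, lr, momentum, weight_decay):
    for k in params:
        g = grads[k] + weight_decay * params[k]
        velocity[k] = momentum * velocity[k] - lr * g
        params[k] += velocity[k]
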