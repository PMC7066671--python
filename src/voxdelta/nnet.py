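"""Minimal NumPy engine for the 3D-convolutional encoder.

Implements exactly the layers the twin network needs — 3D convolution
(kernel 3, stride 1, zero padding 1), ReLU, 2x2x2 max-pooling, global
max-pooling, inverted dropout — with explicit backward passes, plus Glorot
(Xavier) initialization and the Adam optimizer.  Convolutions are evaluated
as batched matrix products over im2col patch matrices; the batch is processed
in chunks so the transient patch buffer stays within a fixed memory budget.
"""

from __future__ import annotations

import numpy as np

# Transient im2col buffers are capped at ~256 MB.
_PATCH_BUDGET_BYTES = 256e6


def xavier_uniform(shape, fan_in: int, fan_out: int, rng, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _chunks(n: int, size: int):
    for start in range(0, n, size):
        yield slice(start, min(start + size, n))


def conv3d_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """3D convolution, kernel 3, stride 1, padding 1.

    x: [B, C, D, H, W]; weight: [F, C, 3, 3, 3]; bias: [F] -> [B, F, D, H, W].
    Evaluated as 27 shifted-slice matrix products, which avoids materializing
    the full im2col patch tensor.
    """
    batch, c_in, d, h, w = x.shape
    f = weight.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    out = np.empty((batch, f, d, h, w), dtype=x.dtype)
    per_sample = d * h * w * max(c_in, f) * x.dtype.itemsize
    chunk = max(1, int(_PATCH_BUDGET_BYTES / per_sample))
    for sl in _chunks(batch, chunk):
        bsz = min(sl.stop, batch) - sl.start
        acc = np.zeros((bsz, d * h * w, f), dtype=x.dtype)
        acc += bias
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    xs = xp[sl, :, i : i + d, j : j + h, k : k + w].reshape(
                        bsz, c_in, -1)
                    acc += xs.transpose(0, 2, 1) @ weight[:, :, i, j, k].T
        out[sl] = acc.reshape(bsz, d, h, w, f).transpose(0, 4, 1, 2, 3)
    return out


def conv3d_backward(x: np.ndarray, weight: np.ndarray, dout: np.ndarray,
                    need_dx: bool = True):
    """Gradients of conv3d_forward; returns (dx, dweight, dbias).

    The input gradient of a stride-1, pad-1 convolution is itself such a
    convolution of ``dout`` with the spatially flipped, channel-transposed
    kernel, so both directions share the shifted-slice GEMM path.
    """
    batch, c_in, d, h, w = x.shape
    f = weight.shape[0]
    dbias = dout.sum(axis=(0, 2, 3, 4))

    dweight = np.zeros_like(weight)
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    per_sample = d * h * w * max(c_in, f) * x.dtype.itemsize
    chunk = max(1, int(_PATCH_BUDGET_BYTES / per_sample))
    for sl in _chunks(batch, chunk):
        bsz = min(sl.stop, batch) - sl.start
        dout_f = dout[sl].transpose(1, 0, 2, 3, 4).reshape(f, -1)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    xs = xp[sl, :, i : i + d, j : j + h, k : k + w].transpose(
                        1, 0, 2, 3, 4).reshape(c_in, -1)
                    dweight[:, :, i, j, k] += dout_f @ xs.T

    dx = None
    if need_dx:
        wflip = np.ascontiguousarray(
            weight[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
        dx = conv3d_forward(dout, wflip, np.zeros(c_in, dtype=x.dtype))
    return dx, dweight, dbias


def relu_forward(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def relu_backward(out: np.ndarray, dout: np.ndarray) -> np.ndarray:
    return dout * (out > 0)


def maxpool2_forward(x: np.ndarray):
    """Non-overlapping 2x2x2 max pool; spatial dims must be even."""
    b, f, d, h, w = x.shape
    xr = (
        x.reshape(b, f, d // 2, 2, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 6, 3, 5, 7)
        .reshape(b, f, d // 2, h // 2, w // 2, 8)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def maxpool2_backward(dout: np.ndarray, idx: np.ndarray, in_shape) -> np.ndarray:
    b, f, d, h, w = in_shape
    dxr = np.zeros((b, f, d // 2, h // 2, w // 2, 8), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    return (
        dxr.reshape(b, f, d // 2, h // 2, w // 2, 2, 2, 2)
        .transpose(0, 1, 2, 5, 3, 6, 4, 7)
        .reshape(b, f, d, h, w)
    )


def global_maxpool_forward(x: np.ndarray):
    b, f = x.shape[:2]
    flat = x.reshape(b, f, -1)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return out, idx


def global_maxpool_backward(dout: np.ndarray, idx: np.ndarray, in_shape) -> np.ndarray:
    b, f = in_shape[:2]
    dflat = np.zeros((b, f, int(np.prod(in_shape[2:]))), dtype=dout.dtype)
    np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
    return dflat.reshape(in_shape)


def dropout_mask(shape, rate: float, rng, dtype) -> np.ndarray:
    """Inverted-dropout multiplier: 0 with probability ``rate``, else 1/(1-rate)."""
    if rate <= 0:
        return np.ones(shape, dtype=dtype)
    keep = (rng.random(shape) >= rate).astype(dtype)
    return keep / (1.0 - rate)


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-4):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(params[name])
                self.v[name] = np.zeros_like(params[name])
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Encoder:
    """Shared-weight convolutional leg: conv-ReLU x2, max-pool, conv-ReLU,
    global max-pool, flatten to a ``latent_dim``-vector."""

    def __init__(self, in_channels=18, conv_channels=(32, 64), latent_dim=192,
                 rng=None, dtype=np.float32):
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.in_channels = in_channels
        self.conv_channels = tuple(conv_channels)
        self.latent_dim = latent_dim
        self.dtype = np.dtype(dtype)
        c1, c2 = self.conv_channels
        self.params = {
            "conv1_w": xavier_uniform((c1, in_channels, 3, 3, 3),
                                      in_channels * 27, c1 * 27, rng, self.dtype),
            "conv1_b": np.zeros(c1, dtype=self.dtype),
            "conv2_w": xavier_uniform((c2, c1, 3, 3, 3), c1 * 27, c2 * 27, rng, self.dtype),
            "conv2_b": np.zeros(c2, dtype=self.dtype),
            "conv3_w": xavier_uniform((latent_dim, c2, 3, 3, 3),
                                      c2 * 27, latent_dim * 27, rng, self.dtype),
            "conv3_b": np.zeros(latent_dim, dtype=self.dtype),
        }

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Encode grids [B, C, D, H, W] -> latents [B, latent_dim]."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        p = self.params
        a1 = relu_forward(conv3d_forward(x, p["conv1_w"], p["conv1_b"]))
        a2 = relu_forward(conv3d_forward(a1, p["conv2_w"], p["conv2_b"]))
        pooled, pool_idx = maxpool2_forward(a2)
        a3 = relu_forward(conv3d_forward(pooled, p["conv3_w"], p["conv3_b"]))
        latent, gmax_idx = global_maxpool_forward(a3)
        if not want_cache:
            return latent
        cache = dict(x=x, a1=a1, a2=a2, pooled=pooled, pool_idx=pool_idx,
                     a3=a3, gmax_idx=gmax_idx)
        return latent, cache

    def backward(self, dlatent: np.ndarray, cache: dict) -> dict:
        """Backprop d(loss)/d(latent) -> parameter gradients."""
        p = self.params
        da3 = relu_backward(
            cache["a3"],
            global_maxpool_backward(dlatent.astype(self.dtype), cache["gmax_idx"],
                                    cache["a3"].shape),
        )
        dpooled, dw3, db3 = conv3d_backward(cache["pooled"], p["conv3_w"], da3)
        da2 = relu_backward(
            cache["a2"], maxpool2_backward(dpooled, cache["pool_idx"], cache["a2"].shape)
        )
        da1_in, dw2, db2 = conv3d_backward(cache["a1"], p["conv2_w"], da2)
        da1 = relu_backward(cache["a1"], da1_in)
        _, dw1, db1 = conv3d_backward(cache["x"], p["conv1_w"], da1, need_dx=False)
        return {"conv1_w": dw1, "conv1_b": db1, "conv2_w": dw2, "conv2_b": db2,
                "conv3_w": dw3, "conv3_b": db3}
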