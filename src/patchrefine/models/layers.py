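"""Minimal NumPy neural-network primitives (NCHW) with manual backprop.

Only what the tiny segmentation backbone needs: same-padded stride-1
convolutions, ReLU, 2x2 average pooling, 2x nearest upsampling, a stable
sigmoid, and Adam.  Convolutions are evaluated as a sum of shifted
tensordots over the kernel taps, which is fast for the 1x1/3x3 kernels
used here and keeps forward/backward symmetric and easy to audit.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv2d_forward",
    "conv2d_backward",
    "relu_forward",
    "relu_backward",
    "avgpool2_forward",
    "avgpool2_backward",
    "upsample2_forward",
    "upsample2_backward",
    "sigmoid",
    "Adam",
]


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded stride-1 convolution. x: (N,C,H,W), w: (O,C,k,k), b: (O,)."""
    k = w.shape[2]
    pad = k // 2
    n, _, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    out = np.zeros((n, w.shape[0], h, wd), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            # (N,C,H,W) x (O,C) -> (N,O,H,W)
            patch = xp[:, :, di : di + h, dj : dj + wd]
            out += np.tensordot(patch, w[:, :, di, dj], axes=([1], [1])).transpose(0, 3, 1, 2)
    return out + b.reshape(1, -1, 1, 1)


def conv2d_backward(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) of :func:`conv2d_forward`."""
    k = w.shape[2]
    pad = k // 2
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for di in range(k):
        for dj in range(k):
            patch = xp[:, :, di : di + h, dj : dj + wd]
            # dW: contract batch and spatial dims
            dw[:, :, di, dj] = np.tensordot(dout, patch, axes=([0, 2, 3], [0, 2, 3]))
            # dX: route dout back through the same tap
            dxp[:, :, di : di + h, dj : dj + wd] += np.tensordot(
                dout, w[:, :, di, dj], axes=([1], [0])
            ).transpose(0, 3, 1, 2)
    db = dout.sum(axis=(0, 2, 3))
    dx = dxp[:, :, pad : pad + h, pad : pad + wd] if pad else dxp
    return dx, dw, db


def relu_forward(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(x: np.ndarray, dout: np.ndarray) -> np.ndarray:
    return dout * (x > 0)


def avgpool2_forward(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"avgpool2 requires even spatial dims, got {h}x{w}")
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def avgpool2_backward(dout: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) * 0.25


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Standard Adam over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
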