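"""A small fully convolutional encoder-decoder that is cheap enough to
train on a CPU in seconds, used as the default backbone for both pipeline
stages in tests and desk-scale experiments.

Layout (same-padded, stride 1 everywhere; ~19k parameters)::

    conv3x3 3->16, relu
    avgpool 2x2
    conv3x3 16->32, relu
    conv3x3 32->32, relu
    nearest upsample x2
    conv3x3 32->16, relu      <- penultimate activation (context fusion site)
    conv1x1 16->1             -> logits

The penultimate activation is the input of the final 1x1 prediction
convolution; cross-stage context is fused there by elementwise addition.
"""

from __future__ import annotations

import numpy as np

from . import layers as L

__all__ = ["TinySegModel"]

_PENULTIMATE_CHANNELS = 16


class TinySegModel:
    """Trainable NumPy segmentation model satisfying the SegModel contract."""

    architecture_id = "tiny"
    penultimate_channels = _PENULTIMATE_CHANNELS

    def __init__(self, input_size: tuple[int, int], seed: int = 0):
        h, w = int(input_size[0]), int(input_size[1])
        if h % 2 or w % 2:
            raise ValueError(f"tiny model input size must be even, got {h}x{w}")
        self.input_size = (h, w)
        self.seed = seed
        rng = np.random.default_rng(seed)

        def he(shape):
            fan_in = shape[1] * shape[2] * shape[3]
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float64)

        self.params: dict[str, np.ndarray] = {
            "w1": he((16, 3, 3, 3)), "b1": np.zeros(16),
            "w2": he((32, 16, 3, 3)), "b2": np.zeros(32),
            "w3": he((32, 32, 3, 3)), "b3": np.zeros(32),
            "w4": he((16, 32, 3, 3)), "b4": np.zeros(16),
            "w5": he((1, 16, 1, 1)), "b5": np.zeros(1),
        }
        self.trainable = True

    # -- core NCHW batched forward/backward ---------------------------------

    def forward_batch(
        self, xb: np.ndarray, context: np.ndarray | None = None, need_cache: bool = False
    ):
        """xb: (N,3,H,W) floats in [0,1]; context: (N,16,H,W) or None.

        Returns (logits (N,H,W), penultimate (N,16,H,W)[, cache]).
        """
        p = self.params
        z1 = L.conv2d_forward(xb, p["w1"], p["b1"]); a1 = L.relu_forward(z1)
        d1 = L.avgpool2_forward(a1)
        z2 = L.conv2d_forward(d1, p["w2"], p["b2"]); a2 = L.relu_forward(z2)
        z3 = L.conv2d_forward(a2, p["w3"], p["b3"]); a3 = L.relu_forward(z3)
        u3 = L.upsample2_forward(a3)
        z4 = L.conv2d_forward(u3, p["w4"], p["b4"]); a4 = L.relu_forward(z4)
        pen = a4 if context is None else a4 + context
        z5 = L.conv2d_forward(pen, p["w5"], p["b5"])
        logits = z5[:, 0]
        if not need_cache:
            return logits, pen
        cache = (xb, z1, d1, z2, a2, z3, u3, z4, pen)
        return logits, pen, cache

    def backward_batch(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. all parameters given d(loss)/d(logits)."""
        xb, z1, d1, z2, a2, z3, u3, z4, pen = cache
        p = self.params
        d5 = dlogits[:, None]
        dpen, dw5, db5 = L.conv2d_backward(pen, p["w5"], d5)
        # the context branch is a frozen constant; its gradient is dropped
        dz4 = L.relu_backward(z4, dpen)
        du3, dw4, db4 = L.conv2d_backward(u3, p["w4"], dz4)
        da3 = L.upsample2_backward(du3)
        dz3 = L.relu_backward(z3, da3)
        da2, dw3, db3 = L.conv2d_backward(a2, p["w3"], dz3)
        dz2 = L.relu_backward(z2, da2)
        dd1, dw2, db2 = L.conv2d_backward(d1, p["w2"], dz2)
        da1 = L.avgpool2_backward(dd1)
        dz1 = L.relu_backward(z1, da1)
        _, dw1, db1 = L.conv2d_backward(xb, p["w1"], dz1)
        return {
            "w1": dw1, "b1": db1, "w2": dw2, "b2": db2, "w3": dw3, "b3": db3,
            "w4": dw4, "b4": db4, "w5": dw5, "b5": db5,
        }

    # -- public single-image API --------------------------------------------

    @staticmethod
    def _to_nchw(x: np.ndarray) -> np.ndarray:
        if x.ndim == 2:
            x = x[:, :, None]
        if x.shape[2] == 1:
            x = np.repeat(x, 3, axis=2)
        if x.shape[2] != 3:
            raise ValueError(f"expected 1 or 3 channels, got {x.shape[2]}")
        return x.transpose(2, 0, 1)[None].astype(np.float64)

    def forward(self, x: np.ndarray, context: np.ndarray | None = None):
        """Image (H,W,C) in [0,1] -> (logits (H,W), penultimate (H',W',C'))."""
        if x.shape[:2] != self.input_size:
            raise ValueError(
                f"input of shape {x.shape[:2]} does not match model input size {self.input_size}"
            )
        ctx = None if context is None else context.transpose(2, 0, 1)[None].astype(np.float64)
        logits, pen = self.forward_batch(self._to_nchw(x), ctx)
        return logits[0], pen[0].transpose(1, 2, 0)

    # -- bookkeeping ---------------------------------------------------------

    def param_shapes(self) -> dict[str, tuple[int, ...]]:
        return {k: v.shape for k, v in self.params.items()}

    def num_params(self, trainable_only: bool = True) -> int:
        if trainable_only and not self.trainable:
            return 0
        return int(sum(v.size for v in self.params.values()))

    def copy(self) -> "TinySegModel":
        other = TinySegModel(self.input_size, seed=self.seed)
        other.params = {k: v.copy() for k, v in self.params.items()}
        other.trainable = self.trainable
        return other

    def state_hash(self) -> int:
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return int.from_bytes(h.digest()[:8], "big")
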