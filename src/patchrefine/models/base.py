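"""The segmentation-model contract shared by both pipeline stages.

A SegModel maps an image (H, W, C) in [0, 1] to per-pixel logits of the
same spatial size plus its penultimate activation (the input of the final
prediction layer), where cross-stage context fusion happens.

The ``tiny`` backbone is a real trainable NumPy network.  The heavyweight
architectures (ResNet-50-encoder FCN / DeepLab v3 / U-Net / SegNet) are
represented analytically for parameter and FLOP accounting; running them
requires a GPU deep-learning runtime that is out of scope for this
package's offline test environment, so their ``forward`` raises.
"""

from __future__ import annotations

import json
from typing import Protocol, runtime_checkable

import numpy as np

from .counting import count_ops
from .tiny import TinySegModel

__all__ = [
    "SegModel",
    "build_model",
    "predict_probs",
    "count_params",
    "count_flops",
    "save_checkpoint",
    "load_checkpoint",
]

_ARCH_IDS = ("tiny", "fcn", "deeplabv3", "unet", "segnet")
_ENCODERS = ("tiny", "resnet50")


@runtime_checkable
class SegModel(Protocol):
    architecture_id: str
    input_size: tuple[int, int]

    def forward(self, x: np.ndarray, context: np.ndarray | None = None): ...


class AnalyticSegModel:
    """Shape-level stand-in for the heavy backbones: counts, no forward."""

    def __init__(self, architecture_id: str, input_size: tuple[int, int], seed: int = 0):
        self.architecture_id = architecture_id
        self.input_size = (int(input_size[0]), int(input_size[1]))
        self.seed = seed
        self.trainable = True

    def forward(self, x, context=None):
        raise NotImplementedError(
            f"{self.architecture_id!r} is available for parameter/FLOP accounting only; "
            "running it requires a deep-learning runtime (use --arch tiny for inference)"
        )

    def num_params(self, trainable_only: bool = True) -> int:
        if trainable_only and not self.trainable:
            return 0
        return count_ops(self.architecture_id, self.input_size).params


def build_model(
    architecture_id: str,
    input_size: tuple[int, int],
    encoder: str = "tiny",
    pretrained: bool = False,
    seed: int = 0,
):
    """Instantiate a segmentation model.

    ``tiny`` returns the trainable NumPy backbone; the other ids return
    analytic models for op accounting.  ``pretrained`` would fetch ImageNet
    encoder weights over the network and is rejected in this offline build.
    """
    if architecture_id not in _ARCH_IDS:
        raise ValueError(f"unknown architecture {architecture_id!r}; choose from {_ARCH_IDS}")
    if encoder not in _ENCODERS:
        raise ValueError(f"unknown encoder {encoder!r}; choose from {_ENCODERS}")
    if pretrained:
        raise NotImplementedError("pretrained encoder weights require a network download")
    if architecture_id == "tiny":
        return TinySegModel(input_size, seed=seed)
    return AnalyticSegModel(architecture_id, input_size, seed=seed)


def predict_probs(m: SegModel, x: np.ndarray):
    """Run a model on one image: (ProbMap in (0,1), penultimate activation)."""
    logits, pen = m.forward(x)
    probs = 1.0 / (1.0 + np.exp(-np.clip(logits, -500, 500)))
    return probs, pen


def count_params(m, trainable_only: bool = True) -> int:
    """Number of (trainable) parameter elements of a model."""
    return int(m.num_params(trainable_only=trainable_only))


def count_flops(m, input_size: tuple[int, int] | None = None) -> int:
    """Analytic multiply-accumulate count of one forward pass."""
    size = m.input_size if input_size is None else input_size
    return count_ops(m.architecture_id, size).flops


# ---------------------------------------------------------------------------
# Checkpoints: single .npz with weights plus a JSON metadata blob
# ---------------------------------------------------------------------------

def save_checkpoint(m: TinySegModel, path) -> None:
    meta = {
        "architecture_id": m.architecture_id,
        "input_size": list(m.input_size),
        "seed": m.seed,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **m.params)


def load_checkpoint(path) -> TinySegModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["architecture_id"] != "tiny":
            raise ValueError(f"cannot load runtime weights for {meta['architecture_id']!r}")
        m = TinySegModel(tuple(meta["input_size"]), seed=meta["seed"])
        for k in m.params:
            m.params[k] = data[k].copy()
    return m
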