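"""Training recipe for both stages.

Stage 1 is trained to completion on downscaled whole images and then frozen.
Stage 2 is (optionally) initialized from stage 1's weights and trained on
one patch per image per epoch, sampled by the configured strategy from
stage-1 uncertainty recomputed on the augmented image; optional context is
the stage-1 penultimate activation, cropped and fused by addition.

The loss is focal loss on sigmoid probabilities,
``mean(-alpha_t * (1 - p_t)^gamma * log(p_t))`` with ``p_t = p`` for
foreground pixels and ``1 - p`` otherwise; ``gamma = 0, alpha = 1`` reduces
it to plain binary cross-entropy.  Probabilities are clamped to
``[1e-7, 1 - 1e-7]`` before the logarithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import PatchGrid, crop, downscale, resize_mask, upscale
from .models.layers import Adam, sigmoid
from .models.tiny import TinySegModel
from .pipeline import context_features
from .uncertainty import SelectionConfig, patch_scores, sample_training_patch

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "AugmentConfig",
    "TrainResult",
    "focal_loss",
    "focal_loss_grad",
    "augment",
    "train_stage1",
    "init_stage2_from_stage1",
    "train_stage2",
]

_EPS = 1e-7


@dataclass(frozen=True)
class AugmentConfig:
    hflip_prob: float = 0.5
    jitter_brightness: float = 0.1
    jitter_contrast: float = 0.1
    translate_frac: float = 0.1

    def __post_init__(self) -> None:
        for name in ("hflip_prob", "jitter_brightness", "jitter_contrast", "translate_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"AugmentConfig.{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 20
    batch_size: int = 4
    focal_gamma: float = 2.0
    focal_alpha: float = 1.0  # 1 = unweighted
    image_size: tuple[int, int] = (768, 768)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")


@dataclass
class TrainResult:
    model: TinySegModel
    loss_history: list[float]
    sampled_patches: dict[tuple[int, int], int] | None = None


# ---------------------------------------------------------------------------
# Focal loss
# ---------------------------------------------------------------------------

def _alpha_t(y: np.ndarray, alpha: float) -> np.ndarray:
    if alpha >= 1.0:
        return np.ones_like(y, dtype=np.float64)
    return np.where(y == 1, alpha, 1.0 - alpha)


def focal_loss(p: np.ndarray, y: np.ndarray, gamma: float = 2.0, alpha: float = 1.0) -> float:
    """Mean focal loss of probabilities ``p`` against binary labels ``y``."""
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {y.shape}")
    pc = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    yb = np.asarray(y)
    pt = np.where(yb == 1, pc, 1.0 - pc)
    at = _alpha_t(yb, alpha)
    return float(np.mean(-at * (1.0 - pt) ** gamma * np.log(pt)))


def focal_loss_grad(logits: np.ndarray, y: np.ndarray, gamma: float, alpha: float):
    """(loss, d loss / d logits) for sigmoid probabilities; mean reduction."""
    p = np.clip(sigmoid(logits), _EPS, 1.0 - _EPS)
    yb = np.asarray(y)
    pt = np.where(yb == 1, p, 1.0 - p)
    at = _alpha_t(yb, alpha)
    one_m_pt = 1.0 - pt
    loss = float(np.mean(-at * one_m_pt**gamma * np.log(pt)))
    # dL/dpt, guarding the gamma * (1-pt)^(gamma-1) term at gamma = 0
    if gamma == 0.0:
        dl_dpt = -at / pt
    else:
        dl_dpt = at * (gamma * one_m_pt ** (gamma - 1.0) * np.log(pt) - one_m_pt**gamma / pt)
    dpt_dp = np.where(yb == 1, 1.0, -1.0)
    dlogits = dl_dpt * dpt_dp * p * (1.0 - p) / y.size
    return loss, dlogits


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment(x: np.ndarray, y: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator):
    """Paired augmentation: geometric transforms applied to image and mask
    identically, photometric jitter to the image only."""
    if x.shape[:2] != y.shape[:2]:
        raise ValueError(f"image/mask shapes differ: {x.shape[:2]} vs {y.shape}")
    h, w = y.shape

    if cfg.hflip_prob > 0 and rng.random() < cfg.hflip_prob:
        x = x[:, ::-1].copy()
        y = y[:, ::-1].copy()

    if cfg.translate_frac > 0:
        # translation as upscale followed by a random crop of the original size
        uh = int(round(h * (1.0 + cfg.translate_frac)))
        uw = int(round(w * (1.0 + cfg.translate_frac)))
        big_x = downscale(x, uh, uw)  # bilinear (same routine both directions)
        big_y = resize_mask(y, uh, uw)
        r0 = int(rng.integers(uh - h + 1))
        c0 = int(rng.integers(uw - w + 1))
        x = big_x[r0 : r0 + h, c0 : c0 + w]
        y = big_y[r0 : r0 + h, c0 : c0 + w]

    if cfg.jitter_brightness > 0:
        fb = 1.0 + rng.uniform(-cfg.jitter_brightness, cfg.jitter_brightness)
        x = np.clip(x * fb, 0.0, 1.0)
    if cfg.jitter_contrast > 0:
        fc = 1.0 + rng.uniform(-cfg.jitter_contrast, cfg.jitter_contrast)
        x = np.clip(x.mean() + fc * (x - x.mean()), 0.0, 1.0)
    return x, y


# ---------------------------------------------------------------------------
# Stage training
# ---------------------------------------------------------------------------

def _as_batch(items: list[np.ndarray]) -> np.ndarray:
    return np.stack([TinySegModel._to_nchw(v)[0] for v in items])


def _train_batches(model, batches, opt, cfg: TrainConfig) -> float:
    losses = []
    for xb, yb, ctxb in batches:
        logits, _, cache = model.forward_batch(xb, ctxb, need_cache=True)
        loss, dlogits = focal_loss_grad(logits, yb, cfg.focal_gamma, cfg.focal_alpha)
        grads = model.backward_batch(cache, dlogits)
        opt.step(grads)
        losses.append(loss)
    return float(np.mean(losses))


def train_stage1(model: TinySegModel, data, cfg: TrainConfig) -> TrainResult:
    """Train the coarse model on (downscale(image), resize(mask)) pairs.

    ``data`` is a sequence of (image HxWxC in [0,1], binary mask HxW) pairs.
    Returns the trained model plus the per-epoch mean loss history.
    """
    data = list(data)
    if not data:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params, lr=cfg.learning_rate)
    th, tw = model.input_size
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(data))
        batches = []
        buf_x, buf_y = [], []
        for k in order:
            x, y = data[k]
            x, y = augment(x, y, cfg.augment, rng)
            buf_x.append(downscale(x, th, tw))
            buf_y.append(resize_mask(y, th, tw))
            if len(buf_x) == cfg.batch_size:
                batches.append((_as_batch(buf_x), np.stack(buf_y), None))
                buf_x, buf_y = [], []
        if buf_x:
            batches.append((_as_batch(buf_x), np.stack(buf_y), None))
        history.append(_train_batches(model, batches, opt, cfg))
        logger.debug("stage1 epoch %d/%d loss %.4f", epoch + 1, cfg.epochs, history[-1])
    return TrainResult(model=model, loss_history=history)


def init_stage2_from_stage1(m1: TinySegModel) -> TinySegModel:
    """Deep-copied stage-2 initialization from trained stage-1 weights."""
    return m1.copy()


def train_stage2(
    m1: TinySegModel,
    m2: TinySegModel,
    data,
    grid: PatchGrid,
    strategy: str,
    cfg: TrainConfig,
    context: bool = True,
) -> TrainResult:
    """Train the refinement model on one sampled patch per image per epoch.

    ``m1`` is frozen: each epoch it scores the (augmented) image, the
    configured strategy samples one patch, and ``m2`` trains on the
    full-resolution crop with optional penultimate-context fusion.
    """
    data = list(data)
    if not data:
        raise ValueError("empty training set")
    sel = SelectionConfig(strategy=strategy, seed=cfg.seed)  # validates strategy
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(m2.params, lr=cfg.learning_rate)
    m1_hash = m1.state_hash()
    history: list[float] = []
    sampled: dict[tuple[int, int], int] = {}
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(data))
        batches = []
        buf_x, buf_y, buf_c = [], [], []
        for k in order:
            x, y = data[k]
            x, y = augment(x, y, cfg.augment, rng)
            small = downscale(x, m1.input_size[0], m1.input_size[1])
            logits1, pen1 = m1.forward(small)
            coarse = upscale(sigmoid(logits1), grid.image_h, grid.image_w)
            scores = patch_scores(coarse, grid, sel.variant)
            idx = sample_training_patch(scores, sel, rng)
            sampled[tuple(idx)] = sampled.get(tuple(idx), 0) + 1
            buf_x.append(crop(x, grid, idx))
            buf_y.append(crop(y, grid, idx))
            if context:
                ctx = context_features(pen1, grid, idx, m2.input_size)
                buf_c.append(ctx.transpose(2, 0, 1))
            if len(buf_x) == cfg.batch_size:
                ctxb = np.stack(buf_c) if context else None
                batches.append((_as_batch(buf_x), np.stack(buf_y), ctxb))
                buf_x, buf_y, buf_c = [], [], []
        if buf_x:
            ctxb = np.stack(buf_c) if context else None
            batches.append((_as_batch(buf_x), np.stack(buf_y), ctxb))
        history.append(_train_batches(m2, batches, opt, cfg))
        logger.debug("stage2 epoch %d/%d loss %.4f", epoch + 1, cfg.epochs, history[-1])
    if m1.state_hash() != m1_hash:
        raise RuntimeError("stage-1 weights changed during stage-2 training")
    return TrainResult(model=m2, loss_history=history, sampled_patches=sampled)
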