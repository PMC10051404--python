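"""Pixel uncertainty, per-patch scoring, and patch selection/sampling.

Two uncertainty variants are supported:

``paper``
    ``u(p) = -p*log2(p)`` with ``u(0) = 0``.  This function peaks at
    ``p = 1/e`` (value ``log2(e)/e ~ 0.531``) rather than at ``p = 0.5``,
    and it is asymmetric in ``p`` vs ``1-p``.
``full_entropy`` (default)
    Binary Shannon entropy ``H(p) = -p*log2(p) - (1-p)*log2(1-p)``,
    symmetric, maximal (1 bit) at ``p = 0.5``.

Selection thresholds are interpreted on a [0, 1] scale normalized by the
variant's maximum, so threshold 1 selects only saturated patches and
threshold 0 selects every patch under either variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .grid import PatchGrid, PatchIndex

__all__ = [
    "PatchScores",
    "SelectionConfig",
    "UNCERTAINTY_MAX",
    "pixel_uncertainty",
    "patch_scores",
    "select_patches",
    "sample_training_patch",
]

Variant = Literal["paper", "full_entropy"]
Strategy = Literal["random", "weighted", "highest"]

#: Maximum attainable pixel uncertainty per variant (used for normalization).
UNCERTAINTY_MAX: dict[str, float] = {
    "paper": math.log2(math.e) / math.e,  # at p = 1/e
    "full_entropy": 1.0,  # at p = 0.5
}

_STRATEGIES = ("random", "weighted", "highest")


def _check_variant(variant: str) -> None:
    if variant not in UNCERTAINTY_MAX:
        raise ValueError(f"unknown uncertainty variant {variant!r}; choose from {sorted(UNCERTAINTY_MAX)}")


def _xlog2x(p: np.ndarray) -> np.ndarray:
    # -p*log2(p) with the 0*log(0) := 0 convention
    out = np.zeros_like(p, dtype=np.float64)
    pos = p > 0
    out[pos] = -p[pos] * np.log2(p[pos])
    return out


def pixel_uncertainty(p, variant: Variant = "full_entropy"):
    """Uncertainty of foreground probability ``p`` (scalar or array)."""
    _check_variant(variant)
    arr = np.asarray(p, dtype=np.float64)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    u = _xlog2x(arr)
    if variant == "full_entropy":
        u = u + _xlog2x(1.0 - arr)
    return float(u[0]) if scalar else u.reshape(np.shape(p))


@dataclass(frozen=True)
class PatchScores:
    """Mean pixel uncertainty of every patch of a grid."""

    grid: PatchGrid
    scores: np.ndarray  # (grid_rows, grid_cols), float64
    variant: str = "full_entropy"

    def __post_init__(self) -> None:
        _check_variant(self.variant)
        expected = (self.grid.grid_rows, self.grid.grid_cols)
        if self.scores.shape != expected:
            raise ValueError(f"scores shape {self.scores.shape} != grid shape {expected}")
        if np.any(self.scores < 0) or np.any(self.scores > UNCERTAINTY_MAX[self.variant] + 1e-12):
            raise ValueError("patch scores outside [0, u_max] for the active variant")

    @property
    def normalized(self) -> np.ndarray:
        return self.scores / UNCERTAINTY_MAX[self.variant]


@dataclass(frozen=True)
class SelectionConfig:
    """How patches are selected: strategy (training), threshold (inference)."""

    strategy: Strategy = "weighted"
    threshold: float = 0.25
    variant: Variant = "full_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {_STRATEGIES}")
        _check_variant(self.variant)
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {self.threshold}")


def patch_scores(p_hat: np.ndarray, grid: PatchGrid, variant: Variant = "full_entropy") -> PatchScores:
    """Mean pixel uncertainty of each grid patch of a probability map."""
    if p_hat.shape != (grid.image_h, grid.image_w):
        raise ValueError(
            f"probability map shape {p_hat.shape} does not match grid "
            f"{grid.image_h}x{grid.image_w}"
        )
    u = pixel_uncertainty(p_hat, variant)
    per_patch = u.reshape(grid.grid_rows, grid.patch_h, grid.grid_cols, grid.patch_w).mean(axis=(1, 3))
    return PatchScores(grid=grid, scores=per_patch, variant=variant)


def select_patches(scores: PatchScores, threshold: float) -> set[PatchIndex]:
    """Patches whose normalized score is ``>= threshold`` (inference-time g)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    mask = scores.normalized >= threshold
    return {PatchIndex(int(i), int(j)) for i, j in zip(*np.nonzero(mask))}


def sample_training_patch(
    scores: PatchScores, cfg: SelectionConfig, rng: np.random.Generator
) -> PatchIndex:
    """Sample one patch for stage-2 training (training-time g).

    ``random`` draws uniformly, ``weighted`` draws proportionally to the
    patch scores (uniform fallback when all scores are zero), ``highest``
    takes the argmax with ties broken by the smallest row-major index.
    """
    flat = scores.scores.ravel()
    n = flat.size
    if cfg.strategy == "random":
        k = int(rng.integers(n))
    elif cfg.strategy == "weighted":
        total = flat.sum()
        probs = np.full(n, 1.0 / n) if total <= 0 else flat / total
        k = int(rng.choice(n, p=probs))
    else:  # highest; np.argmax returns the first (row-major smallest) maximum
        k = int(np.argmax(flat))
    return PatchIndex(k // scores.grid.grid_cols, k % scores.grid.grid_cols)
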