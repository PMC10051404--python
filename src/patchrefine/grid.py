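"""Patch-grid geometry: exact crops, write-back stitching, and resizing.

Conventions used throughout the package (stated once, relied on everywhere):

* coordinates are 0-based and row-major;
* patch rectangles are half-open: patch (i, j) covers rows
  ``[i*patch_h, (i+1)*patch_h)`` and columns ``[j*patch_w, (j+1)*patch_w)``;
* crops are copies, never views, so downstream refinement can never alias
  the buffer it was cut from;
* bilinear resizing follows the align-corners-false / pixel-center
  convention (output pixel centers are mapped back through the scale
  factor), which preserves constant maps and the value range exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PatchGrid",
    "PatchIndex",
    "make_grid",
    "crop",
    "write_patch",
    "downscale",
    "upscale",
    "resize_mask",
]


class PatchIndex(NamedTuple):
    """Address of one patch in a :class:`PatchGrid` (row ``i``, column ``j``)."""

    i: int
    j: int


@dataclass(frozen=True)
class PatchGrid:
    """A contiguous, non-overlapping rectangular partition of an image."""

    grid_rows: int
    grid_cols: int
    image_h: int
    image_w: int
    patch_h: int
    patch_w: int

    def __post_init__(self) -> None:
        for name in ("grid_rows", "grid_cols", "image_h", "image_w", "patch_h", "patch_w"):
            if getattr(self, name) < 1:
                raise ValueError(f"PatchGrid.{name} must be positive, got {getattr(self, name)}")
        if self.grid_rows * self.patch_h != self.image_h:
            raise ValueError(
                f"grid_rows*patch_h = {self.grid_rows * self.patch_h} != image_h = {self.image_h}"
            )
        if self.grid_cols * self.patch_w != self.image_w:
            raise ValueError(
                f"grid_cols*patch_w = {self.grid_cols * self.patch_w} != image_w = {self.image_w}"
            )

    @property
    def num_patches(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def is_square(self) -> bool:
        return self.grid_rows == self.grid_cols

    def indices(self) -> list[PatchIndex]:
        """All patch indices in row-major order."""
        return [PatchIndex(i, j) for i in range(self.grid_rows) for j in range(self.grid_cols)]

    def validate_index(self, idx: PatchIndex) -> None:
        if not (0 <= idx.i < self.grid_rows and 0 <= idx.j < self.grid_cols):
            raise IndexError(
                f"patch index {tuple(idx)} outside {self.grid_rows}x{self.grid_cols} grid"
            )


def make_grid(image_h: int, image_w: int, num_patches: int) -> PatchGrid:
    """Partition an ``image_h x image_w`` image into ``num_patches`` patches.

    Among all factorizations ``rows*cols == num_patches`` with ``rows``
    dividing ``image_h`` and ``cols`` dividing ``image_w``, the one whose
    patch aspect ratio is closest (in log space) to the image aspect ratio
    is chosen; ties prefer more rows than columns.  For perfect squares on
    square images this yields the sqrt(P) x sqrt(P) lattice.
    """
    if num_patches < 1:
        raise ValueError(f"num_patches must be >= 1, got {num_patches}")
    if image_h < 1 or image_w < 1:
        raise ValueError(f"image dimensions must be positive, got {image_h}x{image_w}")

    image_aspect = image_h / image_w
    best: tuple[float, int, int] | None = None
    for rows in range(1, num_patches + 1):
        if num_patches % rows:
            continue
        cols = num_patches // rows
        if image_h % rows or image_w % cols:
            continue
        patch_aspect = (image_h // rows) / (image_w // cols)
        key = abs(math.log(patch_aspect / image_aspect))
        # ties resolved toward more rows: iterate rows ascending, accept strictly
        # better keys or equal keys with larger rows
        if best is None or key < best[0] - 1e-12 or (abs(key - best[0]) <= 1e-12 and rows > best[1]):
            best = (key, rows, cols)
    if best is None:
        raise ValueError(
            f"no factorization of {num_patches} patches tiles a {image_h}x{image_w} image evenly"
        )
    _, rows, cols = best
    grid = PatchGrid(rows, cols, image_h, image_w, image_h // rows, image_w // cols)
    if not grid.is_square:
        logger.warning(
            "non-square %dx%d grid: stage-1 and stage-2 input shapes will differ",
            rows,
            cols,
        )
    return grid


def _check_dims(x: np.ndarray, grid: PatchGrid) -> None:
    if x.shape[0] != grid.image_h or x.shape[1] != grid.image_w:
        raise ValueError(
            f"array of shape {x.shape} does not match grid image size "
            f"{grid.image_h}x{grid.image_w}"
        )


def crop(x: np.ndarray, grid: PatchGrid, idx: PatchIndex) -> np.ndarray:
    """Return a copy of patch ``idx`` of ``x`` (image, probability map or mask)."""
    grid.validate_index(idx)
    _check_dims(x, grid)
    r0, c0 = idx.i * grid.patch_h, idx.j * grid.patch_w
    return x[r0 : r0 + grid.patch_h, c0 : c0 + grid.patch_w].copy()


def write_patch(x: np.ndarray, grid: PatchGrid, idx: PatchIndex, patch: np.ndarray) -> np.ndarray:
    """Return a copy of ``x`` with patch ``idx`` replaced by ``patch``, bit-exact elsewhere."""
    grid.validate_index(idx)
    _check_dims(x, grid)
    if patch.shape[:2] != (grid.patch_h, grid.patch_w):
        raise ValueError(
            f"patch shape {patch.shape[:2]} does not match grid patch size "
            f"{grid.patch_h}x{grid.patch_w}"
        )
    out = x.copy()
    r0, c0 = idx.i * grid.patch_h, idx.j * grid.patch_w
    out[r0 : r0 + grid.patch_h, c0 : c0 + grid.patch_w] = patch
    return out


def _bilinear_axis_coords(out_n: int, in_n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    src = (np.arange(out_n, dtype=np.float64) + 0.5) * (in_n / out_n) - 0.5
    src = np.clip(src, 0.0, in_n - 1.0)
    i0 = np.floor(src).astype(np.int64)
    i1 = np.minimum(i0 + 1, in_n - 1)
    frac = src - i0
    return i0, i1, frac


def _resize_bilinear(a: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    if out_h < 1 or out_w < 1:
        raise ValueError(f"resize target must be positive, got {out_h}x{out_w}")
    in_h, in_w = a.shape[:2]
    if (in_h, in_w) == (out_h, out_w):
        return a.copy()
    a64 = np.asarray(a, dtype=np.float64)
    y0, y1, fy = _bilinear_axis_coords(out_h, in_h)
    x0, x1, fx = _bilinear_axis_coords(out_w, in_w)
    fy = fy.reshape(-1, 1) if a64.ndim == 2 else fy.reshape(-1, 1, 1)
    fx = fx.reshape(1, -1) if a64.ndim == 2 else fx.reshape(1, -1, 1)
    top = a64[y0][:, x0] * (1.0 - fx) + a64[y0][:, x1] * fx
    bot = a64[y1][:, x0] * (1.0 - fx) + a64[y1][:, x1] * fx
    out = top * (1.0 - fy) + bot * fy
    # convex blending can drift by one ulp; clamp so the value range is
    # preserved exactly (constants stay constants, [0,1] stays [0,1])
    np.clip(out, a64.min(), a64.max(), out=out)
    return out.astype(a.dtype if np.issubdtype(a.dtype, np.floating) else np.float64)


def _resize_nearest(a: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    if out_h < 1 or out_w < 1:
        raise ValueError(f"resize target must be positive, got {out_h}x{out_w}")
    in_h, in_w = a.shape[:2]
    if (in_h, in_w) == (out_h, out_w):
        return a.copy()
    ys = np.minimum((np.arange(out_h) + 0.5) * in_h / out_h, in_h - 1).astype(np.int64)
    xs = np.minimum((np.arange(out_w) + 0.5) * in_w / out_w, in_w - 1).astype(np.int64)
    return a[ys][:, xs].copy()


def downscale(x: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize of an image (HxW or HxWxC) to ``out_h x out_w``."""
    return _resize_bilinear(x, out_h, out_w)


def upscale(p: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize of a probability map (values stay within [min, max])."""
    return _resize_bilinear(p, out_h, out_w)


def resize_mask(m: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Nearest-neighbour resize of a binary mask; labels remain in {0, 1}."""
    return _resize_nearest(m, out_h, out_w)
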