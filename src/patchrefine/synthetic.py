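"""Seeded generator of cell-like binary segmentation images with spatially
heterogeneous difficulty.

Difficulty is injected at the granularity of the cells of a reference patch
grid: blobs whose centre falls in a "hard" cell get rougher boundaries, and
hard cells get lower foreground/background contrast plus stronger texture
noise.  This concentrates segmentation difficulty in selectable patches so
the benefit of uncertainty-guided refinement is measurable — an idealization
real data does not share.  The mask is the exact rasterization of the blob
union, independent of any photometric degradation.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "generate_pair", "generate_dataset", "generate_manifest"]


@dataclass(frozen=True)
class SyntheticConfig:
    image_size: tuple[int, int] = (96, 96)
    grid_shape: tuple[int, int] = (4, 4)  # reference difficulty lattice
    n_objects: tuple[int, int] = (3, 24)  # (min, max cap) blobs per image
    radius: tuple[float, float] = (5.0, 11.0)
    hard_region_frac: float = 0.25
    boundary_roughness: tuple[float, float] = (0.06, 0.45)  # (easy, hard)
    contrast: tuple[float, float] = (0.50, 0.14)  # (easy, hard) fg-bg offset
    texture_noise: float = 0.03  # easy-cell noise std
    hard_noise_factor: float = 3.5
    foreground_target: float = 0.18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size[0] < 1 or self.image_size[1] < 1:
            raise ValueError("image_size must be positive")
        if not 0.0 <= self.hard_region_frac <= 1.0:
            raise ValueError("hard_region_frac must lie in [0, 1]")
        if not 0.0 < self.foreground_target < 1.0:
            raise ValueError("foreground_target must lie in (0, 1)")
        if self.n_objects[0] > self.n_objects[1] or self.n_objects[0] < 1:
            raise ValueError("n_objects range is empty")
        if self.radius[0] > self.radius[1] or self.radius[0] <= 0:
            raise ValueError("radius range is empty")


def _blob_mask(h: int, w: int, cy: float, cx: float, r0: float,
               roughness: float, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one radially perturbed ellipse-like blob, exactly."""
    harmonics = np.arange(2, 6)
    amp_c = rng.standard_normal(harmonics.size) / np.sqrt(harmonics)
    amp_s = rng.standard_normal(harmonics.size) / np.sqrt(harmonics)
    squash = rng.uniform(0.7, 1.3)  # mild ellipticity
    pad = int(np.ceil(r0 * (1.0 + 3.0 * roughness))) + 2
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    if y0 >= y1 or x0 >= x1:
        return np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = (yy - cy) * squash
    dx = xx - cx
    theta = np.arctan2(dy, dx)
    wobble = sum(
        amp_c[k] * np.cos(harmonics[k] * theta) + amp_s[k] * np.sin(harmonics[k] * theta)
        for k in range(harmonics.size)
    )
    r_theta = r0 * np.clip(1.0 + roughness * wobble, 0.2, 3.0)
    inside = dy * dy + dx * dx <= r_theta * r_theta
    out = np.zeros((h, w), dtype=bool)
    out[y0:y1, x0:x1] = inside
    return out


def _cell_map(cfg: SyntheticConfig, values: np.ndarray) -> np.ndarray:
    """Expand a per-cell value grid to a per-pixel map."""
    h, w = cfg.image_size
    gr, gc = cfg.grid_shape
    return np.repeat(np.repeat(values, -(-h // gr), axis=0)[:h], -(-w // gc), axis=1)[:, :w]


def generate_pair(cfg: SyntheticConfig, index: int):
    """Generate one (image HxWx3 in [0,1], mask HxW {0,1}, hard_cell_map) triple.

    Fully determined by ``(cfg.seed, index)``.
    """
    h, w = cfg.image_size
    if h < 1 or w < 1:
        raise ValueError("degenerate image size")
    rng = np.random.default_rng([cfg.seed, index])
    gr, gc = cfg.grid_shape

    n_hard = int(round(cfg.hard_region_frac * gr * gc))
    hard_cells = np.zeros((gr, gc), dtype=bool)
    if n_hard:
        flat = rng.choice(gr * gc, size=n_hard, replace=False)
        hard_cells.ravel()[flat] = True

    rough_easy, rough_hard = cfg.boundary_roughness
    mask = np.zeros((h, w), dtype=bool)
    n_min, n_max = cfg.n_objects
    n_blobs = 0
    while n_blobs < n_max:
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r0 = rng.uniform(*cfg.radius)
        ci = min(int(cy * gr / h), gr - 1)
        cj = min(int(cx * gc / w), gc - 1)
        rough = rough_hard if hard_cells[ci, cj] else rough_easy
        mask |= _blob_mask(h, w, cy, cx, r0, rough, rng)
        n_blobs += 1
        if n_blobs >= n_min and mask.mean() >= cfg.foreground_target:
            break

    contrast_easy, contrast_hard = cfg.contrast
    contrast_map = _cell_map(cfg, np.where(hard_cells, contrast_hard, contrast_easy))
    noise_map = _cell_map(
        cfg, np.where(hard_cells, cfg.texture_noise * cfg.hard_noise_factor, cfg.texture_noise)
    )
    background = 0.35 + 0.05 * rng.standard_normal()
    gray = background + contrast_map * mask + noise_map * rng.standard_normal((h, w))
    image = np.clip(gray[:, :, None] + 0.01 * rng.standard_normal((h, w, 3)), 0.0, 1.0)
    return image, mask.astype(np.uint8), hard_cells


def generate_dataset(cfg: SyntheticConfig, n: int, start_index: int = 0):
    """List of (image, mask, hard_cells) triples for indices [start, start+n)."""
    return [generate_pair(cfg, start_index + k) for k in range(n)]


def generate_manifest(cfg: SyntheticConfig, n_train: int, n_test: int, out_dir) -> Path:
    """Write PNG image/mask pairs plus a CSV manifest with a train/test split.

    Returns the manifest path.  Deterministic: re-running with the same
    config reproduces every file byte-for-byte.
    """
    from .io import write_image, write_mask

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.csv"
    rows = []
    for k in range(n_train + n_test):
        image, mask, _ = generate_pair(cfg, k)
        split = "train" if k < n_train else "test"
        img_path = out / "images" / f"img_{k:04d}.png"
        mask_path = out / "masks" / f"mask_{k:04d}.png"
        write_image(img_path, image)
        write_mask(mask_path, mask)
        rows.append((str(img_path), str(mask_path), split))
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "mask", "split"])
        writer.writerows(rows)
    logger.info("wrote %d train / %d test pairs under %s", n_train, n_test, out)
    return manifest_path
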