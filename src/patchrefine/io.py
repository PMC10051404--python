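"""Shared I/O glue: image/mask/probability readers and writers, CSV dataset
manifests, and the run configuration that every CLI command resolves and
writes next to its outputs."""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "ManifestRow",
    "DatasetManifest",
    "RunConfig",
    "read_image",
    "read_mask",
    "read_prob",
    "write_image",
    "write_mask",
    "write_prob",
    "load_manifest",
    "load_pairs",
]

_SPLITS = ("train", "test")


# ---------------------------------------------------------------------------
# Images, masks, probability maps
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """8-bit greyscale/RGB file -> (H, W, C) float64 in [0, 1], C in {1, 3}."""
    with Image.open(path) as img:
        if img.mode not in ("L", "RGB"):
            img = img.convert("RGB")
        arr = np.asarray(img, dtype=np.float64) / 255.0
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return arr


def write_image(path, x: np.ndarray) -> None:
    arr = np.asarray(x)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    data = np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(data).save(path)


def read_mask(path) -> np.ndarray:
    """Mask file -> (H, W) uint8 in {0, 1}; any nonzero value is foreground."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return (arr != 0).astype(np.uint8)


def write_mask(path, m: np.ndarray) -> None:
    arr = np.asarray(m)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must be binary {0, 1}")
    Image.fromarray((arr * 255).astype(np.uint8)).save(path)


def write_prob(path, p: np.ndarray) -> None:
    """Probability map -> 16-bit greyscale PNG, value = round(p * 65535)."""
    arr = np.asarray(p, dtype=np.float64)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    data = np.round(arr * 65535.0).astype(np.uint16)
    Image.fromarray(data).save(path)  # uint16 -> 16-bit greyscale PNG


def read_prob(path) -> np.ndarray:
    with Image.open(path) as img:
        arr = np.asarray(img, dtype=np.float64)
    return arr / 65535.0


# ---------------------------------------------------------------------------
# Dataset manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestRow:
    image_path: str
    mask_path: str
    split: str


@dataclass(frozen=True)
class DatasetManifest:
    rows: tuple[ManifestRow, ...]

    def split(self, which: str) -> list[ManifestRow]:
        if which not in _SPLITS:
            raise ValueError(f"unknown split {which!r}; choose from {_SPLITS}")
        return [r for r in self.rows if r.split == which]


def load_manifest(path) -> DatasetManifest:
    """Load and validate a ``image,mask,split`` CSV manifest."""
    rows: list[ManifestRow] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != ["image", "mask", "split"]:
            raise ValueError(f"{path}: expected header 'image,mask,split', got {reader.fieldnames}")
        for lineno, rec in enumerate(reader, start=2):
            image, mask, split = (rec.get("image") or "", rec.get("mask") or "", rec.get("split") or "")
            if not image or not mask:
                raise ValueError(f"{path}:{lineno}: empty image or mask path")
            if split not in _SPLITS:
                raise ValueError(f"{path}:{lineno}: split must be one of {_SPLITS}, got {split!r}")
            if image in seen:
                raise ValueError(f"{path}:{lineno}: duplicate image path {image!r}")
            seen.add(image)
            rows.append(ManifestRow(image, mask, split))
    manifest = DatasetManifest(tuple(rows))
    logger.info(
        "manifest %s: %d train, %d test", path, len(manifest.split("train")), len(manifest.split("test"))
    )
    return manifest


def load_pairs(manifest: DatasetManifest, split: str, image_size: tuple[int, int] | None = None):
    """Materialize (image, mask) arrays for one split, optionally resized.

    Image/mask dimension mismatches are reported with both paths.
    """
    from .grid import downscale, resize_mask

    pairs = []
    for row in manifest.split(split):
        x = read_image(row.image_path)
        y = read_mask(row.mask_path)
        if x.shape[:2] != y.shape:
            raise ValueError(
                f"image {row.image_path} {x.shape[:2]} does not match mask "
                f"{row.mask_path} {y.shape}"
            )
        if image_size is not None and x.shape[:2] != tuple(image_size):
            x = downscale(x, image_size[0], image_size[1])
            y = resize_mask(y, image_size[0], image_size[1])
        pairs.append((x, y))
    return pairs


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run settings; round-trips losslessly through YAML."""

    arch: str = "tiny"
    image_size: tuple[int, int] = (96, 96)
    num_patches: int = 16
    strategy: str = "weighted"
    threshold: float = 0.25
    variant: str = "full_entropy"
    context: bool = True
    finetune: bool = True
    learning_rate: float = 1e-4
    epochs: int = 20
    batch_size: int = 4
    focal_gamma: float = 2.0
    focal_alpha: float = 1.0
    seed: int = 0
    manifest: str = ""
    out: str = ""

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_size"] = list(d["image_size"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "image_size" in d:
            d = dict(d, image_size=tuple(d["image_size"]))
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
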