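"""Folder dataset loading (ISIC-style layout) and flip augmentation.

A dataset is a directory with an ``images/`` folder, a ``masks/`` folder and a
manifest CSV listing ``image_path, mask_path`` pairs (paths relative to the
manifest).  Images are loaded as RGB, bilinearly resized to the target size
and scaled to [0, 1] channel-first arrays; masks are resized with
nearest-neighbor (to stay binary) and thresholded at 127/255.

Training-time augmentation is the joint horizontal/vertical flip: each axis is
flipped with independent probability 0.5, always applied to image and mask
together.  Test splits are never augmented.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass
class ManifestEntry:
    image_path: Path
    mask_path: Path


@dataclass
class DatasetManifest:
    """A list of image/mask path pairs plus a split tag."""

    entries: list[ManifestEntry]
    split: str = "train"

    def __len__(self) -> int:
        return len(self.entries)


def read_manifest(manifest_path: str | Path, split: str = "train") -> DatasetManifest:
    """Parse a manifest CSV; relative paths resolve against its directory."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    root = manifest_path.parent
    entries = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append(ManifestEntry(root / row["image_path"], root / row["mask_path"]))
    return DatasetManifest(entries=entries, split=split)


def load_pair(image_path: str | Path, mask_path: str | Path,
              target_size: tuple[int, int] | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Load one image/mask pair.

    Returns ``(image, mask)`` with image (3, H, W) float32 in [0, 1] and mask
    (H, W) uint8 in {0, 1}.  ``target_size`` is (H, W); when None, native
    sizes are kept (the mask is still resized to the image's size if needed).
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    for p in (image_path, mask_path):
        if not p.exists():
            raise FileNotFoundError(f"dataset file missing: {p}")
    img = Image.open(image_path).convert("RGB")
    msk = Image.open(mask_path).convert("L")
    if target_size is not None:
        h, w = target_size
        img = img.resize((w, h), Image.BILINEAR)
    if msk.size != img.size:
        msk = msk.resize(img.size, Image.NEAREST)
    image = np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0
    mask_gray = np.asarray(msk)
    levels = np.unique(mask_gray)
    if levels.size > 2:
        warnings.warn(f"mask {mask_path.name} has {levels.size} gray levels; "
                      "thresholding at 127", stacklevel=2)
    mask = (mask_gray > 127).astype(np.uint8)
    return image, mask


def augment_flip(image: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                 force: tuple[bool, bool] | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Jointly flip image (…, H, W) and mask (H, W) with p = 0.5 per axis.

    ``force=(horizontal, vertical)`` overrides the random draws (used in
    tests and for deterministic pipelines).
    """
    if force is None:
        flip_h, flip_v = bool(rng.random() < 0.5), bool(rng.random() < 0.5)
    else:
        flip_h, flip_v = force
    if flip_h:  # reverse columns
        image, mask = image[..., ::-1], mask[..., ::-1]
    if flip_v:  # reverse rows
        image, mask = image[..., ::-1, :], mask[..., ::-1, :]
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


class SegmentationDataset:
    """Materialized dataset: loads all pairs once, augments on access.

    Suitable for the desk-scale datasets this package targets; images are
    held in memory as float32.
    """

    def __init__(self, manifest: DatasetManifest | str | Path,
                 target_size: tuple[int, int] | None = None,
                 augment: bool = False):
        if not isinstance(manifest, DatasetManifest):
            manifest = read_manifest(manifest)
        if len(manifest) == 0:
            raise ValueError("manifest lists no samples")
        if manifest.split == "test" and augment:
            raise ValueError("test splits are never augmented")
        self.manifest = manifest
        self.augment = augment
        pairs = [load_pair(e.image_path, e.mask_path, target_size) for e in manifest.entries]
        self.images = np.stack([p[0] for p in pairs])
        self.masks = np.stack([p[1] for p in pairs])
        self.names = [e.image_path.name for e in manifest.entries]

    def __len__(self) -> int:
        return len(self.names)

    def batch(self, indices: np.ndarray, rng: np.random.Generator | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
        """Assemble a batch; applies flip augmentation when enabled."""
        images = self.images[indices]
        masks = self.masks[indices]
        if self.augment:
            if rng is None:
                raise ValueError("augmentation requires an rng")
            out_i, out_m = [], []
            for im, mk in zip(images, masks):
                im, mk = augment_flip(im, mk, rng)
                out_i.append(im)
                out_m.append(mk)
            images, masks = np.stack(out_i), np.stack(out_m)
        return images, masks

    @classmethod
    def from_arrays(cls, images: np.ndarray, masks: np.ndarray,
                    augment: bool = False, names: list[str] | None = None
                    ) -> "SegmentationDataset":
        """Build a dataset directly from in-memory arrays (no files)."""
        obj = cls.__new__(cls)
        obj.manifest = None
        obj.augment = augment
        obj.images = np.asarray(images, dtype=np.float32)
        obj.masks = np.asarray(masks, dtype=np.uint8)
        obj.names = names or [f"sample_{i:04d}" for i in range(len(obj.images))]
        return obj
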