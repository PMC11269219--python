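"""Instance-mask post-processing: merge per-seed masks into one binary image.

A segmentation model emits one binary mask per detected radicle, each
possibly at its own resolution. Downstream measurement wants a single
8-bit image at the original resolution whose foreground is the union of
all instances, with values exactly {0, 255}. The merged image is
conventionally written as ``in.png``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = ["InstanceMaskSet", "MergedMask", "merge_masks", "write_mask_png", "read_mask_png"]

DEFAULT_MASK_FILENAME = "in.png"


@dataclass
class InstanceMaskSet:
    """Per-instance binary masks ({0,1}) awaiting merge, plus the
    original image size they must be resized to."""

    masks: list[np.ndarray] = field(default_factory=list)
    original_size: tuple[int, int] = (1500, 1500)

    def validate(self) -> None:
        h, w = self.original_size
        if h <= 0 or w <= 0:
            raise ValueError(f"original_size must be positive, got {self.original_size}")
        for i, m in enumerate(self.masks):
            arr = np.asarray(m)
            if arr.ndim != 2:
                raise ValueError(f"mask {i} is not 2-D (shape {arr.shape})")
            if not np.isin(arr, (0, 1)).all():
                bad = arr[~np.isin(arr, (0, 1))].flat[0]
                raise ValueError(f"mask {i} contains value {bad!r} outside {{0, 1}}")


@dataclass
class MergedMask:
    """Union of instance masks as an 8-bit {0, 255} image."""

    grid: np.ndarray
    size: tuple[int, int]

    def validate(self) -> None:
        if tuple(self.grid.shape) != tuple(self.size):
            raise ValueError(f"grid shape {self.grid.shape} != declared size {self.size}")
        if self.grid.dtype != np.uint8 or not np.isin(self.grid, (0, 255)).all():
            raise ValueError("merged mask values must be uint8 in {0, 255}")


def _resize_nearest(mask: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize keeping the mask binary."""
    h_in, w_in = mask.shape
    h_out, w_out = size
    if (h_in, w_in) == (h_out, w_out):
        return mask
    rows = np.minimum((((np.arange(h_out) + 0.5) * h_in / h_out)).astype(int), h_in - 1)
    cols = np.minimum((((np.arange(w_out) + 0.5) * w_in / w_out)).astype(int), w_in - 1)
    return mask[np.ix_(rows, cols)]


def merge_masks(mask_set: InstanceMaskSet) -> MergedMask:
    """Cast each mask to 8-bit, resize to the original size, sum, and
    clamp so the output is exactly {0, 255}.

    The foreground equals the union of the resized input foregrounds; an
    empty set yields an all-zero mask.
    """
    mask_set.validate()
    h, w = mask_set.original_size
    acc = np.zeros((h, w), dtype=np.uint16)
    for m in mask_set.masks:
        resized = _resize_nearest(np.asarray(m).astype(np.uint8), (h, w))
        acc += resized
    merged = np.where(acc > 0, 255, 0).astype(np.uint8)
    return MergedMask(grid=merged, size=(h, w))


def write_mask_png(mask: MergedMask, path: str | Path = DEFAULT_MASK_FILENAME) -> Path:
    """Write as lossless 8-bit grayscale PNG (default filename ``in.png``)."""
    mask.validate()
    path = Path(path)
    Image.fromarray(mask.grid, mode="L").save(path, format="PNG")
    return path


def read_mask_png(path: str | Path) -> MergedMask:
    """Read a merged-mask PNG; any pixel outside {0, 255} is an error."""
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
    bad = ~np.isin(arr, (0, 255))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"pixel ({r}, {c}) has value {arr[r, c]}, expected 0 or 255")
    return MergedMask(grid=arr, size=arr.shape)
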