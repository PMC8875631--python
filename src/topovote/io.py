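"""Mask file I/O and evaluation records.

Two on-disk dialects, both 2D grayscale, row-major and 0-based:

* **PNG** (8-bit grayscale) — hard masks store 0/255 and any nonzero
  pixel reads back as 1; soft masks read as value/255.
* **text grid** — whitespace-delimited reals in [0, 1], one image row
  per line; the writer emits 6 decimals, which round-trips the 8-bit
  and synthetic soft masks used here losslessly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
from PIL import Image

from .masks import (
    HardMask,
    SoftMask,
    binary_accuracy,
    jaccard_distance,
    jaccard_hard,
)

__all__ = ["read_mask", "write_mask", "evaluate"]

PathLike = Union[str, Path]


def _load_gray(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        if im.mode not in ("L", "I", "I;16", "1"):
            raise ValueError(
                f"{path}: expected a single-channel grayscale image, "
                f"got mode {im.mode!r}"
            )
        return np.asarray(im.convert("L"))


def read_mask(path: PathLike, kind: str = "hard"):
    """Read a mask file; ``kind`` is ``"hard"`` or ``"soft"``.

    PNG hard masks treat every nonzero pixel as 1; PNG soft masks are
    scaled by 1/255.  Files not recognized as PNG are parsed as text
    grids.
    """
    path = Path(path)
    if kind not in ("hard", "soft"):
        raise ValueError(f"kind must be 'hard' or 'soft', got {kind!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".png":
        a = _load_gray(path)
        if kind == "hard":
            return HardMask((a != 0).astype(np.uint8))
        return SoftMask(a.astype(np.float64) / 255.0)
    grid = np.loadtxt(path, ndmin=2, dtype=np.float64)
    if kind == "hard":
        if not np.isin(grid, (0.0, 1.0)).all():
            raise ValueError(f"{path}: hard text grid must contain only 0 and 1")
        return HardMask(grid.astype(np.uint8))
    return SoftMask(grid)


def write_mask(mask, path: PathLike) -> None:
    """Write a mask: PNG (0/255 for hard, value*255 for soft) or text grid."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        if isinstance(mask, HardMask):
            data = (mask.values * 255).astype(np.uint8)
        elif isinstance(mask, SoftMask):
            data = np.round(mask.values * 255.0).astype(np.uint8)
        else:
            raise TypeError(f"cannot write {type(mask).__name__} as a mask")
        Image.fromarray(data, mode="L").save(path)
        return
    if isinstance(mask, HardMask):
        np.savetxt(path, mask.values, fmt="%d")
    elif isinstance(mask, SoftMask):
        np.savetxt(path, mask.values, fmt="%.6f")
    else:
        raise TypeError(f"cannot write {type(mask).__name__} as a mask")


def evaluate(pred: HardMask, truth: HardMask) -> dict:
    """Jaccard score, Jaccard distance and binary accuracy vs the truth.

    The binary accuracy is reported for completeness only — for a small
    object it sits near 1 even when the prediction misses the object
    entirely, while the Jaccard score drops to 0.
    """
    return {
        "jaccard": jaccard_hard(pred, truth),
        "jaccard_distance": jaccard_distance(pred, truth),
        "binary_accuracy": binary_accuracy(pred, truth),
    }
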