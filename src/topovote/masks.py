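"""Mask containers and the Jaccard metric substrate.

A *hard* mask is a per-pixel binary labeling of an image (1 = object,
0 = background); a *soft* mask carries continuous per-pixel confidences
in [0, 1], as produced by a sigmoid-output segmentation network.  All
voting methods in this package reduce to comparisons of masks under the
Jaccard (intersection-over-union) score and its min-over-max soft
generalization, implemented here.

Coordinate convention: row-major, 0-based — index ``(i, j)`` is row *i*
from the top, column *j* from the left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence, Union

import numpy as np

__all__ = [
    "HardMask",
    "SoftMask",
    "MaskEnsemble",
    "as_hard_array",
    "as_soft_array",
    "jaccard_hard",
    "jaccard_soft",
    "jaccard_distance",
    "binary_accuracy",
    "threshold_mask",
    "regularize_soft",
]

MaskLike = Union["HardMask", "SoftMask", np.ndarray, Sequence]


def _raw(m: MaskLike) -> np.ndarray:
    a = m.values if isinstance(m, (HardMask, SoftMask)) else np.asarray(m)
    if a.ndim != 2:
        raise ValueError(f"mask must be 2D, got shape {a.shape}")
    return a


def as_hard_array(m: MaskLike) -> np.ndarray:
    """Coerce to a validated 2D uint8 array with entries in {0, 1}."""
    a = np.asarray(_raw(m))
    vals = np.unique(a)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"hard mask entries must be 0 or 1, found {vals[:10]}")
    return a.astype(np.uint8, copy=False)


def as_soft_array(m: MaskLike) -> np.ndarray:
    """Coerce to a validated 2D float64 array with entries in [0, 1]."""
    a = np.asarray(_raw(m), dtype=np.float64)
    if not np.isfinite(a).all():
        raise ValueError("soft mask contains non-finite entries")
    if a.size and (a.min() < 0.0 or a.max() > 1.0):
        raise ValueError(
            f"soft mask entries must lie in [0, 1], range is "
            f"[{a.min():g}, {a.max():g}]"
        )
    return a


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


@dataclass(frozen=True)
class HardMask:
    """A binary segmentation mask: 2D grid of {0, 1} values."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", as_hard_array(self.values))
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("mask must have at least one row and column")
        self.values.setflags(write=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def h(self) -> int:
        return self.values.shape[0]

    @property
    def w(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HardMask):
            return NotImplemented
        return self.shape == other.shape and bool(
            (self.values == other.values).all()
        )


@dataclass(frozen=True)
class SoftMask:
    """A continuous-confidence mask: 2D grid of [0, 1] values."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", as_soft_array(self.values))
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("mask must have at least one row and column")
        self.values.setflags(write=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def h(self) -> int:
        return self.values.shape[0]

    @property
    def w(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SoftMask):
            return NotImplemented
        return self.shape == other.shape and bool(
            (self.values == other.values).all()
        )


@dataclass(frozen=True)
class MaskEnsemble:
    """An ordered collection of n >= 2 same-shape masks of one kind.

    The masks are the outputs of n annotators (model folds, humans, ...)
    for the same image; they are the candidates every voting method
    operates on.
    """

    masks: tuple

    def __init__(self, masks: Sequence) -> None:
        masks = tuple(masks)
        if len(masks) < 2:
            raise ValueError(f"an ensemble needs n >= 2 masks, got {len(masks)}")
        kinds = {type(m) for m in masks}
        if kinds == {HardMask}:
            soft = False
        elif kinds == {SoftMask}:
            soft = True
        else:
            raise TypeError(
                "ensemble must be all HardMask or all SoftMask, got "
                + ", ".join(sorted(k.__name__ for k in kinds))
            )
        shapes = {m.shape for m in masks}
        if len(shapes) > 1:
            raise ValueError(f"ensemble masks must share one shape, got {shapes}")
        object.__setattr__(self, "masks", masks)
        object.__setattr__(self, "_soft", soft)

    @property
    def n(self) -> int:
        return len(self.masks)

    @property
    def soft(self) -> bool:
        return self._soft  # type: ignore[attr-defined]

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks[0].shape

    def arrays(self) -> np.ndarray:
        """Stack the ensemble into an (n, h, w) array."""
        return np.stack([m.values for m in self.masks])

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self) -> Iterator:
        return iter(self.masks)

    def __getitem__(self, k: int):
        return self.masks[k]


def jaccard_hard(a: MaskLike, b: MaskLike) -> float:
    """Jaccard (IoU) score of two binary masks: |a ∩ b| / |a ∪ b|.

    Two empty masks coincide, so the degenerate 0/0 case scores 1.
    """
    av, bv = as_hard_array(a), as_hard_array(b)
    _check_same_shape(av, bv)
    inter = int(np.sum(av & bv))
    union = int(np.sum(av | bv))
    return 1.0 if union == 0 else inter / union


def jaccard_soft(u: MaskLike, v: MaskLike) -> float:
    """Min-over-max soft Jaccard score: Σ min(u, v) / Σ max(u, v).

    Reduces bit-exactly to :func:`jaccard_hard` when both inputs are
    binary-valued.  The 0/0 case (both masks all-zero) scores 1.
    """
    uv, vv = as_soft_array(u), as_soft_array(v)
    _check_same_shape(uv, vv)
    num = float(np.sum(np.minimum(uv, vv)))
    den = float(np.sum(np.maximum(uv, vv)))
    return 1.0 if den == 0.0 else num / den


def jaccard_distance(a: MaskLike, b: MaskLike) -> float:
    """1 − Jaccard score; a metric on masks, 0 iff hard masks coincide.

    Dispatches to the hard or soft score by the kind of the inputs:
    a pair of :class:`HardMask` (or binary arrays) uses the set-based
    score, anything else the min-over-max score.
    """
    if isinstance(a, HardMask) and isinstance(b, HardMask):
        return 1.0 - jaccard_hard(a, b)
    if isinstance(a, SoftMask) and isinstance(b, SoftMask):
        return 1.0 - jaccard_soft(a, b)
    if isinstance(a, (HardMask, SoftMask)) or isinstance(b, (HardMask, SoftMask)):
        raise TypeError(
            f"cannot mix mask kinds: {type(a).__name__} vs {type(b).__name__}"
        )
    av = np.asarray(a)
    if av.dtype.kind in "iub":
        return 1.0 - jaccard_hard(a, b)
    return 1.0 - jaccard_soft(a, b)


def binary_accuracy(a: MaskLike, truth: MaskLike) -> float:
    """Fraction of pixels where ``a`` agrees with ``truth``.

    Misleading for small objects: a prediction missing a tiny object
    entirely still scores near 1, which is why the Jaccard score is the
    primary metric here.
    """
    av, tv = as_hard_array(a), as_hard_array(truth)
    _check_same_shape(av, tv)
    return float(np.mean(av == tv))


def threshold_mask(s: MaskLike, t: float = 0.5) -> HardMask:
    """Binarize a soft mask: pixel -> 1 iff value >= t, else 0."""
    if not 0.0 < t < 1.0:
        raise ValueError(f"threshold must lie in the open interval (0, 1), got {t}")
    sv = as_soft_array(s)
    return HardMask((sv >= t).astype(np.uint8))


def regularize_soft(s: MaskLike) -> SoftMask:
    """Piecewise-linear truncation of sigmoid confidences at 0.2 / 0.8.

    Values in [0, 0.2] map to 0, values in [0.8, 1] map to 1, and the
    middle band [0.2, 0.8] is rescaled linearly: v -> 10(v − 0.2)/6.
    The map is continuous, non-decreasing, and fixes 0.5.  Applying it
    before computing soft Jaccard scores suppresses the influence of
    low-confidence background haze on the min/max sums.
    """
    sv = as_soft_array(s)
    # (5v - 1)/3 == 10(v - 0.2)/6 exactly in reals; the left form also
    # evaluates exactly to 0, 0.5, 1 at v = 0.2, 0.5, 0.8 in float64.
    out = np.clip((5.0 * sv - 1.0) / 3.0, 0.0, 1.0)
    return SoftMask(out)
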