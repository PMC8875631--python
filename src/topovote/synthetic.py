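"""Seeded generator of truth masks and annotator ensembles.

The voting methods are designed for ensembles in which most annotators
are decent — small boundary errors, a few dropped pixels, a slight
misregistration — while a minority may be grossly wrong (displaced,
unrelated, or empty).  This module fabricates exactly that situation so
every claim about the voting methods can be tested without external
datasets:

* *truth masks* in three shape regimes: a smooth connected ``blob``
  (compact deposits), a filled axis-aligned ``rectangle`` (bounding-box
  style annotation), and a thin connected ``vessel`` tree;
* *good annotators*: the truth under translation, boundary jitter
  (random dilation/erosion) and pixel dropout;
* *outliers*: the truth displaced by at least a quarter of the image
  side (``shift``), an unrelated truth draw (``spurious``), or an
  all-zero mask (``empty``).

Everything is deterministic given the spec's seed.  Only masks are
generated — the voting methods never look at image intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .masks import HardMask, MaskEnsemble, SoftMask

__all__ = [
    "GoodNoise",
    "EnsembleSpec",
    "make_truth_mask",
    "perturb_mask",
    "make_ensemble",
    "soften",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass(frozen=True)
class GoodNoise:
    """Noise applied to a good annotator's copy of the truth.

    jitter: max radius (px) of a random boundary dilation/erosion;
    dropout: probability of zeroing each foreground pixel;
    translation: max absolute shift (px) per axis.
    All-zero settings reproduce the truth bit-exactly.
    """

    jitter: int = 1
    dropout: float = 0.05
    translation: int = 1

    def __post_init__(self) -> None:
        if self.jitter < 0 or self.translation < 0:
            raise ValueError("jitter and translation must be >= 0")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError(f"dropout must lie in [0, 1], got {self.dropout}")


@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for one synthetic annotator ensemble."""

    shape: tuple[int, int] = (64, 64)
    truth_kind: str = "blob"
    n: int = 10
    n_outliers: int = 0
    good_noise: GoodNoise = field(default_factory=GoodNoise)
    outlier_mode: str = "shift"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.truth_kind not in ("blob", "rectangle", "vessel"):
            raise ValueError(f"unknown truth kind {self.truth_kind!r}")
        if self.outlier_mode not in ("shift", "spurious", "empty"):
            raise ValueError(f"unknown outlier mode {self.outlier_mode!r}")
        if self.n < 2:
            raise ValueError(f"ensemble needs n >= 2, got {self.n}")
        # voting is hopeless once outliers reach half the ensemble
        if self.n_outliers < 0 or 2 * self.n_outliers >= self.n:
            raise ValueError(
                f"n_outliers must satisfy 0 <= k < n/2, got k={self.n_outliers}"
                f" with n={self.n}"
            )


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, count = ndimage.label(mask, structure=_STRUCT8)
    if count == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, count + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _blob(shape, rng) -> np.ndarray:
    h, w = shape
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=min(h, w) / 8.0)
    cut = np.quantile(smooth, 0.7)
    return _largest_component(smooth > cut)


def _rectangle(shape, rng) -> np.ndarray:
    h, w = shape
    rh = int(rng.integers(h // 4, int(h * 0.7) + 1))
    rw = int(rng.integers(w // 4, int(w * 0.7) + 1))
    r0 = int(rng.integers(0, h - rh + 1))
    c0 = int(rng.integers(0, w - rw + 1))
    out = np.zeros(shape, dtype=bool)
    out[r0 : r0 + rh, c0 : c0 + rw] = True
    return out


_STEPS8 = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
)


def _vessel(shape, rng) -> np.ndarray:
    """Random 8-connected tree of thin branches, 1-3 px wide."""
    h, w = shape
    out = np.zeros(shape, dtype=bool)
    root = (int(rng.integers(h // 4, 3 * h // 4)),
            int(rng.integers(w // 4, 3 * w // 4)))
    visited = [root]
    out[root] = True
    n_branches = 3 + int(rng.integers(0, 3))
    for _ in range(n_branches):
        r, c = visited[int(rng.integers(0, len(visited)))]
        drift = _STEPS8[int(rng.integers(0, 8))]
        length = int(rng.integers(min(h, w) // 3, min(h, w)))
        wide = rng.random() < 0.3  # some branches 2-3 px wide
        for _ in range(length):
            step = drift if rng.random() < 0.6 else _STEPS8[int(rng.integers(0, 8))]
            r = min(max(r + int(step[0]), 0), h - 1)
            c = min(max(c + int(step[1]), 0), w - 1)
            out[r, c] = True
            if wide:
                out[max(r - 1, 0), c] = True
                out[r, max(c - 1, 0)] = True
            visited.append((r, c))
    return _largest_component(out)


def make_truth_mask(shape: tuple[int, int], truth_kind: str, seed: int) -> HardMask:
    """Deterministic ground-truth mask of the requested shape regime."""
    h, w = shape
    if h < 16 or w < 16:
        raise ValueError(f"truth masks need at least 16x16 pixels, got {shape}")
    rng = np.random.default_rng(seed)
    if truth_kind == "blob":
        m = _blob(shape, rng)
    elif truth_kind == "rectangle":
        m = _rectangle(shape, rng)
    elif truth_kind == "vessel":
        m = _vessel(shape, rng)
    else:
        raise ValueError(f"unknown truth kind {truth_kind!r}")
    return HardMask(m.astype(np.uint8))


def _translate(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Integer shift with zero fill (pixels leaving the frame are lost)."""
    out = np.zeros_like(a)
    h, w = a.shape
    src_r = slice(max(0, -dr), min(h, h - dr))
    dst_r = slice(max(0, dr), min(h, h + dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = a[src_r, src_c]
    return out


def perturb_mask(truth: HardMask, good_noise: GoodNoise, seed: int) -> HardMask:
    """A good annotator's mask: translated, jittered, dropped-out truth.

    Zero noise returns the truth bit-exactly.
    """
    rng = np.random.default_rng(seed)
    a = truth.values.astype(bool)
    if good_noise.translation > 0:
        t = good_noise.translation
        dr, dc = (int(rng.integers(-t, t + 1)) for _ in range(2))
        if dr or dc:
            a = _translate(a, dr, dc)
    if good_noise.jitter > 0:
        radius = int(rng.integers(1, good_noise.jitter + 1))
        footprint = ndimage.generate_binary_structure(2, 2)
        if rng.random() < 0.5:
            a = ndimage.binary_dilation(a, structure=footprint,
                                        iterations=radius)
        else:
            eroded = ndimage.binary_erosion(a, structure=footprint,
                                            iterations=radius)
            # erosion annihilates thin structures (a 1-px vessel has no
            # interior); a good annotator never loses the object, so
            # back off when most of the foreground would vanish
            if eroded.sum() >= 0.5 * a.sum():
                a = eroded
    if good_noise.dropout > 0:
        keep = rng.random(a.shape) >= good_noise.dropout
        a = a & keep
    return HardMask(a.astype(np.uint8))


def _make_outlier(truth: HardMask, mode: str, spec: EnsembleSpec,
                  rng: np.random.Generator) -> HardMask:
    h, w = truth.shape
    if mode == "empty":
        return HardMask(np.zeros((h, w), dtype=np.uint8))
    if mode == "spurious":
        return make_truth_mask((h, w), spec.truth_kind,
                               int(rng.integers(0, 2**31 - 1)))
    # shift: displace by at least a quarter of the image side
    side = min(h, w)
    mag = int(rng.integers(math.ceil(0.25 * side), math.ceil(0.4 * side) + 1))
    angle = rng.uniform(0, 2 * math.pi)
    dr = int(round(mag * math.sin(angle)))
    dc = int(round(mag * math.cos(angle)))
    if abs(dr) + abs(dc) == 0:
        dr = mag
    return HardMask(_translate(truth.values, dr, dc))


def make_ensemble(spec: EnsembleSpec):
    """Build (ensemble, truth, outlier_indices) from a spec.

    ``n - n_outliers`` good perturbations of the truth plus
    ``n_outliers`` outliers, in seed-determined random order.  Returns
    the planted outlier positions as a sorted tuple.
    """
    ss = np.random.SeedSequence(spec.seed)
    truth_seed, order_seed, *mask_seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in ss.spawn(2 + spec.n)
    ]
    truth = make_truth_mask(spec.shape, spec.truth_kind, truth_seed)
    n_good = spec.n - spec.n_outliers
    masks = [
        perturb_mask(truth, spec.good_noise, mask_seeds[i]) for i in range(n_good)
    ]
    for i in range(spec.n_outliers):
        rng_i = np.random.default_rng(mask_seeds[n_good + i])
        masks.append(_make_outlier(truth, spec.outlier_mode, spec, rng_i))
    order = np.random.default_rng(order_seed).permutation(spec.n)
    ordered = [masks[k] for k in order]
    outlier_positions = tuple(sorted(
        int(pos) for pos, k in enumerate(order) if k >= n_good
    ))
    return MaskEnsemble(ordered), truth, outlier_positions


def soften(e: MaskEnsemble, sigma: float = 1.0) -> MaskEnsemble:
    """Blur a hard ensemble into calibrated soft masks.

    Each mask is Gaussian-smoothed with the given kernel width (px), so
    confidences fall off across boundaries the way sigmoid outputs of a
    segmentation network do.
    """
    if e.soft:
        raise TypeError("soften expects a hard ensemble")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    soft_masks = [
        SoftMask(np.clip(
            ndimage.gaussian_filter(m.values.astype(np.float64), sigma=sigma),
            0.0, 1.0,
        ))
        for m in e
    ]
    return MaskEnsemble(soft_masks)
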