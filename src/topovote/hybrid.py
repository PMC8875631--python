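"""Hybrid topological-arithmetical voting (two rounds).

Round one uses topological scoring not to pick a winner but to reject
outliers: each candidate's total Jaccard score J_k = Σ_i J(S_i, S_k)
measures how well it agrees with the rest of the ensemble, and
candidates that agree too little are excluded.  Round two fuses the
survivors arithmetically (hard majority or soft averaging).

Two exclusion rules are supported:

* *threshold* — keep candidate k iff J_k >= n/H for a chosen H > 1; the
  number of survivors varies per input.  Should every candidate fall
  below the cutoff, the single top scorer is kept so the vote always
  produces an output.
* *rank* — keep the ``n_select`` candidates with the highest J_k; the
  survivor count is fixed.

The two rules bracket the plain methods: keep-all reproduces
arithmetical voting exactly, and ``n_select = 1`` reproduces
winner-takes-all topological voting exactly.

With a ``radius``, round one is run per pixel on clipped square
neighborhoods (the windowed J_k of the local-voting module) and each
pixel's survivors vote on that pixel alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .local import pixel_total_distances
from .masks import HardMask, MaskEnsemble, SoftMask, threshold_mask
from .voting import VoteReport, total_scores

__all__ = [
    "ExclusionRule",
    "exclude_by_threshold",
    "exclude_by_rank",
    "hybrid_vote",
]


@dataclass(frozen=True)
class ExclusionRule:
    """First-round outlier-exclusion rule.

    Exactly one of ``H`` (threshold method, H > 1) or ``n_select``
    (rank method, 1 <= n_select <= n) is set.
    """

    method: str
    H: Optional[float] = None
    n_select: Optional[int] = None

    def __post_init__(self) -> None:
        if self.method not in ("threshold", "rank"):
            raise ValueError(f"unknown exclusion method {self.method!r}")
        if self.method == "threshold":
            if self.H is None or self.n_select is not None:
                raise ValueError("threshold rule takes H only")
            if self.H <= 1:
                raise ValueError(f"H must exceed 1, got {self.H}")
        else:
            if self.n_select is None or self.H is not None:
                raise ValueError("rank rule takes n_select only")
            if self.n_select < 1:
                raise ValueError(f"n_select must be >= 1, got {self.n_select}")

    @classmethod
    def threshold(cls, H: float) -> "ExclusionRule":
        return cls(method="threshold", H=H)

    @classmethod
    def rank(cls, n_select: int) -> "ExclusionRule":
        return cls(method="rank", n_select=n_select)


def exclude_by_threshold(
    scores: Sequence[float], n: int, H: float
) -> tuple[int, ...]:
    """Survivors of the threshold rule: indices k with J_k >= n/H.

    If no candidate clears the cutoff the single top scorer survives,
    so the second round is never empty.
    """
    if H <= 1:
        raise ValueError(f"H must exceed 1, got {H}")
    J = np.asarray(scores, dtype=np.float64)
    cutoff = n / H
    keep = np.flatnonzero(J >= cutoff)
    if keep.size == 0:
        keep = np.array([int(np.argmax(J))])
    return tuple(int(k) for k in keep)


def exclude_by_rank(scores: Sequence[float], n_select: int) -> tuple[int, ...]:
    """Survivors of the rank rule: the n_select highest-scoring indices.

    Ties at the cut go to the lowest index.
    """
    J = np.asarray(scores, dtype=np.float64)
    if not 1 <= n_select <= J.size:
        raise ValueError(
            f"n_select must lie in [1, {J.size}], got {n_select}"
        )
    order = np.argsort(-J, kind="stable")  # descending J, ties by index
    return tuple(sorted(int(k) for k in order[:n_select]))


def _apply_rule(J: np.ndarray, n: int, rule: ExclusionRule) -> tuple[int, ...]:
    if rule.method == "threshold":
        return exclude_by_threshold(J, n, rule.H)
    return exclude_by_rank(J, rule.n_select)


def _fuse_survivors(e: MaskEnsemble, survivors: Sequence[int]) -> VoteReport:
    """Second round: arithmetical vote among the surviving candidates."""
    stack = e.arrays()[list(survivors)]
    m = len(survivors)
    if e.soft:
        soft_fused = SoftMask(stack.mean(axis=0))
        fused = threshold_mask(soft_fused)
    else:
        soft_fused = None
        fused = HardMask((2 * stack.sum(axis=0) >= m).astype(np.uint8))
    return VoteReport(
        method="hybrid",
        fused=fused,
        soft_fused=soft_fused,
        survivors=tuple(survivors),
    )


def hybrid_vote(
    e: MaskEnsemble,
    rule: ExclusionRule,
    radius: Optional[int] = None,
    soft: bool | None = None,
    per_pixel_exclusion: bool = True,
) -> VoteReport:
    """Two-round voting: topological exclusion, then arithmetical fusion.

    Parameters
    ----------
    e:
        The mask ensemble.
    rule:
        The round-one exclusion rule (threshold or rank).
    radius:
        ``None`` for global scoring (whole-mask J_k); an integer s for
        per-pixel windowed scoring on radius-s neighborhoods.
    soft:
        Score soft ensembles with the soft Jaccard (regularized); the
        default follows the ensemble kind.
    per_pixel_exclusion:
        With a radius, the default excludes per pixel from windowed
        scores.  Set False for the alternative reading in which
        survivors are chosen once from whole-mask scores and only the
        second round is per-pixel (then the radius does not enter).
    """
    soft = e.soft if soft is None else soft
    if radius is None or not per_pixel_exclusion:
        J = total_scores(e, soft)
        survivors = _apply_rule(J, e.n, rule)
        rep = _fuse_survivors(e, survivors)
        return VoteReport(
            method="hybrid",
            fused=rep.fused,
            soft_fused=rep.soft_fused,
            scores=J,
            survivors=survivors,
        )
    # per-pixel windowed exclusion and per-pixel fusion
    d = pixel_total_distances(e, radius, soft)
    J = e.n - d  # (n, h, w)
    n, h, w = J.shape
    if rule.method == "threshold":
        keep = J >= n / rule.H
        none_kept = ~keep.any(axis=0)
        if none_kept.any():
            top = np.argmax(J, axis=0)
            rows, cols = np.nonzero(none_kept)
            keep[top[rows, cols], rows, cols] = True
    else:
        if not 1 <= rule.n_select <= n:
            raise ValueError(
                f"n_select must lie in [1, {n}], got {rule.n_select}"
            )
        order = np.argsort(-J, axis=0, kind="stable")
        keep = np.zeros_like(J, dtype=bool)
        rank_idx = order[: rule.n_select]
        np.put_along_axis(keep, rank_idx, True, axis=0)
    counts = keep.sum(axis=0)
    stack = e.arrays()
    if e.soft:
        mean = np.where(keep, stack, 0.0).sum(axis=0) / counts
        soft_fused = SoftMask(np.clip(mean, 0.0, 1.0))
        fused = threshold_mask(soft_fused)
    else:
        votes = np.where(keep, stack, 0).sum(axis=0)
        soft_fused = None
        fused = HardMask((2 * votes >= counts).astype(np.uint8))
    return VoteReport(
        method="hybrid-local",
        fused=fused,
        soft_fused=soft_fused,
        survivor_counts=counts,
    )
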