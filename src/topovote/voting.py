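"""Global voting methods over a mask ensemble.

Two families:

* *arithmetical* voting fuses masks pixel by pixel — hard majority, or
  per-pixel (optionally weighted) averaging of soft masks followed by
  thresholding;
* *topological* voting is whole-mask winner-takes-all — the candidate
  whose total Jaccard distance to all the others is smallest is returned
  verbatim (the medoid of the ensemble under the Jaccard distance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .masks import (
    HardMask,
    MaskEnsemble,
    SoftMask,
    jaccard_distance,
    regularize_soft,
    threshold_mask,
)

__all__ = [
    "VoteReport",
    "total_distances",
    "total_scores",
    "topological_vote",
    "arithmetical_vote_hard",
    "arithmetical_vote_soft",
    "weighted_arithmetical_vote",
]


@dataclass(frozen=True)
class VoteReport:
    """Outcome of a voting method.

    Attributes
    ----------
    method:
        Label of the method that produced the report.
    fused:
        The fused hard mask.
    soft_fused:
        The pre-threshold soft mask, for soft/weighted arithmetical
        voting and soft topological voting; ``None`` otherwise.
    winner_index:
        Index of the winning candidate for winner-takes-all methods;
        ``None`` for arithmetical methods (no single winner exists).
    distances:
        Per-candidate total Jaccard distances d_k, when computed.
    scores:
        Per-candidate total Jaccard scores J_k, when computed.
    winner_map:
        Per-pixel winner indices for local voting; ``None`` otherwise.
    survivors:
        Indices admitted to the second round of hybrid voting.
    """

    method: str
    fused: HardMask
    soft_fused: Optional[SoftMask] = None
    winner_index: Optional[int] = None
    distances: Optional[np.ndarray] = None
    scores: Optional[np.ndarray] = None
    winner_map: Optional[np.ndarray] = None
    survivors: Optional[tuple] = None
    survivor_counts: Optional[np.ndarray] = None


def _scoring_masks(e: MaskEnsemble, soft: bool):
    """Masks used for Jaccard scoring: soft masks are regularized first.

    Regularization is a scoring aid only — fused outputs are always
    drawn from the original masks.
    """
    if soft:
        if not e.soft:
            raise TypeError("soft voting requires an ensemble of SoftMask")
        return [regularize_soft(m) for m in e]
    return list(e.masks)


def total_distances(e: MaskEnsemble, soft: bool | None = None) -> np.ndarray:
    """Total Jaccard distance of each candidate to the whole ensemble.

    d_k = Σ_i d_Jaccard(S_i, S_k), the self term included (it is zero
    for hard masks).  Soft ensembles are regularized before scoring.
    """
    soft = e.soft if soft is None else soft
    ms = _scoring_masks(e, soft)
    n = e.n
    # Pair distances are symmetric and computed once, but each total is
    # accumulated in ascending-i order so that d_k is reproduced bit for
    # bit by the windowed accumulation in the local-voting module (the
    # s >= max(h, w) limit must agree exactly, ties included).
    pair = {}
    for k in range(n):
        for i in range(k, n):
            pair[(i, k)] = jaccard_distance(ms[i], ms[k])
    d = np.zeros(n)
    for k in range(n):
        dk = 0.0
        for i in range(n):
            dk += pair[(i, k)] if i >= k else pair[(k, i)]
        d[k] = dk
    return d


def total_scores(e: MaskEnsemble, soft: bool | None = None) -> np.ndarray:
    """Total Jaccard score of each candidate: J_k = Σ_i J(S_i, S_k).

    Complementary to :func:`total_distances`: J_k = n − d_k.
    """
    return e.n - total_distances(e, soft)


def topological_vote(e: MaskEnsemble, soft: bool | None = None) -> VoteReport:
    """Winner-takes-all voting: the medoid of the ensemble wins.

    The candidate with the smallest total Jaccard distance to the other
    masks (equivalently the highest total Jaccard score) is returned
    verbatim; ties go to the lowest index.  For soft ensembles the
    scores are computed on regularized masks, the winner's original soft
    mask is reported, and the hard output thresholds it at 0.5.
    """
    soft = e.soft if soft is None else soft
    d = total_distances(e, soft)
    winner = int(np.argmin(d))
    if soft:
        soft_fused = e[winner]
        fused = threshold_mask(soft_fused)
        method = "topo-soft"
    else:
        soft_fused = None
        fused = e[winner]
        method = "topo-hard"
    return VoteReport(
        method=method,
        fused=fused,
        soft_fused=soft_fused,
        winner_index=winner,
        distances=d,
        scores=e.n - d,
    )


def arithmetical_vote_hard(e: MaskEnsemble) -> VoteReport:
    """Per-pixel majority vote over hard masks.

    Equivalent to thresholding the per-pixel mean at 0.5 with >=, so an
    exact tie (n even) yields 1.
    """
    if e.soft:
        raise TypeError("hard majority voting requires an ensemble of HardMask")
    stack = e.arrays()
    fused = HardMask((2 * stack.sum(axis=0) >= e.n).astype(np.uint8))
    return VoteReport(method="arith-hard", fused=fused)


def arithmetical_vote_soft(e: MaskEnsemble) -> VoteReport:
    """Per-pixel averaging of soft masks, then thresholding at 0.5."""
    if not e.soft:
        raise TypeError("soft averaging requires an ensemble of SoftMask")
    mean = e.arrays().mean(axis=0)
    soft_fused = SoftMask(mean)
    return VoteReport(
        method="arith-soft",
        fused=threshold_mask(soft_fused),
        soft_fused=soft_fused,
    )


def weighted_arithmetical_vote(
    e: MaskEnsemble, weights: Optional[Sequence[float]] = None
) -> VoteReport:
    """Weighted per-pixel averaging: fused = Σ w_k S_k / Σ w_k.

    With no ``weights`` given, w_k defaults to the total Jaccard score
    J_k of each candidate, so better-agreeing annotators count more.
    Equal weights reproduce plain averaging; a one-hot weight vector
    reproduces topological selection of that candidate.  Works for hard
    ensembles too (the weighted mean is then thresholded).
    """
    if weights is None:
        w = total_scores(e)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (e.n,):
            raise ValueError(f"expected {e.n} weights, got shape {w.shape}")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
    wsum = float(w.sum())
    if wsum <= 0:
        raise ValueError("weights must not all be zero")
    stack = e.arrays().astype(np.float64)
    mean = np.tensordot(w / wsum, stack, axes=1)
    soft_fused = SoftMask(np.clip(mean, 0.0, 1.0))
    return VoteReport(
        method="weighted",
        fused=threshold_mask(soft_fused),
        soft_fused=soft_fused,
        scores=np.asarray(w, dtype=np.float64) if weights is None else None,
    )
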