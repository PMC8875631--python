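"""Local (sliding-window) topological voting.

Global topological voting picks one whole mask; arithmetical voting
decides every pixel independently.  Local topological voting
interpolates between the two: for each pixel, the candidates' masks are
restricted to the inclusive square neighborhood of radius ``s`` around
it (clipped at the image border), topological voting is run on those n
windows, and the locally winning annotator's value at the center pixel
is emitted.

* ``s = 0`` — windows are single pixels and, for hard masks with n odd,
  the result coincides with per-pixel majority voting;
* ``s >= max(h, w)`` — every window is the whole image and the result
  coincides with global topological voting.

Two implementations are provided: :func:`local_vote_reference`, a
literal per-pixel loop that serves as the definitional oracle, and
:func:`local_topological_vote`, an accelerated version required to
agree with the oracle bit-exactly (winner map and fused mask alike).
For hard masks the accelerated path counts window intersections and
unions with integer summed-area tables, so window scores are exact;
clipped border windows use clipped-area sums — zero padding would
corrupt union counts at the border.
"""

from __future__ import annotations

import numpy as np

from .masks import HardMask, MaskEnsemble, SoftMask, regularize_soft, threshold_mask
from .voting import VoteReport

__all__ = [
    "extract_window",
    "pixel_total_distances",
    "local_topological_vote",
    "local_vote_reference",
]


def extract_window(m, center: tuple[int, int], s: int):
    """Clipped inclusive s-neighborhood of ``center``.

    Returns the sub-grid ``[i-s, i+s] x [j-s, j+s]`` intersected with
    the image; interior windows have shape ``(2s+1, 2s+1)``.
    """
    a = m.values if isinstance(m, (HardMask, SoftMask)) else np.asarray(m)
    if s < 0:
        raise ValueError(f"radius must be >= 0, got {s}")
    i, j = center
    h, w = a.shape
    if not (0 <= i < h and 0 <= j < w):
        raise ValueError(f"center {center} outside {h}x{w} image")
    return a[max(0, i - s) : min(h, i + s + 1), max(0, j - s) : min(w, j + s + 1)]


def _scoring_arrays(e: MaskEnsemble, soft: bool) -> list[np.ndarray]:
    if soft:
        if not e.soft:
            raise TypeError("soft voting requires an ensemble of SoftMask")
        return [regularize_soft(m).values for m in e]
    if e.soft:
        raise TypeError("hard voting requires an ensemble of HardMask")
    return [m.values for m in e]


def _assemble_report(e: MaskEnsemble, s: int, soft: bool, winner_map: np.ndarray,
                     method: str) -> VoteReport:
    stack = e.arrays()
    fused_vals = np.take_along_axis(stack, winner_map[None], axis=0)[0]
    if soft:
        soft_fused = SoftMask(fused_vals)
        fused = threshold_mask(soft_fused)
    else:
        soft_fused = None
        fused = HardMask(fused_vals)
    return VoteReport(
        method=method, fused=fused, soft_fused=soft_fused, winner_map=winner_map
    )


def _pair_score_hard(ai: np.ndarray, ak: np.ndarray, s: int) -> np.ndarray:
    """Per-pixel windowed Jaccard score of two hard masks, via SATs."""
    inter = _box_sum(ai & ak, s)
    union = _box_sum(ai | ak, s)
    out = np.ones(ai.shape, dtype=np.float64)
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out


def _box_sum(a: np.ndarray, s: int) -> np.ndarray:
    """Clipped-window box sum: out[i,j] = Σ a over the s-neighborhood.

    Exact for integer input (int64 summed-area table).
    """
    h, w = a.shape
    sat = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(a, axis=0, dtype=np.int64), axis=1, out=sat[1:, 1:])
    r0 = np.clip(np.arange(h) - s, 0, h)
    r1 = np.clip(np.arange(h) + s + 1, 0, h)
    c0 = np.clip(np.arange(w) - s, 0, w)
    c1 = np.clip(np.arange(w) + s + 1, 0, w)
    return (
        sat[r1[:, None], c1[None, :]]
        - sat[r0[:, None], c1[None, :]]
        - sat[r1[:, None], c0[None, :]]
        + sat[r0[:, None], c0[None, :]]
    )


def _pixel_totals_hard(arrs: list[np.ndarray], s: int) -> np.ndarray:
    """Per-pixel windowed total distances d_k, shape (n, h, w)."""
    n = len(arrs)
    h, w = arrs[0].shape
    scores = {}
    for k in range(n):
        for i in range(k, n):
            scores[(i, k)] = _pair_score_hard(arrs[i], arrs[k], s)
    d = np.zeros((n, h, w))
    for k in range(n):
        for i in range(n):
            j = scores[(i, k)] if i >= k else scores[(k, i)]
            d[k] += 1.0 - j
    return d


def _pixel_totals_soft(arrs: list[np.ndarray], s: int) -> np.ndarray:
    n = len(arrs)
    h, w = arrs[0].shape
    # Pair min/max images computed once; window sums are taken over
    # contiguous copies so the accumulation matches the per-window
    # reference computation bit for bit.
    mins, maxs = {}, {}
    for k in range(n):
        for i in range(k + 1, n):
            mins[(i, k)] = np.minimum(arrs[i], arrs[k])
            maxs[(i, k)] = np.maximum(arrs[i], arrs[k])
    d = np.zeros((n, h, w))
    for p_i in range(h):
        r0, r1 = max(0, p_i - s), min(h, p_i + s + 1)
        for p_j in range(w):
            c0, c1 = max(0, p_j - s), min(w, p_j + s + 1)
            for k in range(n):
                dk = 0.0
                for i in range(n):
                    if i == k:
                        continue
                    key = (i, k) if i > k else (k, i)
                    num = float(np.sum(np.ascontiguousarray(
                        mins[key][r0:r1, c0:c1])))
                    den = float(np.sum(np.ascontiguousarray(
                        maxs[key][r0:r1, c0:c1])))
                    jik = 1.0 if den == 0.0 else num / den
                    dk += 1.0 - jik
                d[k, p_i, p_j] = dk
    return d


def pixel_total_distances(e: MaskEnsemble, s: int, soft: bool | None = None
                          ) -> np.ndarray:
    """Windowed total Jaccard distances, shape (n, h, w).

    Entry ``(k, i, j)`` is d_k computed on the radius-``s`` neighborhood
    of pixel ``(i, j)``: the total Jaccard distance of candidate k's
    window to every other candidate's window (self term included, zero).
    Soft ensembles are regularized before scoring.
    """
    soft = e.soft if soft is None else soft
    if s < 0:
        raise ValueError(f"radius must be >= 0, got {s}")
    arrs = _scoring_arrays(e, soft)
    if soft:
        return _pixel_totals_soft(arrs, s)
    return _pixel_totals_hard(arrs, s)


def local_topological_vote(
    e: MaskEnsemble, s: int, soft: bool | None = None
) -> VoteReport:
    """Per-pixel topological voting on radius-``s`` neighborhoods.

    For every pixel, the n windows of radius ``s`` vote topologically
    (lowest-index tie-breaking) and the winner's value at the center is
    emitted.  Returns the fused mask and the per-pixel winner map.  Soft
    ensembles are regularized for scoring only; the emitted values come
    from the original masks.
    """
    soft = e.soft if soft is None else soft
    if s < 0:
        raise ValueError(f"radius must be >= 0, got {s}")
    d = pixel_total_distances(e, s, soft)
    winner_map = np.argmin(d, axis=0).astype(np.intp)
    method = "local-topo-soft" if soft else "local-topo"
    return _assemble_report(e, s, soft, winner_map, method)


def local_vote_reference(
    e: MaskEnsemble, s: int, soft: bool | None = None
) -> VoteReport:
    """Naive per-pixel implementation of local topological voting.

    Extracts every window explicitly and scores every pair from
    scratch; no shared computation.  This is the definitional oracle
    that the accelerated :func:`local_topological_vote` must match
    bit-exactly.
    """
    soft = e.soft if soft is None else soft
    if s < 0:
        raise ValueError(f"radius must be >= 0, got {s}")
    arrs = _scoring_arrays(e, soft)
    n = e.n
    h, w = e.shape
    winner_map = np.zeros((h, w), dtype=np.intp)
    for p_i in range(h):
        for p_j in range(w):
            wins = [extract_window(a, (p_i, p_j), s) for a in arrs]
            d = np.zeros(n)
            for k in range(n):
                dk = 0.0
                for i in range(n):
                    if i == k:
                        continue
                    if soft:
                        num = float(np.sum(np.minimum(wins[i], wins[k])))
                        den = float(np.sum(np.maximum(wins[i], wins[k])))
                        jik = 1.0 if den == 0.0 else num / den
                    else:
                        inter = int(np.sum(wins[i] & wins[k]))
                        union = int(np.sum(wins[i] | wins[k]))
                        jik = 1.0 if union == 0 else inter / union
                    dk += 1.0 - jik
                d[k] = dk
            winner_map[p_i, p_j] = int(np.argmin(d))
    method = "local-topo-soft-ref" if soft else "local-topo-ref"
    return _assemble_report(e, s, soft, winner_map, method)
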