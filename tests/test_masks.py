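"""Jaccard metric substrate: scores, distances, thresholding, regularization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from topovote import (
    HardMask,
    MaskEnsemble,
    SoftMask,
    binary_accuracy,
    jaccard_distance,
    jaccard_hard,
    jaccard_soft,
    regularize_soft,
    threshold_mask,
)

hard_grids = arrays(np.uint8, (6, 6), elements=st.integers(0, 1))
soft_grids = arrays(
    np.float64, (6, 6),
    elements=st.floats(0.0, 1.0, allow_nan=False, allow_infinity=False),
)


class TestJaccardHard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([[1, 1], [0, 0]], [[1, 0], [0, 1]], 1 / 3),
            ([[1, 1], [0, 0]], [[1, 1], [0, 0]], 1.0),
            ([[0, 0], [0, 0]], [[0, 0], [0, 0]], 1.0),  # empty/empty convention
            ([[0, 0], [0, 0]], [[0, 1], [0, 0]], 0.0),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert jaccard_hard(a, b) == pytest.approx(expected, abs=0)

    def test_shape_mismatch_names_both_shapes(self):
        with pytest.raises(ValueError, match=r"\(2, 2\).*\(2, 3\)"):
            jaccard_hard([[1, 0], [0, 1]], [[1, 0, 0], [0, 1, 0]])

    def test_rejects_nonbinary_values(self):
        with pytest.raises(ValueError, match="0 or 1"):
            jaccard_hard([[2, 0], [0, 1]], [[1, 0], [0, 1]])


class TestJaccardSoft:
    def test_min_over_max_by_hand(self):
        assert jaccard_soft([[0.5]], [[1.0]]) == 0.5

    def test_identity_scores_one(self):
        u = [[0.2, 0.7], [0.0, 1.0]]
        assert jaccard_soft(u, u) == 1.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            jaccard_soft([[1.5]], [[0.5]])

    @given(a=hard_grids, b=hard_grids)
    @settings(deadline=None, max_examples=100)
    def test_reduces_to_hard_on_binary_inputs(self, a, b):
        assert jaccard_soft(a.astype(float), b.astype(float)) == jaccard_hard(a, b)


class TestJaccardDistance:
    def test_zero_iff_coincide(self, rng):
        a = (rng.random((6, 6)) < 0.5).astype(np.uint8)
        assert jaccard_distance(HardMask(a), HardMask(a)) == 0.0
        b = a.copy()
        b[0, 0] ^= 1
        assert jaccard_distance(HardMask(a), HardMask(b)) > 0.0

    def test_complement_of_score(self):
        assert jaccard_distance([[1, 1], [0, 0]], [[1, 0], [0, 1]]) == 1 - 1 / 3

    def test_disjoint_nonempty_masks_at_max(self):
        assert jaccard_distance([[1, 0], [0, 0]], [[0, 0], [0, 1]]) == 1.0

    def test_mixed_kinds_rejected(self):
        with pytest.raises(TypeError, match="mix"):
            jaccard_distance(HardMask([[1]]), SoftMask([[0.5]]))

    @given(a=hard_grids, b=hard_grids)
    @settings(deadline=None, max_examples=100)
    def test_symmetry_and_range(self, a, b):
        d = jaccard_distance(a, b)
        assert d == jaccard_distance(b, a)
        assert 0.0 <= d <= 1.0

    @given(a=hard_grids, b=hard_grids, c=hard_grids)
    @settings(deadline=None, max_examples=150)
    def test_triangle_inequality(self, a, b, c):
        dac = jaccard_distance(a, c)
        dab = jaccard_distance(a, b)
        dbc = jaccard_distance(b, c)
        assert dac <= dab + dbc + 1e-12

    @given(u=soft_grids, v=soft_grids)
    @settings(deadline=None, max_examples=100)
    def test_soft_symmetry_and_range(self, u, v):
        s = jaccard_soft(u, v)
        assert s == jaccard_soft(v, u)
        assert 0.0 <= s <= 1.0


class TestBinaryAccuracy:
    def test_identity_and_complement(self):
        t = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        assert binary_accuracy(t, t) == 1.0
        assert binary_accuracy(1 - t, t) == 0.0

    def test_partial_agreement(self):
        assert binary_accuracy([[1, 0], [0, 0]], [[1, 1], [0, 0]]) == 0.75


class TestThreshold:
    def test_ge_on_upper_branch(self):
        out = threshold_mask(SoftMask([[0.5, 0.49, 0.51, 0.0]]))
        assert out.values.tolist() == [[1, 0, 1, 0]]

    def test_all_zero(self):
        assert threshold_mask(SoftMask(np.zeros((3, 3)))).values.sum() == 0

    @pytest.mark.parametrize("t", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_must_be_interior(self, t):
        with pytest.raises(ValueError):
            threshold_mask(SoftMask([[0.5]]), t)


class TestRegularize:
    @pytest.mark.parametrize(
        "v, expected",
        [(0.1, 0.0), (0.2, 0.0), (0.5, 0.5), (0.8, 1.0), (0.9, 1.0), (0.0, 0.0),
         (1.0, 1.0)],
    )
    def test_piecewise_map(self, v, expected):
        assert regularize_soft([[v]]).values[0, 0] == expected

    @given(u=soft_grids)
    @settings(deadline=None, max_examples=100)
    def test_monotone_and_in_range(self, u):
        r = regularize_soft(u).values
        assert r.min() >= 0.0 and r.max() <= 1.0
        flat_in = np.sort(u.ravel())
        flat_out = np.sort(r.ravel())
        order = np.argsort(u.ravel(), kind="stable")
        assert (np.diff(r.ravel()[order]) >= 0).all()
        del flat_in, flat_out

    @given(u=soft_grids)
    @settings(deadline=None, max_examples=100)
    def test_threshold_commutes_away_from_half(self, u):
        mask = u != 0.5
        before = threshold_mask(SoftMask(u)).values
        after = threshold_mask(regularize_soft(u)).values
        assert (before[mask] == after[mask]).all()


class TestEnsembleInvariants:
    def test_needs_two_masks(self):
        with pytest.raises(ValueError, match="n >= 2"):
            MaskEnsemble([HardMask([[1]])])

    def test_uniform_kind(self):
        with pytest.raises(TypeError, match="all HardMask or all SoftMask"):
            MaskEnsemble([HardMask([[1]]), SoftMask([[0.5]])])

    def test_uniform_shape(self):
        with pytest.raises(ValueError, match="share one shape"):
            MaskEnsemble([HardMask([[1]]), HardMask([[1, 0]])])
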