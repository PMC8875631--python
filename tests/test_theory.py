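"""Scalar/planar estimator simulations and the closest-to-mean identity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topovote import (
    SimConfig,
    prop1_oracle,
    run_convergence_experiment,
    run_structured_2d_experiment,
    topological_winner_1d,
    topological_winner_2d,
)


def brute_force_winner_1d(samples):
    """Independent O(n^2) evaluation of the total-squared-distance argmin."""
    s = np.asarray(samples, dtype=np.float64)
    totals = [(np.sum((x - s) ** 2), i) for i, x in enumerate(s)]
    return min(totals, key=lambda t: (t[0], t[1]))[1]


class TestWinner1D:
    def test_hand_computed_totals(self):
        # totals for {0, 1, 10} are (101, 82, 181)
        value, idx = topological_winner_1d([0, 1, 10])
        assert (value, idx) == (1.0, 1)

    def test_single_sample_wins(self):
        assert topological_winner_1d([4.2]) == (4.2, 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            topological_winner_1d([])

    @given(st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=200)
    def test_winner_attains_brute_force_minimum(self, samples):
        # Adversarial floats can tie totals to within rounding noise, so
        # compare achieved totals, not indices, against the O(n^2) oracle.
        s = np.asarray(samples, dtype=np.float64)
        _, idx = topological_winner_1d(samples)
        brute = np.array([np.sum((x - s) ** 2) for x in s])
        assert brute[idx] <= brute.min() + 1e-9 * (1.0 + brute.min())

    def test_matches_brute_force_index_on_random_draws(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            s = rng.normal(scale=rng.uniform(0.1, 5.0),
                           size=int(rng.integers(1, 25)))
            assert topological_winner_1d(s)[1] == brute_force_winner_1d(s)


class TestClosestToMeanIdentity:
    def test_hand_example(self):
        # mean of {0, 1, 10} is 11/3; nearest sample is 1
        assert prop1_oracle([0, 1, 10]) == 1

    def test_symmetric_pair_ties_to_lowest_index(self):
        assert prop1_oracle([-1.0, 1.0]) == 0
        assert topological_winner_1d([-1.0, 1.0])[1] == 0

    def test_identity_holds_on_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(2000):
            n = int(rng.integers(3, 31))
            s = rng.normal(size=n) if rng.random() < 0.5 else rng.uniform(size=n)
            assert topological_winner_1d(s)[1] == prop1_oracle(s)


class TestWinner2D:
    def test_identical_points(self):
        pt, idx = topological_winner_2d([(2.0, 3.0)] * 4)
        assert idx == 0 and pt.tolist() == [2.0, 3.0]

    def test_hand_computed_totals(self):
        # totals (10102, 9884, 19982) -> middle point wins
        pt, idx = topological_winner_2d([(0, 0), (1, 1), (10, 100)])
        assert idx == 1 and pt.tolist() == [1.0, 1.0]

    def test_winner_is_a_sample(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(15, 2))
        pt, idx = topological_winner_2d(pts)
        assert (pt == pts[idx]).all()

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError, match=r"\(n, 2\)"):
            topological_winner_2d([[1.0, 2.0, 3.0]])


class TestSimConfig:
    def test_uniform_mean(self):
        assert SimConfig(distribution="uniform", params=(0.0, 1.0)).theta == 0.5

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(distribution="cauchy")
        with pytest.raises(ValueError):
            SimConfig(dimension=2, f="sin")


class TestConvergence:
    def test_seeded_determinism(self):
        cfg = SimConfig(n_grid=(10, 50), replicates=20, seed=5)
        a = run_convergence_experiment(cfg)
        b = run_convergence_experiment(cfg)
        assert a.per_replicate.equals(b.per_replicate)

    def test_error_shrinks_with_n(self):
        cfg = SimConfig(distribution="normal", params=(0.0, 1.0),
                        n_grid=(100, 10000), replicates=200, seed=11)
        s = run_convergence_experiment(cfg).summary.set_index("n")
        assert s.loc[10000, "err_topo_mean"] < s.loc[100, "err_topo_mean"]

    def test_tiny_support_pins_both_estimators(self):
        cfg = SimConfig(distribution="uniform",
                        params=(2.0 - 1e-6, 2.0 + 1e-6),
                        n_grid=(10,), replicates=50, seed=1)
        res = run_convergence_experiment(cfg)
        assert (res.per_replicate["err_topo"] <= 1e-6 + 1e-12).all()
        assert (res.per_replicate["err_avg"] <= 1e-6 + 1e-12).all()


class TestStructured2D:
    def test_topological_stays_on_curve_average_leaves_it(self):
        cfg = SimConfig(dimension=2, distribution="uniform", params=(0.0, 1.0),
                        n_grid=(50,), replicates=100, seed=2, f="square")
        res = run_structured_2d_experiment(cfg)
        df = res.per_replicate
        assert np.allclose(df["topo_y"], df["topo_x"] ** 2)
        # Jensen: mean(x^2) > (mean x)^2 for non-degenerate draws
        assert (df["avg_y"] > df["avg_x"] ** 2).all()

    def test_symmetric_cube_favors_topological(self):
        cfg = SimConfig(dimension=2, distribution="uniform", params=(-1.0, 1.0),
                        n_grid=(200,), replicates=200, seed=4, f="cube")
        s = run_structured_2d_experiment(cfg).summary
        assert s["err_topo_mean"].iloc[0] <= s["err_avg_mean"].iloc[0]

    def test_missing_f_rejected(self):
        cfg = SimConfig(dimension=2, n_grid=(10,), replicates=5, seed=0)
        with pytest.raises(ValueError, match="structure function"):
            run_structured_2d_experiment(cfg)
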