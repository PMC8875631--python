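"""Why winner-takes-all voting works: scalar and planar simulations.

Strip the voting problem down to estimation.  n i.i.d. annotations
S_1..S_n with mean θ are fused either *arithmetically* — the sample
mean Σ_n — or *topologically* — the annotation minimizing its total
squared distance to the others,

    Y_n = argmin_{S_i} Σ_j d(S_i, S_j),   d(x, y) = (x − y)².

In one dimension the two estimators behave alike: Y_n is exactly the
sample closest to the sample mean (an identity this module exposes as
:func:`prop1_oracle`), it converges almost surely to θ, and it does so
at the √n rate, just like Σ_n.  The difference appears for structured
vectors: when S_i = [x_i, f(x_i)] lies on a curve, the average leaves
the curve (mean of f is not f of the mean) while the topological
estimate is always one of the samples and hence stays on it.  The
experiment drivers here reproduce both regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimResult",
    "STRUCTURE_FUNCTIONS",
    "topological_winner_1d",
    "prop1_oracle",
    "topological_winner_2d",
    "run_convergence_experiment",
    "run_structured_2d_experiment",
]

#: Structure functions available for the 2D experiment.
STRUCTURE_FUNCTIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "square": lambda x: x**2,
    "cube": lambda x: x**3,
    "inv1p": lambda x: 1.0 / (1.0 + x),
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a simulation run.

    ``distribution`` is ``"normal"`` with params (θ, σ) — σ being the
    standard deviation — or ``"uniform"`` with params (a, b), whose
    mean is θ = (a + b)/2.  ``f`` names the structure function for the
    2D experiment (see :data:`STRUCTURE_FUNCTIONS`).
    """

    dimension: int = 1
    distribution: str = "normal"
    params: tuple[float, float] = (0.0, 1.0)
    n_grid: tuple[int, ...] = (10, 100, 1000, 10000)
    replicates: int = 500
    seed: int = 0
    f: Optional[str] = None

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2):
            raise ValueError(f"dimension must be 1 or 2, got {self.dimension}")
        if self.distribution not in ("normal", "uniform"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.replicates < 1 or any(n < 1 for n in self.n_grid):
            raise ValueError("n_grid entries and replicates must be >= 1")
        if self.f is not None and self.f not in STRUCTURE_FUNCTIONS:
            raise ValueError(
                f"unknown structure function {self.f!r}; "
                f"choose from {sorted(STRUCTURE_FUNCTIONS)}"
            )

    @property
    def theta(self) -> float:
        """Population mean of the sampling distribution."""
        if self.distribution == "normal":
            return self.params[0]
        a, b = self.params
        return 0.5 * (a + b)

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.distribution == "normal":
            theta, sigma = self.params
            return rng.normal(theta, sigma, size=size)
        a, b = self.params
        return rng.uniform(a, b, size=size)


@dataclass(frozen=True)
class SimResult:
    """Per-replicate estimates and per-n error summaries."""

    config: SimConfig
    per_replicate: pd.DataFrame
    summary: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def topological_winner_1d(samples: Sequence[float]) -> tuple[float, int]:
    """The sample minimizing its total squared distance to the others.

    Ties go to the lowest index.  For modest n the totals h(S_i) =
    Σ_j (S_i − S_j)² are summed pairwise as written, which keeps exact
    ties (e.g. any two-sample input) exactly tied in floating point;
    for large n the algebraic expansion n·S_i² − 2·S_i·ΣS_j + ΣS_j²
    is used, which costs O(n) instead of O(n²).
    """
    s = np.asarray(samples, dtype=np.float64)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("samples must be a non-empty 1D sequence")
    n = s.size
    if n <= 256:
        totals = np.sum((s[:, None] - s[None, :]) ** 2, axis=1)
    else:
        totals = n * s**2 - 2.0 * s * s.sum() + np.sum(s**2)
    idx = int(np.argmin(totals))
    return float(s[idx]), idx


def prop1_oracle(samples: Sequence[float]) -> int:
    """Index of the sample nearest the sample mean (ties: lowest index).

    For the squared-difference distance, the total-distance minimizer
    is exactly the sample closest to the sample mean, so this closed
    form must agree with :func:`topological_winner_1d` on every input.
    """
    s = np.asarray(samples, dtype=np.float64)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("samples must be a non-empty 1D sequence")
    return int(np.argmin(np.abs(s - s.mean())))


def topological_winner_2d(samples) -> tuple[np.ndarray, int]:
    """The planar sample minimizing Σ_j ‖S_i − S_j‖² (squared Euclidean).

    Ties go to the lowest index; the winner is always one of the input
    points.
    """
    pts = np.asarray(samples, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] == 0 or pts.shape[1] != 2:
        raise ValueError(f"samples must have shape (n, 2), got {pts.shape}")
    n = pts.shape[0]
    sq = np.sum(pts**2, axis=1)
    totals = n * sq - 2.0 * pts @ pts.sum(axis=0) + sq.sum()
    idx = int(np.argmin(totals))
    return pts[idx].copy(), idx


def _winners_1d_batch(draws: np.ndarray) -> np.ndarray:
    """Vectorized Y_n over a (replicates, n) batch of draws."""
    n = draws.shape[1]
    T = draws.sum(axis=1, keepdims=True)
    Q = np.sum(draws**2, axis=1, keepdims=True)
    totals = n * draws**2 - 2.0 * draws * T + Q
    idx = np.argmin(totals, axis=1)
    return draws[np.arange(draws.shape[0]), idx]


def run_convergence_experiment(cfg: SimConfig) -> SimResult:
    """Compare Σ_n and Y_n against θ across a grid of sample sizes.

    For every n in ``cfg.n_grid``, ``cfg.replicates`` independent
    datasets are drawn; the absolute errors |Σ_n − θ| and |Y_n − θ| are
    recorded per replicate and summarized (mean, sd, and the
    √n-rescaled mean error) per n.  Deterministic given ``cfg.seed``.
    """
    if cfg.dimension != 1:
        raise ValueError("convergence experiment is one-dimensional")
    rng = np.random.default_rng(cfg.seed)
    theta = cfg.theta
    rows = []
    for n in cfg.n_grid:
        draws = cfg.draw(rng, (cfg.replicates, n))
        avg = draws.mean(axis=1)
        topo = _winners_1d_batch(draws)
        for r in range(cfg.replicates):
            rows.append(
                {
                    "n": n,
                    "replicate": r,
                    "avg_estimate": avg[r],
                    "topo_estimate": topo[r],
                    "err_avg": abs(avg[r] - theta),
                    "err_topo": abs(topo[r] - theta),
                }
            )
    per_rep = pd.DataFrame(rows)
    summary = (
        per_rep.groupby("n")[["err_avg", "err_topo"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = ["n", "err_avg_mean", "err_avg_sd",
                       "err_topo_mean", "err_topo_sd"]
    summary["err_topo_mean_sqrt_n"] = (
        summary["err_topo_mean"] * np.sqrt(summary["n"])
    )
    return SimResult(config=cfg, per_replicate=per_rep, summary=summary)


def run_structured_2d_experiment(cfg: SimConfig) -> SimResult:
    """Average vs topological fusion of curve-structured planar samples.

    Draws x_i from the configured distribution, forms S_i = [x_i,
    f(x_i)], and measures each estimator's Euclidean distance to the
    true point [θ, f(θ)].  The average estimator is [mean x, mean
    f(x)]; the topological estimator is the squared-Euclidean medoid
    of the samples (always on the curve).
    """
    if cfg.dimension != 2:
        raise ValueError("structured experiment is two-dimensional")
    if cfg.f is None:
        raise ValueError("2D experiment needs a structure function label f")
    f = STRUCTURE_FUNCTIONS[cfg.f]
    rng = np.random.default_rng(cfg.seed)
    theta = cfg.theta
    truth = np.array([theta, float(f(np.float64(theta)))])
    rows = []
    for n in cfg.n_grid:
        xs = cfg.draw(rng, (cfg.replicates, n))
        ys = f(xs)
        for r in range(cfg.replicates):
            pts = np.column_stack([xs[r], ys[r]])
            avg = pts.mean(axis=0)
            topo, idx = topological_winner_2d(pts)
            rows.append(
                {
                    "n": n,
                    "replicate": r,
                    "avg_x": avg[0],
                    "avg_y": avg[1],
                    "topo_x": topo[0],
                    "topo_y": topo[1],
                    "winner_index": idx,
                    "err_avg": float(np.linalg.norm(avg - truth)),
                    "err_topo": float(np.linalg.norm(topo - truth)),
                }
            )
    per_rep = pd.DataFrame(rows)
    summary = (
        per_rep.groupby("n")[["err_avg", "err_topo"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = ["n", "err_avg_mean", "err_avg_sd",
                       "err_topo_mean", "err_topo_sd"]
    return SimResult(config=cfg, per_replicate=per_rep, summary=summary)
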