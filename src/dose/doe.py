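"""Space-filling experimental designs over the simulation parameters.

A Latin hypercube design (LHD) with ``N`` points in ``d`` dimensions
places, in every dimension, exactly one point inside each of the ``N``
equal-width intervals of [0, 1).  Because the Latin property alone does
not guarantee good space filling, many candidate LHDs are generated and
the one with the best maximin properties is kept: largest minimal
nearest-neighbour distance (``mindist``), ties broken by smallest
``coverage`` (relative dispersion of nearest-neighbour distances, zero
for a perfectly regular mesh).

The selected unit-cube design is then mapped onto the parameter ranges
of the simulation study.  Four parameters use a linear map
``t = L + u * (U - L)`` (with rounding to the nearest integer for the
discrete parameters ``n`` and ``p``).  The signal-to-noise parameter
``delta`` uses a piecewise-linear map that places half of the design
mass in [0.1, 1] (noise dominates) and half in [1, 10] (signal
dominates), continuous at ``u = 0.5 -> delta = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import qmc

__all__ = [
    "ParameterSpace",
    "UnitDesign",
    "DesignMetrics",
    "generate_unit_lhd",
    "design_metrics",
    "select_best_design",
    "transform_design",
    "read_scenarios",
    "write_scenarios",
]

#: Column order of the 5-dimensional design.
PARAM_NAMES = ("n", "p", "psi", "delta", "rho")

SCENARIO_COLUMNS = ["scenario_id", "n", "p", "psi", "delta", "rho", "seed"]


@dataclass(frozen=True)
class ParameterSpace:
    """Ranges of the five simulation parameters.

    Parameters
    ----------
    n_range
        Discrete range of the sample size (per training / testing half).
    p_range
        Discrete range of the feature count.  The lower bound must
        exceed ``n_range`` so that every scenario sits in the
        large-p-small-n regime (p > n).
    psi_range
        Continuous range of the saturation parameter: the probability
        that a feature enters the true model.  Open interval (0, 1),
        implemented with a small numerical margin.
    delta_range
        Continuous range of the signal-to-noise ratio (mean absolute
        nonzero coefficient over the residual variance).  Mapped with
        the 0.5-split piecewise transform; must contain 1.
    rho_range
        Continuous range of the within-block Toeplitz correlation.
    """

    n_range: tuple[int, int] = (100, 1000)
    p_range: tuple[int, int] = (1001, 40000)
    psi_range: tuple[float, float] = (1e-6, 1.0 - 1e-6)
    delta_range: tuple[float, float] = (0.1, 10.0)
    rho_range: tuple[float, float] = (0.0, 0.95)

    def __post_init__(self) -> None:
        for name in ("n_range", "p_range", "psi_range", "delta_range", "rho_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound {lo} must be < upper bound {hi}")
        if self.n_range[1] > self.p_range[0] - 1:
            raise ValueError(
                "n_range.max must be <= p_range.min - 1 so that p > n in every scenario"
            )
        lo, hi = self.delta_range
        if not lo < 1.0 < hi:
            raise ValueError("delta_range must contain 1 (the split of the piecewise map)")

    @property
    def bounds(self) -> dict[str, tuple[float, float]]:
        return {
            "n": self.n_range,
            "p": self.p_range,
            "psi": self.psi_range,
            "delta": self.delta_range,
            "rho": self.rho_range,
        }


@dataclass(frozen=True)
class UnitDesign:
    """An N x d matrix of points in the unit hypercube with the Latin property."""

    points: np.ndarray
    seed: int

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_dims(self) -> int:
        return self.points.shape[1]


@dataclass(frozen=True)
class DesignMetrics:
    """Space-filling metrics of a design.

    ``per_point_nn[i]`` is the Euclidean distance from point ``i`` to its
    nearest neighbour; ``mindist`` is the minimum of those; ``coverage``
    is their relative dispersion, sqrt(mean((g_i - g_bar)^2)) / g_bar,
    which is 0 exactly when all nearest-neighbour distances are equal
    (a regular mesh).
    """

    mindist: float
    coverage: float
    per_point_nn: np.ndarray = field(repr=False)


def generate_unit_lhd(N: int, d: int, seed: int) -> UnitDesign:
    """Draw a random Latin hypercube design on [0, 1)^d.

    Each column is a random permutation of the N strata with uniform
    within-stratum jitter, so every column places exactly one point in
    each interval [(i-1)/N, i/N).  Deterministic given ``seed``.
    """
    if N < 1 or d < 1:
        raise ValueError(f"N and d must be positive, got N={N}, d={d}")
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    pts = sampler.random(N)
    return UnitDesign(points=pts, seed=seed)


def design_metrics(design: UnitDesign) -> DesignMetrics:
    """Exact nearest-neighbour distances, mindist and coverage of a design."""
    pts = design.points
    if pts.shape[0] < 2:
        raise ValueError("design metrics require at least 2 points")
    tree = cKDTree(pts)
    # k=2: the first neighbour of each point is itself at distance 0.
    dists, _ = tree.query(pts, k=2)
    gamma = dists[:, 1]
    gbar = gamma.mean()
    coverage = float(np.sqrt(np.mean((gamma - gbar) ** 2)) / gbar)
    return DesignMetrics(mindist=float(gamma.min()), coverage=coverage, per_point_nn=gamma)


def select_best_design(N: int, d: int, n_candidates: int, seed: int) -> UnitDesign:
    """Generate ``n_candidates`` independent LHDs and keep the maximin one.

    Selection: maximal mindist; ties broken by minimal coverage, then by
    lowest candidate index.  Candidate seeds are derived deterministically
    from ``seed`` so the whole selection is reproducible.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    best: UnitDesign | None = None
    best_key: tuple[float, float, int] | None = None
    for i in range(n_candidates):
        cand = generate_unit_lhd(N, d, seed=seed + i)
        if N == 1:
            return cand
        m = design_metrics(cand)
        key = (-m.mindist, m.coverage, i)
        if best_key is None or key < best_key:
            best, best_key = cand, key
    assert best is not None
    return best


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def transform_delta(u: np.ndarray, lo: float = 0.1, hi: float = 10.0) -> np.ndarray:
    """Piecewise-linear map from [0, 1] to the signal-to-noise range.

    u < 0.5 maps linearly onto [lo, 1] and u >= 0.5 onto [1, hi]; the two
    pieces meet at u = 0.5 -> delta = 1, so half the design mass lands in
    the noise-dominated regime and half in the signal-dominated one.
    """
    u = np.asarray(u, dtype=float)
    low = lo + (u / 0.5) * (1.0 - lo)
    high = 1.0 + ((u - 0.5) / 0.5) * (hi - 1.0)
    return np.where(u < 0.5, low, high)


def transform_design(design: UnitDesign, space: ParameterSpace, master_seed: int | None = None) -> pd.DataFrame:
    """Map a unit-cube design onto the parameter space -> scenario table.

    Columns are interpreted in the order (n, p, psi, delta, rho).  The
    discrete parameters n and p are rounded half-up after the linear map.
    Per-scenario seeds are ``master_seed + scenario_id`` (scenario ids are
    1-based), so any single scenario can be regenerated in isolation.
    """
    pts = design.points
    if pts.ndim != 2 or pts.shape[1] != 5:
        raise ValueError(f"expected a 5-column design (n, p, psi, delta, rho), got shape {pts.shape}")
    if master_seed is None:
        master_seed = design.seed

    def lin(u, rng):
        lo, hi = rng
        return lo + u * (hi - lo)

    n = _round_half_up(lin(pts[:, 0], space.n_range))
    p = _round_half_up(lin(pts[:, 1], space.p_range))
    psi = lin(pts[:, 2], space.psi_range)
    delta = transform_delta(pts[:, 3], *space.delta_range)
    rho = lin(pts[:, 4], space.rho_range)

    ids = np.arange(1, pts.shape[0] + 1)
    return pd.DataFrame(
        {
            "scenario_id": ids,
            "n": n,
            "p": p,
            "psi": psi,
            "delta": delta,
            "rho": rho,
            "seed": master_seed + ids,
        }
    )


def write_scenarios(scenarios: pd.DataFrame, path) -> None:
    """Write a scenario table as CSV at full float precision (repr round-trip)."""
    scenarios.to_csv(path, index=False, float_format="%.17g")


def read_scenarios(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SCENARIO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"scenario table at {path} is missing columns {sorted(missing)}")
    return df[SCENARIO_COLUMNS]
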