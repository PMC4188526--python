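"""Analysis layer: responses, binning, DISCO and permutation interaction tests.

The study treats each scenario's method performance (or the difference
between two methods' performance) as a response and the five design
parameters as inputs.  Because the response distributions are strongly
non-Gaussian and the parameter effects non-linear, inference is fully
non-parametric:

* each parameter's design range is discretized into ``G`` equal-width
  bins;
* equality of the per-bin response distributions is tested with DISCO
  (distance components): an F-like ratio of between-group to
  within-group mean powered distances.  With distance exponent 2 the
  statistic reduces exactly to the one-way ANOVA F; with exponent 1
  (the default here) it is also sensitive to dispersion differences;
* pairwise parameter interactions are tested with the two-way ANOVA
  interaction F-statistic computed by comparing a full
  one-mean-per-cell model against an additive main-effects model (valid
  for the near-balanced but unbalanced cells a Latin hypercube
  produces);
* all p-values come from label permutation:
  p = (1 + #{T*_b >= T_obs}) / (B + 1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "ResponseContrast",
    "BinnedFactor",
    "DiscoResult",
    "InteractionResult",
    "CONTRAST_NAMES",
    "compute_response",
    "bin_values",
    "disco_statistic",
    "permutation_test",
    "interaction_f_statistic",
    "interaction_plot_data",
    "analyze_contrast",
]

#: Sign conventions: a positive paired contrast means the first-named
#: method outperformed (had strictly smaller MSE than) the second.
CONTRAST_NAMES = (
    "abs_ridge",
    "abs_lasso",
    "abs_enet",
    "ridge_vs_lasso",
    "ridge_vs_enet",
    "lasso_vs_enet",
)

PARAMETERS = ("n", "p", "psi", "delta", "rho")


@dataclass(frozen=True)
class ResponseContrast:
    name: str
    values: np.ndarray


@dataclass(frozen=True)
class BinnedFactor:
    parameter: str
    G: int
    edges: np.ndarray
    labels: np.ndarray  # 1..G


@dataclass(frozen=True)
class DiscoResult:
    parameter: str
    statistic: float
    p_value: float
    B: int
    alpha_index: float


@dataclass(frozen=True)
class InteractionResult:
    parameters: tuple[str, str]
    f_statistic: float
    p_value: float
    B: int


def compute_response(results: pd.DataFrame, contrast: str) -> ResponseContrast:
    """Build a response vector from the per-scenario MSE table.

    Paired contrasts are MSE differences oriented so that positive
    values mark scenarios where the first-named method wins, e.g.
    ``ridge_vs_lasso = mse_lasso - mse_ridge``.
    """
    m = {c: results[f"mse_{c}"].to_numpy(dtype=float) for c in ("ridge", "lasso", "enet")}
    if contrast == "abs_ridge":
        v = m["ridge"]
    elif contrast == "abs_lasso":
        v = m["lasso"]
    elif contrast == "abs_enet":
        v = m["enet"]
    elif contrast == "ridge_vs_lasso":
        v = m["lasso"] - m["ridge"]
    elif contrast == "ridge_vs_enet":
        v = m["enet"] - m["ridge"]
    elif contrast == "lasso_vs_enet":
        v = m["enet"] - m["lasso"]
    else:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRAST_NAMES}")
    return ResponseContrast(name=contrast, values=v.copy())


def bin_values(values, lo: float, hi: float, G: int, parameter: str = "") -> BinnedFactor:
    """Discretize values into G equal-width bins over [lo, hi].

    Bins are half-open [lo + (g-1)w, lo + g*w) with w = (hi - lo)/G,
    except that the value ``hi`` itself belongs to bin G.  Values
    outside the design range are an error: the declared range is
    authoritative.
    """
    if not lo < hi:
        raise ValueError("lo must be < hi")
    if G < 2:
        raise ValueError("need at least 2 bins")
    v = np.asarray(values, dtype=float)
    if np.any(v < lo) or np.any(v > hi):
        raise ValueError(f"values outside the design range [{lo}, {hi}]")
    w = (hi - lo) / G
    labels = np.minimum(np.floor((v - lo) / w).astype(int), G - 1) + 1
    edges = lo + w * np.arange(G + 1)
    return BinnedFactor(parameter=parameter, G=G, edges=edges, labels=labels)


def _mean_powered_distance(a: np.ndarray, b: np.ndarray, alpha_index: float) -> float:
    """(1/(n_a n_b)) * sum_{i,j} |a_i - b_j|^alpha, chunked to bound memory."""
    total = 0.0
    step = max(1, int(2e7) // max(b.size, 1))
    for start in range(0, a.size, step):
        chunk = a[start : start + step, None] - b[None, :]
        np.abs(chunk, out=chunk)
        if alpha_index != 1.0:
            chunk **= alpha_index
        total += chunk.sum()
    return total / (a.size * b.size)


def disco_statistic(y, labels, alpha_index: float = 1.0) -> float:
    """One-way distance-components F-like ratio.

    With d(x, y) = |x - y|^alpha and g(A, B) the mean pairwise distance
    between samples A and B: total dispersion T = (N/2) g(pooled, pooled)
    splits into within W = sum_k (n_k/2) g(A_k, A_k) and between
    S_B = T - W; the statistic is (S_B/(K-1)) / (W/(N-K)).  At
    alpha = 2 this equals the classical one-way ANOVA F.  A zero
    within-group dispersion with positive between-group dispersion
    yields an infinite statistic (returned as ``inf`` with a warning).
    """
    if not 0.0 < alpha_index <= 2.0:
        raise ValueError("alpha_index must be in (0, 2]")
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    K = groups.size
    N = y.size
    if K < 2:
        raise ValueError("need at least 2 nonempty groups")
    T = (N / 2.0) * _mean_powered_distance(y, y, alpha_index)
    W = 0.0
    for g in groups:
        yg = y[labels == g]
        W += (yg.size / 2.0) * _mean_powered_distance(yg, yg, alpha_index)
    S_B = T - W
    if W <= 0.0:
        if S_B <= 0.0:
            return 0.0
        warnings.warn("zero within-group dispersion: distance-components ratio is infinite")
        return float("inf")
    return float((S_B / (K - 1)) / (W / (N - K)))


def permutation_test(
    y,
    labels,
    statistic_fn: Callable[[np.ndarray, np.ndarray], float],
    B: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation p-value p = (1 + #{T*_b >= T_obs}) / (B + 1).

    Labels are permuted uniformly at random B times; infinite permuted
    statistics count as exceeding any finite observed value (IEEE
    comparison semantics), never silently dropped.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    t_obs = statistic_fn(y, labels)
    count = 0
    for _ in range(B):
        perm = rng.permutation(labels)
        if statistic_fn(y, perm) >= t_obs:
            count += 1
    return float(t_obs), (1.0 + count) / (B + 1.0)


def _cell_codes(labelsA: np.ndarray, labelsB: np.ndarray):
    a_levels, a_codes = np.unique(labelsA, return_inverse=True)
    b_levels, b_codes = np.unique(labelsB, return_inverse=True)
    cell = a_codes * b_levels.size + b_codes
    occupied, cell_codes = np.unique(cell, return_inverse=True)
    return a_levels, a_codes, b_levels, b_codes, occupied, cell_codes


def interaction_f_statistic(y, labelsA, labelsB) -> float:
    """Two-way interaction F from full-vs-additive least-squares models.

    The full model fits one mean per occupied cell of the A x B
    cross-classification; the additive model fits main effects of A and
    B only.  F = [(RSS_add - RSS_full)/df_int] / [RSS_full/df_resid]
    with df_int = #cells - #levels(A) - #levels(B) + 1 and
    df_resid = N - #cells.  Valid for unbalanced (near-balanced) cells.
    """
    y = np.asarray(y, dtype=float)
    a_levels, a_codes, b_levels, b_codes, occupied, cell_codes = _cell_codes(
        np.asarray(labelsA), np.asarray(labelsB)
    )
    N = y.size
    n_cells = occupied.size
    df_int = n_cells - a_levels.size - b_levels.size + 1
    df_resid = N - n_cells
    if df_int <= 0 or df_resid <= 0:
        raise ValueError(
            f"degenerate cross-classification: df_int={df_int}, df_resid={df_resid}"
        )
    # full model: cell means
    cell_sums = np.bincount(cell_codes, weights=y, minlength=n_cells)
    cell_counts = np.bincount(cell_codes, minlength=n_cells)
    fitted_full = (cell_sums / cell_counts)[cell_codes]
    rss_full = float(np.sum((y - fitted_full) ** 2))
    # additive model: least squares on main-effect dummies (reference coding)
    D = np.zeros((N, 1 + (a_levels.size - 1) + (b_levels.size - 1)))
    D[:, 0] = 1.0
    for i in range(1, a_levels.size):
        D[a_codes == i, i] = 1.0
    off = a_levels.size
    for i in range(1, b_levels.size):
        D[b_codes == i, off + i - 1] = 1.0
    coefs, *_ = np.linalg.lstsq(D, y, rcond=None)
    rss_add = float(np.sum((y - D @ coefs) ** 2))
    if rss_full <= max(1e-12 * rss_add, 0.0):
        if rss_add - rss_full <= 0.0:
            return 0.0
        warnings.warn("zero within-cell residual: interaction F is infinite")
        return float("inf")
    return ((rss_add - rss_full) / df_int) / (rss_full / df_resid)


def interaction_plot_data(y, factorX: BinnedFactor, factorZ: BinnedFactor) -> pd.DataFrame:
    """Mean response and count per (X-bin, Z-bin) cell; empty cells are NaN."""
    df = pd.DataFrame({"x": factorX.labels, "z": factorZ.labels, "y": np.asarray(y, dtype=float)})
    full = pd.MultiIndex.from_product(
        [range(1, factorX.G + 1), range(1, factorZ.G + 1)], names=["x", "z"]
    )
    agg = df.groupby(["x", "z"])["y"].agg(["mean", "count"]).reindex(full)
    agg["count"] = agg["count"].fillna(0).astype(int)
    return agg.reset_index()


def analyze_contrast(
    results: pd.DataFrame,
    scenarios: pd.DataFrame,
    contrast: str,
    space=None,
    G: int = 10,
    G_int: int | None = None,
    B: int = 999,
    alpha_index: float = 1.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Main-effect and interaction permutation tests for one contrast.

    Returns a table with one DISCO row per design parameter (in the
    order n, p, psi, delta, rho) followed by one interaction row per
    unordered parameter pair.  Binning uses the design ranges from
    ``space`` (defaults to the standard parameter space); interaction
    tests use ``G_int`` bins per factor (defaults to ``G``).
    """
    from dose.doe import ParameterSpace

    if space is None:
        space = ParameterSpace()
    if G_int is None:
        G_int = G
    if rng is None:
        rng = np.random.default_rng()
    merged = results.merge(
        scenarios[["scenario_id"] + list(PARAMETERS)], on="scenario_id", suffixes=("", "_design")
    )
    y = compute_response(merged, contrast).values
    bounds = space.bounds
    factors = {
        name: bin_values(merged[name].to_numpy(dtype=float), *bounds[name], G, parameter=name)
        for name in PARAMETERS
    }
    rows = []
    for name in PARAMETERS:
        stat, p = permutation_test(
            y,
            factors[name].labels,
            lambda v, lab: disco_statistic(v, lab, alpha_index),
            B=B,
            rng=rng,
        )
        rows.append(
            {"contrast": contrast, "term": name, "type": "main", "statistic": stat,
             "p_value": p, "B": B, "G": G}
        )
    if G_int == G:
        int_factors = factors
    else:
        int_factors = {
            name: bin_values(
                merged[name].to_numpy(dtype=float), *bounds[name], G_int, parameter=name
            )
            for name in PARAMETERS
        }
    for a, b in itertools.combinations(PARAMETERS, 2):
        la, lb = int_factors[a].labels, int_factors[b].labels
        stat, p = permutation_test(
            y, np.arange(y.size), lambda v, idx: interaction_f_statistic(v[idx], la, lb),
            B=B, rng=rng,
        )
        rows.append(
            {"contrast": contrast, "term": f"{a}:{b}", "type": "interaction",
             "statistic": stat, "p_value": p, "B": B, "G": G_int}
        )
    return pd.DataFrame(rows)
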