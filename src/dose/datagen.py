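"""Stochastic generation of high-dimensional regression data sets.

One data set per design scenario, following a plate model:

1. Features are drawn in ``K`` independent blocks of random sizes
   (uniform on 20..300, a final remainder under 20 merged into the last
   block), each block multivariate normal with a Toeplitz correlation
   ``rho**|i-j|`` and unit variances.  Blocked structures mimic the
   grouped correlation patterns of real omics data and keep the
   Cholesky factorizations small.
2. Each feature enters the true model independently with probability
   ``psi`` (inclusion indicators ``gamma_j``); raw effect sizes are
   drawn from a symmetric continuous distribution and rescaled so that
   the signal-to-noise ratio mean(|beta_nonzero|) / sigma^2 equals the
   scenario's ``delta`` exactly.
3. The response is ``y = X beta + eps`` with standard normal noise
   (sigma^2 = 1).

2n rows are simulated; the first n become the training set and the last
n the testing set, each standardized independently (columns and
response to mean 0, sd 1, denominator n - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, toeplitz

__all__ = [
    "BlockStructure",
    "SimulatedDataset",
    "sample_block_sizes",
    "toeplitz_covariance",
    "simulate_features",
    "simulate_indicators",
    "scale_coefficients",
    "simulate_response",
    "split_and_standardize",
    "generate_dataset",
]

MIN_BLOCK = 20
MAX_BLOCK = 300


@dataclass(frozen=True)
class BlockStructure:
    """Partition of the p features into correlated blocks."""

    sizes: tuple[int, ...]

    @property
    def K(self) -> int:
        return len(self.sizes)

    @property
    def p(self) -> int:
        return sum(self.sizes)


@dataclass
class SimulatedDataset:
    """Standardized train/test split of one simulated scenario."""

    X_train: np.ndarray
    X_test: np.ndarray
    y_train: np.ndarray
    y_test: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    sigma2: float
    scenario_id: int
    block_sizes: tuple[int, ...] = field(default=())

    @property
    def m_true(self) -> int:
        """Number of features in the true model."""
        return int(self.gamma.sum())

    @property
    def pure_noise(self) -> bool:
        """True when no feature entered the model (beta identically zero)."""
        return self.m_true == 0


def sample_block_sizes(p: int, rng: np.random.Generator) -> BlockStructure:
    """Draw block sizes uniformly on {20..300} until p features are used.

    Sizes are drawn sequentially while at least ``MIN_BLOCK`` features
    remain; when a draw would leave a remainder below ``MIN_BLOCK``, the
    remainder is absorbed into that block (so a single block may reach
    319).  The sizes always sum to p.
    """
    if p < MIN_BLOCK:
        raise ValueError(f"p must be >= {MIN_BLOCK}, got {p}")
    sizes: list[int] = []
    remaining = p
    while remaining >= MIN_BLOCK:
        s = int(rng.integers(MIN_BLOCK, MAX_BLOCK + 1))
        s = min(s, remaining)
        if remaining - s < MIN_BLOCK:
            s = remaining
        sizes.append(s)
        remaining -= s
    assert remaining == 0
    return BlockStructure(sizes=tuple(sizes))


def toeplitz_covariance(rho: float, m: int) -> np.ndarray:
    """Toeplitz correlation matrix with entries rho**|i-j| (unit diagonal)."""
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if m < 1:
        raise ValueError(f"block size must be >= 1, got {m}")
    return toeplitz(rho ** np.arange(m, dtype=float))


def simulate_features(
    n_rows: int, blocks: BlockStructure, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw the raw feature matrix: independent Toeplitz-correlated blocks.

    Each block is i.i.d. across rows from N(0, Sigma_k) with
    Sigma_k[i, j] = rho**|i-j|; blocks are mutually independent and
    concatenated in order.  Cholesky factors are cached per block size.
    """
    if n_rows < 2:
        raise ValueError(f"n_rows must be >= 2, got {n_rows}")
    X = np.empty((n_rows, blocks.p))
    chol_cache: dict[int, np.ndarray] = {}
    col = 0
    for m in blocks.sizes:
        L = chol_cache.get(m)
        if L is None:
            L = cholesky(toeplitz_covariance(rho, m), lower=False)  # upper: X = Z @ L
            chol_cache[m] = L
        Z = rng.standard_normal((n_rows, m))
        X[:, col : col + m] = Z @ L
        col += m
    return X


def simulate_indicators(p: int, psi: float, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli(psi) inclusion indicators for the p features."""
    if not 0.0 <= psi <= 1.0:
        raise ValueError(f"psi must be in [0, 1], got {psi}")
    return (rng.random(p) < psi).astype(np.int8)


def scale_coefficients(
    b: np.ndarray, gamma: np.ndarray, delta: float, sigma2: float = 1.0
) -> np.ndarray:
    """Rescale raw effects so mean(|beta_nonzero|) / sigma2 == delta exactly.

    beta_j = 0 where gamma_j = 0; otherwise beta_j = c * b_j with
    c = delta * sigma2 / mean(|b_j| over the support), which preserves
    signs.  If the support is empty the zero vector is returned (the
    pure-noise case).
    """
    b = np.asarray(b, dtype=float)
    gamma = np.asarray(gamma)
    if b.shape != gamma.shape:
        raise ValueError("b and gamma must have the same length")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    beta = np.zeros_like(b)
    support = gamma.astype(bool)
    if not support.any():
        return beta
    b_sup = b[support]
    if np.any(b_sup == 0.0):
        raise ValueError("raw effects on the support must be nonzero; re-draw them")
    c = delta * sigma2 / np.mean(np.abs(b_sup))
    beta[support] = c * b_sup
    return beta


def simulate_response(
    X_raw: np.ndarray, beta: np.ndarray, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """y = X beta + eps with eps i.i.d. N(0, sigma2)."""
    if X_raw.shape[1] != beta.shape[0]:
        raise ValueError("X_raw and beta dimensions do not conform")
    return X_raw @ beta + np.sqrt(sigma2) * rng.standard_normal(X_raw.shape[0])


def _standardize(A: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to sd 1 (denominator n - 1), columnwise.

    Zero-variance columns are mapped to all zeros with a warning.
    """
    A = np.asarray(A, dtype=float)
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    if A.ndim == 1:
        if sd == 0:
            warnings.warn("constant vector standardized to zeros")
            return np.zeros_like(A)
        return (A - mu) / sd
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance column(s) standardized to zeros")
        sd = np.where(zero, 1.0, sd)
    out = (A - mu) / sd
    if zero.any():
        out[:, zero] = 0.0
    return out


def split_and_standardize(
    X_raw: np.ndarray, y_raw: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split the 2n-row simulation into train/test halves and standardize each.

    The first n rows form the training set and the last n the testing
    set; each half is standardized independently (its own means and
    standard deviations), matching the convention under which a zero
    predictor scores an MSE of (n-1)/n ~= 1 on the test response.
    """
    if X_raw.shape[0] != 2 * n:
        raise ValueError(f"X_raw must have exactly 2n = {2 * n} rows, got {X_raw.shape[0]}")
    X_train = _standardize(X_raw[:n])
    X_test = _standardize(X_raw[n:])
    y_train = _standardize(y_raw[:n])
    y_test = _standardize(y_raw[n:])
    return X_train, X_test, y_train, y_test


def generate_dataset(scenario, raw_effect_dist: str = "normal") -> SimulatedDataset:
    """Generate the complete data set for one scenario table row.

    ``scenario`` is any mapping/record with fields ``scenario_id, n, p,
    psi, delta, rho, seed`` (e.g. a row of the scenario table).  The
    scenario seed drives all randomness, so repeated calls are
    bit-identical.
    """
    n = int(scenario["n"])
    p = int(scenario["p"])
    psi = float(scenario["psi"])
    delta = float(scenario["delta"])
    rho = float(scenario["rho"])
    seed = int(scenario["seed"])
    scenario_id = int(scenario["scenario_id"])

    rng = np.random.default_rng(seed)
    blocks = sample_block_sizes(p, rng)
    X_raw = simulate_features(2 * n, blocks, rho, rng)
    gamma = simulate_indicators(p, psi, rng)
    if raw_effect_dist == "normal":
        b = rng.standard_normal(p)
    elif raw_effect_dist == "uniform":
        b = rng.uniform(-1.0, 1.0, p)
    else:
        raise ValueError(f"unknown raw effect distribution {raw_effect_dist!r}")
    # A zero raw effect on the support has probability zero under a
    # continuous draw; guard by re-drawing the offending entries.
    support = gamma.astype(bool)
    while np.any(b[support] == 0.0):
        bad = support & (b == 0.0)
        b[bad] = rng.standard_normal(int(bad.sum()))
    sigma2 = 1.0
    beta = scale_coefficients(b, gamma, delta, sigma2)
    y_raw = simulate_response(X_raw, beta, sigma2, rng)
    X_train, X_test, y_train, y_test = split_and_standardize(X_raw, y_raw, n)
    return SimulatedDataset(
        X_train=X_train,
        X_test=X_test,
        y_train=y_train,
        y_test=y_test,
        gamma=gamma,
        beta=beta,
        sigma2=sigma2,
        scenario_id=scenario_id,
        block_sizes=blocks.sizes,
    )
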