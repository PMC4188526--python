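"""Pathwise coordinate descent for the elastic net, batched across CV folds.

Solves, for a decreasing penalty path ``lambdas`` and a fixed mixing
parameter ``l1_ratio`` (1 = lasso), the problem

    min_beta  (1/(2m)) * ||y - X beta||^2
              + lam * [ (1 - l1_ratio)/2 * ||beta||^2 + l1_ratio * ||beta||_1 ]

on each cross-validation fold's training rows (m rows), warm-starting
along the path.  The engine follows the screening strategy of
coordinate-descent elastic-net solvers for p >> n problems:

* sequential strong rule: at step ``lam_k`` only coordinates with
  ``|x_j' r| >= m * l1_ratio * (2*lam_k - lam_prev)`` at the previous
  solution (plus every currently nonzero coordinate) enter the
  coordinate-descent working set;
* active-set iteration: one full sweep over the working set, then
  cycling over the currently nonzero coordinates until convergence,
  repeated until a full working-set sweep makes no meaningful update;
* full KKT verification without extra gradient passes: all folds share
  one BLAS product ``C = R X`` per round, which simultaneously
  (a) verifies the KKT conditions of each fold's last solved penalty
  over all p coordinates and (b) screens the working set for that
  fold's next penalty.  A fold with strong-rule violations is repaired
  and simply re-verified on the following round, so the (rare) repairs
  never trigger per-fold gradient computations.

Confining the per-coordinate work to small working sets (numba kernels
over contiguous per-fold matrices) while running the only O(p*n)
operations as dense matrix products is what makes a full 10-fold,
100-penalty path affordable on one CPU at p of a few thousand.

All solutions satisfy the KKT conditions of the stated objective at the
convergence threshold; agreement with an independent solver is checked
in the test suite on small instances.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["PathWorkspace", "enet_path_cv", "enet_path_fit"]

_KKT_RTOL = 1e-9
# The working set can admit coordinates below the strong-rule threshold
# (margin < 1) to trade extra inner products for rarer strong-rule
# violations; correctness is unaffected because every solution is
# KKT-verified over all p coordinates either way.  Profiling showed the
# exact rule (margin 1) is the better trade at these problem shapes.
_STRONG_MARGIN = 1.0


@njit(cache=True, fastmath=True)
def _sweep(XTf, r, beta_f, idx, g_f, lam_l1_m, lam_l2_m):
    """One cyclic pass over ``idx``; returns max of g_j * delta_j^2.

    All inner loops accumulate in the arrays' own dtype so they
    vectorize for both float64 and float32 inputs.
    """
    m = r.size
    maxd = 0.0
    for t in range(idx.size):
        j = idx[t]
        gj = g_f[j]
        if gj <= 0.0:
            continue
        bj = beta_f[j]
        xj = XTf[j]
        cj = bj * 0  # zero of the array dtype
        for i in range(m):
            cj += xj[i] * r[i]
        rho = cj + gj * bj
        if rho > lam_l1_m:
            bn = (rho - lam_l1_m) / (gj + lam_l2_m)
        elif rho < -lam_l1_m:
            bn = (rho + lam_l1_m) / (gj + lam_l2_m)
        else:
            bn = 0.0
        beta_f[j] = bn
        d = beta_f[j] - bj  # delta in the array dtype
        if d != 0.0:
            for i in range(m):
                r[i] -= d * xj[i]
            dd = gj * d * d
            if dd > maxd:
                maxd = dd
    return maxd


@njit(cache=True, fastmath=True)
def _cd_pass(XTf, r, beta_f, cand, g_f, lam_l1_m, lam_l2_m, tol_m, max_iter):
    """Working-set coordinate descent: full sweeps over ``cand`` alternate
    with convergence loops over the currently active (nonzero) subset.
    Returns the number of sweeps used."""
    sweeps = 0
    while sweeps < max_iter:
        maxd = _sweep(XTf, r, beta_f, cand, g_f, lam_l1_m, lam_l2_m)
        sweeps += 1
        if maxd < tol_m:
            return sweeps
        n_act = 0
        for t in range(cand.size):
            if beta_f[cand[t]] != 0.0:
                n_act += 1
        active = np.empty(n_act, dtype=cand.dtype)
        k = 0
        for t in range(cand.size):
            j = cand[t]
            if beta_f[j] != 0.0:
                active[k] = j
                k += 1
        while sweeps < max_iter:
            maxd = _sweep(XTf, r, beta_f, active, g_f, lam_l1_m, lam_l2_m)
            sweeps += 1
            if maxd < tol_m:
                break
    return sweeps


@njit(cache=True, fastmath=True)
def _fold_round(XTf, XTe, y_te, r, beta_f, mark_f, g_f, C_f, m, l1_ratio,
                lam_pos, lam_next, lam_prev, tol_m, max_iter, kkt_rtol, margin):
    """One verification/advance round for a single fold, entirely in numba.

    Given the fold's full gradient ``C_f`` at its current state:
    verify the KKT conditions at ``lam_pos`` (if >= 0); on violation,
    add the violators to the working set, re-solve at ``lam_pos`` and
    report a repair.  Otherwise compute the held-out MSE of the
    ``lam_pos`` solution and, if ``lam_next >= 0``, rebuild the working
    set (currently nonzero coordinates plus the sequential strong set)
    and solve at ``lam_next``.

    ``mark_f`` flags membership in the most recent working set; only
    coordinates outside it can register KKT violations (members satisfy
    the conditions by convergence, up to solver tolerance).

    Returns (advanced, mse_pos): advanced is 0 after a repair (the fold
    must be re-verified on the next round) and 1 otherwise; mse_pos is
    the held-out MSE at ``lam_pos`` (nan when lam_pos < 0).
    """
    p = beta_f.size
    mse_pos = np.nan
    if lam_pos >= 0.0:
        thresh = m * l1_ratio * lam_pos * (1.0 + kkt_rtol)
        nviol = 0
        for j in range(p):
            if mark_f[j] == 0 and beta_f[j] == 0.0 and abs(C_f[j]) > thresh:
                mark_f[j] = 1
                nviol += 1
        if nviol > 0:
            n_ws = 0
            for j in range(p):
                if mark_f[j] == 1:
                    n_ws += 1
            cand = np.empty(n_ws, dtype=np.int64)
            k = 0
            for j in range(p):
                if mark_f[j] == 1:
                    cand[k] = j
                    k += 1
            _cd_pass(XTf, r, beta_f, cand, g_f,
                     m * lam_pos * l1_ratio, m * lam_pos * (1.0 - l1_ratio),
                     tol_m, max_iter)
            return 0, mse_pos
        # verified: held-out error of the lam_pos solution
        n_te = y_te.size
        if n_te > 0:
            pred = np.zeros(n_te)
            for j in range(p):
                bj = beta_f[j]
                if bj != 0.0:
                    xj = XTe[j]
                    for i in range(n_te):
                        pred[i] += bj * xj[i]
            acc = 0.0
            for i in range(n_te):
                d = y_te[i] - pred[i]
                acc += d * d
            mse_pos = acc / n_te
        else:
            mse_pos = 0.0
    if lam_next >= 0.0:
        strong_lim = m * l1_ratio * (2.0 * lam_next - lam_prev) * margin
        if strong_lim < 0.0:
            strong_lim = 0.0
        n_cand = 0
        for j in range(p):
            if beta_f[j] != 0.0 or abs(C_f[j]) >= strong_lim:
                mark_f[j] = 1
                n_cand += 1
            else:
                mark_f[j] = 0
        cand = np.empty(n_cand, dtype=np.int64)
        k = 0
        for j in range(p):
            if mark_f[j] == 1:
                cand[k] = j
                k += 1
        _cd_pass(XTf, r, beta_f, cand, g_f,
                 m * lam_next * l1_ratio, m * lam_next * (1.0 - l1_ratio),
                 tol_m, max_iter)
    return 1, mse_pos


class PathWorkspace:
    """Per-data-set buffers shared by every penalty path (all mixing values).

    Holds the contiguous per-fold training and held-out matrices, the
    per-fold column norms, and the scattered-residual buffer used for
    the batched gradient, so that running 20 mixing values costs the
    fold-matrix setup only once.
    """

    def __init__(self, X, y, fold_ids=None, dtype=np.float64):
        """``dtype=np.float32`` halves the memory traffic of the sweep and
        gradient kernels; appropriate for CV model selection, where the
        ~1e-6 relative error it introduces is far below fold noise.
        Final coefficient fits should use the float64 default."""
        X = np.asarray(X, dtype=dtype)
        self.dtype = np.dtype(dtype)
        self.y = np.asarray(y, dtype=dtype)
        self.n, self.p = X.shape
        self.XT = np.ascontiguousarray(X.T)
        if fold_ids is None:
            self.train_rows = [np.arange(self.n)]
            self.test_rows = [np.empty(0, dtype=np.int64)]
        else:
            fold_ids = np.asarray(fold_ids)
            folds = np.unique(fold_ids)
            self.train_rows = [np.flatnonzero(fold_ids != f) for f in folds]
            self.test_rows = [np.flatnonzero(fold_ids == f) for f in folds]
        self.K = len(self.train_rows)
        self.XTf = [np.ascontiguousarray(self.XT[:, rows]) for rows in self.train_rows]
        self.XTe = [np.ascontiguousarray(self.XT[:, rows]) for rows in self.test_rows]
        self.y_tr = [self.y[rows] for rows in self.train_rows]
        self.y_te = [self.y[rows] for rows in self.test_rows]
        self.g = np.stack([np.einsum("jn,jn->j", Xf, Xf) for Xf in self.XTf])
        self.m_sizes = np.array([rows.size for rows in self.train_rows])


def _run_path(ws: PathWorkspace, l1_ratio, lambdas, tol, max_iter):
    """Warm-started path on every fold of a workspace.

    Returns ``(mse, beta)``: held-out MSE per (penalty, fold) and the
    (K, p) coefficient state at the final path value.  Folds advance
    through the path asynchronously; each round of the shared gradient
    product verifies the last solved penalty (repairing strong-rule
    violations) and screens the next one.
    """
    p, K = ws.p, ws.K
    lambdas = np.asarray(lambdas, dtype=float)
    L = lambdas.size
    if L > 1 and np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda path must be strictly decreasing")
    if not 0.0 < l1_ratio <= 1.0:
        raise ValueError("the coordinate-descent path requires 0 < l1_ratio <= 1")

    R = np.zeros((K, ws.n), dtype=ws.dtype)
    rf = []
    for f in range(K):
        rf.append(ws.y_tr[f].copy())
        R[f, ws.train_rows[f]] = rf[f]
    beta = np.zeros((K, p), dtype=ws.dtype)
    mark = [np.zeros(p, dtype=np.uint8) for _ in range(K)]
    mse = np.zeros((L, K))
    # pos[f]: path index solved but not yet KKT-verified (-1: none yet)
    pos = np.full(K, -1)
    nxt = np.zeros(K, dtype=int)
    done = np.zeros(K, dtype=bool)

    guard = 0
    while not done.all():
        guard += 1
        if guard > 100 * (L + 10):
            raise RuntimeError("path solver failed to advance; nonconvergence suspected")
        live = np.flatnonzero(~done)
        C_live = R[live] @ ws.XT.T  # each live fold's gradient at its current state
        for ci, f in enumerate(live):
            m = float(ws.m_sizes[f])
            k = nxt[f]
            lam_pos = lambdas[pos[f]] if pos[f] >= 0 else -1.0
            lam_next = lambdas[k] if k < L else -1.0
            lam_prev = lambdas[k - 1] if k > 0 else (lambdas[k] if k < L else -1.0)
            advanced, mse_pos = _fold_round(
                ws.XTf[f], ws.XTe[f], ws.y_te[f], rf[f], beta[f], mark[f],
                ws.g[f], C_live[ci], m, l1_ratio,
                lam_pos, lam_next, lam_prev, tol * m, max_iter,
                _KKT_RTOL, _STRONG_MARGIN,
            )
            R[f, ws.train_rows[f]] = rf[f]
            if advanced == 0:
                continue  # repaired; re-verify next round
            if pos[f] >= 0:
                mse[pos[f], f] = mse_pos
            if k < L:
                pos[f] = k
                nxt[f] = k + 1
            else:
                done[f] = True
    return mse, beta


def enet_path_cv(X, y, l1_ratio, lambdas, fold_ids, tol=1e-7, max_iter=1000, workspace=None):
    """Held-out squared error along a penalty path for every CV fold.

    Parameters
    ----------
    X, y
        Standardized training data (n x p) and response.
    l1_ratio
        Elastic-net mixing parameter in (0, 1]; 1 gives the lasso.
    lambdas
        Strictly decreasing penalty path (shared across folds).
    fold_ids
        Length-n integer array assigning each row to a fold.
    workspace
        Optional precomputed :class:`PathWorkspace` for these
        (X, y, fold_ids), reused across mixing values.

    Returns
    -------
    (n_lambda, K) array of held-out MSE (fold f's column uses fold f as
    the held-out set and the remaining rows for fitting).
    """
    ws = workspace if workspace is not None else PathWorkspace(X, y, fold_ids)
    mse, _ = _run_path(ws, l1_ratio, lambdas, tol, max_iter)
    return mse


def enet_path_fit(X, y, l1_ratio, lambdas, tol=1e-7, max_iter=1000, workspace=None):
    """Coefficients at the last value of a decreasing penalty path (full data).

    Warm-starts through the whole path, matching how a CV-selected
    penalty is refit in pathwise solvers.
    """
    ws = workspace if workspace is not None else PathWorkspace(X, y, None)
    _, beta = _run_path(ws, l1_ratio, lambdas, tol, max_iter)
    return beta[0]
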