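"""Quadratic-program solver for row-stochastic matrix estimation.

Minimizes  sum_t || w_t ∘ (g_t - f_t P) ||_2^2  +  lam * <mask, P>
over matrices P whose rows lie on the probability simplex. ``mask`` carries
the per-entry penalty weight (zero on self-transitions). The solver is
accelerated projected gradient (FISTA with adaptive restart, numba-compiled)
followed by an exact active-set "polish": an equality-constrained KKT solve
restricted to the identified support, accepted only when primal and dual
feasibility hold, which yields solutions accurate to machine-level KKT
residuals at FISTA cost.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _proj_row_simplex(v):
    K = v.shape[0]
    u = np.sort(v)[::-1]
    csum = 0.0
    theta = 0.0
    for i in range(K):
        csum += u[i]
        t = (csum - 1.0) / (i + 1)
        if u[i] - t > 0:
            theta = t
    out = np.empty(K)
    for i in range(K):
        d = v[i] - theta
        out[i] = d if d > 0 else 0.0
    return out


@njit(cache=True)
def _fista(F, G, W, lam, mask, P0, step, tol, maxit):
    n, K = P0.shape
    P = P0.copy()
    Y = P.copy()
    tk = 1.0
    for it in range(maxit):
        R = (F @ Y - G) * W
        grad = 2.0 * (F.T @ R) + lam * mask
        Z = Y - step * grad
        Pn = np.empty_like(P)
        for j in range(n):
            Pn[j] = _proj_row_simplex(Z[j])
        d = Pn - P
        sg = 0.0
        md = 0.0
        for j in range(n):
            for k in range(K):
                sg += grad[j, k] * d[j, k]
                ad = abs(d[j, k])
                if ad > md:
                    md = ad
        if sg > 0.0:  # momentum no longer descends: restart
            Y = P.copy()
            tk = 1.0
            continue
        tn = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        for j in range(n):
            for k in range(K):
                Y[j, k] = Pn[j, k] + ((tk - 1.0) / tn) * d[j, k]
        tk = tn
        P = Pn
        if md < tol:
            break
    return P


def _kkt_solve_on_support(F, G, W, lam, mask, act):
    """Equality-constrained QP on a fixed support; returns (P, mu).

    Builds the per-column Hessian blocks 2 F^T diag(W_k^2-ish) F restricted
    to the active entries, couples rows via the sum-to-one constraints, and
    solves the symmetric KKT system directly.
    """
    n, K = act.shape
    idx = np.flatnonzero(act.ravel())
    nv = idx.size
    pos = {v: i for i, v in enumerate(idx)}
    H = np.zeros((nv, nv))
    g0 = np.zeros(nv)
    for k in range(K):
        rows = [j for j in range(n) if act[j, k]]
        if not rows:
            continue
        Fa = F[:, rows]
        Wk = W[:, k]
        ii = np.array([pos[j * K + k] for j in rows])
        H[np.ix_(ii, ii)] += 2.0 * (Fa * Wk[:, None]).T @ Fa
        g0[ii] += -2.0 * (Fa * Wk[:, None]).T @ G[:, k] + lam * mask[rows, k]
    A = np.zeros((n, nv))
    for j in range(n):
        for k in range(K):
            if act[j, k]:
                A[j, pos[j * K + k]] = 1.0
    KKT = np.block([[H, A.T], [A, np.zeros((n, n))]])
    rhs = np.concatenate([-g0, np.ones(n)])
    try:
        sol = np.linalg.solve(KKT, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(KKT, rhs, rcond=None)[0]
    P = np.zeros((n, K))
    P.ravel()[idx] = sol[:nv]
    return P, sol[nv:]


def _polish(F, G, W, lam, mask, P, support_eps=1e-7):
    """Try an exact KKT solve on P's support; None if KKT conditions fail."""
    n, K = P.shape
    act = P > support_eps
    for j in range(n):
        if not act[j].any():
            act[j, np.argmin(mask[j])] = True
    Pn, mu = _kkt_solve_on_support(F, G, W, lam, mask, act)
    if Pn[act].min() < -1e-9:
        return None
    Pn = np.clip(Pn, 0.0, None)
    grad = 2.0 * (F.T @ ((F @ Pn - G) * W)) + lam * mask
    slack = grad + mu[:, None]
    inact = ~act
    if inact.any() and slack[inact].min() < -1e-7:
        return None
    return Pn


def solve_row_stochastic(
    F: np.ndarray,
    G: np.ndarray,
    lam: float,
    mask: np.ndarray,
    W: np.ndarray | None = None,
    P0: np.ndarray | None = None,
    tol: float = 1e-8,
    maxit: int = 3000,
    rounds: int = 6,
) -> np.ndarray:
    """Solve the penalized row-stochastic least-squares problem.

    ``rounds`` alternates FISTA passes with polish attempts; the first
    successful polish (primal+dual feasible on the identified support) is
    returned, which is the exact optimum of the convex program.
    """
    Tm1, K = G.shape
    n = F.shape[1]
    if W is None:
        W = np.ones_like(G)
    W = np.ascontiguousarray(W, dtype=np.float64)
    L = 2.0 * float(np.linalg.eigvalsh(F.T @ F)[-1]) * float(W.max())
    step = 1.0 / max(L, 1e-12)
    P = (
        np.full((n, K), 1.0 / K)
        if P0 is None
        else np.ascontiguousarray(P0, dtype=np.float64)
    )
    F = np.ascontiguousarray(F, dtype=np.float64)
    G = np.ascontiguousarray(G, dtype=np.float64)
    mask = np.ascontiguousarray(mask, dtype=np.float64)
    for _ in range(rounds):
        P = _fista(F, G, W, lam, mask, P, step, tol, maxit)
        Pp = _polish(F, G, W, lam, mask, P)
        if Pp is not None:
            return Pp
    return P


def solve_restricted_ls(
    F: np.ndarray, G: np.ndarray, support: np.ndarray, W: np.ndarray | None = None
) -> np.ndarray:
    """Unpenalized least squares restricted to a support (plus diagonals).

    Negative entries are pruned from the support and the system re-solved,
    so the result is feasible (nonnegative, rows summing to one). Used to
    debias a penalized fit on its selected support (relaxed refit).
    """
    n, K = support.shape
    act = support.copy().astype(bool)
    for j in range(min(n, K)):
        act[j, j] = True
    if W is None:
        W = np.ones_like(G)
    mask = np.zeros((n, K))
    for _ in range(n * K):
        P, _ = _kkt_solve_on_support(F, G, W, 0.0, mask, act)
        neg = (P < -1e-9) & act
        if not neg.any():
            break
        # never prune a row's last entry
        for j in range(n):
            if neg[j].any() and act[j].sum() > 1:
                act[j, np.argmin(np.where(act[j], P[j], np.inf))] = False
    P = np.clip(P, 0.0, 1.0)
    P /= P.sum(axis=1, keepdims=True)
    return P
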