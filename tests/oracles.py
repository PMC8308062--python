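"""Independent oracles used by the tests.

Each oracle recomputes a quantity by a route unrelated to the package's own
implementation: the L1 solution via a general-purpose bound-constrained
convex solver on the split positive/negative-part formulation, AUC by
brute-force enumeration of case-control pairs, and soft-threshold closed
forms for orthonormal designs.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def oracle_lasso(Z: np.ndarray, yc: np.ndarray, lam: float) -> np.ndarray:
    """Solve min (1/2n)||yc - Z b||^2 + lam ||b||_1 with L-BFGS-B.

    Splits b = u - v with u, v >= 0, giving a smooth bound-constrained
    problem a general convex solver handles; entirely independent of the
    package's coordinate descent.
    """
    n, p = Z.shape

    def fg(w):
        u, v = w[:p], w[p:]
        r = yc - Z @ (u - v)
        f = 0.5 * np.dot(r, r) / n + lam * (u.sum() + v.sum())
        g = -Z.T @ r / n
        return f, np.concatenate([g + lam, -g + lam])

    res = minimize(
        fg,
        np.zeros(2 * p),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * p),
        options={"maxiter": 50_000, "ftol": 1e-18, "gtol": 1e-12},
    )
    approx = res.x[:p] - res.x[p:]
    polished = _polish(Z, yc, lam, approx)
    return polished if polished is not None else approx


def _kkt_gap(Z, yc, beta, lam):
    n = len(yc)
    g = Z.T @ (yc - Z @ beta) / n
    active = beta != 0.0
    va = np.abs(g[active] - lam * np.sign(beta[active])).max(initial=0.0)
    vi = np.maximum(np.abs(g[~active]) - lam, 0.0).max(initial=0.0)
    return max(va, vi)


def _polish(Z, yc, lam, approx, tol=1e-10):
    """Exact solve of the KKT system on the sign pattern the quasi-Newton
    solve identified; returns None unless the result verifies as optimal."""
    n = Z.shape[0]
    G = Z.T @ Z / n
    c = Z.T @ yc / n
    beta = approx.copy()
    for _ in range(20):
        active = np.abs(beta) > 1e-7
        if not active.any():
            zero = np.zeros_like(beta)
            return zero if _kkt_gap(Z, yc, zero, lam) <= tol else None
        s = np.sign(beta[active])
        try:
            ba = np.linalg.solve(G[np.ix_(active, active)], c[active] - lam * s)
        except np.linalg.LinAlgError:
            return None
        beta = np.zeros_like(beta)
        beta[active] = ba
        if np.all(np.sign(ba) == s) and _kkt_gap(Z, yc, beta, lam) <= tol:
            return beta
    return None


def soft_threshold(rho: float, lam: float) -> float:
    return float(np.sign(rho) * max(abs(rho) - lam, 0.0))


def brute_force_auc(scores: np.ndarray, statuses: np.ndarray) -> float:
    """Enumerate every case-control pair; ties count one half."""
    scores = np.asarray(scores, float)
    statuses = np.asarray(statuses)
    case_scores = scores[statuses == 1]
    ctrl_scores = scores[statuses == 0]
    total = 0.0
    for c in case_scores:
        for k in ctrl_scores:
            if c > k:
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(case_scores) * len(ctrl_scores))
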