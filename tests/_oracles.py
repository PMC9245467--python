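"""Independent reference solvers used only by the test suite.

These deliberately share no code with the package solvers: the joint G×E
objective is minimized by monolithic FISTA over the stacked coefficient
vector, small nonsmooth subproblems by generic derivative-free
minimization, and LASSO subproblems by scikit-learn.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize, minimize_scalar


def soft(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def gxe_objective(E, X, Z, y, m, lam, alpha, beta, gamma):
    """(1/2n)||y - Ea - Xb - Zg||^2 + lam*sum_blocks(||b||2 + |b|1) + lam|g|1."""
    n = y.shape[0]
    r = y - E @ alpha - X @ beta - Z @ gamma
    obj = 0.5 / n * float(r @ r)
    for b0 in range(0, X.shape[1], m):
        blk = beta[b0:b0 + m]
        obj += lam * (np.linalg.norm(blk) + np.abs(blk).sum())
    obj += lam * np.abs(gamma).sum()
    return obj


def solve_gxe_fista(E, X, Z, y, m, lam, n_iter=30_000, tol=1e-13):
    """Joint proximal-gradient (FISTA) solution of the G×E objective.

    Treats (alpha, beta, gamma) as one vector; the prox leaves alpha alone,
    applies soft-then-group shrinkage per beta block, and soft-thresholds
    gamma.  Accurate to ~1e-8 in objective on small instances.
    """
    n = y.shape[0]
    q, pX, pZ = E.shape[1], X.shape[1], Z.shape[1]
    A = np.hstack([E, X, Z])
    AtA = A.T @ A / n
    Aty = A.T @ y / n
    step = 1.0 / np.linalg.eigvalsh(AtA)[-1]

    def prox(w, t):
        out = w.copy()
        for b0 in range(q, q + pX, m):
            blk = soft(w[b0:b0 + m], t * lam)
            nrm = np.linalg.norm(blk)
            out[b0:b0 + m] = 0.0 if nrm <= t * lam else blk * (1 - t * lam / nrm)
        out[q + pX:] = soft(w[q + pX:], t * lam)
        return out

    theta = np.zeros(A.shape[1])
    zv = theta.copy()
    tk = 1.0
    for _ in range(n_iter):
        grad = AtA @ zv - Aty
        theta_new = prox(zv - step * grad, step)
        tk_new = 0.5 * (1 + np.sqrt(1 + 4 * tk * tk))
        zv = theta_new + (tk - 1) / tk_new * (theta_new - theta)
        if np.max(np.abs(theta_new - theta)) < tol:
            theta = theta_new
            break
        theta, tk = theta_new, tk_new
    return theta[:q], theta[q:q + pX], theta[q + pX:]


def block_objective(r, Xb, lam, b):
    n = r.shape[0]
    res = r - Xb @ b
    return (0.5 / n * float(res @ res)
            + lam * (np.linalg.norm(b) + np.abs(b).sum()))


def solve_block_nm(r, Xb, lam, restarts=5, seed=0):
    """Nelder-Mead minimization of one sparse-group block subproblem."""
    m = Xb.shape[1]
    rng = np.random.default_rng(seed)
    best_x, best_f = np.zeros(m), block_objective(r, Xb, lam, np.zeros(m))
    starts = [np.zeros(m), np.linalg.lstsq(Xb, r, rcond=None)[0]]
    starts += [rng.normal(size=m) for _ in range(restarts)]
    for x0 in starts:
        res = minimize(lambda b: block_objective(r, Xb, lam, b), x0,
                       method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10,
                                "fatol": 1e-12})
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    return best_x, best_f


def ssvd_alternate_scalar(M, lam, n_samples, max_iter=200, tol=1e-9):
    """Alternating sparse rank-1 fit with each coordinate of each
    subproblem solved by generic 1-D minimization (no closed forms).

    Subproblem (v fixed, unit): min_w (1/2n)||M - w v'||_F^2 + lam|w|_1,
    separable per coordinate; each scalar piece is minimized numerically.
    """
    def coord_min(mv_i):
        # minimize the separable piece (1/2n)(w - (Mv)_i)^2 + lam|w|
        def f(w):
            return 0.5 / n_samples * (w - mv_i) ** 2 + lam * abs(w)
        lo = min(0.0, mv_i) - 1.0
        hi = max(0.0, mv_i) + 1.0
        res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12})
        cand = [res.x, 0.0]
        return min(cand, key=f)

    U0, s0, Vt0 = np.linalg.svd(M, full_matrices=False)
    u, v = U0[:, 0], Vt0[0]
    d = s0[0]
    for _ in range(max_iter):
        mv = M @ v
        w = np.array([coord_min(x) for x in mv])
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0, np.zeros(M.shape[0]), np.zeros(M.shape[1])
        u_new = w / nw
        mu = M.T @ u_new
        w2 = np.array([coord_min(x) for x in mu])
        nw2 = np.linalg.norm(w2)
        if nw2 == 0:
            return 0.0, np.zeros(M.shape[0]), np.zeros(M.shape[1])
        v_new = w2 / nw2
        d_new = nw2
        if (np.linalg.norm(d_new * np.outer(u_new, v_new)
                           - d * np.outer(u, v)) < tol):
            u, v, d = u_new, v_new, d_new
            break
        u, v, d = u_new, v_new, d_new
    return d, u, v
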