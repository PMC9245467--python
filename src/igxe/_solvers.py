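"""Low-level penalized-regression kernels (numba-compiled).

Two workhorses live here:

* :func:`lasso_gram_path` — coordinate descent for a single-response LASSO
  on precomputed Gram/covariance statistics, over a descending penalty grid
  with warm starts.  Used for the per-gene regulatory regressions, where the
  Gram matrix of the regulators is shared across thousands of solves.
* :func:`sgl_path` — the alternating solver for the second-stage G×E model:
  exact least-squares update for the unpenalized environment coefficients,
  blockwise sparse-group-LASSO updates (group check + proximal inner loop)
  for the regulated/residual expression blocks, and coordinate-wise LASSO
  for the residual-regulator coefficients.

All kernels operate on centered (and, for the second stage, typically
standardized) inputs; intercepts are handled by the callers.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "soft_threshold",
    "sparse_group_prox",
    "lasso_gram_path",
    "sgl_path",
    "sgl_solve_single",
]


@njit(cache=True)
def soft_threshold(z, t):
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=True)
def _soft_vec(v, t, out):
    for i in range(v.shape[0]):
        out[i] = soft_threshold(v[i], t)


@njit(cache=True)
def sparse_group_prox(v, t, out):
    """Proximal operator of t*(||.||_2 + ||.||_1), written into ``out``.

    The prox of the sum decomposes: soft-threshold first (L1), then apply
    the group (L2) shrinkage to the thresholded vector.
    """
    _soft_vec(v, t, out)
    nrm = 0.0
    for i in range(out.shape[0]):
        nrm += out[i] * out[i]
    nrm = np.sqrt(nrm)
    if nrm <= t:
        for i in range(out.shape[0]):
            out[i] = 0.0
    else:
        scale = 1.0 - t / nrm
        for i in range(out.shape[0]):
            out[i] *= scale


@njit(cache=True)
def lasso_gram_path(gram, c, lambdas, tol, max_iter):
    """LASSO path on covariance statistics.

    Minimizes (1/2) theta' gram theta - c' theta + lam * |theta|_1 for each
    lam in ``lambdas`` (descending recommended), which for gram = X'X/n and
    c = X'y/n is the standard (1/2n)||y - X theta||^2 + lam|theta|_1.

    Returns an (n_lambda, p) coefficient array.
    """
    p = c.shape[0]
    n_lam = lambdas.shape[0]
    coefs = np.zeros((n_lam, p))
    theta = np.zeros(p)
    # gc = gram @ theta, maintained incrementally
    gc = np.zeros(p)
    active = np.zeros(p, dtype=np.bool_)
    for il in range(n_lam):
        lam = lambdas[il]
        for it in range(max_iter):
            # full sweep
            maxchg = 0.0
            for t in range(p):
                d = gram[t, t]
                if d <= 0.0:
                    continue
                z = c[t] - gc[t] + d * theta[t]
                new = soft_threshold(z, lam) / d
                delta = new - theta[t]
                if delta != 0.0:
                    theta[t] = new
                    for s in range(p):
                        gc[s] += gram[s, t] * delta
                    if abs(delta) > maxchg:
                        maxchg = abs(delta)
                active[t] = theta[t] != 0.0
            if maxchg < tol:
                break
            # active-set sweeps
            for _ in range(50):
                achg = 0.0
                for t in range(p):
                    if not active[t]:
                        continue
                    d = gram[t, t]
                    z = c[t] - gc[t] + d * theta[t]
                    new = soft_threshold(z, lam) / d
                    delta = new - theta[t]
                    if delta != 0.0:
                        theta[t] = new
                        for s in range(p):
                            gc[s] += gram[s, t] * delta
                        if abs(delta) > achg:
                            achg = abs(delta)
                if achg < tol:
                    break
        coefs[il] = theta
    return coefs


@njit(cache=True)
def _block_update(X, Gb, Lb, r, beta, b0, m, n, lam, inner_max, inner_tol):
    """Sparse-group update of one (q+1)-column block against residual r.

    beta[b0:b0+m] is the current block coefficient; r is the full residual
    (y minus all fitted parts).  Returns the largest coefficient change.
    """
    # s = X_b' (r + X_b beta_b) / n  computed without forming rp
    s = np.empty(m)
    for k in range(m):
        acc = 0.0
        col = b0 + k
        for i in range(n):
            acc += X[i, col] * r[i]
        s[k] = acc / n
    for k in range(m):
        for k2 in range(m):
            s[k] += Gb[k, k2] * beta[b0 + k2]
    # group-level zero check: ||soft(s, lam)||_2 <= lam  -> whole block zero
    nrm = 0.0
    for k in range(m):
        v = soft_threshold(s[k], lam)
        nrm += v * v
    old = np.empty(m)
    for k in range(m):
        old[k] = beta[b0 + k]
    if np.sqrt(nrm) <= lam or Lb <= 0.0:
        new = np.zeros(m)
    else:
        # ISTA on the block objective (1/2) b'Gb b - s'b + lam||b||_2 + lam|b|_1
        new = old.copy()
        step = 1.0 / Lb
        tmp = np.empty(m)
        prox = np.empty(m)
        for _ in range(inner_max):
            for k in range(m):
                g = -s[k]
                for k2 in range(m):
                    g += Gb[k, k2] * new[k2]
                tmp[k] = new[k] - step * g
            sparse_group_prox(tmp, step * lam, prox)
            chg = 0.0
            for k in range(m):
                d = abs(prox[k] - new[k])
                if d > chg:
                    chg = d
                new[k] = prox[k]
            if chg < inner_tol:
                break
    maxchg = 0.0
    for k in range(m):
        delta = new[k] - old[k]
        if delta != 0.0:
            col = b0 + k
            for i in range(n):
                r[i] -= X[i, col] * delta
            beta[col] = new[k]
            if abs(delta) > maxchg:
                maxchg = abs(delta)
    return maxchg


@njit(cache=True)
def _gamma_sweep(Z, zn, r, gamma, lam, n):
    maxchg = 0.0
    for t in range(gamma.shape[0]):
        d = zn[t]
        if d <= 0.0:
            continue
        acc = 0.0
        for i in range(n):
            acc += Z[i, t] * r[i]
        z = acc / n + d * gamma[t]
        new = soft_threshold(z, lam) / d
        delta = new - gamma[t]
        if delta != 0.0:
            gamma[t] = new
            for i in range(n):
                r[i] -= Z[i, t] * delta
            if abs(delta) > maxchg:
                maxchg = abs(delta)
    return maxchg


@njit(cache=True)
def _alpha_update(E, EtE, r, alpha):
    """Exact least-squares refresh of the unpenalized environment terms."""
    n, q = E.shape
    # target residual with alpha removed: r + E alpha
    et = np.zeros(q)
    for k in range(q):
        acc = 0.0
        for i in range(n):
            acc += E[i, k] * r[i]
        et[k] = acc
    et = et + EtE @ alpha
    new = np.linalg.solve(EtE, et)
    maxchg = 0.0
    for k in range(q):
        delta = new[k] - alpha[k]
        if delta != 0.0:
            for i in range(n):
                r[i] -= E[i, k] * delta
            alpha[k] = new[k]
            if abs(delta) > maxchg:
                maxchg = abs(delta)
    return maxchg


@njit(cache=True)
def _objective(r, beta, gamma, m, lam, n):
    obj = 0.0
    for i in range(n):
        obj += r[i] * r[i]
    obj /= 2.0 * n
    B = beta.shape[0] // m
    for b in range(B):
        g2 = 0.0
        for k in range(m):
            v = beta[b * m + k]
            g2 += v * v
            obj += lam * abs(v)
        obj += lam * np.sqrt(g2)
    for t in range(gamma.shape[0]):
        obj += lam * abs(gamma[t])
    return obj


@njit(cache=True)
def sgl_solve_single(E, X, Z, y, m, lam, alpha, beta, gamma,
                     tol, max_iter, inner_max, inner_tol,
                     EtE, Gb, Lb, zn):
    """Solve the tied-penalty G×E objective at one penalty value.

    Alternates (i) exact alpha update, (ii) cyclic sparse-group block
    updates over all blocks of X (block width m), (iii) coordinate LASSO
    sweeps for gamma, until the largest coefficient change in a full cycle
    drops below ``tol``.  alpha/beta/gamma are updated in place (warm
    starts).  Returns (n_iter, converged, objective_history).
    """
    n = y.shape[0]
    B = X.shape[1] // m
    r = y - E @ alpha - X @ beta - Z @ gamma
    obj_hist = np.empty(max_iter)
    n_it = 0
    converged = False
    for it in range(max_iter):
        maxchg = _alpha_update(E, EtE, r, alpha)
        for b in range(B):
            chg = _block_update(X, Gb[b], Lb[b], r, beta, b * m, m, n, lam,
                                inner_max, inner_tol)
            if chg > maxchg:
                maxchg = chg
        chg = _gamma_sweep(Z, zn, r, gamma, lam, n)
        if chg > maxchg:
            maxchg = chg
        obj_hist[it] = _objective(r, beta, gamma, m, lam, n)
        n_it = it + 1
        if maxchg < tol:
            converged = True
            break
    return n_it, converged, obj_hist[:n_it]


@njit(cache=True)
def sgl_path(E, X, Z, y, m, lambdas, tol, max_iter, inner_max, inner_tol):
    """Warm-started path of the G×E solver over a descending penalty grid.

    Returns (alphas, betas, gammas, n_iters, converged_flags, objectives).
    """
    n, q = E.shape
    pX = X.shape[1]
    pZ = Z.shape[1]
    B = pX // m
    EtE = E.T @ E
    Gb = np.empty((B, m, m))
    Lb = np.empty(B)
    for b in range(B):
        Xb = X[:, b * m:(b + 1) * m]
        G = (Xb.T @ Xb) / n
        Gb[b] = G
        ev = np.linalg.eigvalsh(G)
        Lb[b] = ev[-1]
    zn = np.empty(pZ)
    for t in range(pZ):
        acc = 0.0
        for i in range(n):
            acc += Z[i, t] * Z[i, t]
        zn[t] = acc / n

    n_lam = lambdas.shape[0]
    alphas = np.zeros((n_lam, q))
    betas = np.zeros((n_lam, pX))
    gammas = np.zeros((n_lam, pZ))
    n_iters = np.zeros(n_lam, dtype=np.int64)
    flags = np.zeros(n_lam, dtype=np.bool_)
    objs = np.zeros(n_lam)

    alpha = np.zeros(q)
    beta = np.zeros(pX)
    gamma = np.zeros(pZ)
    for il in range(n_lam):
        ni, conv, oh = sgl_solve_single(
            E, X, Z, y, m, lambdas[il], alpha, beta, gamma,
            tol, max_iter, inner_max, inner_tol, EtE, Gb, Lb, zn)
        alphas[il] = alpha
        betas[il] = beta
        gammas[il] = gamma
        n_iters[il] = ni
        flags[il] = conv
        objs[il] = oh[ni - 1] if ni > 0 else np.nan
    return alphas, betas, gammas, n_iters, flags, objs
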