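"""Stage 2: penalized G×E model on the decomposed design.

The outcome is regressed on unpenalized environmental main effects, the
regulated-component blocks X1, the residual-expression blocks X2, and the
residual regulators, with a single tied penalty: sparse group LASSO
(lam*||b||_2 + lam*|b|_1) on every (q+1)-sized main+interaction block and a
plain LASSO on the residual-regulator coefficients.  The solver alternates
an exact least-squares update of the environment coefficients with cyclic
blockwise proximal updates, exactly as in the two-step estimation scheme.

Penalty values refer to columns standardized to unit variance and an
outcome scaled to unit variance (the convention under which the default
0-to-3 grid spans the whole path); reported coefficients are mapped back to
the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._solvers import sgl_path, sgl_solve_single, sparse_group_prox
from .decompose import DecomposedDesign, decompose
from .stage1 import fit_stage1

__all__ = [
    "GxEFit",
    "PathFit",
    "sgl_block_update",
    "fit_ige",
    "fit_path",
    "cross_validate",
    "lambda_max",
    "default_lambda_grid",
]


@dataclass
class GxEFit:
    alpha_hat: np.ndarray    # (q,)
    b1_hat: np.ndarray       # (L*(q+1),) blocks of size q+1 per component
    b2_hat: np.ndarray       # (p_g*(q+1),)
    gamma_hat: np.ndarray    # (p_r,)
    lam: float
    n_iter: int
    converged: bool
    objective: float
    objective_history: np.ndarray | None = None
    intercept: float = 0.0

    def b1_blocks(self, q: int) -> np.ndarray:
        return self.b1_hat.reshape(-1, q + 1)

    def b2_blocks(self, q: int) -> np.ndarray:
        return self.b2_hat.reshape(-1, q + 1)


@dataclass
class PathFit:
    lambda_grid: np.ndarray          # descending
    fits: list[GxEFit]
    cv_errors: np.ndarray | None = None
    best_lambda: float | None = None

    def __len__(self) -> int:
        return len(self.fits)


def default_lambda_grid(n_lambda: int = 100, lam_max: float = 3.0,
                        lam_min: float = 0.0, floor: float = 1e-4) -> np.ndarray:
    """Equally spaced penalty grid, descending; an exact-zero endpoint is
    replaced by ``floor`` since the unpenalized p > n fit is ill-posed."""
    grid = np.linspace(lam_min, lam_max, n_lambda)
    grid[grid <= 0.0] = floor
    return np.unique(grid)[::-1].copy()


def sgl_block_update(residual_target: np.ndarray, block_cols: np.ndarray,
                     lam: float, tol: float = 1e-10,
                     max_iter: int = 10_000) -> np.ndarray:
    """Minimize (1/2n)||r - X b||^2 + lam||b||_2 + lam|b|_1 over one block.

    The two-level rule: if the group condition ||soft(X'r/n, lam)||_2 <= lam
    holds the whole block is zero; otherwise proximal-gradient iterations
    with the exact sparse-group prox solve the small convex subproblem.
    """
    r = np.asarray(residual_target, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(block_cols, dtype=float))
    n, m = X.shape
    s = X.T @ r / n
    soft = np.sign(s) * np.maximum(np.abs(s) - lam, 0.0)
    if np.linalg.norm(soft) <= lam:
        return np.zeros(m)
    G = X.T @ X / n
    lip = float(np.linalg.eigvalsh(G)[-1])
    if lip <= 0.0:
        return np.zeros(m)
    step = 1.0 / lip
    b = np.zeros(m)
    out = np.empty(m)
    for _ in range(max_iter):
        grad = G @ b - s
        sparse_group_prox(b - step * grad, step * lam, out)
        if np.max(np.abs(out - b)) < tol:
            b = out.copy()
            break
        b = out.copy()
    return b


class _Scaled:
    """Centered/standardized working copies plus back-mapping statistics.

    ``standardize`` may be True (center and scale to unit variance), the
    string 'center' (center only, keep native column scales), or False
    (use the matrices verbatim).
    """

    def __init__(self, E, X, Z, y, standardize):
        self.standardize = standardize
        if standardize:
            do_scale = standardize != "center"
            self.y_mean = float(y.mean())
            yc = y - self.y_mean
            sd = float(yc.std()) if do_scale else 1.0
            self.sd_y = sd if sd > 1e-12 else 1.0
            self.y = yc / self.sd_y

            def prep(M):
                mu = M.mean(axis=0)
                Mc = M - mu
                if do_scale:
                    sd = Mc.std(axis=0)
                    sd = np.where(sd > 1e-12, sd, 1.0)
                else:
                    sd = np.ones(M.shape[1])
                return np.ascontiguousarray(Mc / sd), mu, sd

            self.E, self.mu_e, self.sd_e = prep(E)
            self.X, self.mu_x, self.sd_x = prep(X)
            self.Z, self.mu_z, self.sd_z = prep(Z)
        else:
            self.y_mean, self.sd_y = 0.0, 1.0
            self.y = y.copy()
            self.E, self.X, self.Z = (np.ascontiguousarray(E),
                                      np.ascontiguousarray(X),
                                      np.ascontiguousarray(Z))
            self.mu_e = np.zeros(E.shape[1]); self.sd_e = np.ones(E.shape[1])
            self.mu_x = np.zeros(X.shape[1]); self.sd_x = np.ones(X.shape[1])
            self.mu_z = np.zeros(Z.shape[1]); self.sd_z = np.ones(Z.shape[1])

    def unscale(self, alpha, beta, gamma):
        """Map solver-scale coefficients to the original data scale, with the
        intercept absorbing all centering offsets."""
        a = alpha * self.sd_y / self.sd_e
        b = beta * self.sd_y / self.sd_x
        g = gamma * self.sd_y / self.sd_z
        icpt = self.y_mean - self.mu_e @ a - self.mu_x @ b - self.mu_z @ g
        return a, b, g, float(icpt)


def _prepare(design: DecomposedDesign, Y, E, R_resid, standardize) -> _Scaled:
    Y = np.asarray(Y, dtype=float).ravel()
    E = np.atleast_2d(np.asarray(E, dtype=float))
    Z = design.R_resid if R_resid is None else np.atleast_2d(np.asarray(R_resid, float))
    X = np.ascontiguousarray(np.hstack([design.X1, design.X2]))
    return _Scaled(E, X, Z, Y, standardize)


def _lambda_max_scaled(sc: _Scaled) -> float:
    Es, Xs, Zs, ys = sc.E, sc.X, sc.Z, sc.y
    n = ys.shape[0]
    alpha = np.linalg.lstsq(Es, ys, rcond=None)[0]
    r0 = ys - Es @ alpha
    lam = float(np.max(np.abs(Zs.T @ r0)) / n) if Zs.shape[1] else 0.0
    m = Es.shape[1] + 1
    S = Xs.T @ r0 / n
    for b0 in range(0, Xs.shape[1], m):
        s = S[b0:b0 + m]
        hi = float(np.max(np.abs(s)))
        if hi == 0.0:
            continue
        lo = 0.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            soft = np.sign(s) * np.maximum(np.abs(s) - mid, 0.0)
            if np.linalg.norm(soft) <= mid:
                hi = mid
            else:
                lo = mid
        lam = max(lam, hi)
    return lam


def lambda_max(design: DecomposedDesign, Y, E, R_resid=None,
               standardize: bool = True) -> float:
    """Smallest penalty at which every penalized coefficient is zero.

    With all blocks zeroed, the environment fit is plain OLS; the block-level
    zero condition ||soft(X_b' r0 / n, lam)||_2 <= lam is monotone in lam,
    so the critical value per block is found by bisection.
    """
    return _lambda_max_scaled(_prepare(design, Y, E, R_resid, standardize))


def fit_ige(design: DecomposedDesign, Y, E, R_resid=None, lam: float = 0.1,
            tol: float = 1e-5, max_iter: int = 500,
            standardize: bool = True, inner_max: int = 200,
            inner_tol: float = 1e-9,
            warm: GxEFit | None = None) -> GxEFit:
    """Fit the G×E model at one penalty value.

    Coefficients start at zero (or at ``warm``); each iteration performs the
    closed-form environment update, a cyclic pass of sparse-group updates
    over all regulated and residual blocks, and a LASSO sweep over the
    residual regulators, until the largest coefficient change falls below
    ``tol``.  The penalized objective is recorded every iteration.
    """
    sc = _prepare(design, Y, E, R_resid, standardize)
    Es, Xs, Zs, ys = sc.E, sc.X, sc.Z, sc.y
    n, q = Es.shape
    m = q + 1
    B = Xs.shape[1] // m

    EtE = Es.T @ Es
    Gb = np.empty((B, m, m))
    Lb = np.empty(B)
    for b in range(B):
        Xb = Xs[:, b * m:(b + 1) * m]
        Gm = Xb.T @ Xb / n
        Gb[b] = Gm
        Lb[b] = np.linalg.eigvalsh(Gm)[-1]
    zn = (Zs ** 2).sum(axis=0) / n

    if warm is not None:
        alpha = warm.alpha_hat * sc.sd_e / sc.sd_y
        beta = np.concatenate([warm.b1_hat, warm.b2_hat]) * sc.sd_x / sc.sd_y
        gamma = warm.gamma_hat * sc.sd_z / sc.sd_y
    else:
        alpha = np.zeros(q)
        beta = np.zeros(Xs.shape[1])
        gamma = np.zeros(Zs.shape[1])

    n_it, conv, hist = sgl_solve_single(Es, Xs, Zs, ys, m, float(lam),
                                        alpha, beta, gamma, tol, max_iter,
                                        inner_max, inner_tol, EtE, Gb, Lb, zn)
    if not conv:
        warnings.warn(f"G×E solver did not converge at lam={lam:g}")
    L1 = design.X1.shape[1]
    a, b_all, g, icpt = sc.unscale(alpha, beta, gamma)
    return GxEFit(alpha_hat=a, b1_hat=b_all[:L1], b2_hat=b_all[L1:],
                  gamma_hat=g,
                  lam=float(lam), n_iter=int(n_it), converged=bool(conv),
                  objective=float(hist[-1]) if n_it else np.nan,
                  objective_history=np.asarray(hist), intercept=icpt)


def fit_path(design: DecomposedDesign, Y, E, R_resid=None,
             lambda_grid: np.ndarray | None = None,
             tol: float = 1e-5, max_iter: int = 500,
             standardize: bool = True, inner_max: int = 200,
             inner_tol: float = 1e-9,
             grid_units: str = "auto") -> PathFit:
    """Warm-started fits over a descending penalty grid.

    The default grid is 100 equally spaced values spanning 0 to 3, with the
    zero endpoint floored for conditioning.  With ``grid_units='auto'`` (the
    default) the nominal grid is mapped affinely onto the problem's own
    penalty range: the largest grid value corresponds to the computed
    maximal penalty of the standardized problem, so the grid always sweeps
    the full path from dense to empty regardless of data scale.  Use
    ``grid_units='absolute'`` to apply the grid values verbatim.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1].copy()
    sc = _prepare(design, Y, E, R_resid, standardize)
    if grid_units == "auto":
        scale = _lambda_max_scaled(sc) / lambda_grid.max()
        effective = lambda_grid * scale
    elif grid_units == "absolute":
        effective = lambda_grid
    else:
        raise ValueError("grid_units must be 'auto' or 'absolute'")
    m = sc.E.shape[1] + 1
    alphas, betas, gammas, n_iters, flags, objs = sgl_path(
        sc.E, sc.X, sc.Z, sc.y, m, effective, tol, max_iter,
        inner_max, inner_tol)
    L1 = design.X1.shape[1]
    fits = []
    for i, lam in enumerate(effective):
        a, b_all, g, icpt = sc.unscale(alphas[i], betas[i], gammas[i])
        fits.append(GxEFit(
            alpha_hat=a, b1_hat=b_all[:L1], b2_hat=b_all[L1:], gamma_hat=g,
            lam=float(lam), n_iter=int(n_iters[i]), converged=bool(flags[i]),
            objective=float(objs[i]), intercept=icpt))
    return PathFit(lambda_grid=lambda_grid, fits=fits)


def predict(fit: GxEFit, design: DecomposedDesign, E, R_resid=None) -> np.ndarray:
    """Fitted outcome values on a (possibly new) decomposed design."""
    E = np.atleast_2d(np.asarray(E, dtype=float))
    Z = design.R_resid if R_resid is None else R_resid
    X = np.hstack([design.X1, design.X2])
    beta = np.concatenate([fit.b1_hat, fit.b2_hat])
    return (fit.intercept + E @ fit.alpha_hat
            + X @ beta + Z @ fit.gamma_hat)


def cross_validate(design: DecomposedDesign | None, Y, E, R_resid=None,
                   lambda_grid: np.ndarray | None = None, folds: int = 5,
                   rng: np.random.Generator | int | None = 0,
                   refit_stage1: bool = False,
                   G: np.ndarray | None = None, R: np.ndarray | None = None,
                   L: int | None = None,
                   stage1_kwargs: dict | None = None,
                   **fit_kwargs) -> tuple[float, np.ndarray]:
    """Five-fold (by default) CV over the penalty grid.

    Folds come from a seeded permutation.  With ``refit_stage1`` the whole
    first stage (per-gene LASSO, sparse SVD, projections) is re-estimated on
    each training fold and held-out rows are projected with training-fold
    loadings — the honest protocol; the default fixed-design mode splits the
    rows of the precomputed design, the simpler (and faster) reading.

    Returns (best_lambda, mean CV error per grid value).
    """
    Y = np.asarray(Y, dtype=float).ravel()
    E = np.atleast_2d(np.asarray(E, dtype=float))
    n = Y.shape[0]
    if folds < 2 or n < folds:
        raise ValueError("need n >= folds >= 2")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1].copy()
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))
    perm = rng.permutation(n)
    fold_id = np.empty(n, dtype=int)
    for f in range(folds):
        fold_id[perm[f::folds]] = f

    if refit_stage1 and (G is None or R is None or L is None):
        raise ValueError("refit_stage1 requires G, R and L")
    if not refit_stage1 and design is None:
        raise ValueError("fixed-design CV requires a precomputed design")

    errs = np.zeros((folds, len(lambda_grid)))
    for f in range(folds):
        tr = fold_id != f
        va = ~tr
        if refit_stage1:
            s1 = fit_stage1(G[tr], R[tr], L=L, **(stage1_kwargs or {}))
            d_tr = decompose(G[tr], R[tr], E[tr], s1)
            d_va = _project_holdout(G[va], R[va], E[va], G[tr], R[tr], E[tr], s1)
            Z_tr, Z_va = d_tr.R_resid, d_va.R_resid
        else:
            d_tr = _subset_design(design, tr)
            d_va = _subset_design(design, va)
            Z_full = design.R_resid if R_resid is None else np.atleast_2d(R_resid)
            Z_tr, Z_va = Z_full[tr], Z_full[va]
        path = fit_path(d_tr, Y[tr], E[tr], R_resid=Z_tr,
                        lambda_grid=lambda_grid, **fit_kwargs)
        X_va = np.hstack([d_va.X1, d_va.X2])
        for i, ft in enumerate(path.fits):
            beta = np.concatenate([ft.b1_hat, ft.b2_hat])
            pred = ft.intercept + E[va] @ ft.alpha_hat + X_va @ beta + Z_va @ ft.gamma_hat
            errs[f, i] = np.mean((Y[va] - pred) ** 2)
    cv = errs.mean(axis=0)
    best = float(lambda_grid[int(np.argmin(cv))])
    return best, cv


def _subset_design(design: DecomposedDesign, rows) -> DecomposedDesign:
    return DecomposedDesign(GV=design.GV[rows], RU=design.RU[rows],
                            G_resid=design.G_resid[rows],
                            R_resid=design.R_resid[rows],
                            X1=design.X1[rows], X2=design.X2[rows],
                            x1_index=design.x1_index, x2_index=design.x2_index)


def _project_holdout(G_va, R_va, E_va, G_tr, R_tr, E_tr, s1) -> DecomposedDesign:
    """Decompose held-out rows using training-fold loadings and projections."""
    from .decompose import regulated_components, build_design, SUPPORT_EPS

    GV_tr, RU_tr = regulated_components(G_tr, R_tr, s1)
    GV_va, RU_va = regulated_components(G_va, R_va, s1)

    def resid_pair(M_tr, M_va, S_tr, S_va, loadings):
        support = np.abs(loadings) > SUPPORT_EPS
        out = M_va.copy()
        patterns: dict[tuple[int, ...], list[int]] = {}
        for j in range(M_tr.shape[1]):
            Sj = tuple(np.nonzero(support[j])[0])
            if Sj:
                patterns.setdefault(Sj, []).append(j)
        for Sj, cols in patterns.items():
            A_tr = S_tr[:, list(Sj)]
            coef, *_ = np.linalg.lstsq(A_tr, M_tr[:, cols], rcond=None)
            out[:, cols] = M_va[:, cols] - S_va[:, list(Sj)] @ coef
        return out

    G_res_va = resid_pair(G_tr, G_va, GV_tr, GV_va, s1.V)
    R_res_va = resid_pair(R_tr, R_va, RU_tr, RU_va, s1.U)
    R_res_va = R_res_va - R_res_va.mean(axis=0)
    X1, X2, i1, i2 = build_design(GV_va, G_res_va, E_va)
    return DecomposedDesign(GV=GV_va, RU=RU_va, G_resid=G_res_va,
                            R_resid=R_res_va, X1=X1, X2=X2,
                            x1_index=i1, x2_index=i2)
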