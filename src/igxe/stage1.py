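"""Stage 1: sparse regulatory models linking regulators to expressions.

The regulator-to-expression map is estimated gene by gene with the LASSO
(the columns of the transition matrix Theta), then decomposed into L rank-1
components (d_l, u_l, v_l) by a recursively deflated sparse singular value
decomposition.  Each component is a linear regulatory model (LRM): a sparse
set of regulators (u_l) driving a sparse set of genes (v_l), with the scale
carried by d_l and unit-norm loadings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._solvers import lasso_gram_path

__all__ = [
    "RegulatoryFit",
    "fit_gene_lasso",
    "sparse_svd_rank1",
    "extract_lrms",
    "fit_stage1",
]

logger = logging.getLogger(__name__)


@dataclass
class RegulatoryFit:
    """Estimated transition matrix and its extracted rank-1 components."""

    Theta_hat: np.ndarray        # (p_r, p_g)
    intercepts: np.ndarray       # (p_g,)
    d: np.ndarray                # (L,) singular values, descending
    U: np.ndarray                # (p_r, L) unit-norm sparse left loadings
    V: np.ndarray                # (p_g, L) unit-norm sparse right loadings
    lambda_stage1: np.ndarray | float | None = None
    lambda_svd: float | None = None
    converged: bool = True
    residual: np.ndarray | None = None   # deflation remainder of Theta_hat

    @property
    def L(self) -> int:
        return int(self.d.shape[0])

    @property
    def lrm_list(self) -> list[tuple[float, np.ndarray, np.ndarray]]:
        return [(float(self.d[l]), self.U[:, l], self.V[:, l])
                for l in range(self.L)]


def _default_lambda_grid(lam_max: float, n_lambda: int = 20,
                         eps: float = 1e-3) -> np.ndarray:
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * eps, n_lambda)


def fit_gene_lasso(G: np.ndarray, R: np.ndarray,
                   lambda_grid: np.ndarray | None = None,
                   folds: int = 5,
                   rng: np.random.Generator | int | None = 0,
                   shared_lambda: bool = False,
                   tol: float = 1e-7, max_iter: int = 1000,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise LASSO estimate of the transition matrix.

    Each gene expression is regressed on all regulators with an L1 penalty
    (objective (1/2n)||g_j - a_j - R theta_j||^2 + lambda |theta_j|_1); the
    penalty is chosen per gene by ``folds``-fold cross-validated prediction
    error (or one shared penalty minimizing the total CV error when
    ``shared_lambda``).  Columns are centered; intercepts absorb the means.

    Returns (Theta_hat, intercepts, chosen_lambdas).
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    n, p_g = G.shape
    p_r = R.shape[1]
    if folds < 2 or n < folds:
        raise ValueError("need n >= folds >= 2")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))

    g_mean = G.mean(axis=0)
    r_mean = R.mean(axis=0)
    Gc = G - g_mean
    Rc = R - r_mean

    g_sd = Gc.std(axis=0)
    constant = g_sd < 1e-12
    if np.any(constant):
        warnings.warn(f"{int(constant.sum())} constant gene column(s); "
                      "their coefficients are set to zero")

    # per-gene penalty grids share a global shape scaled to each gene's own
    # maximal penalty, so CV picks on a comparable geometric ladder
    c_full = (Rc.T @ Gc) / n                      # (p_r, p_g)
    lam_max_gene = np.abs(c_full).max(axis=0)
    if lambda_grid is None:
        grids = [_default_lambda_grid(lam_max_gene[j]) for j in range(p_g)]
    else:
        lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
        grids = [lambda_grid for _ in range(p_g)]
    n_lam = len(grids[0])

    perm = rng.permutation(n)
    fold_id = np.empty(n, dtype=int)
    for f in range(folds):
        fold_id[perm[f::folds]] = f

    cv_err = np.zeros((p_g, n_lam))
    for f in range(folds):
        tr = fold_id != f
        va = ~tr
        Rt, Rv = Rc[tr], Rc[va]
        Gt, Gv = Gc[tr], Gc[va]
        mt = Gt.mean(axis=0)
        Gt = Gt - mt
        rmt = Rt.mean(axis=0)
        Rt = Rt - rmt
        n_tr = Rt.shape[0]
        gram = (Rt.T @ Rt) / n_tr
        ct = (Rt.T @ Gt) / n_tr
        Rv_c = Rv - rmt
        for j in range(p_g):
            if constant[j]:
                continue
            coefs = lasso_gram_path(gram, ct[:, j], np.asarray(grids[j]),
                                    tol, max_iter)
            pred = Rv_c @ coefs.T + mt[j]
            cv_err[j] += ((Gv[:, [j]] - pred) ** 2).sum(axis=0)

    gram_full = (Rc.T @ Rc) / n
    Theta = np.zeros((p_r, p_g))
    chosen = np.zeros(p_g)
    if shared_lambda:
        # grids differ per gene but share rank structure; pick the grid
        # index minimizing total CV error, then use each gene's value there
        best_idx = int(np.argmin(cv_err.sum(axis=0)))
        idxs = [best_idx] * p_g
    else:
        idxs = [int(np.argmin(cv_err[j])) for j in range(p_g)]
    for j in range(p_g):
        if constant[j]:
            chosen[j] = np.inf
            continue
        lam_j = grids[j][idxs[j]]
        chosen[j] = lam_j
        # warm path down to the chosen value for stability
        path = np.asarray(grids[j][:idxs[j] + 1])
        coefs = lasso_gram_path(gram_full, c_full[:, j], path, tol, max_iter)
        Theta[:, j] = coefs[-1]
    intercepts = g_mean - r_mean @ Theta
    return Theta, intercepts, chosen


def _sign_fix(d: float, u: np.ndarray, v: np.ndarray):
    """Resolve the (u, v) -> (-u, -v) ambiguity: largest-|v| entry positive."""
    if d > 0 and v.any():
        k = int(np.argmax(np.abs(v)))
        if v[k] < 0:
            return d, -u, -v
    return d, u, v


def sparse_svd_rank1(M: np.ndarray, lambda_svd: float = 0.0,
                     tol: float = 1e-6, max_iter: int = 200,
                     n_samples: int = 1,
                     ) -> tuple[float, np.ndarray, np.ndarray, bool]:
    """Best sparse rank-1 approximation d*u*v' of M.

    Locally minimizes (1/2n)||M - d u v'||_F^2 + lambda|d u|_1 + lambda|d v|_1
    with unit-norm u, v by alternating soft-thresholded regressions: fixing
    the unit vector on one side, the other side's unnormalized loading has a
    closed-form soft-threshold solution; scale is re-absorbed into d each
    half step.  ``n_samples`` is the n of the 1/2n factor, so the effective
    entrywise threshold is n*lambda.

    Returns (d, u, v, converged); an all-zero M (or full shrinkage) yields
    (0, zeros, zeros, True).
    """
    M = np.asarray(M, dtype=float)
    p_r, p_g = M.shape
    thr = float(lambda_svd) * float(n_samples)
    zero = (0.0, np.zeros(p_r), np.zeros(p_g), True)
    if not np.any(M):
        return zero

    # dense leading singular pair as the start
    U0, s0, Vt0 = np.linalg.svd(M, full_matrices=False)
    u = U0[:, 0]
    v = Vt0[0]
    prev = s0[0] * np.outer(u, v)
    converged = False
    d = s0[0]
    for _ in range(max_iter):
        wu = _soft(M @ v, thr)
        nu = np.linalg.norm(wu)
        if nu == 0.0:
            return zero
        u = wu / nu
        wv = _soft(M.T @ u, thr)
        nv = np.linalg.norm(wv)
        if nv == 0.0:
            return zero
        v = wv / nv
        d = nv
        cur = d * np.outer(u, v)
        if np.linalg.norm(cur - prev) < tol:
            converged = True
            break
        prev = cur
    if not converged:
        warnings.warn("sparse_svd_rank1 did not converge; returning current iterate")
    d, u, v = _sign_fix(d, u, v)
    return float(d), u, v, converged


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def ssvd_objective(M: np.ndarray, d: float, u: np.ndarray, v: np.ndarray,
                   lambda_svd: float, n_samples: int = 1) -> float:
    """The penalized rank-1 objective, for diagnostics and testing."""
    fit = 0.5 / n_samples * np.linalg.norm(M - d * np.outer(u, v)) ** 2
    return fit + lambda_svd * d * (np.abs(u).sum() + np.abs(v).sum())


def extract_lrms(Theta_hat: np.ndarray, L: int,
                 lambda_svd: float | str = 0.0,
                 tol: float = 1e-6, max_iter: int = 200,
                 n_samples: int = 1,
                 intercepts: np.ndarray | None = None,
                 data: tuple[np.ndarray, np.ndarray] | None = None,
                 ) -> RegulatoryFit:
    """Recursive rank-1 sparse SVD with deflation.

    Extracts up to L components, subtracting d_l u_l v_l' from the running
    residual after each extraction; stops early if a component degenerates
    to zero.  ``lambda_svd='bic'`` selects a single penalty shared by all
    components from a small grid by a BIC-type criterion; when ``data``
    (centered G, R) is supplied the criterion is evaluated on the
    expression-prediction residual ||G - R U D V'||^2, whose irreducible
    noise keeps the fit term on a scale where loading sparsity can compete.
    """
    Theta_hat = np.asarray(Theta_hat, dtype=float)
    if L < 1:
        raise ValueError("L must be >= 1")
    if lambda_svd == "bic":
        lam = _select_lambda_svd_bic(Theta_hat, L, tol, max_iter, n_samples,
                                     data=data)
    else:
        lam = float(lambda_svd)

    p_r, p_g = Theta_hat.shape
    resid = Theta_hat.copy()
    ds, us, vs = [], [], []
    all_conv = True
    for l in range(L):
        d, u, v, conv = sparse_svd_rank1(resid, lam, tol, max_iter, n_samples)
        all_conv &= conv
        if d <= 0.0:
            logger.info("extraction stopped early at l=%d (zero component)", l)
            break
        ds.append(d)
        us.append(u)
        vs.append(v)
        resid = resid - d * np.outer(u, v)

    if ds:
        d_arr = np.array(ds)
        order = np.argsort(-d_arr, kind="stable")
        U = np.column_stack([us[i] for i in order])
        V = np.column_stack([vs[i] for i in order])
        d_arr = d_arr[order]
    else:
        d_arr = np.zeros(0)
        U = np.zeros((p_r, 0))
        V = np.zeros((p_g, 0))
    if intercepts is None:
        intercepts = np.zeros(p_g)
    return RegulatoryFit(Theta_hat=Theta_hat, intercepts=np.asarray(intercepts, float),
                         d=d_arr, U=U, V=V, lambda_svd=lam, converged=all_conv,
                         residual=resid)


_LAMBDA_SVD_FRACS = (0.0, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2)


def _select_lambda_svd_bic(Theta: np.ndarray, L: int, tol: float,
                           max_iter: int, n_samples: int,
                           data: tuple[np.ndarray, np.ndarray] | None = None,
                           ) -> float:
    """BIC-type selection of the shared sparse-SVD penalty.

    Candidates are fractions of the first component's full-shrinkage
    threshold.  The criterion is N*log(RSS/N) + log(N)*df with df the total
    loading support size; RSS is the expression-prediction residual
    ||G - R U D V'||_F^2 when (G, R) are available (preferred — the
    irreducible expression noise keeps the fit term from swamping df),
    otherwise the transition-matrix residual.
    """
    if not np.any(Theta):
        return 0.0
    _, s0, Vt0 = np.linalg.svd(Theta, full_matrices=False)
    t_max = np.abs(Theta @ Vt0[0]).max()
    if data is not None:
        Gc, Rc = data
        Gc = Gc - Gc.mean(axis=0)
        Rc = Rc - Rc.mean(axis=0)
        N = Gc.size
    else:
        N = Theta.size
    best_lam, best_bic = 0.0, np.inf
    for frac in _LAMBDA_SVD_FRACS:
        lam = frac * t_max / n_samples
        resid = Theta.copy()
        df = 0
        for _ in range(L):
            d, u, v, _ = sparse_svd_rank1(resid, lam, tol, max_iter, n_samples)
            if d <= 0:
                break
            df += int(np.count_nonzero(u) + np.count_nonzero(v))
            resid = resid - d * np.outer(u, v)
        if data is not None:
            rss = float(np.linalg.norm(Gc - Rc @ (Theta - resid)) ** 2)
        else:
            rss = float(np.linalg.norm(resid) ** 2)
        rss = max(rss, 1e-300)
        bic = N * np.log(rss / N) + np.log(N) * df
        if bic < best_bic:
            best_bic, best_lam = bic, lam
    return best_lam


def fit_stage1(G: np.ndarray, R: np.ndarray, L: int,
               lambda_svd: float | str = "bic",
               folds: int = 5,
               rng: np.random.Generator | int | None = 0,
               shared_lambda: bool = False,
               svd_tol: float = 1e-6) -> RegulatoryFit:
    """Convenience pipeline: per-gene LASSO then sparse-SVD extraction."""
    n = np.atleast_2d(G).shape[0]
    Theta, intercepts, chosen = fit_gene_lasso(G, R, folds=folds, rng=rng,
                                               shared_lambda=shared_lambda)
    fit = extract_lrms(Theta, L, lambda_svd=lambda_svd, tol=svd_tol,
                       n_samples=n, intercepts=intercepts,
                       data=(np.atleast_2d(G), np.atleast_2d(R)))
    fit.lambda_stage1 = chosen
    return fit
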