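"""LASSO comparison methods for the simulation benchmark.

Two reference approaches against which the integrative model is evaluated:

* J-LASSO — one joint LASSO on the pooled design [E | G | G×E | R], all
  genetic terms penalized with a single penalty, environments unpenalized.
* S-LASSO — two separate LASSO fits, one for the expression side
  (Y on [E | G | G×E]) and one for the regulator side (Y on [E | R]).

Both share the evaluation machinery and penalty-grid convention of the
integrative fit (columns and outcome standardized, grid on that scale).
The unpenalized environment block is handled exactly by partialling it out:
projecting Y and every penalized column off the span of E and solving the
LASSO on the residuals reproduces the joint solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .simulate import OmicsDataset
from .stage2 import default_lambda_grid

__all__ = ["BaselineFit", "BaselinePath", "fit_j_lasso", "fit_s_lasso",
           "j_lasso_path", "s_lasso_path"]


@dataclass
class BaselineFit:
    method: str                       # "s_lasso" | "j_lasso"
    gene_effect_hat: np.ndarray       # (p_g, q+1): main + q interaction slots
    gamma_hat: np.ndarray             # (p_r,)
    alpha_hat: np.ndarray             # (q,)
    lam: float | tuple[float, float]


@dataclass
class BaselinePath:
    method: str
    lambda_grid: np.ndarray           # descending
    gene_effects: np.ndarray          # (n_lambda, p_g, q+1)
    gammas: np.ndarray                # (n_lambda, p_r)
    alphas: np.ndarray                # (n_lambda, q)


def _interaction_design(G: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Columns ordered gene-major: [G_j, G_j*E_1, ..., G_j*E_q] per gene."""
    n, p_g = G.shape
    q = E.shape[1]
    X = np.empty((n, p_g * (q + 1)))
    X[:, ::q + 1] = G
    for k in range(q):
        X[:, k + 1::q + 1] = G * E[:, [k]]
    return X


def _partial_out(E: np.ndarray, *mats):
    """Residualize matrices/vectors on the span of [1, E]."""
    n = E.shape[0]
    A = np.column_stack([np.ones(n), E])
    Q, _ = np.linalg.qr(A)
    out = []
    for M in mats:
        M = np.asarray(M, dtype=float)
        out.append(M - Q @ (Q.T @ M))
    return out


def _std_lasso_path(X: np.ndarray, y: np.ndarray, E: np.ndarray,
                    lambda_grid: np.ndarray, grid_units: str = "absolute"):
    """LASSO path of y on X with E unpenalized, on the standardized scale.

    With ``grid_units='auto'`` the nominal grid is mapped affinely onto
    [0, lambda_max] of the standardized, environment-partialled problem —
    the same path-spanning convention as the integrative fit.  Returns
    (coefs (n_lambda, p) on the original scale, alphas (n_lambda, q)).
    """
    n = y.shape[0]
    sd_y = y.std() if y.std() > 1e-12 else 1.0
    sd_x = X.std(axis=0)
    sd_x = np.where(sd_x > 1e-12, sd_x, 1.0)
    Xp, yp = _partial_out(E, X / sd_x, y / sd_y)
    if grid_units == "auto":
        lam_max = float(np.max(np.abs(Xp.T @ yp)) / n)
        lambda_grid = lambda_grid * (lam_max / lambda_grid.max())
    # scikit-learn's alpha matches the (1/2n) objective convention; the
    # near-unpenalized dense end of the path is intentionally approximate
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = lasso_path(Xp, yp, alphas=lambda_grid, max_iter=3000,
                                 tol=1e-5)
    coefs = coefs.T * (sd_y / sd_x)          # (n_lambda, p), original scale
    # back out the unpenalized environment coefficients per grid point
    A = np.column_stack([np.ones(n), E])
    sol = np.linalg.lstsq(A, y[:, None] - X @ coefs.T, rcond=None)[0]
    alphas = sol[1:].T                        # (n_lambda, q)
    return coefs, alphas


def j_lasso_path(dataset: OmicsDataset, lambda_grid: np.ndarray | None = None,
                 grid_units: str = "auto") -> BaselinePath:
    """Joint LASSO path over [G | G×E | R] with unpenalized environments."""
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1].copy()
    q = dataset.E.shape[1]
    p_g, p_r = dataset.G.shape[1], dataset.R.shape[1]
    W = _interaction_design(dataset.G, dataset.E)
    X = np.hstack([W, dataset.R])
    coefs, alphas = _std_lasso_path(X, dataset.Y, dataset.E, lambda_grid,
                                    grid_units=grid_units)
    gene = coefs[:, :p_g * (q + 1)].reshape(len(lambda_grid), p_g, q + 1)
    gam = coefs[:, p_g * (q + 1):]
    return BaselinePath("j_lasso", lambda_grid, gene, gam, alphas)


def s_lasso_path(dataset: OmicsDataset, lambda_grid: np.ndarray | None = None,
                 grid_units: str = "auto") -> BaselinePath:
    """Separate LASSO paths: expressions (+interactions) and regulators."""
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1].copy()
    q = dataset.E.shape[1]
    p_g = dataset.G.shape[1]
    W = _interaction_design(dataset.G, dataset.E)
    gene_coefs, alphas = _std_lasso_path(W, dataset.Y, dataset.E, lambda_grid,
                                         grid_units=grid_units)
    gam_coefs, _ = _std_lasso_path(dataset.R, dataset.Y, dataset.E,
                                   lambda_grid, grid_units=grid_units)
    gene = gene_coefs.reshape(len(lambda_grid), p_g, q + 1)
    return BaselinePath("s_lasso", lambda_grid, gene, gam_coefs, alphas)


def fit_j_lasso(dataset: OmicsDataset, lam: float) -> BaselineFit:
    """Joint LASSO at a single (absolute, standardized-scale) penalty."""
    path = j_lasso_path(dataset, np.array([lam]), grid_units="absolute")
    return BaselineFit("j_lasso", path.gene_effects[0], path.gammas[0],
                       path.alphas[0], float(lam))


def fit_s_lasso(dataset: OmicsDataset,
                lambdas: float | tuple[float, float]) -> BaselineFit:
    """Separate LASSO fits at single penalty values (one per sub-model)."""
    if np.isscalar(lambdas):
        lam_g = lam_r = float(lambdas)
    else:
        lam_g, lam_r = (float(v) for v in lambdas)
    q = dataset.E.shape[1]
    p_g = dataset.G.shape[1]
    W = _interaction_design(dataset.G, dataset.E)
    gene_coefs, alphas = _std_lasso_path(W, dataset.Y, dataset.E,
                                         np.array([lam_g]))
    gam_coefs, _ = _std_lasso_path(dataset.R, dataset.Y, dataset.E,
                                   np.array([lam_r]))
    gene = gene_coefs.reshape(1, p_g, q + 1)
    return BaselineFit("s_lasso", gene[0], gam_coefs[0], alphas[0],
                       (lam_g, lam_r))
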