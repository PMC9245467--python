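"""Stage-2 design construction: regulated components, residuals, interactions.

Given the extracted regulatory components, each gene expression splits into
the part explained by the components it belongs to (its regulated scores
G v_l) and a residual obtained by perpendicular projection.  The same
recipe residualizes the regulators against their component scores R u_l.
The G×E design then pairs every regulated component and every residual
expression with each environmental factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stage1 import RegulatoryFit

__all__ = [
    "DecomposedDesign",
    "regulated_components",
    "residualize",
    "build_design",
    "decompose",
]

#: loading entries below this magnitude are treated as structural zeros
SUPPORT_EPS = 1e-12


@dataclass
class DecomposedDesign:
    GV: np.ndarray        # (n, L) regulated-expression scores
    RU: np.ndarray        # (n, L) regulated-regulator scores
    G_resid: np.ndarray   # (n, p_g)
    R_resid: np.ndarray   # (n, p_r)
    X1: np.ndarray        # (n, L*(q+1))
    X2: np.ndarray        # (n, p_g*(q+1))
    # column -> (component index, effect slot); slot 0 = main, k = E_k
    x1_index: list[tuple[int, int]] = field(default_factory=list)
    x2_index: list[tuple[int, int]] = field(default_factory=list)

    @property
    def L(self) -> int:
        return self.GV.shape[1]


def regulated_components(G: np.ndarray, R: np.ndarray,
                         fit: RegulatoryFit) -> tuple[np.ndarray, np.ndarray]:
    """Component scores GV[:, l] = G v_l and RU[:, l] = R u_l."""
    G = np.atleast_2d(np.asarray(G, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if G.shape[1] != fit.V.shape[0] or R.shape[1] != fit.U.shape[0]:
        raise ValueError("G/R dimensions do not match the regulatory fit")
    return G @ fit.V, R @ fit.U


def residualize(M: np.ndarray, scores: np.ndarray,
                loadings: np.ndarray) -> np.ndarray:
    """Perpendicular-projection residuals of each feature column.

    For feature j with membership set S_j = {l : loadings[j, l] != 0}, the
    residual is (I - P) M_j where P projects onto span{scores[:, l], l in
    S_j}.  Features in no component pass through unchanged.  Rank-deficient
    score sub-matrices fall back to a pseudo-inverse (least-squares)
    projection with a warning.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    p = M.shape[1]
    resid = M.copy()
    support = np.abs(loadings) > SUPPORT_EPS     # (p, L)
    # features sharing a membership pattern share one projection
    patterns: dict[tuple[int, ...], list[int]] = {}
    for j in range(p):
        S = tuple(np.nonzero(support[j])[0])
        if S:
            patterns.setdefault(S, []).append(j)
    for S, cols in patterns.items():
        A = scores[:, list(S)]
        if np.linalg.matrix_rank(A) < A.shape[1]:
            warnings.warn("rank-deficient component scores; using pseudo-inverse projection")
        coef, *_ = np.linalg.lstsq(A, M[:, cols], rcond=None)
        resid[:, cols] = M[:, cols] - A @ coef
    return resid


def build_design(GV: np.ndarray, G_resid: np.ndarray, E: np.ndarray,
                 center: bool = True,
                 ) -> tuple[np.ndarray, np.ndarray, list, list]:
    """Interaction design blocks.

    Block l of X1 is [GV_l, GV_l*E_1, ..., GV_l*E_q] (elementwise products);
    X2 blocks are built the same way from the residual expressions.  Factors
    are centered before the products are formed and the product columns are
    centered again, so the unpenalized environment update is well
    conditioned.  Returns (X1, X2, x1_index, x2_index).
    """
    GV = np.atleast_2d(np.asarray(GV, dtype=float))
    G_resid = np.atleast_2d(np.asarray(G_resid, dtype=float))
    E = np.atleast_2d(np.asarray(E, dtype=float))
    n, q = E.shape

    if center:
        GV = GV - GV.mean(axis=0)
        G_resid = G_resid - G_resid.mean(axis=0)
        E = E - E.mean(axis=0)

    def blocks(M):
        p = M.shape[1]
        X = np.empty((n, p * (q + 1)))
        index = []
        for j in range(p):
            b = j * (q + 1)
            X[:, b] = M[:, j]
            index.append((j, 0))
            for k in range(q):
                col = M[:, j] * E[:, k]
                if center:
                    col = col - col.mean()
                X[:, b + 1 + k] = col
                index.append((j, k + 1))
        return X, index

    X1, x1_index = blocks(GV)
    X2, x2_index = blocks(G_resid)
    return X1, X2, x1_index, x2_index


def decompose(G: np.ndarray, R: np.ndarray, E: np.ndarray,
              fit: RegulatoryFit, center: bool = True) -> DecomposedDesign:
    """Full design pipeline: scores, residuals, and interaction blocks."""
    GV, RU = regulated_components(G, R, fit)
    G_resid = residualize(G, GV, fit.V)
    R_resid = residualize(R, RU, fit.U)
    if center:
        R_resid = R_resid - R_resid.mean(axis=0)
    X1, X2, x1_index, x2_index = build_design(GV, G_resid, E, center=center)
    return DecomposedDesign(GV=GV, RU=RU, G_resid=G_resid, R_resid=R_resid,
                            X1=X1, X2=X2, x1_index=x1_index, x2_index=x2_index)
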