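"""Selection-accuracy evaluation: calls, ROC curves, partial AUC, summaries.

Fitted models are mapped to binary selection calls at two levels — gene
main/interaction slots (p_g × (q+1)) and regulators (p_r) — and compared
with the simulation ground truth across the whole penalty path.  Sweeping
the path traces an ROC curve per family; its trapezoidal area over the
false-positive range the path actually achieves (no extrapolation to
FPR = 1) is the partial AUC (PAUC) used to rank methods.

For the integrative fit, component-level coefficients are mapped back to
genes/regulators through the loading supports: a gene slot is called when
its residual-block coefficient is nonzero or when any component containing
the gene has that slot active; a regulator is called when its residual
coefficient is nonzero or any component containing it is active at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import BaselinePath, j_lasso_path, s_lasso_path
from .decompose import SUPPORT_EPS, decompose
from .simulate import GroundTruth, SimulationConfig, simulate_dataset
from .stage1 import RegulatoryFit, fit_stage1
from .stage2 import GxEFit, PathFit, fit_path

__all__ = [
    "SelectionCall",
    "ROCResult",
    "call_selection_ige",
    "call_selection_baseline",
    "roc_from_path",
    "roc_from_calls",
    "run_replicate",
    "replicate_summary",
    "FAMILIES",
]

FAMILIES = ("gene_gxe", "regulators")

#: coefficients below this magnitude count as unselected
CALL_EPS = 1e-8


@dataclass
class SelectionCall:
    gene_calls: np.ndarray       # (p_g, q+1) in {0, 1}
    regulator_calls: np.ndarray  # (p_r,) in {0, 1}
    lam: float


@dataclass
class ROCResult:
    family: str
    fpr: np.ndarray
    tpr: np.ndarray
    pauc: float
    n_lambda: int


def call_selection_ige(fit: GxEFit, reg_fit: RegulatoryFit) -> SelectionCall:
    """Map component-level coefficients to gene/regulator selection calls."""
    p_r, L = reg_fit.U.shape
    p_g = reg_fit.V.shape[0]
    q1 = fit.b2_hat.shape[0] // p_g
    b1 = fit.b1_hat.reshape(L, q1) if L else np.zeros((0, q1))
    b2 = fit.b2_hat.reshape(p_g, q1)

    gene = (np.abs(b2) > CALL_EPS).astype(np.int8)
    reg = (np.abs(fit.gamma_hat) > CALL_EPS).astype(np.int8)
    v_sup = np.abs(reg_fit.V) > SUPPORT_EPS       # (p_g, L)
    u_sup = np.abs(reg_fit.U) > SUPPORT_EPS       # (p_r, L)
    b1_active = np.abs(b1) > CALL_EPS             # (L, q1)
    # gene slot (j, k) is on if any component containing gene j has slot k on
    gene |= (v_sup.astype(np.int32) @ b1_active.astype(np.int32) > 0).astype(np.int8)
    # regulator t is on if any component containing t has any active slot
    reg |= (u_sup.astype(np.int32) @ b1_active.any(axis=1).astype(np.int32) > 0).astype(np.int8)
    return SelectionCall(gene_calls=gene, regulator_calls=reg, lam=fit.lam)


def call_selection_baseline(path: BaselinePath, i: int) -> SelectionCall:
    gene = (np.abs(path.gene_effects[i]) > CALL_EPS).astype(np.int8)
    reg = (np.abs(path.gammas[i]) > CALL_EPS).astype(np.int8)
    return SelectionCall(gene_calls=gene, regulator_calls=reg,
                         lam=float(path.lambda_grid[i]))


def _rates(calls: SelectionCall, truth: GroundTruth, family: str):
    if family == "gene_gxe":
        called = calls.gene_calls.ravel().astype(bool)
        true = (np.abs(truth.gene_effects.ravel()) > 0)
    elif family == "regulators":
        called = calls.regulator_calls.astype(bool)
        true = (np.abs(truth.gamma) > 0)
    else:
        raise ValueError(f"unknown family {family!r}")
    P = int(true.sum())
    N = int((~true).sum())
    if P == 0:
        raise ValueError("degenerate truth: no positives in this family")
    tp = int((called & true).sum())
    fp = int((called & ~true).sum())
    return fp / N if N else 0.0, tp / P


def roc_from_calls(calls: list[SelectionCall], truth: GroundTruth,
                   family: str) -> ROCResult:
    """ROC over a sequence of per-penalty selection calls.

    Points are sorted by FPR; at tied FPR only the maximal TPR is kept;
    (0, 0) is prepended.  PAUC is the trapezoidal area over the achieved
    FPR range — a path that never reaches high FPR is not extrapolated.
    """
    pts = np.array([_rates(c, truth, family) for c in calls])
    fpr, tpr = pts[:, 0], pts[:, 1]
    order = np.argsort(fpr, kind="stable")
    fpr, tpr = fpr[order], tpr[order]
    uf, inv = np.unique(fpr, return_inverse=True)
    ut = np.zeros_like(uf)
    np.maximum.at(ut, inv, tpr)
    if uf.size == 0 or uf[0] > 0.0:
        uf = np.concatenate([[0.0], uf])
        ut = np.concatenate([[0.0], ut])
    pauc = float(np.trapezoid(ut, uf))
    return ROCResult(family=family, fpr=uf, tpr=ut, pauc=pauc,
                     n_lambda=len(calls))


def roc_from_path(path: PathFit | BaselinePath, truth: GroundTruth,
                  family: str, reg_fit: RegulatoryFit | None = None
                  ) -> ROCResult:
    """ROC/PAUC for an integrative or baseline penalty path."""
    if isinstance(path, BaselinePath):
        calls = [call_selection_baseline(path, i)
                 for i in range(len(path.lambda_grid))]
    else:
        if reg_fit is None:
            raise ValueError("integrative paths need the stage-1 fit "
                             "for the component-to-feature mapping")
        calls = [call_selection_ige(f, reg_fit) for f in path.fits]
    return roc_from_calls(calls, truth, family)


def run_replicate(config: SimulationConfig, seed: int,
                  methods: tuple[str, ...] = ("ige", "j_lasso", "s_lasso"),
                  lambda_grid: np.ndarray | None = None,
                  L: int | None = None,
                  stage1_kwargs: dict | None = None,
                  stage2_kwargs: dict | None = None) -> dict[str, float]:
    """Simulate one dataset and score every method's PAUC in both families.

    Returns a flat dict keyed ``{method}/{family}``.
    """
    dataset, truth = simulate_dataset(config, np.random.default_rng(seed))
    out: dict[str, float] = {}
    if L is None:
        L = config.L_true
    def record(method, roc, fam):
        out[f"{method}/{fam}"] = roc.pauc
        out[f"{method}/{fam}:max_fpr"] = float(roc.fpr[-1])

    if "ige" in methods:
        s1 = fit_stage1(dataset.G, dataset.R, L=L, rng=seed,
                        **(stage1_kwargs or {}))
        design = decompose(dataset.G, dataset.R, dataset.E, s1)
        path = fit_path(design, dataset.Y, dataset.E,
                        lambda_grid=lambda_grid, **(stage2_kwargs or {}))
        for fam in FAMILIES:
            record("ige", roc_from_path(path, truth, fam, s1), fam)
    if "j_lasso" in methods:
        jp = j_lasso_path(dataset, lambda_grid)
        for fam in FAMILIES:
            record("j_lasso", roc_from_path(jp, truth, fam), fam)
    if "s_lasso" in methods:
        sp = s_lasso_path(dataset, lambda_grid)
        for fam in FAMILIES:
            record("s_lasso", roc_from_path(sp, truth, fam), fam)
    return out


def replicate_summary(configs: list[SimulationConfig],
                      methods: tuple[str, ...] = ("ige", "j_lasso", "s_lasso"),
                      n_replicates: int = 10, base_seed: int = 0,
                      lambda_grid: np.ndarray | None = None,
                      **kwargs) -> pd.DataFrame:
    """Mean (sd) PAUC per scenario/method/family across seeded replicates.

    Replicate r of every scenario uses seed ``base_seed + r`` so scenarios
    are paired across sample sizes and signal strengths.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates for a dispersion estimate")
    rows = []
    for config in configs:
        reps = [run_replicate(config, base_seed + r, methods, lambda_grid,
                              **kwargs)
                for r in range(n_replicates)]
        for method in methods:
            for fam in FAMILIES:
                vals = np.array([rep[f"{method}/{fam}"] for rep in reps])
                rows.append({
                    "covariance": config.cov_kind, "signal": config.signal,
                    "n": config.n, "method": method, "family": fam,
                    "pauc_mean": float(vals.mean()),
                    "pauc_sd": float(vals.std(ddof=1)),
                    "n_replicates": n_replicates,
                })
    return pd.DataFrame(rows)
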