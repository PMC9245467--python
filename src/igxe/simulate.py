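"""Synthetic multi-omics G×E data generator.

Emulates the simulation design used to benchmark the two-stage integrative
G×E selection method: regulators (methylation + copy number) drawn from a
multivariate normal with AR-1 or banded correlation, gene expressions driven
through a sparse low-rank transition matrix, environments from an AR-1
normal, and a continuous outcome assembled from environmental main effects,
gene main effects, gene-environment interactions, and direct regulator
effects, all under standard normal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "OmicsDataset",
    "build_covariance",
    "simulate_loadings",
    "simulate_dataset",
]

_COV_KINDS = ("ar1", "banded", "custom")
_SIGNALS = ("weak", "strong")

#: coefficient ranges for the outcome model, by role
COEF_RANGES = {
    "gene_weak": (0.25, 0.5),
    "gene_strong": (0.5, 1.0),
    "regulator": (1.0, 2.0),
    "environment": (2.0, 3.0),
    "loading": (2.0, 4.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the benchmark conditions: n in {500, 1000} subjects,
    200 gene expressions, 200 regulators, 4 environments, 20 generating
    rank-1 regulatory components with 5-sparse loadings, 30 causal genes
    with 4 nonzero effect slots each, and 30 causal regulators.
    """

    n: int = 500
    p_g: int = 200
    p_r: int = 200
    q: int = 4
    L_true: int = 20
    support_size: int = 5
    cov_kind: str = "ar1"
    custom_cov: np.ndarray | None = None
    signal: str = "weak"
    n_causal_genes: int = 30
    effects_per_gene: int = 4
    n_causal_regulators: int = 30
    disjoint_supports: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cov_kind not in _COV_KINDS:
            raise ValueError(f"cov_kind must be one of {_COV_KINDS}, got {self.cov_kind!r}")
        if self.signal not in _SIGNALS:
            raise ValueError(f"signal must be one of {_SIGNALS}, got {self.signal!r}")
        for name in ("n", "p_g", "p_r", "q", "L_true", "support_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.disjoint_supports:
            need = self.L_true * self.support_size
            if need > min(self.p_g, self.p_r):
                raise ValueError(
                    "disjoint loading supports need L_true*support_size "
                    f"<= min(p_g, p_r); got {need} > {min(self.p_g, self.p_r)}")
        if self.n_causal_genes > self.p_g:
            raise ValueError("n_causal_genes exceeds p_g")
        if self.effects_per_gene > self.q + 1:
            raise ValueError("effects_per_gene exceeds q+1 coefficient slots")
        if self.n_causal_regulators > self.p_r:
            raise ValueError("n_causal_regulators exceeds p_r")
        if self.cov_kind == "custom":
            C = self.custom_cov
            if C is None:
                raise ValueError("cov_kind='custom' requires custom_cov")
            C = np.asarray(C, dtype=float)
            if C.shape != (self.p_r, self.p_r):
                raise ValueError("custom_cov must be p_r x p_r")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError("custom_cov must be symmetric")
            try:
                np.linalg.cholesky(C)
            except np.linalg.LinAlgError as exc:
                raise ValueError("custom_cov is not positive definite") from exc


@dataclass
class GroundTruth:
    """Generating coefficients and loadings of one simulated dataset.

    ``gene_effects`` holds, per gene, the main effect in column 0 and the
    q interaction coefficients in columns 1..q.
    """

    alpha: np.ndarray            # (q,)
    gene_effects: np.ndarray     # (p_g, q+1)
    gamma: np.ndarray            # (p_r,)
    U_true: np.ndarray           # (p_r, L_true), unnormalized loadings
    V_true: np.ndarray           # (p_g, L_true)
    Theta_true: np.ndarray       # (p_r, p_g)


@dataclass
class OmicsDataset:
    """Aligned outcome / environment / expression / regulator matrices."""

    Y: np.ndarray                  # (n,)
    E: np.ndarray                  # (n, q)
    G: np.ndarray                  # (n, p_g)
    R: np.ndarray                  # (n, p_r)
    regulator_blocks: tuple[int, int]
    g_names: list[str] = field(default_factory=list)
    r_names: list[str] = field(default_factory=list)
    e_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        self.E = np.atleast_2d(np.asarray(self.E, dtype=float))
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        n = self.Y.shape[0]
        for name, M in (("E", self.E), ("G", self.G), ("R", self.R)):
            if M.shape[0] != n:
                raise ValueError(f"{name} has {M.shape[0]} rows, outcome has {n}")
            if not np.all(np.isfinite(M)):
                raise ValueError(f"{name} contains missing or non-finite values")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("Y contains missing or non-finite values")
        if sum(self.regulator_blocks) != self.R.shape[1]:
            raise ValueError("regulator block sizes must sum to p_r")
        if not self.g_names:
            self.g_names = [f"G{j+1}" for j in range(self.G.shape[1])]
        if not self.r_names:
            p1 = self.regulator_blocks[0]
            self.r_names = [f"DM{t+1}" for t in range(p1)] + [
                f"CNA{t+1}" for t in range(self.R.shape[1] - p1)]
        if not self.e_names:
            self.e_names = [f"E{k+1}" for k in range(self.E.shape[1])]

    @property
    def n(self) -> int:
        return self.Y.shape[0]


def build_covariance(config: SimulationConfig) -> np.ndarray:
    """Regulator covariance: AR-1 with rho=0.25, banded with rho=0.33, or custom.

    AR-1 entries are 0.25**|i-j|; the banded structure has 0.33 on the first
    off-diagonal and zeros elsewhere off the unit diagonal.
    """
    p = config.p_r
    if config.cov_kind == "ar1":
        return toeplitz(0.25 ** np.arange(p))
    if config.cov_kind == "banded":
        first = np.zeros(p)
        first[0] = 1.0
        if p > 1:
            first[1] = 0.33
        return toeplitz(first)
    return np.asarray(config.custom_cov, dtype=float).copy()


def _environment_covariance(q: int) -> np.ndarray:
    # environments follow an AR-1 with correlation 0.5**|i-j|
    return toeplitz(0.5 ** np.arange(q))


def _sparse_loadings(p: int, L: int, s: int, rng: np.random.Generator,
                     disjoint: bool) -> np.ndarray:
    M = np.zeros((p, L))
    if disjoint:
        perm = rng.permutation(p)
        for l in range(L):
            idx = perm[l * s:(l + 1) * s]
            M[idx, l] = rng.uniform(*COEF_RANGES["loading"], size=s)
    else:
        for l in range(L):
            idx = rng.choice(p, size=s, replace=False)
            M[idx, l] = rng.uniform(*COEF_RANGES["loading"], size=s)
    return M


def simulate_loadings(config: SimulationConfig,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw sparse loading matrices and the implied transition matrix.

    Each of the L_true columns of U (regulator side) and V (gene side)
    receives ``support_size`` nonzeros drawn from Uniform(2, 4).  With
    disjoint supports (default), columns are mutually orthogonal, so
    different rank-1 regulatory components share no genes or regulators.
    """
    if config.disjoint_supports:
        need = config.L_true * config.support_size
        if need > min(config.p_g, config.p_r):
            raise ValueError("infeasible disjoint supports")
    U = _sparse_loadings(config.p_r, config.L_true, config.support_size, rng,
                         config.disjoint_supports)
    V = _sparse_loadings(config.p_g, config.L_true, config.support_size, rng,
                         config.disjoint_supports)
    Theta = U @ V.T
    return U, V, Theta


def simulate_dataset(config: SimulationConfig,
                     rng: np.random.Generator | int | None = None
                     ) -> tuple[OmicsDataset, GroundTruth]:
    """Generate one dataset plus its ground truth.

    Draw order is fixed (loadings, causal-gene assignment, gamma, alpha,
    then R, expression noise, E, outcome noise) so a given (config, seed)
    always yields bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    U, V, Theta = simulate_loadings(config, rng)

    # outcome coefficients
    lo, hi = COEF_RANGES["gene_weak" if config.signal == "weak" else "gene_strong"]
    gene_effects = np.zeros((config.p_g, config.q + 1))
    causal_genes = rng.choice(config.p_g, size=config.n_causal_genes, replace=False)
    for j in causal_genes:
        slots = rng.choice(config.q + 1, size=config.effects_per_gene, replace=False)
        gene_effects[j, slots] = rng.uniform(lo, hi, size=config.effects_per_gene)
    gamma = np.zeros(config.p_r)
    causal_regs = rng.choice(config.p_r, size=config.n_causal_regulators, replace=False)
    gamma[causal_regs] = rng.uniform(*COEF_RANGES["regulator"],
                                     size=config.n_causal_regulators)
    alpha = rng.uniform(*COEF_RANGES["environment"], size=config.q)

    # design matrices
    Sigma = build_covariance(config)
    chol = np.linalg.cholesky(Sigma)
    R = rng.standard_normal((config.n, config.p_r)) @ chol.T
    eps_cov = Sigma if config.p_g == config.p_r else _resized_cov(Sigma, config.p_g, config)
    eps = rng.standard_normal((config.n, config.p_g)) @ np.linalg.cholesky(eps_cov).T
    G = R @ Theta + eps
    chol_e = np.linalg.cholesky(_environment_covariance(config.q))
    E = rng.standard_normal((config.n, config.q)) @ chol_e.T

    beta = gene_effects[:, 0]
    eta = gene_effects[:, 1:]
    Y = E @ alpha + G @ beta + R @ gamma
    for k in range(config.q):
        Y += (G * E[:, [k]]) @ eta[:, k]
    Y += rng.standard_normal(config.n)

    p1 = config.p_r // 2
    dataset = OmicsDataset(Y=Y, E=E, G=G, R=R,
                           regulator_blocks=(p1, config.p_r - p1))
    truth = GroundTruth(alpha=alpha, gene_effects=gene_effects, gamma=gamma,
                        U_true=U, V_true=V, Theta_true=Theta)
    return dataset, truth


def _resized_cov(Sigma: np.ndarray, p: int, config: SimulationConfig) -> np.ndarray:
    """Expression-noise covariance when p_g differs from p_r.

    The expression noise shares the regulators' covariance family; when the
    dimensions differ the same structural recipe is rebuilt at size p_g.
    """
    if config.cov_kind == "ar1":
        return toeplitz(0.25 ** np.arange(p))
    if config.cov_kind == "banded":
        first = np.zeros(p)
        first[0] = 1.0
        if p > 1:
            first[1] = 0.33
        return toeplitz(first)
    k = min(p, Sigma.shape[0])
    out = np.eye(p)
    out[:k, :k] = Sigma[:k, :k]
    return out
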