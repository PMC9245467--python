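import numpy as np
import pytest

import igxe


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully featured configuration for pipeline-level tests."""
    return igxe.SimulationConfig(n=120, p_g=24, p_r=24, q=3, L_true=4,
                                 support_size=3, n_causal_genes=6,
                                 effects_per_gene=3, n_causal_regulators=6,
                                 seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return igxe.simulate_dataset(small_config, np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_stage1(small_dataset):
    ds, _ = small_dataset
    return igxe.fit_stage1(ds.G, ds.R, L=4, rng=7)


@pytest.fixture(scope="session")
def small_design(small_dataset, small_stage1):
    ds, _ = small_dataset
    return igxe.decompose(ds.G, ds.R, ds.E, small_stage1)


def make_tiny_gxe(seed=0, n=60, L=2, p_g=4, p_r=4, q=2, snr=1.0):
    """Random small second-stage problem built directly from matrices."""
    rng = np.random.default_rng(seed)
    GV = rng.normal(size=(n, L))
    G_resid = rng.normal(size=(n, p_g))
    E = rng.normal(size=(n, q))
    Z = rng.normal(size=(n, p_r))
    X1, X2, i1, i2 = igxe.build_design(GV, G_resid, E, center=False)
    design = igxe.DecomposedDesign(GV=GV, RU=GV.copy(), G_resid=G_resid,
                                   R_resid=Z, X1=X1, X2=X2,
                                   x1_index=i1, x2_index=i2)
    beta1 = np.zeros(X1.shape[1])
    beta1[: q + 1] = rng.normal(size=q + 1)
    beta2 = np.zeros(X2.shape[1])
    beta2[: 2] = rng.normal(size=2)
    gamma = np.zeros(p_r)
    gamma[0] = 1.0
    alpha = rng.normal(size=q)
    y = (E @ alpha + X1 @ beta1 + X2 @ beta2 + Z @ gamma
         + rng.normal(size=n) / snr)
    return design, y, E, Z
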