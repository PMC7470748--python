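import numpy as np
import pandas as pd
import pytest

from smist.simulate import SimulationConfig, run_replicates
from smist.summary_io import LDPanel, harmonized_from_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gene(rng, P=8, K=1, rho=0.3, dialect="wald", n_ref=5000):
    """Small synthetic harmonized gene with an exchangeable-correlation panel
    and arbitrary (but reproducible) summary statistics."""
    cor = np.full((P, P), rho)
    np.fill_diagonal(cor, 1.0)
    d = rng.uniform(0.2, 0.6, size=P)
    cov = cor * np.outer(np.sqrt(d), np.sqrt(d))
    panel = LDPanel([f"v{i}" for i in range(P)], cov, n_ref=n_ref)
    W = rng.normal(0, 0.5, size=(P, K))
    beta = rng.normal(0, 0.1, size=P)
    se = rng.uniform(0.02, 0.08, size=P)
    if dialect == "wald":
        return harmonized_from_arrays("g1", panel.variant_ids, W, beta=beta,
                                      se=se, panel=panel)
    if dialect == "score":
        v = 1.0 / se ** 2
        return harmonized_from_arrays("g1", panel.variant_ids, W,
                                      score_u=beta * v, score_v=v, panel=panel)
    return harmonized_from_arrays("g1", panel.variant_ids, W, z=beta / se,
                                  panel=panel)


@pytest.fixture
def small_gene(rng):
    return make_gene(rng)


@pytest.fixture(scope="session")
def null_replicates():
    """Complete-null replicate table (no mediator effect, no direct effects)
    shared by the calibration and independence checks.

    1000 studies of 1000 cases / 1000 controls each, exact in-sample LD.
    """
    cfg = SimulationConfig(gamma=0.0, tau_var=0.0, prop_direct=0.0)
    return run_replicates(cfg, 1000, seed=0)
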