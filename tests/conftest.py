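"""Shared fixtures: moderately sized planted simulations reused across
test modules to keep the suite fast."""

import numpy as np
import pytest

from fatetrace.io_qc import normalize_log
from fatetrace.synthetic import SimConfig, simulate_bifurcation


@pytest.fixture(scope="session")
def planted():
    """Standard planted bifurcation: strong effects, early divergence."""
    cfg = SimConfig(n_cells=1500, n_genes=500, frac_branch_genes=0.2,
                    divergence_times=(10.0, 40.0), effect_size=1.5,
                    nb_dispersion=0.2, branch_gene_boost=6.0,
                    split_time=20.0, seed=11)
    cm, meta, truth = simulate_bifurcation(cfg)
    return cm, meta, truth


@pytest.fixture(scope="session")
def planted_norm(planted):
    cm, meta, truth = planted
    return normalize_log(cm), meta, truth


@pytest.fixture(scope="session")
def null_sim():
    """No branch effect anywhere: every gene is null."""
    cfg = SimConfig(n_cells=1200, n_genes=600, frac_branch_genes=0.0,
                    divergence_times=(), effect_size=0.0, seed=23)
    cm, meta, truth = simulate_bifurcation(cfg)
    return cm, meta, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
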