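import warnings

import numpy as np
import pytest

from anchornet.io import ExpressionMatrix, GeneCNVMatrix
from anchornet.simulate import SimConfig, simulate_cohort


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Recovery experiments intentionally trip 'low power' style warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_expr(rng):
    vals = rng.normal(size=(6, 12))
    return ExpressionMatrix([f"G{i}" for i in range(6)],
                            [f"S{j}" for j in range(12)], vals)


@pytest.fixture
def small_cnv(rng):
    vals = rng.normal(size=(6, 12))
    return GeneCNVMatrix([f"G{i}" for i in range(6)],
                         [f"S{j}" for j in range(12)], vals)


@pytest.fixture(scope="session")
def base_cohort():
    """Moderate cohort reused across tests (no swaps)."""
    cfg = SimConfig(n_genes=120, n_samples=150, edge_density=0.03,
                    cis_fraction=0.4, beta=1.0, n_cnv_blocks=12, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(cfg)
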