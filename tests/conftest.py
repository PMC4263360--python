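import numpy as np
import pytest

import nutlinsim as ns
from nutlinsim.model_core import N_SPECIES


@pytest.fixture(scope="session")
def rko_params() -> ns.ParameterSet:
    """Calibrated RKO-like fixture (2 Mdm2 gene copies)."""
    return ns.validate_parameters(ns.ParameterSet())


@pytest.fixture(scope="session")
def sjsa_params() -> ns.ParameterSet:
    """SJSA-1-like fixture: Mdm2 amplified, lower p53 threshold."""
    return ns.load_config(ns.fixture_path("sjsa1"))


@pytest.fixture(scope="session")
def rko_baseline(rko_params):
    """Drug-free baseline cell state (shared; steady-state solve is costly)."""
    return ns.initial_state(rko_params)


@pytest.fixture()
def random_states():
    """Positive random state vectors for RHS comparisons."""
    rng = np.random.default_rng(42)

    def make(n: int = 10, scale: float = 1e4):
        for _ in range(n):
            y = rng.uniform(0.0, scale, N_SPECIES)
            genes = tuple(int(g) for g in rng.integers(0, 3, 3))
            n_ext = float(rng.uniform(0.0, 5.0))
            yield y, genes, n_ext

    return make
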