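import warnings

import numpy as np
import pytest

from msodyn import McmcConfig, sample_posterior
from msodyn.encounters import block_arrays
from msodyn.inference import ConvergenceWarning
from msodyn.simulate import BlockSpec, SimConfig, generate


@pytest.fixture(scope="session")
def small_truth():
    """A small synthetic dataset with known parameters and states."""
    cfg = SimConfig(blocks=[BlockSpec("A", 15, 2000, 2007)], seed=42)
    return generate(cfg)


@pytest.fixture(scope="session")
def small_design(small_truth):
    return block_arrays(small_truth.data, "A")


@pytest.fixture(scope="session")
def small_fit(small_truth):
    """A reduced-length fit of the small dataset, reused across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return sample_posterior(
            small_truth.data,
            config=McmcConfig(n_chains=2, n_iter=2500, n_burnin=500, thin=5, seed=7),
            block="A",
        )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
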