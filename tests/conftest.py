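import warnings

import numpy as np
import pytest

import forager
from forager.config import RunConfig
from forager.inference import ConvergenceWarning, fit


@pytest.fixture(scope="session")
def table1():
    """Study-sized synthetic dataset plus its generative truth."""
    ds, truth = forager.simulate_dataset("table1", seed=20)
    return ds, truth


@pytest.fixture(scope="session")
def shellfish_fit(table1):
    """One age-only shellfish fit at the study scale, shared across tests."""
    ds, truth = table1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        draws = fit(
            ds,
            RunConfig(chains=2, warmup=2000, samples=400, thin=5, seed=3),
            resource="shellfish",
        )
    return draws, truth
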