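import numpy as np
import pytest

import plasmidfate as pf


@pytest.fixture(scope="session")
def params() -> pf.ModelParameters:
    """The main illustrative parameter set (bistable regime)."""
    return pf.ModelParameters()


@pytest.fixture(scope="session")
def settings() -> pf.SimulationSettings:
    return pf.SimulationSettings()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_parameters(rng: np.random.Generator) -> pf.ModelParameters:
    """Draw parameters uniformly from the explored sensitivity ranges."""
    return pf.ModelParameters(
        lam=rng.uniform(0.5, 2.0),
        gamma=rng.uniform(0.5, 2.0),
        A=rng.uniform(0.0, 2.0),
        cR=rng.uniform(0.0, 0.5),
        cP=rng.uniform(0.0, 0.5),
        beta=rng.uniform(0.0, 0.25),
        s=rng.uniform(0.0, 0.1),
    )
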