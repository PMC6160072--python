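import numpy as np
import pytest

from rumidyn import CohortSpec, ModelParams


@pytest.fixture(scope="session")
def params() -> ModelParams:
    """Shipped point estimates with default integration settings."""
    return ModelParams.defaults()


@pytest.fixture()
def small_spec() -> CohortSpec:
    """A scaled-down cohort for fast pipeline tests."""
    return CohortSpec(n_girls=60, n_boys=50)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
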