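import numpy as np
import pytest

from chamberflux.synthetic import ScenarioSpec


@pytest.fixture(scope="session")
def noise_free_spec() -> ScenarioSpec:
    return ScenarioSpec(seed=42).noise_free()


@pytest.fixture(scope="session")
def noisy_spec() -> ScenarioSpec:
    return ScenarioSpec(seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
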