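import numpy as np
import pytest

from herbfp.synthetic import GeneratorConfig, TriturationDesign, generate_study


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Coarse, quick instrument settings for unit and integration tests."""
    return GeneratorConfig(points_per_min=40)


@pytest.fixture(scope="session")
def small_design() -> TriturationDesign:
    return TriturationDesign(n_matrices=4, ratios=(1 / 10, 1 / 2), seed=7)


@pytest.fixture(scope="session")
def small_study(small_design, small_config):
    """4 matrices x 2 ratios + 4 blanks + 1 reference = 13 fingerprints."""
    return generate_study(small_design, config=small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
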