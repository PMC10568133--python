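import numpy as np
import pytest

from momix.io import PipelineConfig
from momix.kegg import MiniKeggFixture
from momix.synth import SyntheticDesign, build_mini_kegg


@pytest.fixture(scope="session")
def mini_kegg() -> MiniKeggFixture:
    return build_mini_kegg()


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture()
def small_design() -> SyntheticDesign:
    """Reduced design for fast unit tests; planted structure kept intact."""
    return SyntheticDesign(seed=7, n_per_group=10, n_pathways=40, n_species=30)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
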