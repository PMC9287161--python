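import numpy as np
import pytest

from sigcrf.grammar import build_state_space
from sigcrf import synth
from sigcrf.types import SpClass


@pytest.fixture(scope="session")
def space():
    return build_state_space()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced small synthetic dataset shared by slow-ish tests."""
    counts = {SpClass.SEC_SPI: 25, SpClass.SEC_SPII: 15,
              SpClass.SEC_SPIII: 10, SpClass.TAT_SPI: 15,
              SpClass.TAT_SPII: 10, SpClass.NO_SP: 25}
    return synth.generate(synth.GeneratorConfig(counts=counts, seed=77))


@pytest.fixture(scope="session")
def family_fixture():
    """Six well-separated single-class homology families (5 members)."""
    return synth.generate_homology_families(
        synth.GeneratorConfig(seed=3), 6, 0.05,
        classes=[SpClass.SEC_SPI])
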