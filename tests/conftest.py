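import numpy as np
import pytest

from mixedpower import DesignParams, muse_spec, table2_spec


@pytest.fixture(scope="session")
def design():
    return DesignParams(alpha=0.025, target_power=0.80)


@pytest.fixture(scope="session")
def design_bonf():
    return DesignParams(alpha=0.025, target_power=0.80, adjustment="bonferroni")


@pytest.fixture(scope="session")
def muse():
    return muse_spec()


@pytest.fixture(scope="session")
def grid_spec():
    """Equicorrelated 4-outcome design, all standardized effects 0.12."""
    return table2_spec((0.12, 0.12, 0.12, 0.12), 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
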