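import numpy as np
import pytest

from nichemix.isotope_core import IsotopePair, SourceDistribution
from nichemix.synthetic_data import default_scenario, pooled_epphlo


@pytest.fixture(scope="session")
def scenario():
    """The default study-conditions scenario (master seed 0)."""
    return default_scenario(seed=0)


@pytest.fixture(scope="session")
def source_table(scenario):
    return scenario.source_table()


@pytest.fixture(scope="session")
def fall_sources_red(source_table):
    """Red-squirrel fall model endmembers: seeds, truffles, epphlo."""
    return [
        source_table["red_seeds"],
        source_table["truffles"],
        pooled_epphlo(source_table),
    ]


@pytest.fixture(scope="session")
def separated_sources():
    """Three artificial, strongly separated sources for recovery tests."""
    return [
        SourceDistribution("A", IsotopePair(-12.0, 0.0), (0.5, 0.5), 10),
        SourceDistribution("B", IsotopePair(-24.0, 12.0), (0.5, 0.5), 10),
        SourceDistribution("C", IsotopePair(-30.0, -2.0), (0.5, 0.5), 10),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
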