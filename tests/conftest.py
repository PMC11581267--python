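import pytest

from exante.io import write_fixture
from exante.synthetic import COWPEA_EXEMPLAR, GeneratorConfig
from exante.types import CountryBaseline, EnvironmentMacro


@pytest.fixture
def cowpea():
    """The one fully published technology profile (drought-tolerant cowpea)."""
    return COWPEA_EXEMPLAR


@pytest.fixture
def unit_country():
    """Single-country baseline with unit elasticities and round numbers,
    convenient for hand-checked surplus arithmetic."""
    return CountryBaseline(
        country="toyland",
        production=1000.0,
        area=500.0,
        price=100.0,
        supply_elasticity=1.0,
        demand_elasticity=1.0,
        ag_gdp=1_000_000.0,
        poor_count=1_000_000.0,
        poverty_elasticity=-0.7,
    )


@pytest.fixture
def unit_macro(unit_country):
    return EnvironmentMacro(environment="toy-env", countries=(unit_country,))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Seeded 12-technology / 3-country study written as CSV tables."""
    outdir = tmp_path_factory.mktemp("study")
    write_fixture(outdir, GeneratorConfig(seed=0))
    return outdir
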