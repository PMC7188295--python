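import pandas as pd
import pytest

from kdrhaplo import build_default_panel, panel_index


@pytest.fixture(scope="session")
def models_panel():
    return build_default_panel()


@pytest.fixture(scope="session")
def models(models_panel):
    return models_panel[0]


@pytest.fixture(scope="session")
def panel(models_panel):
    return models_panel[1]


@pytest.fixture(scope="session")
def pidx(panel):
    return panel_index(panel)


def make_manifest(*rows):
    """rows of (barcode, population_id, country, continent, year)."""
    return pd.DataFrame(list(rows), columns=[
        "barcode", "population_id", "country", "continent", "year"])


@pytest.fixture
def one_pop_manifest():
    return make_manifest(("ACGTACGTAC", "P1", "Brazil", "South America", 2010))
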