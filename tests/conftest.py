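import pytest

from netpharm import datasets
from netpharm.screen import ScreenConfig, dedupe_compounds, screen_compounds


@pytest.fixture(scope="session")
def bundled_records():
    return datasets.load_compound_table()


@pytest.fixture(scope="session")
def bundled_unique(bundled_records):
    screened = screen_compounds(bundled_records, ScreenConfig())
    unique, _ = dedupe_compounds(screened)
    return unique


@pytest.fixture(scope="session")
def bundled_tmap():
    return datasets.example_target_map()


@pytest.fixture(scope="session")
def bundled_genes():
    return datasets.example_gene_universe()


@pytest.fixture(scope="session")
def bundled_summary():
    return datasets.load_herb_summary()
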