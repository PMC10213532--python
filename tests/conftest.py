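import pytest

from acetotrace import concat, synthetic
from acetotrace import screen as screen_mod


@pytest.fixture(scope="session")
def mock_db():
    """The standard mock database: 20 genomes, fixed seed."""
    return synthetic.generate_database(synthetic.DatabaseConfig(n_genomes=20), seed=42)


@pytest.fixture(scope="session")
def submap(mock_db):
    return concat.build_concatenated_query(mock_db.panel)


@pytest.fixture(scope="session")
def search_records(mock_db, submap):
    return synthetic.simulate_search_output(mock_db.truth, submap)


@pytest.fixture(scope="session")
def screened(search_records, submap):
    rules = screen_mod.default_rules(eche_subqueries=["echE"])
    return screen_mod.screen(search_records, submap, rules)


@pytest.fixture(scope="session")
def retained(screened):
    return [h for h in screened if h.passed]
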