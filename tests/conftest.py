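from pathlib import Path

import pytest

from exergame import default_terms, session_to_graph, sideraises_fixture

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def terms():
    return default_terms()


@pytest.fixture()
def fixture_game():
    return sideraises_fixture()[0]


@pytest.fixture()
def fixture_session():
    return sideraises_fixture()[1]


@pytest.fixture()
def fixture_graph(fixture_session, terms):
    return session_to_graph(fixture_session, terms)


@pytest.fixture()
def small_config():
    """A pilot small enough for per-test simulation."""
    from exergame import SimulationConfig

    return SimulationConfig(
        n_players=2, n_male=1, visits_per_player=2, games_per_visit=3, seed=11
    )


@pytest.fixture(scope="session")
def golden_canonical():
    return (DATA_DIR / "sideraises_session_canonical.nt").read_text(encoding="utf-8")
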