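import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "landpop",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("landpop")

from landpop import (  # noqa: E402
    Scenario,
    default_initial_state,
    default_parameters,
    integrate,
    make_default_fixture,
)


@pytest.fixture(scope="session")
def params():
    """Packaged baseline parameters."""
    return default_parameters()


@pytest.fixture(scope="session")
def initial(params):
    return default_initial_state(params)


@pytest.fixture(scope="session")
def bau_scenario(params, initial):
    """Baseline projection: historical start, integrated through 2120."""
    return Scenario(
        params=params, initial=initial, t_start=1960.0, t_end=2120.0,
        output_step=1.0, label="BAU",
    )


@pytest.fixture(scope="session")
def bau_trajectory(bau_scenario):
    return integrate(bau_scenario)


@pytest.fixture(scope="session")
def fixture_series(tmp_path_factory):
    """The standard synthetic observation fixture (written to a temp dir)."""
    out = tmp_path_factory.mktemp("fixture") / "observed.csv"
    series = make_default_fixture(out)
    return series, out
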