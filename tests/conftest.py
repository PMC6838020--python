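import pytest
from hypothesis import HealthCheck, settings

from fructoflux import build_default_network, infer_all, reference_fixture, run_resting_cell
from fructoflux.synthdata import DEFAULT_TIME_GRID

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def network():
    return build_default_network()


@pytest.fixture(scope="session")
def fixture_configs():
    """Shipped ground-truth configs, (C1 tracer, C2 tracer)."""
    return reference_fixture()


@pytest.fixture(scope="session")
def noiseless_pair(fixture_configs, network):
    """Noiseless fixture simulations for both tracers."""
    c1, c2 = fixture_configs
    return (
        run_resting_cell(c1, DEFAULT_TIME_GRID, network),
        run_resting_cell(c2, DEFAULT_TIME_GRID, network),
    )


@pytest.fixture(scope="session")
def fixture_estimate(noiseless_pair):
    """infer_all output on the noiseless fixture pair."""
    return infer_all(*noiseless_pair, seed=0)
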