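import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def somatic_fit():
    """Gaussian-time fit of the default somatic diary (shared: ~2 s)."""
    from navblock.report import somatic_diary_fit
    return somatic_diary_fit(seed=7)


@pytest.fixture(scope="session")
def availability():
    from navblock.report import availability_midpoints
    return availability_midpoints(seed=7)


@pytest.fixture(scope="session")
def recovery():
    from navblock.report import recovery_half_times
    return recovery_half_times(seed=7)


@pytest.fixture(scope="session")
def vehicle_bundle():
    """Short no-drug diary bundle with noise disabled."""
    from navblock import make_protocol, simulate_experiment, get_scenario
    sc = get_scenario("vehicle")
    proto = make_protocol("diary_step", n_sweeps=20)
    return simulate_experiment(sc, proto, seed=11)
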