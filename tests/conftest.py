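import pytest

from mbaptox import ExposureEvent, build_model, default_bundle, simulate

ROUTES = ("intravenous", "intratracheal", "oral")


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()


@pytest.fixture(scope="session")
def model(bundle):
    return build_model(bundle)


@pytest.fixture(scope="session")
def results_10mgkg(model):
    """High-accuracy 72 h simulations at 10 mg/kg bw for all three routes."""
    return {
        route: simulate(model, ExposureEvent(route, 10.0), t_end=72.0,
                        rtol=1e-8, atol=1e-10)
        for route in ROUTES
    }


@pytest.fixture(scope="session")
def result_iv50(model):
    """50 mg/kg bw intravenous bolus, 72 h."""
    return simulate(model, ExposureEvent("intravenous", 50.0), t_end=72.0,
                    rtol=1e-8, atol=1e-10)
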