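import pytest

from graftsim.circuit import CircuitModel
from graftsim.control import PressureRegime, run_regulated_stimulation


@pytest.fixture(scope="session")
def normotensive_regime():
    return PressureRegime(80.0, 120.0, frequency=1.0, tolerance=2.0)


@pytest.fixture(scope="session")
def ct_model():
    return CircuitModel.compliance_test()


@pytest.fixture(scope="session")
def coronary_model():
    return CircuitModel.coronary()


@pytest.fixture(scope="session")
def ct_run(ct_model, normotensive_regime):
    """Seeded 37-cycle compliance-test stimulation (normotensive, 1 Hz)."""
    return run_regulated_stimulation(
        ct_model, normotensive_regime, "sinusoidal", n_cycles=37, seed=1
    )


@pytest.fixture(scope="session")
def coronary_run(coronary_model, normotensive_regime):
    """Seeded 37-cycle coronary-like stimulation (0.35 s/0.65 s valve law)."""
    return run_regulated_stimulation(
        coronary_model, normotensive_regime, "coronary_piecewise", n_cycles=37, seed=1
    )
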