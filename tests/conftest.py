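import numpy as np
import pytest

from cvrpipe import (
    AcquisitionSpec,
    BreathModel,
    ParadigmSpec,
    build_regressor,
    extract_end_tidal,
    simulate_capnometry,
)


@pytest.fixture(scope="session")
def paradigm():
    return ParadigmSpec()


@pytest.fixture(scope="session")
def acq():
    return AcquisitionSpec(repetition_time=2.0, n_volumes=178)


@pytest.fixture(scope="session")
def step_capno(paradigm):
    """Instantaneous-transition trace: plateaus exactly 40 / 48 mmHg."""
    breath = BreathModel(transition_time_constant=0.0)
    return simulate_capnometry(paradigm, breath, seed=7)


@pytest.fixture(scope="session")
def default_capno(paradigm):
    """Default trace with a 10-s wash-in time constant."""
    return simulate_capnometry(paradigm, BreathModel(), seed=7)


@pytest.fixture(scope="session")
def step_et(step_capno):
    trace, _ = step_capno
    return extract_end_tidal(trace)


@pytest.fixture(scope="session")
def step_reg(step_et, acq, paradigm):
    return build_regressor(step_et, acq, paradigm=paradigm)
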