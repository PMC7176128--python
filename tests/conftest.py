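import numpy as np
import pytest

import fdopakin as fk
from fdopakin.kinetic_models import KineticParams, MODEL_1T2K

#: cohort-mean single-tissue parameters used throughout the recovery tests
TRUTH = dict(K1=0.161, k2=0.087, VB=0.084)


@pytest.fixture(scope="session")
def input_function():
    """Default synthetic arterial input, metabolite/hematocrit corrected."""
    return fk.apply_corrections(fk.synth_bolus())


@pytest.fixture(scope="session")
def truth_params():
    return KineticParams(model_id=MODEL_1T2K, **TRUTH)


@pytest.fixture(scope="session")
def optimal_schedule():
    return fk.make_schedule(fk.OPTIMAL_SCHEDULE_SPEC)


@pytest.fixture(scope="session")
def clean_tac(input_function, truth_params, optimal_schedule):
    """Noiseless cohort-mean TAC binned to the optimal schedule."""
    curve = fk.simulate(truth_params, input_function, 1200.0)
    return fk.bin_curve(curve, optimal_schedule)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
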