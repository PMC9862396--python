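import numpy as np
import pytest

from tegopbpk.engine import PBPKModel
from tegopbpk.io import build_regimen, load_drug_parameters
from tegopbpk.physiology import build_reference_individual


@pytest.fixture(scope="session")
def tegoprazan():
    return load_drug_parameters("tegoprazan")


@pytest.fixture(scope="session")
def m1():
    return load_drug_parameters("m1")


@pytest.fixture(scope="session")
def reference_individual():
    """73.5 kg reference adult (renal plasma clearance 1.31 L/h)."""
    return build_reference_individual()


@pytest.fixture(scope="session")
def single_dose_result(tegoprazan, m1, reference_individual):
    """One 50 mg fasted oral dose integrated to elimination completion."""
    model = PBPKModel(tegoprazan, m1, reference_individual)
    return model.simulate(build_regimen(50.0), 168.0)


@pytest.fixture(scope="session")
def fit_solver():
    """Loose-but-adequate solver settings for test simulations."""
    return {"rtol": 1e-6, "atol": 1e-9}
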