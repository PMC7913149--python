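import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper module

from tamoxsim import Covariates, IndividualParameters, PopulationModel


@pytest.fixture(scope="session")
def toy_individual():
    """Hand-picked toy parameters with convenient magnitudes."""
    return IndividualParameters(
        ka=0.5, tlag=0.5, v_tam=1000.0, cl23_i=0.2, cl20_i=5.0, v_endx=400.0, cl30=8.0
    )


@pytest.fixture(scope="session")
def default_model():
    return PopulationModel()


@pytest.fixture(scope="session")
def reference_covariates(default_model):
    """Covariates at the model's reference point (no covariate effect)."""
    return Covariates(
        activity_score=2.0, age=default_model.age_ref, weight=default_model.wt_ref
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20210203)


def random_individual(rng) -> IndividualParameters:
    """A random but physiologically sane parameter draw for property tests."""
    return IndividualParameters(
        ka=rng.uniform(0.2, 2.0),
        tlag=rng.uniform(0.0, 2.0),
        v_tam=rng.uniform(500.0, 2500.0),
        cl23_i=rng.uniform(0.05, 1.5),
        cl20_i=rng.uniform(2.0, 12.0),
        v_endx=rng.uniform(150.0, 900.0),
        cl30=rng.uniform(2.0, 15.0),
    )
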