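import numpy as np
import pytest

from pkcross.datagen import GenerativeModel, StudyDesign, generate_study
from pkcross.model import ThetaFixed


@pytest.fixture(scope="session")
def theta_ref() -> ThetaFixed:
    """Final-model typical values used as the reference parameter set."""
    return ThetaFixed(cl=0.255, vc=7.11, cld=127.0, vp=2.51, ka=0.471, f=0.908)


@pytest.fixture(scope="session")
def gen_ref() -> GenerativeModel:
    return GenerativeModel.reference()


@pytest.fixture(scope="session")
def design_default() -> StudyDesign:
    return StudyDesign()


@pytest.fixture(scope="session")
def study_default(design_default, gen_ref):
    return generate_study(design_default, gen_ref, seed=20240531)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_200(gen_ref):
    """The 200-subject recovery study shared by estimation and acceptance."""
    return generate_study(StudyDesign(n_subjects=200), gen_ref, seed=2024)


@pytest.fixture(scope="session")
def fit_recovery_200(study_200):
    from pkcross.nlme import PopulationModel, fit_population, initial_from_nca

    model = PopulationModel(theta=initial_from_nca(study_200))
    return fit_population(
        study_200, model, method="SAEM+LAPLACE", seed=11, compute_mofv=False
    )


def random_theta(rng: np.random.Generator) -> ThetaFixed:
    """Random positive parameter draw with well-separated magnitudes."""
    return ThetaFixed(
        cl=float(rng.uniform(0.05, 5.0)),
        vc=float(rng.uniform(1.0, 50.0)),
        cld=float(rng.uniform(0.1, 200.0)),
        vp=float(rng.uniform(0.5, 50.0)),
        ka=float(rng.uniform(0.05, 5.0)),
        f=float(rng.uniform(0.3, 1.0)),
    )
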