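import numpy as np
import pytest

from cabopk import (
    AbsorptionParams,
    DispositionParams,
    OmegaMatrix,
    ResidualModel,
    load_preset,
)
from cabopk.synthetic_data import Arm, DemographicSpec, StudySpec


@pytest.fixture(scope="session")
def fm_theta():
    return load_preset("FM")


@pytest.fixture(scope="session")
def fm_disposition():
    return DispositionParams(cl=2.478, vc=187.0, q=31.213, vp=195.1)


@pytest.fixture(scope="session")
def fm_absorption():
    return AbsorptionParams(ka=0.979, alag1=0.784, d2=2.4, f1=0.854, frel=1.0)


@pytest.fixture(scope="session")
def fm_omega_diag():
    return OmegaMatrix(np.diag([2.063, 0.202, 0.233, 0.466]))


@pytest.fixture(scope="session")
def fm_residual():
    return ResidualModel(0.118)


def make_demo(male=0.5, races=(1, 0, 0, 0), age=(60.0, 10.0, 30.0, 80.0),
              wt=(80.0, 12.0, 50.0, 120.0)):
    counts = np.asarray(races, dtype=float)
    return DemographicSpec(
        male_prop=male, race_props=tuple(counts / counts.sum()),
        age_mean=age[0], age_sd=age[1], age_min=age[2], age_max=age[3],
        wt_mean=wt[0], wt_sd=wt[1], wt_min=wt[2], wt_max=wt[3],
    )


def make_study(study_id="S", population="HV", n=10, dose=60.0,
               formulation="tablet", obs_times=(1.0, 4.0, 24.0),
               qd=False, **demo_kwargs):
    demo = make_demo(**demo_kwargs)
    if qd:
        arm = Arm.qd("arm", n, dose, formulation, obs_times)
    else:
        arm = Arm.single("arm", n, dose, formulation, obs_times)
    return StudySpec(study_id, population, demo, (arm,))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
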