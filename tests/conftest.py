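import numpy as np
import pytest

from ivimfit import IvimParams, PhantomSpec, QCThresholds, generate_phantom
from ivimfit.schemes import STUDY_BVALUES

#: Cohort-median biexponential parameters of the emulated lesion population
#: (D = 0.84e-3 mm^2/s, D* = 11.9e-3 mm^2/s, fp = 0.16).
MEDIAN_PARAMS = IvimParams(si0=1000.0, d=0.84e-3, d_star=11.9e-3, fp=0.16)


@pytest.fixture(scope="session")
def median_params() -> IvimParams:
    return MEDIAN_PARAMS


@pytest.fixture(scope="session")
def study_b() -> np.ndarray:
    return np.asarray(STUDY_BVALUES)


@pytest.fixture(scope="session")
def noiseless_ivim_phantom():
    """24 heterogeneous lesions, no noise: the core recovery surface."""
    return generate_phantom(PhantomSpec(noise_model="none", seed=11))


@pytest.fixture(scope="session")
def fp0_phantom():
    """Perfusion-free phantom: every scheme must agree with the D truth map."""
    lesion = IvimParams(si0=1000.0, d=1.1e-3, d_star=1.1e-3, fp=0.0)
    return generate_phantom(
        PhantomSpec(n_lesions=6, lesion_params=lesion, noise_model="none", seed=5)
    )


@pytest.fixture()
def vacuous_thresholds() -> QCThresholds:
    return QCThresholds(r2_min=0.0, chi2_max=np.inf)
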