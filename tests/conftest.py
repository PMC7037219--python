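import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fusionpk.model import mouse_reference_parameters
from fusionpk.synthetic import AssayBiasModel, ErrorModel, default_study, generate_study

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

SAMPLING_TIMES = np.array([5.0 / 60.0, 1.0, 6.0, 24.0, 72.0, 168.0, 240.0, 336.0])


@pytest.fixture(scope="session")
def ref_params():
    return mouse_reference_parameters()


@pytest.fixture(scope="session")
def study():
    """(design, generating parameters) of the reference virtual study."""
    return default_study()


@pytest.fixture(scope="session")
def noise_free_dataset(study):
    design, params = study
    return generate_study(
        design, params, ErrorModel(proportional_cv=0.0, seed=0), AssayBiasModel()
    )


@pytest.fixture(scope="session")
def noisy_dataset(study):
    design, params = study
    return generate_study(
        design, params, ErrorModel(proportional_cv=0.2, seed=42), AssayBiasModel()
    )
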