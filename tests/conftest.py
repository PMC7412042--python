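import numpy as np
import pytest

from pecg_ira import DipoleParams, ClassPerturbation, generate_dipole_record
from pecg_ira.synthetic import CLASS_PERTURBATIONS


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free healthy record with identical beats (HR 60, no jitter)."""
    params = DipoleParams(hr_mean=60.0, hr_sd=0.0)
    pert = ClassPerturbation("HC", noise_sd=0.0)
    return generate_dipole_record(params, pert, seed=1)


@pytest.fixture(scope="session")
def noisy_record():
    """Healthy record under generator defaults (RR jitter + noise)."""
    return generate_dipole_record(DipoleParams(), CLASS_PERTURBATIONS["HC"], seed=7)
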