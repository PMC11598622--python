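import numpy as np
import pytest

from emgtorque.desk import SOURCE_DESK, TARGET_DESK
from emgtorque.protocols import DomainProtocol
from emgtorque.synth import sample_ground_truth, synthesize_domain


@pytest.fixture(scope="session")
def target_desk_dataset():
    """Two desk-scale target-domain subjects (shared across tests)."""
    return synthesize_domain(TARGET_DESK, 2, 12345)


@pytest.fixture(scope="session")
def noiseless_linear_subject():
    """One desk-scale subject with saturation, torque noise, power line and
    sensor noise all switched off: torque is an exact linear functional of
    the latent amplitudes."""
    ds = synthesize_domain(
        TARGET_DESK, 1, 999,
        saturation_coeff=0.0, noise_sd=0.0, line_amplitude=0.0, sensor_noise_sd=0.0,
    )
    return ds.subjects["s000"]


@pytest.fixture(scope="session")
def desk_truth():
    return sample_ground_truth(TARGET_DESK, 42)


@pytest.fixture
def tiny_protocol():
    """Minimal valid protocol for structural tests (fast to synthesize)."""
    return DomainProtocol(
        name="tiny", n_channels=2, fs=204.8, dofs=("d1",),
        trials_per_dof=4, trial_duration=6.0, target_bandlimit=1.0,
        target_range=(30.0,), calibration_duration=3.0, mvt_duration=3.0,
    )
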