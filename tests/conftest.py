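import logging

import numpy as np
import pytest

from tdekit import SimulationConfig, generate_cohort, generate_subject

logging.getLogger("tdekit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_subject():
    """One synthetic subject at the default (axial) study conditions."""
    return generate_subject(SimulationConfig(n_subjects=1, seed=7), 0)


@pytest.fixture(scope="session")
def reference_subject():
    """Subject at the reported axial mean dynamics (tau=92, C=284, t_shift=0.7)."""
    cfg = SimulationConfig(n_subjects=1, seed=13)
    return generate_subject(cfg, 0, tau=92.0, C=284.0, t_shift=0.7)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort; small but large enough for cohort-level stages."""
    return generate_cohort(SimulationConfig(n_subjects=6, seed=11))


@pytest.fixture(scope="session")
def fast_config():
    """Quick-running configuration for I/O and CLI tests."""
    return SimulationConfig(
        n_subjects=2, grid_shape=(40, 40), n_frames=48,
        tau_mean=30.0, tau_sd=5.0, C_mean=120.0, C_sd=10.0,
        tshift_mean=1.0, tshift_sd=1.0, seed=9,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
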