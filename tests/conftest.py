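import numpy as np
import pytest

from lagcvr import capno, cvr_glm
from lagcvr import synthetic_world as sw

SMALL_GRID = (16, 16, 8)


@pytest.fixture(scope="session")
def timing():
    return sw.TimingConfig()


@pytest.fixture(scope="session")
def noiseless_bh_subject():
    """One noiseless subject with only the breath-hold segment (closure tests)."""
    return sw.make_subject(
        seed=42, grid_shape=SMALL_GRID, segments=("BH+REST",), noiseless=True
    )


@pytest.fixture(scope="session")
def noisy_subject():
    """One subject at default study noise with BH+REST and REST segments."""
    return sw.make_subject(seed=7, grid_shape=SMALL_GRID, segments=("BH+REST", "REST"))


def fit_segment(subject, label, scheme="Lag-Opt"):
    """Full single-segment analysis chain used by several test modules."""
    prot = subject.protocols[label]
    pet = capno.detect_end_tidal(
        subject.co2_traces[label], baseline_windows=prot.rest_windows()
    )
    regset = capno.build_regressors(pet, prot)
    motion = subject.motion_params[label].to_numpy()[prot.n_discard :]
    if np.allclose(motion, motion.mean(axis=0)):
        motion = None
    fn = cvr_glm.cvr_lag_opt if scheme == "Lag-Opt" else cvr_glm.cvr_no_opt
    return fn(
        subject.bold_segments[label][..., prot.n_discard :],
        subject.gm_mask,
        regset,
        motion_table=motion,
    )
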