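import numpy as np
import pytest

from infantpress import synthetic
from infantpress.io import compute_mpp, pca_vertical_rotate
from infantpress.registration import mpp_to_cloud


@pytest.fixture(scope="session")
def profiles():
    """Small deterministic cohort shared across tests."""
    return synthetic.sample_cohort(synthetic.CohortConfig(n_infants=4, seed=1))


@pytest.fixture(scope="session")
def profile(profiles):
    return profiles[0]


@pytest.fixture(scope="session")
def clean_step(profile):
    """Noise-free new-walker step at a known identity pose."""
    rollover = synthetic.RolloverParams(contact_onset_frac=0.5, noise_sd=0.0)
    return synthetic.synthesize_step(
        profile, "new", rollover=rollover, seed=4, pose=(0.0, 6.0, 2.0)
    )


@pytest.fixture(scope="session")
def noisy_step(profile):
    """Default (noisy, random-pose) new-walker step."""
    return synthetic.synthesize_step(profile, "new", seed=7)


@pytest.fixture(scope="session")
def rotated_cloud(noisy_step):
    rotated, _ = pca_vertical_rotate(noisy_step.step)
    return mpp_to_cloud(compute_mpp(rotated), 1.0)


@pytest.fixture(scope="session")
def big_cohort_table():
    """Large cohort table for distribution-level checks (single draw)."""
    profs = synthetic.sample_cohort(synthetic.CohortConfig(n_infants=5000, seed=7))
    return synthetic.cohort_table(profs)


def grid_centroid_shift(step_frames):
    """Translation applied by the recentring vertical rotation: support
    centroid of the MPP -> grid centre (x_ml, y_ap), in cm."""
    mpp = step_frames.max(axis=0)
    rows, cols = np.nonzero(mpp > 0)
    return (
        (25 - 1) / 2 * 0.5 - cols.mean() * 0.5,
        (36 - 1) / 2 * 0.5 - rows.mean() * 0.5,
    )
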