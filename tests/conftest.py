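import numpy as np
import pytest

import ultradce as u

DT = 1.695  # seconds per dynamic
N_WINDOW = 71  # frames in a 120 s window at 1.695 s/dynamic


@pytest.fixture
def window_times_min():
    """Uniform 2-minute analysis grid in minutes, origin at arrival."""
    return np.arange(N_WINDOW) * DT / 60.0


@pytest.fixture
def window_aif():
    """Gamma-variate AIF re-origined so the bolus arrives at frame 0."""
    return u.make_aif(u.AifSpec(arrival_s=0.0, peak_amplitude=5.0),
                      n_dynamics=N_WINDOW, dt_seconds=DT)


@pytest.fixture
def full_aif():
    """Full-length AIF with a 25 s pre-bolus baseline."""
    return u.make_aif(u.AifSpec(), n_dynamics=150, dt_seconds=DT)


@pytest.fixture
def small_phantom():
    """Two-region noiseless phantom with artery, lesion and normal ROIs."""
    shape = (12, 12, 2)
    artery = np.zeros(shape, bool); artery[0:2, 0:2, :] = True
    lesion = np.zeros(shape, bool); lesion[5:8, 5:8, :] = True
    normal = np.zeros(shape, bool); normal[9:11, 2:5, :] = True
    spec = u.PhantomSpec(
        shape=shape, artery_mask=artery, noise_sd_rel=0.0, seed=3,
        regions=[
            u.Region("lesion", lesion, "2cu", u.TwoCUParams(0.2, 0.4, 0.4)),
            u.Region("normal", normal, "2cu", u.TwoCUParams(0.1, 0.1, 0.2)),
        ],
    )
    return u.make_phantom(spec)
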