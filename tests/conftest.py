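import numpy as np
import pytest

from mcdiff import simstudy
from mcdiff.acquisition import AcquisitionScheme
from mcdiff.compartments import build_model


@pytest.fixture(scope="session")
def tiny_scheme():
    """10-volume scheme with random directions over three shells + one b0."""
    rng = np.random.default_rng(0)
    dirs = rng.standard_normal((10, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs[0] = 0.0
    b = np.array([0, 1e9, 1e9, 2e9, 2e9, 3e9, 3e9, 1e9, 2e9, 3e9], dtype=float)
    return AcquisitionScheme(directions=dirs, b_values=b)


@pytest.fixture(scope="session")
def tiny_timed_scheme(tiny_scheme):
    """Same 10 volumes with Δ/δ/TE timing attached (for CHARMED)."""
    m = tiny_scheme.n_volumes
    return AcquisitionScheme(
        directions=tiny_scheme.directions,
        b_values=tiny_scheme.b_values,
        big_delta=np.full(m, 21.8e-3),
        small_delta=np.full(m, 12.9e-3),
        echo_time=np.full(m, 57.0e-3))


@pytest.fixture(scope="session")
def rls_scheme():
    """Synthetic 3-shell, 134-volume scheme (30/40/50 directions + 14 b0)."""
    return simstudy.preset_scheme("rls", seed=0)


@pytest.fixture(scope="session")
def ballstick():
    return build_model("BallStick_in1")


@pytest.fixture(scope="session")
def ballstick_voxel(rls_scheme, ballstick):
    """One SNR-30 Ball&Stick phantom voxel with its ground truth."""
    phantom = simstudy.simulate_ground_truth(
        "BallStick_in1", 1, rls_scheme, snr=30, seed=7)
    return phantom.voxel(0), phantom.truths.iloc[0].to_numpy()
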