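import numpy as np
import pytest

from gaitmat.pipeline import process_recording
from gaitmat.synthetic_gait import GaitConfig, simulate_pass
from gaitmat.walkway_io import MatGeometry


@pytest.fixture(scope="session")
def paper_geometry():
    return MatGeometry.paper_mat()


@pytest.fixture()
def small_geometry():
    """Tiny mat for fast I/O and toy-volume tests."""
    return MatGeometry(n_rows=12, n_cols=40, sensel_pitch=0.005, frame_rate=30.0)


@pytest.fixture(scope="session")
def clean_pass():
    """One noise-free default (naive) pass with its ground truth."""
    return simulate_pass(GaitConfig(seed=1))


@pytest.fixture(scope="session")
def processed_clean(clean_pass):
    recording, _ = clean_pass
    return process_recording(recording)


@pytest.fixture(scope="session")
def deterministic_pass():
    """Zero-variance pass: every stride identical by construction."""
    config = GaitConfig(
        stance_time_mean=0.30,
        swing_time_mean=0.15,
        stance_time_sd=0.0,
        swing_time_sd=0.0,
        stride_length_sd=0.0,
        seed=5,
    )
    return simulate_pass(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
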