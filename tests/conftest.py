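import numpy as np
import pytest

from ccfdq import EnFaceImage, SimulationConfig


def make_image(pixels, pitch_um=6000.0 / 1024.0, laterality="OD", kind="angio"):
    return EnFaceImage(np.asarray(pixels, dtype=float), pitch_um, laterality, kind)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort_config():
    """A small rendered cohort at reduced resolution, reused across tests."""
    return SimulationConfig(seed=77, n_iamd=2, n_control=2, image_size_px=128)


@pytest.fixture(scope="session")
def small_scene(small_cohort_config):
    from ccfdq import simulate_eye

    return simulate_eye(small_cohort_config, 0, "iamd")
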