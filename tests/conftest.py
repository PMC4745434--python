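import numpy as np
import pytest

from gaitkin.synthetic import SimulationConfig, SyntheticSubject, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def subject():
    return SyntheticSubject()


def random_rotations(n: int, seed: int) -> np.ndarray:
    """Uniform random rotation matrices via normalised quaternions."""
    g = np.random.default_rng(seed)
    q = g.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack([
        np.stack([1 - 2 * (y**2 + z**2), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
        np.stack([2 * (x * y + z * w), 1 - 2 * (x**2 + z**2), 2 * (y * z - x * w)], -1),
        np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x**2 + y**2)], -1),
    ], axis=-2)


@pytest.fixture(scope="session")
def clean_single_study(tmp_path_factory):
    """1 subject x 1 trial, zero noise and zero injected variation."""
    d = tmp_path_factory.mktemp("study_clean")
    cfg = SimulationConfig(n_subjects=1, n_trials=1, intertrial_sd_deg=0.0,
                           between_subject_sd_deg=0.0, seed=17)
    manifest = generate_study(cfg, d)
    return d, cfg, manifest


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """The default study design: 4 subjects x 3 trials, clean markers."""
    d = tmp_path_factory.mktemp("study_default")
    cfg = SimulationConfig(seed=7)
    manifest = generate_study(cfg, d)
    return d, cfg, manifest
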