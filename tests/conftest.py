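import numpy as np
import pytest

from sfstates import (
    SyntheticSpec,
    compute_features,
    generate_ensemble,
    make_topology,
)


@pytest.fixture(scope="session")
def conductive_ideal():
    """Noise-free conductive ensemble (1 frame) with topology."""
    frame_set, truth = generate_ensemble(
        SyntheticSpec(n_frames=1, noise_sigma=0.0))
    return frame_set, make_topology(frame_set), truth


@pytest.fixture(scope="session")
def widened_ideal():
    frame_set, truth = generate_ensemble(
        SyntheticSpec(n_frames=1, noise_sigma=0.0, geometry_state="widened"))
    return frame_set, make_topology(frame_set), truth


@pytest.fixture(scope="session")
def noisy_ensemble():
    """Small noisy ensemble cycling two ion configurations."""
    from sfstates import cycling_schedule

    schedule = cycling_schedule([(0, 2, 4), (1, 3)], 200, block=4)
    frame_set, truth = generate_ensemble(
        SyntheticSpec(n_frames=200, noise_sigma=0.1, seed=7,
                      ion_schedule=schedule))
    return frame_set, make_topology(frame_set), truth


@pytest.fixture(scope="session")
def noisy_features(noisy_ensemble):
    frame_set, topology, truth = noisy_ensemble
    return compute_features(frame_set, topology)


def random_rotation(seed: int) -> np.ndarray:
    """Uniform random rotation matrix (for invariance tests)."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
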