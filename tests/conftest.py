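import numpy as np
import pytest

from auriplan import CameraModel, Isometry, MarkerModel, SynthSpec, make_head


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalised quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_isometry(rng: np.random.Generator, translation_scale: float = 50.0) -> Isometry:
    return Isometry.from_rotation_translation(
        random_rotation(rng), rng.uniform(-translation_scale, translation_scale, 3)
    )


def rotation_angle_deg(r: np.ndarray) -> float:
    c = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


@pytest.fixture(scope="session")
def head_case():
    """Default symmetric synthetic head shared across the suite."""
    spec = SynthSpec(seed=1)
    mesh, landmarks, truth = make_head(spec)
    return mesh, landmarks, truth


@pytest.fixture(scope="session")
def camera():
    return CameraModel(fx=1500.0, fy=1500.0, cx=960.0, cy=540.0, image_size=(1920, 1080))


@pytest.fixture(scope="session")
def cube_marker():
    return MarkerModel.cube(30.0)
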