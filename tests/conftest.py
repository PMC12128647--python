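import numpy as np
import pytest

from spermshape import synth


def circle_polygon(radius: float, n: int = 360, center=(0.0, 0.0)) -> np.ndarray:
    t = np.arange(n) * (2 * np.pi / n)
    return np.column_stack(
        [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]
    )


def ellipse_polygon(a: float, b: float, n: int = 720, center=(0.0, 0.0)) -> np.ndarray:
    t = np.arange(n) * (2 * np.pi / n)
    return np.column_stack([center[0] + a * np.cos(t), center[1] + b * np.sin(t)])


@pytest.fixture(scope="session")
def af_params():
    return synth.sample_shape_params("AF")


@pytest.fixture(scope="session")
def sampled_shapes(af_params):
    """A handful of realistic nucleus shapes (centroid frame)."""
    return synth.sample_nucleus_harmonics(af_params, 12, rng_seed=421)


@pytest.fixture(scope="session")
def small_cohort():
    """Small summary-level cohort shared across tests."""
    return synth.generate_cohort(8, 4, 30, rng_seed=77, detail="summary")
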