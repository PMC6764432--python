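import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def blob_contour() -> np.ndarray:
    """Smooth asymmetric float contour (math convention, closed polygon)."""
    t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    r = 10 + 2 * np.cos(2 * t) + 1.2 * np.sin(3 * t) + 0.7 * np.cos(5 * t + 1.0)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


@pytest.fixture(scope="session")
def disc_mask() -> np.ndarray:
    from skimage import draw

    m = np.zeros((110, 110), dtype=bool)
    rr, cc = draw.disk((55, 55), 50)
    m[rr, cc] = True
    return m


@pytest.fixture(scope="session")
def ellipse_leaf():
    """Symmetric synthetic ellipse leaf with ground truth."""
    from leafmass.synthetic_shapes import LeafSpec, generate_leaf

    return generate_leaf(LeafSpec(length_px=200, width_px=100, seed=1))


@pytest.fixture(scope="session")
def lobed_leaf():
    from leafmass.synthetic_shapes import LeafSpec, generate_leaf

    return generate_leaf(
        LeafSpec(length_px=220, width_px=180, n_lobes=5, lobe_depth=0.3, seed=2)
    )
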