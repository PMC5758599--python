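import numpy as np
import pytest

from leafscape.synthetic import LeafParams, generate_leaf_outline, rasterize_outline


@pytest.fixture(scope="session")
def generic_leaf_outline():
    """A generic asymmetric serrated leaf polygon (no special symmetry)."""
    params = LeafParams(
        aspect_ratio=1.7,
        blade_scale=400.0,
        serration_amplitude=0.08,
        serration_count=25,
        petiole_length=0.2,
        asymmetry=0.08,
        seed=5,
    )
    return generate_leaf_outline(params, n_points=512)


@pytest.fixture(scope="session")
def generic_leaf_image(generic_leaf_outline):
    return rasterize_outline(generic_leaf_outline)


@pytest.fixture(scope="session")
def dense_ellipse():
    """Analytic ellipse x = 2 cos t, y = sin t sampled densely in t."""
    t = np.linspace(0.0, 2.0 * np.pi, 4000, endpoint=False)
    return np.column_stack([2.0 * np.cos(t), np.sin(t)])
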