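import numpy as np
import pytest

from sfxgeom.geometry import Panel, build_hierarchy
from sfxgeom.synthetic import SceneSpec, make_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def panel():
    """An off-axis panel with non-trivial orientation."""
    f = np.array([1.0, 0.2, 0.1])
    f /= np.linalg.norm(f)
    s = np.cross(np.array([0.0, 0.0, 1.0]), f)
    s /= np.linalg.norm(s)
    return Panel(
        id="p00",
        midpoint=np.array([-25.0, 13.0, 91.0]),
        fast_axis=f,
        slow_axis=s,
        n_fast=120,
        n_slow=100,
        pixel_size=0.11,
    )


@pytest.fixture
def grid_detector():
    """Small 2x2 detector facing the beam."""
    panels = []
    for r in range(2):
        for c in range(2):
            panels.append(
                Panel(
                    id=f"p{r}{c}",
                    midpoint=np.array([(-1) ** c * 10.0, (-1) ** r * 10.0, 90.0]),
                    fast_axis=np.array([1.0, 0.0, 0.0]),
                    slow_axis=np.array([0.0, 1.0, 0.0]),
                    n_fast=100,
                    n_slow=100,
                    pixel_size=0.11,
                )
            )
    return build_hierarchy(panels)


@pytest.fixture(scope="session")
def small_scene():
    """Noise-free 20-image scene on the 16-panel preset (shared, read-only)."""
    return make_scene(SceneSpec(n_images=20, seed=42))


@pytest.fixture(scope="session")
def preindex_scene():
    """Noise-free 150-image scene for fingerprint-path tests (read-only)."""
    return make_scene(SceneSpec(n_images=150, seed=42))


@pytest.fixture(scope="session")
def default_lookup():
    """Full-size fingerprint lookup for the default cell (shared, read-only)."""
    from sfxgeom.fingerprint import build_ideal_lookup

    return build_ideal_lookup((105.5, 105.5, 105.5, 90.0, 90.0, 90.0), "I",
                              rlp_radius=0.002)
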