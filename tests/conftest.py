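import numpy as np
import pytest

from winstitch import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_scene():
    """A 256x256 3-class scene with a handful of blobs (shared, read-only)."""
    spec = SceneSpec(
        height=256, width=256, n_blobs=10, radius_range=(6.0, 14.0), edge_band=2, seed=3
    )
    image, gt = generate_scene(spec)
    return spec, image, gt
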