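import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def content_layout():
    from guvcolocal.synthesis import default_content_exchange_layout

    return default_content_exchange_layout()


@pytest.fixture(scope="session")
def small_clean_scene(content_layout):
    """A small high-SNR scene with a mixed population, reused across tests."""
    from guvcolocal.synthesis import SceneSpec, render_scene

    channels, amounts = content_layout
    spec = SceneSpec(
        image_shape=(384, 384),
        n_vesicles=18,
        fractions={"P1": 0.4, "P2": 0.4, "PC": 0.2},
        min_gap_px=10.0,
        seed=421,
    )
    return render_scene(spec, channels, amounts)


@pytest.fixture(scope="session")
def segmented_small_scene(small_clean_scene, content_layout):
    from guvcolocal.io import FieldOfView
    from guvcolocal.segmentation import SegmentationParams, segment_field

    channels, _ = content_layout
    spec = small_clean_scene.spec
    fov = FieldOfView(0, (0, 0), small_clean_scene.channels, spec.pixel_size)
    lipid_map, content_map, records, log = segment_field(fov, channels, SegmentationParams())
    return fov, lipid_map, content_map, records


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
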