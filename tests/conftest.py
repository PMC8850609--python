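import numpy as np
import pytest

from thermoprick.synthetic import SceneConfig, generate_case


def small_scene(**overrides) -> SceneConfig:
    """Desk-size scene: same structure as the default, ~6% of the pixels."""
    params = dict(
        image_size=(96, 128),
        marker_radius_range=(5.0, 7.0),
        inter_marker_spacing=26.0,
        line_spacing=26.0,
        position_jitter=1.5,
        max_rotation_deg=2.0,
        max_translation_px=4.0,
        hotspot_sigma=4.0,
        hair_density=4,
        vessel_count=1,
    )
    params.update(overrides)
    return SceneConfig(**params)


@pytest.fixture
def scene_small() -> SceneConfig:
    return small_scene()


@pytest.fixture(scope="session")
def case_small():
    return generate_case(small_scene(), patient_seed=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
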