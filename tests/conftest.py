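import numpy as np
import pytest

from fishline.core import (
    BoundingBox,
    CameraCalibration,
    Detection,
    SpeciesCatalog,
    default_catalog,
)
from fishline.synthetic_scenes import SceneConfig


@pytest.fixture(scope="session")
def catalog() -> SpeciesCatalog:
    cat, _ = default_catalog()
    return cat


@pytest.fixture(scope="session")
def calibration() -> CameraCalibration:
    _, cal = default_catalog()
    return cal


@pytest.fixture
def small_scene_config() -> SceneConfig:
    """Desk-scale scene: 320x240 px at 0.25 cm/px so 30 cm fish fit easily."""
    return SceneConfig(
        image_size=(320, 240),
        cm_per_pixel=0.25,
        instance_count=(3, 5),
    )


def random_box(rng: np.random.Generator, w: float = 1000.0, h: float = 1000.0) -> BoundingBox:
    x0 = rng.uniform(0, w - 2)
    y0 = rng.uniform(0, h - 2)
    return BoundingBox(x0, y0, x0 + rng.uniform(1, w - x0), y0 + rng.uniform(1, h - y0))


def random_detection(
    rng: np.random.Generator, species_names, frame_id: str = "frame-0"
) -> Detection:
    return Detection(
        box=random_box(rng, 400, 400),
        species=str(rng.choice(list(species_names))),
        confidence=float(rng.random()),
        frame_id=frame_id,
    )
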