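from __future__ import annotations

import numpy as np
import pytest

from cfucount.plate_io import make_plate_image
from cfucount.synth import PlateSpec, generate_plate


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def plate50():
    """800x800 plate with 50 isolated white colonies plus its ground truth."""
    spec = PlateSpec(width=800, height=800, counts={"white": 50}, radius_mean=10, seed=3)
    return generate_plate(spec)


@pytest.fixture(scope="session")
def plate_two_color():
    spec = PlateSpec(
        width=900, height=900, counts={"blue": 50, "white": 50}, radius_mean=10, seed=13
    )
    return generate_plate(spec)


@pytest.fixture
def blank_dish():
    """A dish with no colonies at all."""
    spec = PlateSpec(width=400, height=400, counts={}, seed=5)
    return generate_plate(spec)


def disk_image(size=120, center=(60, 60), radius=20, fg=80, bg=200):
    """Uniform dark disk on a bright field, as a PlateImage."""
    yy, xx = np.mgrid[0:size, 0:size]
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    gray = np.full((size, size), bg, dtype=np.uint8)
    gray[d2 <= radius**2] = fg
    return make_plate_image(np.stack([gray] * 3, axis=-1))


@pytest.fixture
def disk_plate():
    return disk_image()
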