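"""Shared fixtures: tiny synthetic images and cohorts, generated at test
time (nothing is stored on disk)."""

from __future__ import annotations

import numpy as np
import pytest

from wormstage.preprocessing import FilterConfig
from wormstage.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def desk_config() -> SimulationConfig:
    """Generator config at the 256-px bench scale used throughout the
    suite (full-size spot geometry, faster images)."""
    return SimulationConfig(image_height=256, image_width=256, seed=0)


@pytest.fixture(scope="session")
def filter_config() -> FilterConfig:
    return FilterConfig(pool_factor=2)


def make_disk_image(
    shape: tuple[int, int],
    disks: list[tuple[float, float, float]],
    value: float = 1.0,
    background: float = 0.0,
) -> np.ndarray:
    """Rasterize filled disks (x, y, r) onto a constant background."""
    img = np.full(shape, background, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for x, y, r in disks:
        img[(xx - x) ** 2 + (yy - y) ** 2 <= r**2] = value
    return img


@pytest.fixture
def disk_image_factory():
    return make_disk_image
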