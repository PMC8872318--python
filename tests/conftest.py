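"""Shared fixtures: sensor, zones, renderer and calibrated background."""

import numpy as np
import pytest
from hypothesis import settings

from bedwatch.geometry import SensorConfig, ZoneMap, default_zones
from bedwatch.pipeline import BackgroundModel
from bedwatch.simulate import SceneRenderer
from bedwatch.suite import calibrate_background

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> SensorConfig:
    return SensorConfig()


@pytest.fixture(scope="session")
def zones() -> ZoneMap:
    return default_zones()


@pytest.fixture(scope="session")
def renderer(config, zones) -> SceneRenderer:
    return SceneRenderer(config, zones)


@pytest.fixture(scope="session")
def background(renderer, config) -> BackgroundModel:
    """Noisy empty-room calibration, as the pipeline would do in the field."""
    return calibrate_background(renderer, config, seed=123)


@pytest.fixture(scope="session")
def clean_background(renderer, config) -> BackgroundModel:
    """Noise-free background (exact reference heights) for geometry tests."""
    depth = renderer.background_depth
    heights = np.clip(config.mount_height - depth, 0.0, config.mount_height)
    return BackgroundModel(reference_heights=heights)
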