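"""Shared fixtures: small ground-truthed scenes rendered once per session."""

import warnings

import numpy as np
import pytest

from octapipe.synthetic_oct import NoiseModel, render_volume, simulate_scene
from octapipe.volume_core import VolumeGeometry, segment_surfaces

warnings.filterwarnings("ignore")


@pytest.fixture(scope="session")
def acute_scene():
    """Single calibrated acute lesion (dispersion off) at native pitch."""
    geo = VolumeGeometry(256, 64, 384)
    return simulate_scene(geo, "acute", 1, seed=7, dispersion=False)


@pytest.fixture(scope="session")
def acute_day1(acute_scene):
    """Rendered acute day-1 volume without motion, with ground truth."""
    vol, truth = render_volume(
        acute_scene, 1.0, NoiseModel(motion_jitter_um=(0, 0), seed=3), return_truth=True
    )
    return vol, truth


@pytest.fixture(scope="session")
def acute_day1_surfaces(acute_day1):
    vol, _ = acute_day1
    return segment_surfaces(vol)


@pytest.fixture(scope="session")
def control_volume():
    """Small control eye with motion jitter, plus its ground truth."""
    geo = VolumeGeometry(192, 192, 384)
    scene = simulate_scene(geo, "control", 0, seed=21)
    vol, truth = render_volume(scene, 1.0, NoiseModel(seed=4), return_truth=True)
    return scene, vol, truth


@pytest.fixture(scope="session")
def cnv_scene_wide():
    """Single CNV lesion on a widefield grid (2.8 um pitch), dispersion off."""
    geo = VolumeGeometry(448, 48, 384, dx_um=2.8)
    return simulate_scene(geo, "cnv", 1, seed=11, dispersion=False)


@pytest.fixture(scope="session")
def cnv_day1_wide(cnv_scene_wide):
    vol, truth = render_volume(
        cnv_scene_wide, 1.0, NoiseModel(motion_jitter_um=(0, 0), seed=3), return_truth=True
    )
    return vol, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
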