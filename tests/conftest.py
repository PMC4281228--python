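"""Shared fixtures: small synthetic scenes and grids, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import colonymap as cm
from colonymap.grid import GridSpec


@pytest.fixture(scope="session")
def small_scene() -> cm.SceneTruth:
    """3 colonies x 100 cells, default culture-like parameters."""
    return cm.generate_colony_scene(cm.SceneParams(), seed=1)


@pytest.fixture(scope="session")
def small_grid(small_scene) -> GridSpec:
    """2x2 grid with ~40 um overlap covering the small scene."""
    h, w = small_scene.shape_px
    ov = 62
    fw = -(-(w - ov) // 2) + ov
    fh = -(-(h - ov) // 2) + ov
    return GridSpec(2, 2, fw, fh, ov)


@pytest.fixture(scope="session")
def small_fields(small_scene, small_grid):
    return cm.render_fields(small_scene, small_grid)


def grid_covering(scene: cm.SceneTruth, nx: int, ny: int, overlap: int) -> GridSpec:
    """Smallest nx x ny grid with the given overlap covering the scene."""
    h, w = scene.shape_px
    fw = -(-(w - overlap) // nx) + overlap
    fh = -(-(h - overlap) // ny) + overlap
    return GridSpec(nx, ny, fw, fh, overlap)
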