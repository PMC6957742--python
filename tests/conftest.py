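"""Shared fixtures: small synthetic scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import ichnocore as ic


@pytest.fixture(scope="session")
def small_tube_scene() -> ic.SceneSpec:
    """One fat vertical cylinder in a short half-core (fast to render)."""
    return ic.SceneSpec(
        shape_voxels=(192, 96, 80),
        seed=101,
        burrows=(
            ic.BurrowSpec(
                diameter_mm=4.0,
                length_mm=25.0,
                z_angle_deg=90.0,
                anchor_mm=(33.7, 15.0, 7.0),
                contrast=8.0,
            ),
        ),
    )


@pytest.fixture(scope="session")
def small_tube_rendered(small_tube_scene):
    return ic.generate_core(small_tube_scene)


@pytest.fixture(scope="session")
def three_tube_scene() -> ic.SceneSpec:
    """Three disjoint tubes at 90/0/45 degrees, contrast 8 sigma."""
    return ic.SceneSpec(
        shape_voxels=(192, 96, 120),
        seed=7,
        burrows=(
            ic.BurrowSpec(diameter_mm=3.0, length_mm=30.0, z_angle_deg=90.0,
                          anchor_mm=(25.0, 12.0, 8.0), contrast=8.0),
            ic.BurrowSpec(diameter_mm=3.0, length_mm=25.0, z_angle_deg=0.0,
                          azimuth_deg=0.0, anchor_mm=(20.0, 20.0, 40.0), contrast=8.0),
            ic.BurrowSpec(diameter_mm=3.0, length_mm=28.0, z_angle_deg=45.0,
                          azimuth_deg=90.0, anchor_mm=(40.0, 8.0, 28.0), contrast=8.0),
        ),
    )


@pytest.fixture(scope="session")
def three_tube_rendered(three_tube_scene):
    return ic.generate_core(three_tube_scene)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
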