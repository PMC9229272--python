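"""Shared fixtures: rendered synthetic scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import rotospin as rs


@pytest.fixture(scope="session")
def replica():
    """Reference acquisition: 159 frames, 15 fps, textured ellipsoid at a
    true 86 rpm, vignetting + noise + debris."""
    config = rs.replica_scene(rpm=86.0, seed=0)
    stack, truths = rs.render_video(config)
    return config, stack, truths[0]


@pytest.fixture(scope="session")
def in_plane_60():
    """Spot-textured sphere rotating in-plane at 60 rpm."""
    config = rs.in_plane_scene(rpm=60.0, seed=0)
    stack, truths = rs.render_video(config)
    return config, stack, truths[0]


@pytest.fixture(scope="session")
def bare_ellipsoid():
    """Texture-free out-of-plane ellipsoid: pure pi-symmetric outline signal."""
    cell = rs.CellSpec(
        semi_axes=(12.0, 12.0, 7.0),
        rotation_rpm=86.0,
        rotation_mode="out_of_plane",
        texture=None,
        initial_centroid=(96.0, 96.0),
        phase0=0.4,
    )
    config = rs.SceneConfig(n_frames=120, cells=(cell,), rng_seed=1)
    stack, truths = rs.render_video(config)
    return config, stack, truths[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
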