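"""Synthetic rotating-cell video generator with exact ground truth.

Emulates the imaging conditions of an ODEP microfluidic chip viewed under a
fluorescence microscope in poor light: a brighter center with dark vignetted
corners, low cell/background contrast, Gaussian sensor noise, and small
impurities (bright specks and dim broken-cell fragments) in the background.

Cells are triaxial ellipsoids, optionally carrying internal spots that make
rotation observable even when the silhouette is rotationally symmetric:

* ``out_of_plane`` — the rotation axis lies in the image plane (along image
  columns).  The silhouette is an axis-aligned ellipse whose row semi-axis is
  u(theta) = sqrt(a^2 cos^2 theta + c^2 sin^2 theta); because any rigid
  silhouette is mirror-symmetric under a half revolution, the outline area is
  pi-periodic (it repeats twice per revolution).
* ``in_plane`` — the rotation axis is the optical axis.  The silhouette is
  constant for a circular outline; only internal texture moves, with full
  2*pi periodicity.

Angles follow theta_t = phase0 + 2*pi*rpm*t / (60*fps); rendering is fully
deterministic given the config's ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .datatypes import FrameStack, SceneTruth

__all__ = [
    "CellSpec",
    "SpotTexture",
    "SceneConfig",
    "render_frame",
    "render_video",
    "replica_scene",
    "in_plane_scene",
    "flat_field_scene",
    "drift_scene",
    "circular_drift_scene",
]


@dataclass(frozen=True)
class SpotTexture:
    """Internal spots riding on the cell: ``n_spots`` disks of radius
    ``radius`` px at body-frame distance ``orbit`` px from the center, drawn
    at intensity cell_level * (1 - contrast) (dark for contrast > 0)."""

    n_spots: int = 1
    contrast: float = 0.6
    radius: float = 3.0
    orbit: float = 6.0


@dataclass(frozen=True)
class CellSpec:
    """One rendered cell.

    ``semi_axes`` (a, b, c) in pixels: a along image rows, b along columns,
    c along the optical axis (a = b = c gives a sphere).  ``rotation_rpm``
    in revolutions/minute, ``velocity`` in pixels/frame (row, col).
    """

    semi_axes: tuple[float, float, float] = (12.0, 12.0, 7.0)
    rotation_rpm: float = 86.0
    rotation_mode: Literal["out_of_plane", "in_plane"] = "out_of_plane"
    texture: SpotTexture | None = None
    initial_centroid: tuple[float, float] = (96.0, 96.0)
    velocity: tuple[float, float] = (0.0, 0.0)
    phase0: float = 0.0
    # optional circular drift superimposed on the linear velocity:
    # one lap of radius orbit_radius every orbit_period_frames frames
    orbit_radius: float = 0.0
    orbit_period_frames: float = 0.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError("semi_axes must be positive")
        if self.rotation_rpm < 0:
            raise ValueError("rotation_rpm must be >= 0")

    def angle_at(self, t: int, fps: float) -> float:
        return self.phase0 + 2.0 * math.pi * self.rotation_rpm * t / (60.0 * fps)

    def centroid_at(self, t: int) -> tuple[float, float]:
        row = self.initial_centroid[0] + self.velocity[0] * t
        col = self.initial_centroid[1] + self.velocity[1] * t
        if self.orbit_radius > 0 and self.orbit_period_frames > 0:
            w = 2.0 * math.pi * t / self.orbit_period_frames
            row += self.orbit_radius * (math.cos(w) - 1.0)
            col += self.orbit_radius * math.sin(w)
        return (row, col)


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic video; identical configs (including
    ``rng_seed``) render bit-identical stacks."""

    image_height: int = 192
    image_width: int = 192
    n_frames: int = 159
    fps: float = 15.0
    cells: tuple[CellSpec, ...] = (CellSpec(),)
    vignette_strength: float = 0.3
    background_level: float = 95.0
    cell_level: float = 135.0
    noise_sigma: float = 3.0
    n_debris: int = 6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not (0 <= self.vignette_strength < 1):
            raise ValueError("vignette_strength must be in [0, 1)")
        for lvl in (self.background_level, self.cell_level):
            if not (0 <= lvl <= 255):
                raise ValueError("intensity levels must be in [0, 255]")


def _pixel_grid(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    return np.mgrid[0 : config.image_height, 0 : config.image_width]


def _vignette_field(config: SceneConfig) -> np.ndarray:
    """Multiplicative radial gain g(r) = 1 - strength * (r / r_corner)^2."""
    rr, cc = _pixel_grid(config)
    cr = (config.image_height - 1) / 2.0
    ccol = (config.image_width - 1) / 2.0
    r2 = (rr - cr) ** 2 + (cc - ccol) ** 2
    r_corner2 = cr**2 + ccol**2
    return 1.0 - config.vignette_strength * (r2 / r_corner2)


def _silhouette(
    cell: CellSpec, theta: float, centroid: tuple[float, float], rr: np.ndarray, cc: np.ndarray
) -> np.ndarray:
    """Boolean mask of the projected (rotated) ellipsoid outline; a pixel is
    foreground when its center lies inside the projected ellipse."""
    a, b, c = cell.semi_axes
    dr = rr - centroid[0]
    dc = cc - centroid[1]
    if cell.rotation_mode == "out_of_plane":
        u = math.sqrt(a**2 * math.cos(theta) ** 2 + c**2 * math.sin(theta) ** 2)
        return (dr / u) ** 2 + (dc / b) ** 2 <= 1.0
    # in_plane: silhouette ellipse (a, b) rotated by theta in the image plane
    x = math.cos(theta) * dr + math.sin(theta) * dc
    y = -math.sin(theta) * dr + math.cos(theta) * dc
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


def _spot_centers(cell: CellSpec, theta: float) -> list[tuple[float, float, float]]:
    """Body-frame spots rotated to camera frame: (row_off, col_off, z)."""
    tex = cell.texture
    if tex is None or tex.n_spots == 0:
        return []
    out = []
    for k in range(tex.n_spots):
        phi = 2.0 * math.pi * k / tex.n_spots
        if cell.rotation_mode == "out_of_plane":
            # spots orbit in the (row, optical) plane about the column axis
            row_off = tex.orbit * math.cos(theta + phi)
            z = tex.orbit * math.sin(theta + phi)
            col_off = 0.0
        else:
            row_off = tex.orbit * math.cos(theta + phi)
            col_off = tex.orbit * math.sin(theta + phi)
            z = 1.0  # always on the visible side
        out.append((row_off, col_off, z))
    return out


def _draw_cell(
    canvas: np.ndarray,
    cell: CellSpec,
    theta: float,
    centroid: tuple[float, float],
    cell_level: float,
    rr: np.ndarray,
    cc: np.ndarray,
) -> np.ndarray:
    mask = _silhouette(cell, theta, centroid, rr, cc)
    canvas[mask] = cell_level
    tex = cell.texture
    if tex is not None:
        spot_level = cell_level * (1.0 - tex.contrast)
        for row_off, col_off, z in _spot_centers(cell, theta):
            if z < 0:  # far side of the cell, occluded
                continue
            d2 = (rr - centroid[0] - row_off) ** 2 + (cc - centroid[1] - col_off) ** 2
            canvas[(d2 <= tex.radius**2) & mask] = spot_level
    return mask


def _debris_specs(config: SceneConfig, rng: np.random.Generator) -> list[tuple]:
    """Static impurities: (row, col, radius, level); bright specks alternate
    with dim broken-cell fragments."""
    out = []
    m = 8  # keep clear of the border
    for k in range(config.n_debris):
        r = rng.uniform(m, config.image_height - m)
        c = rng.uniform(m, config.image_width - m)
        if k % 2 == 0:
            out.append((r, c, rng.uniform(1.0, 2.0), min(255.0, config.cell_level + 60)))
        else:
            out.append((r, c, rng.uniform(1.5, 2.5), 0.5 * (config.background_level + config.cell_level)))
    return out


def render_frame(
    config: SceneConfig,
    states: Sequence[tuple[tuple[float, float], float]],
    rng: np.random.Generator | None = None,
    debris: Sequence[tuple] | None = None,
    return_masks: bool = False,
):
    """Render one frame given per-cell states ``[(centroid, angle), ...]``.

    Returns the uint8 image, plus the per-cell silhouette masks when
    ``return_masks`` is set.
    """
    if len(states) != len(config.cells):
        raise ValueError("one (centroid, angle) state required per cell")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    rr, cc = _pixel_grid(config)
    canvas = np.full((config.image_height, config.image_width), config.background_level, dtype=float)
    for r, c, rad, level in debris or ():
        canvas[(rr - r) ** 2 + (cc - c) ** 2 <= rad**2] = level
    masks = []
    for cell, (centroid, theta) in zip(config.cells, states):
        masks.append(_draw_cell(canvas, cell, theta, centroid, config.cell_level, rr, cc))
    canvas *= _vignette_field(config)
    if config.noise_sigma > 0:
        canvas += rng.normal(0.0, config.noise_sigma, canvas.shape)
    img = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return (img, masks) if return_masks else img


def _area_period_frames(cell: CellSpec, fps: float) -> float:
    if cell.rotation_rpm == 0:
        return math.inf
    full = 60.0 * fps / cell.rotation_rpm
    if cell.rotation_mode == "out_of_plane" and cell.texture is None:
        return full / 2.0  # pi-symmetry of the texture-free silhouette
    return full


def render_video(config: SceneConfig) -> tuple[FrameStack, list[SceneTruth]]:
    """Render the full video; returns the stack and one SceneTruth per cell."""
    rng = np.random.default_rng(config.rng_seed)
    debris = _debris_specs(config, rng)
    n = config.n_frames
    frames = np.empty((n, config.image_height, config.image_width), dtype=np.uint8)
    angles = np.zeros((len(config.cells), n))
    cents = np.zeros((len(config.cells), n, 2))
    areas = np.zeros((len(config.cells), n))
    for t in range(n):
        states = []
        for j, cell in enumerate(config.cells):
            theta = cell.angle_at(t, config.fps)
            centroid = cell.centroid_at(t)
            angles[j, t] = theta
            cents[j, t] = centroid
            states.append((centroid, theta))
        img, masks = render_frame(config, states, rng=rng, debris=debris, return_masks=True)
        frames[t] = img
        for j, m in enumerate(masks):
            areas[j, t] = int(m.sum())
    truths = [
        SceneTruth(
            angle=angles[j],
            centroid=cents[j],
            projected_area=areas[j],
            true_rpm=cell.rotation_rpm,
            area_period_frames=_area_period_frames(cell, config.fps),
        )
        for j, cell in enumerate(config.cells)
    ]
    return FrameStack(frames, config.fps), truths


# ---------------------------------------------------------------------------
# Canonical study scenes.  These defaults ARE the benchmark conditions used by
# the test suite and the acceptance script; they emulate the reference
# acquisition (159 frames at 15 fps, ~24 px cells, dark corners, low
# contrast) and are not tuning knobs.
# ---------------------------------------------------------------------------


def replica_scene(rpm: float = 86.0, seed: int = 0, n_frames: int = 159) -> SceneConfig:
    """Out-of-plane textured ellipsoid under the reference acquisition:
    159 frames at 15 fps with vignetting, noise and background debris."""
    cell = CellSpec(
        semi_axes=(12.0, 12.0, 7.0),
        rotation_rpm=rpm,
        rotation_mode="out_of_plane",
        texture=SpotTexture(n_spots=1, contrast=0.5, radius=2.5, orbit=5.0),
        initial_centroid=(96.0, 96.0),
        phase0=0.4,
    )
    return SceneConfig(n_frames=n_frames, cells=(cell,), rng_seed=seed)


def in_plane_scene(rpm: float = 60.0, seed: int = 0, n_frames: int = 159) -> SceneConfig:
    """Spot-textured sphere rotating in-plane: constant circular outline, one
    dark internal spot giving a full-revolution quarter-box signal."""
    cell = CellSpec(
        semi_axes=(12.0, 12.0, 12.0),
        rotation_rpm=rpm,
        rotation_mode="in_plane",
        texture=SpotTexture(n_spots=1, contrast=0.6, radius=3.0, orbit=6.0),
        initial_centroid=(96.0, 96.0),
        phase0=0.3,
    )
    return SceneConfig(n_frames=n_frames, cells=(cell,), rng_seed=seed)


def flat_field_scene(
    vignette_strength: float = 0.35, seed: int = 0, n_frames: int = 2
) -> SceneConfig:
    """Cell-free, near-saturated-center field for vignette-correction
    studies: the only structure is the quadratic corner falloff plus noise."""
    return SceneConfig(
        n_frames=n_frames,
        cells=(),
        vignette_strength=vignette_strength,
        background_level=200.0,
        noise_sigma=2.0,
        n_debris=0,
        rng_seed=seed,
    )


def drift_scene(
    velocity: tuple[float, float] = (1.0, 0.5),
    rpm: float = 60.0,
    seed: int = 0,
    n_frames: int = 60,
) -> SceneConfig:
    """Single translating rotator for trajectory-recovery studies."""
    start = (60.0, 40.0)
    cell = CellSpec(
        semi_axes=(10.0, 10.0, 7.0),
        rotation_rpm=rpm,
        rotation_mode="out_of_plane",
        initial_centroid=start,
        velocity=velocity,
    )
    return SceneConfig(n_frames=n_frames, cells=(cell,), rng_seed=seed)


def circular_drift_scene(
    orbit_radius: float = 30.0,
    orbit_period_frames: float = 60.0,
    rpm: float = 60.0,
    seed: int = 0,
    n_frames: int = 60,
) -> SceneConfig:
    """Rotator drifting on a circle (tangential speed 2*pi*R/P px/frame)."""
    cell = CellSpec(
        semi_axes=(10.0, 10.0, 7.0),
        rotation_rpm=rpm,
        rotation_mode="out_of_plane",
        initial_centroid=(96.0, 126.0),
        orbit_radius=orbit_radius,
        orbit_period_frames=orbit_period_frames,
    )
    return SceneConfig(n_frames=n_frames, cells=(cell,), rng_seed=seed)
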