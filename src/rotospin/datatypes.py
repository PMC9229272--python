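"""Shared containers for the area-change pipeline.

Conventions: images are 2-D uint8 arrays with intensities in [0, 255],
indexed (row, col) with 0-based pixel indices. Frame indices are 0-based
internally; every user-facing frame number is 1-based (so a 159-frame video
spans frames 1..159).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "FrameStack",
    "Detection",
    "AreaSeries",
    "RotationResult",
    "Trajectory",
    "SceneTruth",
    "TrackState",
    "StretchParams",
]


@dataclass
class FrameStack:
    """An ordered grayscale video: ``frames`` is (n_frames, rows, cols) uint8,
    ``fps`` the acquisition frame rate in frames/second."""

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]


@dataclass(frozen=True)
class Detection:
    """One labeled connected domain of a binary mask.

    ``bbox`` is the tightest axis-aligned rectangle (row0, col0, height,
    width), 0-based and half-open; ``centroid`` the mean (row, col) of the
    member pixels; ``area`` the foreground pixel count.
    """

    label: int
    area: int
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        if self.label < 1:
            raise ValueError("label must be a positive integer")
        if self.area < 1:
            raise ValueError("area must be >= 1")

    @property
    def bbox_diagonal(self) -> float:
        _, _, h, w = self.bbox
        return float(np.hypot(h, w))


@dataclass
class AreaSeries:
    """Per-frame projected area of one tracked cell.

    ``mode`` records whether ``areas`` are full-outline pixel counts or the
    quarter-bounding-box counts used for in-plane rotation.
    """

    frame_numbers: np.ndarray  # 1-based
    areas: np.ndarray  # pixels
    mode: Literal["outline", "quarter_box"] = "outline"

    def __post_init__(self) -> None:
        self.frame_numbers = np.asarray(self.frame_numbers, dtype=int)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.frame_numbers.shape != self.areas.shape:
            raise ValueError("frame_numbers and areas must have equal length")
        if len(self.frame_numbers) and np.any(np.diff(self.frame_numbers) <= 0):
            raise ValueError("frame_numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.areas)

    def window(self, first: int, last: int) -> "AreaSeries":
        """Restrict to 1-based frame numbers ``first..last`` inclusive."""
        keep = (self.frame_numbers >= first) & (self.frame_numbers <= last)
        if not keep.any():
            raise ValueError(f"no frames in window {first}:{last}")
        return AreaSeries(self.frame_numbers[keep], self.areas[keep], self.mode)


@dataclass
class RotationResult:
    """Self-rotation speed extracted from an area-change curve.

    ``trough_frames`` are the 1-based frame numbers of the area minima, one
    per cycle boundary.  Each adjacent pair gives a per-cycle speed
    n = 60 * fps / ((X_i - X_{i-1}) * symmetry_factor) rpm; ``mean_rpm`` is
    their average and ``max_deviation_rpm`` the largest absolute departure
    from it (the mean ± maximum-deviation convention).  ``mean_rpm_pooled``
    is the single-ratio estimate over the whole trough span.
    """

    trough_frames: np.ndarray
    per_cycle_rpm: np.ndarray
    mean_rpm: float
    max_deviation_rpm: float
    n_cycles: int
    symmetry_factor: int
    smoothing_width: int
    mean_rpm_pooled: float
    fps: float

    def to_dict(self) -> dict:
        return {
            "trough_frames": [int(x) for x in self.trough_frames],
            "per_cycle_rpm": [float(x) for x in self.per_cycle_rpm],
            "mean_rpm": float(self.mean_rpm),
            "max_deviation_rpm": float(self.max_deviation_rpm),
            "n_cycles": int(self.n_cycles),
            "symmetry_factor": int(self.symmetry_factor),
            "smoothing_width": int(self.smoothing_width),
            "mean_rpm_pooled": float(self.mean_rpm_pooled),
            "fps": float(self.fps),
        }


@dataclass
class Trajectory:
    """Motion path of one tracked cell: per-frame centroids and per-step
    Euclidean displacements in pixels (displacements[0] = 0)."""

    frame_numbers: np.ndarray  # 1-based
    centroids: np.ndarray  # (n, 2) of (row, col)
    displacements: np.ndarray  # pixels

    def __post_init__(self) -> None:
        self.frame_numbers = np.asarray(self.frame_numbers, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        n = len(self.frame_numbers)
        if self.centroids.shape != (n, 2) or self.displacements.shape != (n,):
            raise ValueError("inconsistent trajectory array lengths")
        if n and self.displacements[0] != 0:
            raise ValueError("displacements[0] must be 0")

    def __len__(self) -> int:
        return len(self.frame_numbers)

    @property
    def total_displacement(self) -> float:
        return float(self.displacements.sum())


@dataclass
class SceneTruth:
    """Ground truth for a rendered synthetic video (per tracked cell):
    per-frame rotation angle, analytic centroid, rasterized silhouette area,
    plus the true speed and the period of the area signal in frames."""

    angle: np.ndarray  # radians, per frame
    centroid: np.ndarray  # (n_frames, 2) of (row, col)
    projected_area: np.ndarray  # pixels, per frame
    true_rpm: float
    area_period_frames: float

    def __post_init__(self) -> None:
        n = len(self.angle)
        if len(self.projected_area) != n or self.centroid.shape != (n, 2):
            raise ValueError("truth arrays must all have length n_frames")


@dataclass
class TrackState:
    """Mutable association state while following one cell."""

    detection: Detection
    last_centroid: tuple[float, float]
    gate: float  # search radius, pixels

    def __post_init__(self) -> None:
        if self.gate <= 0:
            raise ValueError("gate must be positive")


@dataclass(frozen=True)
class StretchParams:
    """Breakpoints of the piecewise-linear grey stretch: [0,a]->[0,y_a],
    [a,b]->[y_a,y_b], [b,M_f]->[y_b,M_f]; the middle slope exceeds 1 when
    configured for enhancement."""

    a: float
    b: float
    y_a: float
    y_b: float
    M_f: float = 255.0

    def __post_init__(self) -> None:
        if not (0 <= self.a < self.b <= self.M_f):
            raise ValueError("require 0 <= a < b <= M_f")
        if not (0 <= self.y_a <= self.y_b <= self.M_f):
            raise ValueError("require 0 <= y_a <= y_b <= M_f")
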