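"""Self-rotation speed from the area-change curve.

The tracked cell's area series is smoothed with a uniform moving-average
kernel, its cycle troughs (local area minima) are located, and each pair of
adjacent troughs X_{i-1}, X_i yields a per-cycle speed

    n = 60 * fps / ((X_i - X_{i-1}) * symmetry_factor)   [rpm]

since one area cycle corresponds to one revolution of the cell — or half a
revolution when the silhouette is pi-symmetric, which the symmetry factor
(2) corrects.  The summary is the mean of the per-cycle speeds with the
maximum absolute deviation as the error bar, plus a pooled single-ratio
estimate over the whole trough span.

Detection limit: with the default 3-frame minimum trough separation, area
cycles shorter than 3 frames (e.g. a pi-symmetric signal above ~150 rpm at
15 fps) cannot be resolved; a full-period (asymmetric/textured) signal at
the same speed still can.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .datatypes import AreaSeries, FrameStack, RotationResult
from .areatrack import build_area_series

__all__ = [
    "smooth_series",
    "find_troughs",
    "rotation_speed",
    "measure_rotation",
    "TroughDetectionError",
    "DEFAULT_SMOOTH_WIDTH",
    "DEFAULT_MIN_SEPARATION",
]

logger = logging.getLogger(__name__)

DEFAULT_SMOOTH_WIDTH = 5  # frames, odd
DEFAULT_MIN_SEPARATION = 3  # frames between adjacent troughs
DEFAULT_PROMINENCE_FRACTION = 0.02  # of the series mean


class TroughDetectionError(RuntimeError):
    """Fewer than two area minima — the speed cannot be measured."""


def smooth_series(series: AreaSeries, width: int = DEFAULT_SMOOTH_WIDTH) -> AreaSeries:
    """Uniform moving-average convolution of odd ``width``; edges are
    mirror-padded, which preserves the series mean exactly."""
    n = len(series)
    if width % 2 == 0 or not (1 <= width < n):
        raise ValueError("width must be odd and in [1, series length)")
    if width == 1:
        return AreaSeries(series.frame_numbers.copy(), series.areas.copy(), series.mode)
    half = width // 2
    padded = np.pad(series.areas, half, mode="symmetric")
    smoothed = np.convolve(padded, np.full(width, 1.0 / width), mode="valid")
    return AreaSeries(series.frame_numbers.copy(), smoothed, series.mode)


def find_troughs(
    series: AreaSeries,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    min_prominence: float | None = None,
) -> np.ndarray:
    """1-based frame numbers of the area-cycle troughs.

    Troughs are local minima deeper than both neighbors, pairwise separated
    by at least ``min_separation`` frames, with prominence at least
    ``min_prominence`` (default: 2% of the series mean).  Raises
    :class:`TroughDetectionError` when fewer than two are found.
    """
    if len(series) < 3:
        raise ValueError("series too short for trough detection")
    if min_prominence is None:
        min_prominence = DEFAULT_PROMINENCE_FRACTION * float(series.areas.mean())
    idx, _ = signal.find_peaks(-series.areas, distance=min_separation, prominence=min_prominence)
    troughs = series.frame_numbers[idx]
    if len(troughs) < 2:
        raise TroughDetectionError(
            f"found {len(troughs)} trough(s); at least 2 are needed to measure a period"
        )
    logger.debug("troughs at frames %s", troughs.tolist())
    return troughs


def rotation_speed(
    troughs: np.ndarray,
    fps: float,
    symmetry_factor: int = 1,
    smoothing_width: int = DEFAULT_SMOOTH_WIDTH,
) -> RotationResult:
    """Per-cycle speeds from adjacent trough pairs, averaged.

    ``symmetry_factor`` is 1 when one area cycle is one revolution and 2
    when the silhouette repeats every half revolution (pi-symmetric
    texture-free cells viewed out-of-plane).
    """
    troughs = np.asarray(troughs)
    if len(troughs) < 2:
        raise ValueError("need at least 2 troughs")
    if np.any(np.diff(troughs) <= 0):
        raise ValueError("trough frames must be strictly increasing")
    if fps <= 0:
        raise ValueError("fps must be positive")
    if symmetry_factor not in (1, 2):
        raise ValueError("symmetry_factor must be 1 or 2")
    spacings = np.diff(troughs).astype(float)
    per_cycle = 60.0 * fps / (spacings * symmetry_factor)
    mean = float(per_cycle.mean())
    pooled = 60.0 * fps * len(spacings) / (float(troughs[-1] - troughs[0]) * symmetry_factor)
    return RotationResult(
        trough_frames=troughs.astype(int),
        per_cycle_rpm=per_cycle,
        mean_rpm=mean,
        max_deviation_rpm=float(np.abs(per_cycle - mean).max()),
        n_cycles=len(spacings),
        symmetry_factor=symmetry_factor,
        smoothing_width=smoothing_width,
        mean_rpm_pooled=pooled,
        fps=float(fps),
    )


def measure_rotation(
    stack: FrameStack,
    seed: tuple[float, float] | int,
    mode: str = "outline",
    frame_window: tuple[int, int] | None = None,
    smooth_width: int = DEFAULT_SMOOTH_WIDTH,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    min_prominence: float | None = None,
    symmetry_factor: int | None = None,
    preprocess_kwargs: dict | None = None,
    segment_kwargs: dict | None = None,
) -> tuple[RotationResult, AreaSeries]:
    """End-to-end speed measurement on a video.

    Composes area-series extraction, an optional 1-based inclusive
    ``frame_window`` restriction (e.g. the stabilized tail of a recording),
    smoothing, trough detection and the speed formula.  When
    ``symmetry_factor`` is not given it defaults to 2 for outline mode
    (pi-symmetric silhouette) and 1 for quarter-box mode (full-period
    texture signal).  Returns the result and the (windowed, smoothed)
    series.
    """
    if symmetry_factor is None:
        symmetry_factor = 2 if mode == "outline" else 1
    series = build_area_series(stack, seed, mode, preprocess_kwargs, segment_kwargs)
    if frame_window is not None:
        series = series.window(*frame_window)
    smoothed = smooth_series(series, smooth_width)
    troughs = find_troughs(smoothed, min_separation, min_prominence)
    result = rotation_speed(troughs, stack.fps, symmetry_factor, smooth_width)
    logger.info(
        "mean rpm %.1f ± %.1f over %d cycles (troughs %s)",
        result.mean_rpm,
        result.max_deviation_rpm,
        result.n_cycles,
        result.trough_frames.tolist(),
    )
    return result, smoothed
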