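"""Motion-trajectory extraction by frame differencing.

Moving targets are detected by thresholding the absolute difference of
consecutive frames; the tracked cell is the motion candidate nearest a
constant-velocity prediction from its trajectory so far, and its position
is then refined to the centroid of the segmented cell component (the raw
motion mask straddles the vacated and newly covered ground, so its centroid
lags a fast mover by half a step).  A stationary rotator produces little or
no motion mask, in which case the tracker falls back to the segmentation
centroid directly.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import Detection, FrameStack, Trajectory
from .areatrack import (
    GATE_FACTOR,
    TrackLostError,
    _nearest,
    resolve_video_preprocessing,
    select_cell,
)
from .preprocess import preprocess_frame
from .segment import otsu_threshold, remove_small_objects, label_components, segment_frame

__all__ = ["frame_difference", "predict_position", "track_trajectory"]

logger = logging.getLogger(__name__)

#: absolute differences at or below this are treated as sensor noise even
#: before thresholding (guards Otsu against a motion-free difference image)
_NOISE_FLOOR = 2


def frame_difference(
    prev: np.ndarray, curr: np.ndarray, diff_threshold: float | None = None
) -> np.ndarray:
    """Binary motion mask: |curr - prev| > diff_threshold.

    With ``diff_threshold`` unset, the threshold is the Otsu criterion on
    the absolute-difference image, floored at three times the
    median-absolute-deviation estimate of the sensor-noise sigma — moving
    pixels are usually a tiny fraction of the frame, and without the floor
    Otsu merely splits the noise distribution.  A difference image that
    never rises above the noise floor yields an empty mask.
    """
    prev = np.asarray(prev)
    curr = np.asarray(curr)
    if prev.shape != curr.shape:
        raise ValueError("frames must share a shape")
    diff = np.abs(curr.astype(np.int16) - prev.astype(np.int16))
    if diff_threshold is None:
        if diff.max() <= _NOISE_FLOOR:
            return np.zeros(prev.shape, dtype=np.uint8)
        noise_sigma = float(np.median(diff)) / 0.6745  # MAD of a zero-mean diff
        diff_threshold = max(otsu_threshold(diff), 3.0 * noise_sigma)
    return (diff > diff_threshold).astype(np.uint8)


def predict_position(trajectory_points: np.ndarray | list) -> tuple[float, float]:
    """Constant-velocity extrapolation from the last two points (the last
    point itself when only one exists)."""
    pts = np.asarray(trajectory_points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("need at least one trajectory point")
    if len(pts) == 1:
        return (float(pts[-1, 0]), float(pts[-1, 1]))
    step = pts[-1] - pts[-2]
    pred = pts[-1] + step
    return (float(pred[0]), float(pred[1]))


def track_trajectory(
    stack: FrameStack,
    seed: tuple[float, float] | int,
    diff_threshold: float | None = None,
    min_motion_area: int = 10,
    max_coast_frames: int = 5,
    preprocess_kwargs: dict | None = None,
    segment_kwargs: dict | None = None,
) -> Trajectory:
    """Displacement trajectory of the seeded cell over the whole video.

    Per frame: motion candidates from the cleaned frame-difference mask are
    gated against the predicted position; the winning candidate is refined
    to the nearest segmented-cell centroid.  Frames with no usable candidate
    coast on the prediction for up to ``max_coast_frames`` before the track
    is declared lost.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    pre = resolve_video_preprocessing(stack, preprocess_kwargs)
    seg = segment_kwargs or {}

    def detections_at(t: int) -> list[Detection]:
        img = preprocess_frame(stack[t], **pre)
        _, dets = segment_frame(img, **seg)
        return dets

    first = detections_at(0)
    det0 = select_cell(first, seed)
    gate = max(GATE_FACTOR * det0.bbox_diagonal, 1.0)
    points = [det0.centroid]
    coasting = 0
    for t in range(1, stack.n_frames):
        predicted = predict_position(points)
        motion = frame_difference(stack[t - 1], stack[t], diff_threshold)
        motion = remove_small_objects(motion, min_motion_area)
        candidates = label_components(motion)
        anchor = None
        if candidates:
            cand, dist = _nearest(candidates, predicted)
            if dist <= gate:
                anchor = cand.centroid
        dets = detections_at(t)
        chosen = None
        if dets:
            det, dist = _nearest(dets, anchor if anchor is not None else predicted)
            if dist <= gate:
                chosen = det
        if chosen is not None:
            points.append(chosen.centroid)
            gate = max(GATE_FACTOR * chosen.bbox_diagonal, 1.0)
            coasting = 0
        else:
            coasting += 1
            if coasting > max_coast_frames:
                raise TrackLostError(
                    f"track lost at frame {t + 1} after coasting {max_coast_frames} frames"
                )
            logger.warning("no candidate at frame %d; coasting on prediction", t + 1)
            points.append(predicted)
    pts = np.asarray(points)
    steps = np.zeros(len(pts))
    steps[1:] = np.hypot(*(np.diff(pts, axis=0).T))
    return Trajectory(np.arange(1, len(pts) + 1), pts, steps)
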