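"""Follow one selected cell through the video and build its area series.

The cell of interest is picked once (the single manual step of the method);
every later frame is associated by nearest centroid within a search gate so
other cells in the field never capture the track.  The per-frame measurement
is either the full outline area of the labeled component (out-of-plane
rotation, where the projected silhouette breathes) or the foreground count
inside one fixed quadrant of the cell's bounding box (in-plane rotation,
where the outline is constant but internal structure sweeps through the
quadrant once per revolution).
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import AreaSeries, Detection, FrameStack, TrackState
from .preprocess import VignetteFitError, estimate_vignette_gain, preprocess_frame, to_grayscale
from .segment import segment_frame

__all__ = [
    "TrackLostError",
    "resolve_video_preprocessing",
    "select_cell",
    "associate",
    "quarter_box_area",
    "track_cell",
    "build_area_series",
    "GATE_FACTOR",
]

logger = logging.getLogger(__name__)

#: association gate = GATE_FACTOR x current bounding-box diagonal
GATE_FACTOR = 2.0


class TrackLostError(RuntimeError):
    """No detection fell inside the association gate."""


def resolve_video_preprocessing(stack: FrameStack, preprocess_kwargs: dict | None) -> dict:
    """Per-video preprocessing defaults.

    Videos default to the entropy-minimization shading correction: the
    vignette is a static property of the optics, so its gain field is
    fitted once on the first frame and reused for every frame.  (A tone
    curve such as gamma cannot reorder corner-background against cell
    pixels, so under a strong vignette only an explicit multiplicative
    gain makes the global threshold separate cell from background.)
    """
    pre = {"vignette": "entropy", **(preprocess_kwargs or {})}
    if pre.get("vignette") == "entropy" and pre.get("gain") is None:
        first = to_grayscale(stack[0])
        try:
            pre["gain"] = estimate_vignette_gain(first)
        except VignetteFitError as exc:
            logger.warning("shading fit did not converge; using best candidate: %s", exc)
            pre["gain"] = exc.best_gain
    return pre


def _nearest(detections: list[Detection], point: tuple[float, float]) -> tuple[Detection, float]:
    """Nearest-centroid detection; exact distance ties go to the lower label."""
    best, best_key = None, None
    for det in detections:
        d = float(np.hypot(det.centroid[0] - point[0], det.centroid[1] - point[1]))
        key = (d, det.label)
        if best_key is None or key < best_key:
            best, best_key = det, key
    return best, best_key[0]


def select_cell(
    detections: list[Detection],
    seed: tuple[float, float] | int,
    max_distance: float | None = None,
) -> Detection:
    """Pick the cell of interest by label or by a clicked (row, col) point.

    A point inside a component's bounding box selects that component;
    otherwise the nearest centroid wins (lower label on exact ties).  With
    ``max_distance`` set, a point farther than that from every centroid is
    an error.
    """
    if not detections:
        raise ValueError("no detections to select from")
    if isinstance(seed, int):
        for det in detections:
            if det.label == seed:
                return det
        raise ValueError(f"no detection with label {seed}")
    inside = [
        det
        for det in detections
        if det.bbox[0] <= seed[0] < det.bbox[0] + det.bbox[2]
        and det.bbox[1] <= seed[1] < det.bbox[1] + det.bbox[3]
    ]
    det, dist = _nearest(inside or detections, seed)
    if not inside and max_distance is not None and dist > max_distance:
        raise TrackLostError(f"no detection within {max_distance} px of seed point")
    return det


def associate(state: TrackState, detections_next: list[Detection]) -> Detection:
    """Advance the track to the nearest-centroid detection within the gate.

    Updates ``state`` in place; raises :class:`TrackLostError` when nothing
    falls inside the gate.
    """
    if not detections_next:
        raise TrackLostError("no detections in next frame")
    det, dist = _nearest(detections_next, state.last_centroid)
    if dist > state.gate:
        raise TrackLostError(f"nearest candidate at {dist:.1f} px exceeds gate {state.gate:.1f} px")
    state.detection = det
    state.last_centroid = det.centroid
    state.gate = max(GATE_FACTOR * det.bbox_diagonal, 1.0)
    return det


def quarter_box_area(mask: np.ndarray, det: Detection) -> int:
    """Foreground pixels in the top-left quadrant of the cell's bounding box.

    For a rotationally symmetric cell this is ~area/4 and constant; internal
    or asymmetric structure rotating in-plane modulates it with the full
    rotation period.  The top-left quadrant is a fixed, documented choice —
    any fixed quadrant carries the same periodicity.
    """
    r0, c0, h, w = det.bbox
    if h < 2 or w < 2:
        raise ValueError("bounding box too small for a quadrant split")
    quad = np.asarray(mask)[r0 : r0 + h // 2, c0 : c0 + w // 2]
    return int(np.count_nonzero(quad))


def track_cell(
    stack: FrameStack,
    seed: tuple[float, float] | int,
    mode: str = "outline",
    preprocess_kwargs: dict | None = None,
    segment_kwargs: dict | None = None,
    on_track_lost: str = "truncate",
) -> tuple[AreaSeries, list[Detection]]:
    """Run preprocessing + segmentation per frame and follow the seeded cell.

    Returns the area series (1-based frame numbers) and the per-frame
    detections of the tracked cell.  ``on_track_lost`` is ``truncate``
    (stop and return what was measured, logged) or ``raise``.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if mode not in ("outline", "quarter_box"):
        raise ValueError(f"unknown mode {mode!r}")
    pre = resolve_video_preprocessing(stack, preprocess_kwargs)
    seg = segment_kwargs or {}
    frames_out: list[int] = []
    areas: list[float] = []
    dets_out: list[Detection] = []
    state: TrackState | None = None
    for t in range(stack.n_frames):
        img = preprocess_frame(stack[t], **pre)
        mask, dets = segment_frame(img, **seg)
        try:
            if state is None:
                det = select_cell(dets, seed)
                state = TrackState(det, det.centroid, max(GATE_FACTOR * det.bbox_diagonal, 1.0))
            else:
                det = associate(state, dets)
        except (TrackLostError, ValueError) as exc:
            if on_track_lost == "raise" or state is None:
                raise TrackLostError(f"track lost at frame {t + 1}: {exc}") from exc
            logger.warning("track lost at frame %d: %s", t + 1, exc)
            break
        frames_out.append(t + 1)
        areas.append(det.area if mode == "outline" else quarter_box_area(mask, det))
        dets_out.append(det)
    logger.debug("tracked %d/%d frames", len(frames_out), stack.n_frames)
    return AreaSeries(np.array(frames_out), np.array(areas, dtype=float), mode), dets_out


def build_area_series(
    stack: FrameStack,
    seed: tuple[float, float] | int,
    mode: str = "outline",
    preprocess_kwargs: dict | None = None,
    segment_kwargs: dict | None = None,
) -> AreaSeries:
    """Area-change curve of the seeded cell over the whole video."""
    series, _ = track_cell(stack, seed, mode, preprocess_kwargs, segment_kwargs)
    return series
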