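"""Video readers and result writers.

Reference dialects are multi-page TIFF stacks and directories of numbered
PNG/TIFF frames (bit-exact round trips); AVI decoding is attempted through
imageio when a video plugin is available.  Color frames are collapsed to
grayscale on read.  All user-facing frame numbers are 1-based.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .datatypes import AreaSeries, FrameStack, RotationResult, SceneTruth, Trajectory
from .preprocess import to_grayscale

__all__ = [
    "read_frames",
    "write_tiff_stack",
    "write_truth_csv",
    "write_series_csv",
    "write_trajectory_csv",
    "write_results",
]


def _numeric_key(path: Path) -> tuple:
    m = re.search(r"(\d+)(?=\D*$)", path.stem)
    return (int(m.group(1)) if m else -1, path.name)


def read_frames(path: str | Path, fps: float, dialect: str | None = None) -> FrameStack:
    """Load a video as a FrameStack.

    ``dialect`` is ``tiff_stack``, ``png_dir`` or ``avi``; when omitted it
    is inferred from the path (directory -> png_dir, .tif/.tiff ->
    tiff_stack, .avi -> avi).  Frames must share one shape; color input is
    converted to grayscale by the Rec. 601 luma weights.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        if path.is_dir():
            dialect = "png_dir"
        elif path.suffix.lower() in (".tif", ".tiff"):
            dialect = "tiff_stack"
        elif path.suffix.lower() == ".avi":
            dialect = "avi"
        else:
            raise ValueError(f"cannot infer input dialect from {path.name!r}")
    if dialect == "tiff_stack":
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        frames = [to_grayscale(fr) for fr in arr]
    elif dialect == "png_dir":
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")),
            key=_numeric_key,
        )
        if not files:
            raise ValueError(f"no PNG/TIFF frames found in {path}")
        frames = [to_grayscale(iio.imread(p)) for p in files]
    elif dialect == "avi":
        try:
            frames = [to_grayscale(fr) for fr in iio.imiter(path)]
        except Exception as exc:  # no decoder plugin in a minimal install
            raise RuntimeError(
                "AVI decoding requires an imageio video plugin (e.g. ffmpeg); "
                "convert the video to a multi-page TIFF or PNG directory"
            ) from exc
        if not frames:
            raise ValueError(f"no frames decoded from {path}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    shapes = {fr.shape for fr in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
    return FrameStack(np.stack(frames).astype(np.uint8), fps)


def write_tiff_stack(stack: FrameStack, path: str | Path) -> Path:
    """8-bit grayscale multi-page TIFF; round-trips bit-identically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames)
    return path


def write_truth_csv(truth: SceneTruth, path: str | Path) -> Path:
    """Ground-truth table: frame (1-based), angle_rad, row, col, area_px."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "frame": np.arange(1, len(truth.angle) + 1),
            "angle_rad": truth.angle,
            "row": truth.centroid[:, 0],
            "col": truth.centroid[:, 1],
            "area_px": truth.projected_area.astype(int),
        }
    ).to_csv(path, index=False)
    return path


def write_series_csv(series: AreaSeries, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"frame": series.frame_numbers, "area_px": series.areas}).to_csv(
        path, index=False
    )
    return path


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "frame": traj.frame_numbers,
            "row": traj.centroids[:, 0],
            "col": traj.centroids[:, 1],
            "step_px": traj.displacements,
        }
    ).to_csv(path, index=False)
    return path


def write_results(
    result: RotationResult,
    outdir: str | Path,
    series: AreaSeries | None = None,
    trajectory: Trajectory | None = None,
    config_echo: dict | None = None,
) -> dict[str, Path]:
    """Emit result.json (+ series.csv / trajectory.csv when given).

    ``config_echo`` is embedded verbatim in the JSON so a run can be
    reproduced exactly; identical inputs give byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = result.to_dict()
    if config_echo is not None:
        payload["config"] = config_echo
    paths = {"result": outdir / "result.json"}
    paths["result"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if series is not None:
        paths["series"] = write_series_csv(series, outdir / "series.csv")
    if trajectory is not None:
        paths["trajectory"] = write_trajectory_csv(trajectory, outdir / "trajectory.csv")
    return paths
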