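"""Quick-look plots for the area-change curve and the motion trajectory."""

from __future__ import annotations

from .datatypes import AreaSeries, RotationResult, Trajectory

__all__ = ["plot_area_series", "plot_trajectory"]


def plot_area_series(series: AreaSeries, result: RotationResult | None = None, ax=None):
    """Area-change curve with the detected cycle troughs marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(series.frame_numbers, series.areas, lw=1.2, label=f"area ({series.mode})")
    if result is not None:
        in_series = {int(f) for f in series.frame_numbers}
        xs = [f for f in result.trough_frames if f in in_series]
        ys = [series.areas[list(series.frame_numbers).index(f)] for f in xs]
        ax.plot(xs, ys, "v", color="tab:red", label="troughs")
        ax.set_title(
            f"{result.mean_rpm:.1f} ± {result.max_deviation_rpm:.1f} rpm "
            f"over {result.n_cycles} cycles"
        )
    ax.set_xlabel("frame")
    ax.set_ylabel("area (px)")
    ax.legend()
    return ax


def plot_trajectory(traj: Trajectory, ax=None):
    """Motion path in image coordinates (row axis points down)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(traj.centroids[:, 1], traj.centroids[:, 0], "-o", ms=2)
    ax.plot(traj.centroids[0, 1], traj.centroids[0, 0], "s", color="tab:green", label="start")
    ax.invert_yaxis()
    ax.set_xlabel("col (px)")
    ax.set_ylabel("row (px)")
    ax.set_aspect("equal")
    ax.legend()
    return ax
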