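"""Footprint plots with binned pressure colors, overlays, and GIF export.

Pressure values are mapped to a small ordered set of colors through
ascending break values: with breaks ``(100, 200, 300)`` and four colors,
values up to and including 100 take the first color, 101–200 the second,
and anything above 300 the last (lower break inclusive).  The default
8-color scale uses breaks at 15, 40, 60, 100, 150, 220 and 300 kPa,
approximating the blue-to-red ramp conventional in pedobarography.

Two render paths share the same binning: :func:`render_pressure_array`
produces a deterministic flat-color RGB raster (used for every GIF frame),
while :func:`plot_pressure` draws a full matplotlib figure with optional
COP path, footprint convex-hull outline, sensor outlines and legend.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import matplotlib

matplotlib.use("Agg")  # headless, deterministic
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import LineCollection
from matplotlib.colors import ListedColormap, to_rgb
from shapely.geometry import MultiPoint

from .core import PressureRecording
from .preprocess import cop

__all__ = [
    "PlotSpec",
    "DEFAULT_BREAKS",
    "DEFAULT_COLORS",
    "color_bin",
    "variable_field",
    "render_pressure_array",
    "plot_pressure",
    "animate_pressure",
]

DEFAULT_BREAKS = (15.0, 40.0, 60.0, 100.0, 150.0, 220.0, 300.0)
DEFAULT_COLORS = (
    "#2166ac", "#4393c3", "#92c5de", "#a6dba0", "#ffee65",
    "#f4a582", "#d6604d", "#b2182b",
)

_NAMED = {
    "light_blue": "#a6cee3",
    "light_green": "#b2df8a",
    "yellow": "#ffff99",
    "pink": "#fb9a99",
}


@dataclass
class PlotSpec:
    """Rendering options for footprint plots and animations."""

    variable: str = "max"  # max | mean | frame
    frame: int | None = None
    plot_colors: str = "default"  # default | custom
    break_values: tuple[float, ...] = DEFAULT_BREAKS
    break_colors: tuple[str, ...] = DEFAULT_COLORS
    plot_cop: bool = False
    plot_outline: bool = False
    sensor_outline: bool = True
    legend: bool = True
    width_px: int = 480
    height_px: int = 640
    dpi: int = 96
    upscale: int = 8  # pixels per cell for the flat-array renderer

    def __post_init__(self) -> None:
        if self.variable not in ("max", "mean", "frame"):
            raise ValueError("variable must be 'max', 'mean' or 'frame'")
        if self.plot_colors == "custom":
            breaks = np.asarray(self.break_values, dtype=float)
            if len(breaks) and not (np.diff(breaks) > 0).all():
                raise ValueError("break_values must be strictly ascending")
            if len(self.break_colors) != len(breaks) + 1:
                raise ValueError("need exactly one more color than break values")

    @property
    def breaks(self) -> np.ndarray:
        if self.plot_colors == "default":
            return np.asarray(DEFAULT_BREAKS)
        return np.asarray(self.break_values, dtype=float)

    @property
    def colors(self) -> tuple[str, ...]:
        names = DEFAULT_COLORS if self.plot_colors == "default" else self.break_colors
        return tuple(_NAMED.get(c, c) for c in names)


def color_bin(value: float, spec: PlotSpec) -> int:
    """Bin index of a pressure value under the spec's color breaks.

    Break values are inclusive on the lower color: 100 maps to the first
    bin of breaks (100, 200, 300), 101 to the second, 301+ to the last.
    """
    breaks = spec.breaks
    if len(breaks) > 1 and not (np.diff(breaks) > 0).all():
        raise ValueError("break_values must be strictly ascending")
    return int(np.searchsorted(breaks, value, side="left"))


def variable_field(rec: PressureRecording, spec: PlotSpec) -> np.ndarray:
    """The (n_rows, n_cols) field selected by ``spec.variable``."""
    if spec.variable == "max":
        return rec.frames.values.max(axis=0)
    if spec.variable == "mean":
        return rec.frames.values.mean(axis=0)
    t = spec.frame
    if t is None or not 0 <= t < rec.n_frames:
        raise ValueError(f"frame index {t} out of range [0, {rec.n_frames - 1}]")
    return rec.frames.values[t]


def render_pressure_array(rec: PressureRecording, spec: PlotSpec) -> np.ndarray:
    """Flat-color RGB raster (H, W, 3) uint8 of the selected field.

    Cells at zero pressure (or inactive) are white; each loaded cell is the
    solid color of its pressure bin; the image is oriented with row 0 at
    the bottom.  Deterministic for fixed inputs, and uses at most
    ``len(colors) + 1`` distinct colors, so GIF palette quantization is
    lossless.
    """
    field = variable_field(rec, spec)
    bins = np.searchsorted(spec.breaks, field, side="left")
    palette = np.array([np.array(to_rgb(c)) * 255 for c in spec.colors], dtype=np.uint8)
    rgb = palette[bins]
    background = (field <= 0) | (~rec.grid.active)
    rgb[background] = 255
    rgb = np.kron(rgb[::-1], np.ones((spec.upscale, spec.upscale, 1), dtype=np.uint8))
    return rgb


def _draw_figure(rec: PressureRecording, spec: PlotSpec):
    field = variable_field(rec, spec)
    bins = np.searchsorted(spec.breaks, field, side="left").astype(float)
    masked = np.ma.masked_where((field <= 0) | (~rec.grid.active), bins)
    cmap = ListedColormap(spec.colors)
    cmap.set_bad("white")

    fig = plt.figure(
        figsize=(spec.width_px / spec.dpi, spec.height_px / spec.dpi), dpi=spec.dpi
    )
    ax = fig.add_axes([0.02, 0.02, 0.78 if spec.legend else 0.96, 0.96])
    px, py = rec.grid.pitch()
    x0, y0 = rec.grid.centers[0, 0]
    extent = (
        x0 - px / 2,
        x0 - px / 2 + rec.grid.n_cols * px,
        y0 - py / 2,
        y0 - py / 2 + rec.grid.n_rows * py,
    )
    ax.imshow(
        masked,
        origin="lower",
        extent=extent,
        cmap=cmap,
        vmin=-0.5,
        vmax=len(spec.colors) - 0.5,
        interpolation="nearest",
    )
    layers = ["pressure"]
    if spec.sensor_outline:
        segs = []
        for r, c in np.argwhere(rec.grid.active):
            quad = rec.grid.polygons[r, c]
            segs.append(np.vstack([quad, quad[:1]]))
        ax.add_collection(
            LineCollection(segs, colors="0.6", linewidths=0.3, label="sensor_outline")
        )
        layers.append("sensor_outline")
    if spec.plot_outline:
        maxp = rec.frames.values.max(axis=0)
        loaded = rec.grid.active & (maxp > 0)
        hull = MultiPoint(
            [tuple(v) for rc in np.argwhere(loaded) for v in rec.grid.polygons[tuple(rc)]]
        ).convex_hull
        hx, hy = hull.exterior.xy
        ax.plot(hx, hy, color="black", linewidth=1.2, label="outline")
        layers.append("outline")
    if spec.plot_cop:
        traj = cop(rec)
        pts = traj.points[traj.valid]
        if len(pts):
            ax.plot(pts[:, 0], pts[:, 1], "k--", linewidth=1.0, label="cop")
            layers.append("cop")
    if spec.legend:
        breaks = spec.breaks
        labels = [f"<= {breaks[0]:g}"]
        labels += [f"{breaks[i]:g}-{breaks[i + 1]:g}" for i in range(len(breaks) - 1)]
        labels += [f"> {breaks[-1]:g}"]
        handles = [
            plt.Rectangle((0, 0), 1, 1, facecolor=c, edgecolor="0.3")
            for c in spec.colors
        ]
        fig.legend(
            handles, labels, loc="center right", fontsize=6, title="kPa", title_fontsize=7
        )
        layers.append("legend")
    ax.set_aspect("equal")
    ax.set_axis_off()
    return fig, layers


def plot_pressure(
    rec: PressureRecording, spec: PlotSpec, path: str | os.PathLike
) -> dict:
    """Render a footprint figure to *path* (PNG).

    Returns a manifest dict with the output path, the drawn layer names and
    the pixel dimensions.  Identical recording and spec give identical
    bytes.
    """
    fig, layers = _draw_figure(rec, spec)
    try:
        fig.savefig(path, dpi=spec.dpi, metadata={"Software": "pedobar"})
    finally:
        plt.close(fig)
    return {
        "path": str(path),
        "layers": layers,
        "width_px": spec.width_px,
        "height_px": spec.height_px,
    }


def animate_pressure(
    rec: PressureRecording,
    spec: PlotSpec,
    fps: float,
    path: str | os.PathLike,
) -> dict:
    """Export an animated GIF with one frame per recording frame.

    Each GIF frame is the flat-color raster of that time point
    (:func:`render_pressure_array` with ``variable="frame"``).  GIF frame
    timing is quantized to 10 ms, so use an fps that divides 100 (10, 20,
    25, 50) for exact metadata round-trips.
    """
    if rec.n_frames < 2:
        raise ValueError("need at least 2 frames to animate")
    if fps <= 0:
        raise ValueError("fps must be positive")
    frames = []
    for t in range(rec.n_frames):
        fspec = PlotSpec(
            variable="frame",
            frame=t,
            plot_colors=spec.plot_colors,
            break_values=spec.break_values,
            break_colors=spec.break_colors,
            upscale=spec.upscale,
        )
        frames.append(render_pressure_array(rec, fspec))
    iio.imwrite(path, frames, extension=".gif", duration=1000.0 / fps, loop=0)
    return {"path": str(path), "n_frames": rec.n_frames, "fps": fps}
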