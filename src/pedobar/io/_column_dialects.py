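"""Sensor-major column dialects: pedar and pliance ``.asc`` exports.

One column per sensor, one row per frame.  pedar files carry no geometry —
sensor positions come from a registered insole layout resolved by name or
by sensor count.  pliance exports describe a full rectangular mat in the
header, sensors numbered row-major from the bottom (heel) row.
"""

from __future__ import annotations

import os

import numpy as np

from ..core import PressureFrameSeries, PressureRecording, SensorGrid, System
from ._common import DialectError, fmt, parse_number, unit_factor
from .layouts import find_layout_for_grid, get_layout, known_layouts

__all__ = ["load_pedar", "load_pliance", "write_pedar", "write_pliance"]

_PEDAR_MAGIC = "PEDAR-ASC SIMPLIFIED EXPORT"
_PLIANCE_MAGIC = "PLIANCE-ASC SIMPLIFIED EXPORT"


def _read_columns(lines: list[str], i: int, n_sensors: int, n_frames: int) -> np.ndarray:
    if i >= len(lines) or not lines[i].startswith("time"):
        raise DialectError("missing column header line starting with 'time'")
    header_cols = lines[i].split("\t")
    if len(header_cols) != n_sensors + 1:
        raise DialectError(
            f"column header has {len(header_cols) - 1} sensor columns, expected {n_sensors}"
        )
    i += 1
    data = np.empty((n_frames, n_sensors))
    for t in range(n_frames):
        if i + t >= len(lines) or not lines[i + t].strip():
            raise DialectError(f"file truncated at frame {t}")
        tokens = lines[i + t].split("\t")
        if len(tokens) != n_sensors + 1:
            raise DialectError(
                f"frame {t}: row has {len(tokens) - 1} sensor values, expected {n_sensors}"
            )
        data[t] = [parse_number(tok) for tok in tokens[1:]]
    return data


def _header(lines: list[str], magic: str, required: list[str]):
    if not lines or lines[0].strip() != magic:
        raise DialectError(f"missing dialect header line {magic!r}")
    hdr: dict[str, str] = {}
    i = 1
    while i < len(lines) and lines[i].strip() and not lines[i].startswith("time"):
        key, _, val = lines[i].partition(":")
        hdr[key.strip()] = val.strip()
        i += 1
    for key in required:
        if key not in hdr:
            raise DialectError(f"header is missing {key!r}")
    return hdr, i


def load_pedar(path: str | os.PathLike) -> PressureRecording:
    """Read a pedar-style ``.asc`` in-shoe export (simplified dialect).

    The insole geometry comes from the registered layout named in the
    header (falling back to a unique sensor-count match).  Multi-step
    series are kept in full; events stay empty until step detection.
    """
    lines = open(path).read().splitlines()
    hdr, i = _header(
        lines, _PEDAR_MAGIC, ["sampling_rate_hz", "units", "sensors", "frames"]
    )
    n_sensors = int(hdr["sensors"])
    try:
        if hdr.get("insole_layout"):
            layout = get_layout(hdr["insole_layout"])
            if layout.n_sensors != n_sensors:
                raise DialectError(
                    f"layout {layout.name!r} has {layout.n_sensors} sensors, file has {n_sensors}"
                )
        else:
            layout = get_layout(n_sensors=n_sensors)
    except KeyError:
        raise DialectError(
            f"no insole layout for {n_sensors} sensors; known layouts: {known_layouts()}"
        ) from None
    factor = unit_factor(hdr["units"])
    data = _read_columns(lines, i, n_sensors, int(hdr["frames"]))
    grid = layout.grid
    values = np.zeros((len(data), grid.n_rows, grid.n_cols))
    order = layout.order
    values[:, order[:, 0], order[:, 1]] = factor * data
    return PressureRecording(
        frames=PressureFrameSeries(values, parse_number(hdr["sampling_rate_hz"])),
        grid=SensorGrid(
            grid.centers.copy(), grid.polygons.copy(), grid.areas.copy(), grid.active.copy()
        ),
        system=System.PEDAR,
    )


def load_pliance(path: str | os.PathLike) -> PressureRecording:
    """Read a pliance-style ``.asc`` mat export (simplified dialect).

    The header declares the full rectangular mat (rows, columns, pitch);
    sensor columns are numbered row-major from the bottom row.
    """
    lines = open(path).read().splitlines()
    hdr, i = _header(
        lines,
        _PLIANCE_MAGIC,
        ["sampling_rate_hz", "rows", "columns", "pitch_x_mm", "pitch_y_mm", "units", "sensors", "frames"],
    )
    n_rows, n_cols = int(hdr["rows"]), int(hdr["columns"])
    n_sensors = int(hdr["sensors"])
    if n_sensors != n_rows * n_cols:
        raise DialectError(
            f"sensor count {n_sensors} does not match {n_rows}x{n_cols} mat"
        )
    factor = unit_factor(hdr["units"])
    data = _read_columns(lines, i, n_sensors, int(hdr["frames"]))
    grid = SensorGrid.uniform(
        n_rows, n_cols, parse_number(hdr["pitch_x_mm"]), parse_number(hdr["pitch_y_mm"])
    )
    values = (factor * data).reshape(len(data), n_rows, n_cols)
    return PressureRecording(
        frames=PressureFrameSeries(values, parse_number(hdr["sampling_rate_hz"])),
        grid=grid,
        system=System.PLIANCE,
    )


def _column_body(data: np.ndarray, rate: float, factor: float) -> list[str]:
    n_sensors = data.shape[1]
    lines = ["time[s]\t" + "\t".join(f"S{k + 1:03d}" for k in range(n_sensors))]
    for t, row in enumerate(data):
        lines.append(
            fmt(t / rate) + "\t" + "\t".join(fmt(v / factor) for v in row)
        )
    return lines


def write_pedar(rec: PressureRecording, path: str | os.PathLike, units: str = "kPa") -> None:
    layout = find_layout_for_grid(rec.grid)
    if layout is None:
        raise DialectError(
            "recording grid matches no registered insole layout; "
            f"known layouts: {known_layouts()}"
        )
    factor = unit_factor(units)
    order = layout.order
    data = rec.frames.values[:, order[:, 0], order[:, 1]]
    lines = [
        _PEDAR_MAGIC,
        f"insole_layout: {layout.name}",
        f"sampling_rate_hz: {fmt(rec.sampling_rate)}",
        f"units: {units}",
        f"sensors: {layout.n_sensors}",
        f"frames: {rec.n_frames}",
    ] + _column_body(data, rec.sampling_rate, factor)
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def write_pliance(rec: PressureRecording, path: str | os.PathLike, units: str = "kPa") -> None:
    if not rec.grid.is_uniform_rectangular():
        raise DialectError(
            "pliance dialect represents full rectangular mats only; "
            "recording has a trimmed or non-uniform grid"
        )
    px, py = rec.grid.pitch()
    factor = unit_factor(units)
    data = rec.frames.values.reshape(rec.n_frames, -1)
    lines = [
        _PLIANCE_MAGIC,
        f"sampling_rate_hz: {fmt(rec.sampling_rate)}",
        f"rows: {rec.grid.n_rows}",
        f"columns: {rec.grid.n_cols}",
        f"pitch_x_mm: {fmt(px)}",
        f"pitch_y_mm: {fmt(py)}",
        f"units: {units}",
        f"sensors: {rec.grid.n_rows * rec.grid.n_cols}",
        f"frames: {rec.n_frames}",
    ] + _column_body(data, rec.sampling_rate, factor)
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
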