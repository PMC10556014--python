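"""Frame-block dialects: emed ``.lst``, Tekscan ``.asf``/``.csv`` and
footscan ``.xls``-style tab-separated tables.

Each dialect is a simplified, strictly parsed text form of the vendor's
export: a small header (sampling rate, grid dimensions, sensor pitch,
pressure units) followed by one dense ``rows × columns`` block per frame,
top sensor row first.  Real vendor exports vary by software version;
anything that does not match the documented dialect fails loudly rather
than being guessed at.
"""

from __future__ import annotations

import os

import numpy as np

from ..core import PressureFrameSeries, PressureRecording, SensorGrid, System
from ._common import DialectError, fmt, parse_number, unit_factor

__all__ = ["load_emed", "load_tekscan", "load_footscan", "write_emed", "write_tekscan", "write_footscan"]

_EMED_MAGIC = "EMED-LST SIMPLIFIED EXPORT"
_TEKSCAN_MAGIC = "TEKSCAN SIMPLIFIED ASCII EXPORT"
_FOOTSCAN_MAGIC = "FOOTSCAN SIMPLIFIED EXPORT"


def _require_uniform(rec: PressureRecording, system: str) -> tuple[float, float]:
    if not rec.grid.is_uniform_rectangular():
        raise DialectError(
            f"{system} dialect represents full rectangular platforms only; "
            "recording has a trimmed or non-uniform grid"
        )
    return rec.grid.pitch()


def _frame_lines(values_2d: np.ndarray, sep: str) -> list[str]:
    # top sensor row (largest y) printed first
    return [sep.join(fmt(v) for v in row) for row in values_2d[::-1]]


def _parse_frame_block(
    lines: list[str], start: int, n_rows: int, n_cols: int, sep: str | None, frame_idx: int
) -> np.ndarray:
    block = np.empty((n_rows, n_cols))
    for i in range(n_rows):
        if start + i >= len(lines):
            raise DialectError(f"frame {frame_idx}: file truncated inside frame block")
        tokens = lines[start + i].split(sep)
        if len(tokens) != n_cols:
            raise DialectError(
                f"frame {frame_idx}: row has {len(tokens)} columns, expected {n_cols}"
            )
        try:
            block[n_rows - 1 - i] = [parse_number(t) for t in tokens]
        except DialectError as e:
            raise DialectError(f"frame {frame_idx}: {e}") from None
    return block


def _read_kv_header(lines: list[str], keys: dict[str, str], magic: str, sep: str = ":"):
    if not lines or lines[0].strip() != magic:
        raise DialectError(f"missing dialect header line {magic!r}")
    found: dict[str, str] = {}
    i = 1
    while i < len(lines) and lines[i].strip():
        key, _, val = lines[i].partition(sep)
        found[key.strip()] = val.strip()
        i += 1
    for required, label in keys.items():
        if required not in found:
            raise DialectError(f"header is missing {label} ({required!r})")
    return found, i


# --------------------------------------------------------------- emed .lst


def load_emed(path: str | os.PathLike) -> PressureRecording:
    """Read an emed-style ``.lst`` export (simplified dialect).

    Header keys: ``sampling_rate_hz``, ``rows``, ``columns``,
    ``pitch_x_mm``, ``pitch_y_mm``, ``units`` (kPa or N/cm2), ``frames``;
    then one ``Frame <t>`` block per time point with space-separated values,
    top row first.
    """
    lines = open(path).read().splitlines()
    hdr, i = _read_kv_header(
        lines,
        {
            "sampling_rate_hz": "the sampling rate",
            "rows": "grid rows",
            "columns": "grid columns",
            "pitch_x_mm": "sensor pitch x",
            "pitch_y_mm": "sensor pitch y",
            "units": "pressure units",
            "frames": "frame count",
        },
        _EMED_MAGIC,
    )
    factor = unit_factor(hdr["units"])
    n_rows, n_cols = int(hdr["rows"]), int(hdr["columns"])
    n_frames = int(hdr["frames"])
    grid = SensorGrid.uniform(
        n_rows, n_cols, parse_number(hdr["pitch_x_mm"]), parse_number(hdr["pitch_y_mm"])
    )
    frames = _read_frame_blocks(lines, i, n_frames, n_rows, n_cols, sep=None)
    return PressureRecording(
        frames=PressureFrameSeries(factor * frames, parse_number(hdr["sampling_rate_hz"])),
        grid=grid,
        system=System.EMED,
    )


def _read_frame_blocks(lines, i, n_frames, n_rows, n_cols, sep) -> np.ndarray:
    frames = []
    t = 0
    while t < n_frames:
        while i < len(lines) and not lines[i].strip():
            i += 1
        if i >= len(lines) or not lines[i].startswith("Frame"):
            raise DialectError(f"frame {t}: missing 'Frame' separator line")
        i += 1
        frames.append(_parse_frame_block(lines, i, n_rows, n_cols, sep, t))
        i += n_rows
        t += 1
    return np.stack(frames)


def write_emed(rec: PressureRecording, path: str | os.PathLike, units: str = "kPa") -> None:
    px, py = _require_uniform(rec, "emed")
    factor = unit_factor(units)
    lines = [
        _EMED_MAGIC,
        f"sampling_rate_hz: {fmt(rec.sampling_rate)}",
        f"rows: {rec.grid.n_rows}",
        f"columns: {rec.grid.n_cols}",
        f"pitch_x_mm: {fmt(px)}",
        f"pitch_y_mm: {fmt(py)}",
        f"units: {units}",
        f"frames: {rec.n_frames}",
        "",
    ]
    for t in range(rec.n_frames):
        lines.append(f"Frame {t}")
        lines.extend(_frame_lines(rec.frames.values[t] / factor, " "))
        lines.append("")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines))


# ------------------------------------------------------- tekscan .asf/.csv


def load_tekscan(path: str | os.PathLike) -> PressureRecording:
    """Read a Tekscan-style ASCII export (simplified dialect).

    Header: ``ROWS``, ``COLS``, ``ROW_SPACING_MM``, ``COL_SPACING_MM``,
    ``FRAME_RATE_HZ``, ``UNITS`` and ``FRAME_COUNT``; comma-separated frame
    blocks, top row first.  Uncalibrated exports (``UNITS RAW``) are
    rejected: sensor calibration belongs to the vendor software.
    """
    lines = open(path).read().splitlines()
    hdr, i = _read_kv_header(
        lines,
        {
            "ROWS": "grid rows",
            "COLS": "grid columns",
            "ROW_SPACING_MM": "row spacing",
            "COL_SPACING_MM": "column spacing",
            "FRAME_RATE_HZ": "the frame rate",
            "UNITS": "pressure units",
            "FRAME_COUNT": "frame count",
        },
        _TEKSCAN_MAGIC,
        sep=" ",
    )
    if hdr["UNITS"].strip().upper() == "RAW":
        raise DialectError(
            "uncalibrated Tekscan export (UNITS RAW); export calibrated pressures instead"
        )
    factor = unit_factor(hdr["UNITS"])
    n_rows, n_cols = int(hdr["ROWS"]), int(hdr["COLS"])
    grid = SensorGrid.uniform(
        n_rows, n_cols, parse_number(hdr["COL_SPACING_MM"]), parse_number(hdr["ROW_SPACING_MM"])
    )
    frames = _read_frame_blocks(lines, i, int(hdr["FRAME_COUNT"]), n_rows, n_cols, sep=",")
    return PressureRecording(
        frames=PressureFrameSeries(factor * frames, parse_number(hdr["FRAME_RATE_HZ"])),
        grid=grid,
        system=System.TEKSCAN,
    )


def write_tekscan(rec: PressureRecording, path: str | os.PathLike, units: str = "kPa") -> None:
    px, py = _require_uniform(rec, "tekscan")
    factor = unit_factor(units)
    lines = [
        _TEKSCAN_MAGIC,
        f"ROWS {rec.grid.n_rows}",
        f"COLS {rec.grid.n_cols}",
        f"ROW_SPACING_MM {fmt(py)}",
        f"COL_SPACING_MM {fmt(px)}",
        f"FRAME_RATE_HZ {fmt(rec.sampling_rate)}",
        f"UNITS {units}",
        f"FRAME_COUNT {rec.n_frames}",
        "",
    ]
    for t in range(rec.n_frames):
        lines.append(f"Frame {t}")
        lines.extend(_frame_lines(rec.frames.values[t] / factor, ","))
        lines.append("")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines))


# ------------------------------------------------- footscan .xls-style TSV


def load_footscan(path: str | os.PathLike) -> PressureRecording:
    """Read a footscan-style spreadsheet export saved as tab-separated text.

    Header rows are ``<label>\\t<value>`` pairs (sampling rate, grid
    dimensions, cell sizes, units) followed by rectangular per-frame tables.
    """
    lines = open(path).read().splitlines()
    hdr, i = _read_kv_header(
        lines,
        {
            "Sampling rate (Hz)": "the sampling rate",
            "Rows": "grid rows",
            "Columns": "grid columns",
            "Cell size X (mm)": "cell size x",
            "Cell size Y (mm)": "cell size y",
            "Units": "pressure units",
            "Frames": "frame count",
        },
        _FOOTSCAN_MAGIC,
        sep="\t",
    )
    factor = unit_factor(hdr["Units"])
    n_rows, n_cols = int(hdr["Rows"]), int(hdr["Columns"])
    n_frames = int(hdr["Frames"])
    if n_frames < 1:
        raise DialectError("export contains no frames")
    grid = SensorGrid.uniform(
        n_rows, n_cols, parse_number(hdr["Cell size X (mm)"]), parse_number(hdr["Cell size Y (mm)"])
    )
    frames = _read_frame_blocks(lines, i, n_frames, n_rows, n_cols, sep="\t")
    return PressureRecording(
        frames=PressureFrameSeries(factor * frames, parse_number(hdr["Sampling rate (Hz)"])),
        grid=grid,
        system=System.FOOTSCAN,
    )


def write_footscan(rec: PressureRecording, path: str | os.PathLike, units: str = "kPa") -> None:
    px, py = _require_uniform(rec, "footscan")
    factor = unit_factor(units)
    lines = [
        _FOOTSCAN_MAGIC,
        f"Sampling rate (Hz)\t{fmt(rec.sampling_rate)}",
        f"Rows\t{rec.grid.n_rows}",
        f"Columns\t{rec.grid.n_cols}",
        f"Cell size X (mm)\t{fmt(px)}",
        f"Cell size Y (mm)\t{fmt(py)}",
        f"Units\t{units}",
        f"Frames\t{rec.n_frames}",
        "",
    ]
    for t in range(rec.n_frames):
        lines.append(f"Frame {t}")
        lines.extend(_frame_lines(rec.frames.values[t] / factor, "\t"))
        lines.append("")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines))
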