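"""Versioned plain-text interchange format for pressure recordings.

The canonical file is self-describing and lossless: a header with units and
format version, a per-cell geometry table, one dense pressure block per
frame, and optional EVENTS and MASKS sections.  Floats are written with
``repr`` (shortest round-tripping decimal), so write → read is bit-faithful
and two writes of the same recording are byte-identical.

Layout (version 1)::

    PEDOBAR-CANONICAL 1
    system: emed
    side: unknown
    sampling_rate_hz: 100.0
    n_rows: 4
    n_cols: 3
    pressure_unit: kPa
    area_unit: cm2
    length_unit: mm
    GEOMETRY
    row,col,active,area,cx,cy,x1,y1,x2,y2,x3,y3,x4,y4
    ...
    FRAME 0
    <n_rows lines of n_cols comma-separated kPa values, row 0 first>
    ...
    EVENTS
    start,end
    ...
    MASKS
    MASK <name> polygon <coverage_rule> <fraction>
    x,y
    ...
    MASK <name> cells
    r,c
    ...
    END
"""

from __future__ import annotations

import os
from typing import TextIO

import numpy as np

from .core import (
    EventList,
    Mask,
    PressureFrameSeries,
    PressureRecording,
    SensorGrid,
    Side,
    System,
    validate_recording,
)

__all__ = ["write_canonical", "read_canonical", "CanonicalFormatError"]

FORMAT_VERSION = 1
_MAGIC = "PEDOBAR-CANONICAL"


class CanonicalFormatError(ValueError):
    """Raised for version mismatches, unsupported units or corrupt blocks."""


def _f(x: float) -> str:
    return repr(float(x))


def write_canonical(rec: PressureRecording, path: str | os.PathLike) -> None:
    """Write *rec* to *path* in the canonical text format (lossless)."""
    report = validate_recording(rec)
    if not report:
        raise ValueError("refusing to write invalid recording: " + "; ".join(report.violations))
    g = rec.grid
    lines: list[str] = [
        f"{_MAGIC} {FORMAT_VERSION}",
        f"system: {rec.system.value}",
        f"side: {rec.side.value}",
        f"sampling_rate_hz: {_f(rec.sampling_rate)}",
        f"n_rows: {g.n_rows}",
        f"n_cols: {g.n_cols}",
        "pressure_unit: kPa",
        "area_unit: cm2",
        "length_unit: mm",
        "GEOMETRY",
        "row,col,active,area,cx,cy,x1,y1,x2,y2,x3,y3,x4,y4",
    ]
    for r in range(g.n_rows):
        for c in range(g.n_cols):
            quad = ",".join(_f(v) for v in g.polygons[r, c].ravel())
            lines.append(
                f"{r},{c},{int(g.active[r, c])},{_f(g.areas[r, c])},"
                f"{_f(g.centers[r, c, 0])},{_f(g.centers[r, c, 1])},{quad}"
            )
    for t in range(rec.n_frames):
        lines.append(f"FRAME {t}")
        for r in range(g.n_rows):
            lines.append(",".join(_f(v) for v in rec.frames.values[t, r]))
    if len(rec.events):
        lines.append("EVENTS")
        lines.append("start,end")
        for a, b in rec.events:
            lines.append(f"{a},{b}")
    if rec.masks:
        lines.append("MASKS")
        for name, m in rec.masks.items():
            if m.is_polygon:
                lines.append(
                    f"MASK {name} polygon {m.coverage_rule} {_f(m.fraction)} {len(m.polygon)}"
                )
                for x, y in m.polygon:
                    lines.append(f"{_f(x)},{_f(y)}")
            else:
                cells = sorted(m.cells)
                lines.append(f"MASK {name} cells {len(cells)}")
                for r, c in cells:
                    lines.append(f"{r},{c}")
    lines.append("END")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_header_value(line: str, key: str) -> str:
    k, _, val = line.partition(":")
    if k.strip() != key:
        raise CanonicalFormatError(f"expected header key {key!r}, got {line!r}")
    return val.strip()


def read_canonical(path: str | os.PathLike) -> PressureRecording:
    """Read a canonical file back into a :class:`PressureRecording`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    it = iter(enumerate(lines))

    def next_line() -> str:
        try:
            _, ln = next(it)
        except StopIteration:
            raise CanonicalFormatError("unexpected end of file") from None
        return ln

    first = next_line().split()
    if len(first) != 2 or first[0] != _MAGIC:
        raise CanonicalFormatError("not a canonical pressure file")
    if int(first[1]) != FORMAT_VERSION:
        raise CanonicalFormatError(
            f"unsupported format version {first[1]} (supported: {FORMAT_VERSION})"
        )
    system = System(_read_header_value(next_line(), "system"))
    side = Side(_read_header_value(next_line(), "side"))
    rate = float(_read_header_value(next_line(), "sampling_rate_hz"))
    n_rows = int(_read_header_value(next_line(), "n_rows"))
    n_cols = int(_read_header_value(next_line(), "n_cols"))
    for key, allowed in (("pressure_unit", "kPa"), ("area_unit", "cm2"), ("length_unit", "mm")):
        unit = _read_header_value(next_line(), key)
        if unit != allowed:
            raise CanonicalFormatError(f"unsupported unit {unit!r} for {key}")
    if next_line() != "GEOMETRY":
        raise CanonicalFormatError("missing GEOMETRY section")
    next_line()  # geometry column header
    centers = np.zeros((n_rows, n_cols, 2))
    polygons = np.zeros((n_rows, n_cols, 4, 2))
    areas = np.zeros((n_rows, n_cols))
    active = np.zeros((n_rows, n_cols), dtype=bool)
    for _ in range(n_rows * n_cols):
        parts = next_line().split(",")
        if len(parts) != 14:
            raise CanonicalFormatError("malformed geometry row")
        r, c = int(parts[0]), int(parts[1])
        active[r, c] = bool(int(parts[2]))
        areas[r, c] = float(parts[3])
        centers[r, c] = [float(parts[4]), float(parts[5])]
        polygons[r, c] = np.array([float(v) for v in parts[6:]]).reshape(4, 2)

    frames: list[np.ndarray] = []
    events = EventList()
    masks: dict[str, Mask] = {}
    line = next_line()
    while line.startswith("FRAME"):
        t = int(line.split()[1])
        block = np.empty((n_rows, n_cols))
        for r in range(n_rows):
            try:
                row = next_line()
            except CanonicalFormatError:
                raise CanonicalFormatError(f"frame {t} is incomplete (truncated file)") from None
            vals = row.split(",")
            if len(vals) != n_cols or row in ("END", "EVENTS", "MASKS"):
                raise CanonicalFormatError(f"frame {t} is incomplete or malformed")
            block[r] = [float(v) for v in vals]
        frames.append(block)
        line = next_line()
    if not frames:
        raise CanonicalFormatError("file contains no frames")

    if line == "EVENTS":
        next_line()  # column header
        line = next_line()
        intervals = []
        while line not in ("MASKS", "END"):
            a, b = line.split(",")
            intervals.append((int(a), int(b)))
            line = next_line()
        events = EventList(intervals)
    if line == "MASKS":
        line = next_line()
        while line != "END":
            parts = line.split()
            if parts[0] != "MASK":
                raise CanonicalFormatError(f"malformed MASKS section at {line!r}")
            name, kind = parts[1], parts[2]
            if kind == "polygon":
                rule, frac, nv = parts[3], float(parts[4]), int(parts[5])
                verts = []
                for _ in range(nv):
                    x, y = next_line().split(",")
                    verts.append((float(x), float(y)))
                masks[name] = Mask(
                    name=name, polygon=np.array(verts), coverage_rule=rule, fraction=frac
                )
            elif kind == "cells":
                n = int(parts[3])
                cells = []
                for _ in range(n):
                    r, c = next_line().split(",")
                    cells.append((int(r), int(c)))
                masks[name] = Mask(name=name, cells=frozenset(cells))
            else:
                raise CanonicalFormatError(f"unknown mask kind {kind!r}")
            line = next_line()
    elif line != "END":
        raise CanonicalFormatError(f"unexpected section {line!r}")

    rec = PressureRecording(
        frames=PressureFrameSeries(np.stack(frames), rate),
        grid=SensorGrid(centers, polygons, areas, active),
        system=system,
        side=side,
        events=events,
        masks=masks,
    )
    report = validate_recording(rec)
    if not report:
        raise CanonicalFormatError("file decodes to invalid recording: " + "; ".join(report.violations))
    return rec
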