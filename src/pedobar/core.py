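"""Standardized data model for pressure-distribution recordings.

A recording bundles everything a pressure trial needs to be analyzed in a
hardware-independent way: the frame-by-frame pressure matrix, the sensor
geometry (centers, polygons, areas, active map), the source system, the
detected or declared foot side, step events, and named regional masks.

Units are fixed package-wide:

* lengths and coordinates in **mm** (x is the column direction, y the row
  direction, origin at the bottom-left cell center, y increasing toward the
  toes once a footprint is aligned);
* sensor areas in **cm²**;
* pressures in **kPa**;
* forces in **N** (1 kPa × 1 cm² = 0.1 N).

Frames are 0-indexed and event intervals are inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "System",
    "Side",
    "SensorGrid",
    "PressureFrameSeries",
    "EventList",
    "Mask",
    "PressureRecording",
    "ValidationReport",
    "validate_recording",
    "recordings_equal",
]


class System(str, Enum):
    """Source hardware family of a recording."""

    EMED = "emed"
    PEDAR = "pedar"
    PLIANCE = "pliance"
    TEKSCAN = "tekscan"
    FOOTSCAN = "footscan"
    SYNTHETIC = "synthetic"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"

    @property
    def opposite(self) -> "Side":
        if self is Side.LEFT:
            return Side.RIGHT
        if self is Side.RIGHT:
            return Side.LEFT
        return Side.UNKNOWN


def _polygon_area_signed(verts: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as (N, 2) vertices."""
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class SensorGrid:
    """Geometry of a rectangular sensor array.

    Parameters
    ----------
    centers : (n_rows, n_cols, 2) float array
        Per-cell (x, y) center position in mm.
    polygons : (n_rows, n_cols, 4, 2) float array
        Per-cell quadrilateral vertices in mm, ordered counter-clockwise.
    areas : (n_rows, n_cols) float array
        Per-cell sensor area in cm².
    active : (n_rows, n_cols) bool array
        False for cells absent from trimmed (insole) layouts.
    """

    centers: np.ndarray
    polygons: np.ndarray
    areas: np.ndarray
    active: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.polygons = np.asarray(self.polygons, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.active = np.asarray(self.active, dtype=bool)
        r, c = self.active.shape
        if self.centers.shape != (r, c, 2):
            raise ValueError(f"centers shape {self.centers.shape} != {(r, c, 2)}")
        if self.polygons.shape != (r, c, 4, 2):
            raise ValueError(f"polygons shape {self.polygons.shape} != {(r, c, 4, 2)}")
        if self.areas.shape != (r, c):
            raise ValueError(f"areas shape {self.areas.shape} != {(r, c)}")

    @property
    def n_rows(self) -> int:
        return self.active.shape[0]

    @property
    def n_cols(self) -> int:
        return self.active.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.active.shape

    @classmethod
    def uniform(
        cls,
        n_rows: int,
        n_cols: int,
        pitch_x: float,
        pitch_y: float,
        active: np.ndarray | None = None,
    ) -> "SensorGrid":
        """Build a uniform rectangular grid.

        Cell (r, c) is centered at ``(c * pitch_x, r * pitch_y)`` with a
        rectangular polygon of size ``pitch_x × pitch_y``; areas are
        ``pitch_x * pitch_y / 100`` cm².
        """
        xs = np.arange(n_cols, dtype=float) * pitch_x
        ys = np.arange(n_rows, dtype=float) * pitch_y
        cx, cy = np.meshgrid(xs, ys)
        centers = np.stack([cx, cy], axis=-1)
        hx, hy = pitch_x / 2.0, pitch_y / 2.0
        offsets = np.array([[-hx, -hy], [hx, -hy], [hx, hy], [-hx, hy]])
        polygons = centers[:, :, None, :] + offsets[None, None, :, :]
        areas = np.full((n_rows, n_cols), pitch_x * pitch_y / 100.0)
        if active is None:
            active = np.ones((n_rows, n_cols), dtype=bool)
        return cls(centers=centers, polygons=polygons, areas=areas, active=active)

    def is_uniform_rectangular(self, rtol: float = 1e-9) -> bool:
        """True when the grid matches :meth:`uniform` geometry (all active)."""
        if not self.active.all():
            return False
        px, py = self.pitch()
        ref = SensorGrid.uniform(self.n_rows, self.n_cols, px, py)
        return (
            np.allclose(self.centers, ref.centers, rtol=rtol, atol=1e-9)
            and np.allclose(self.polygons, ref.polygons, rtol=rtol, atol=1e-9)
            and np.allclose(self.areas, ref.areas, rtol=rtol, atol=1e-9)
        )

    def pitch(self) -> tuple[float, float]:
        """(pitch_x, pitch_y) in mm, inferred from the first cells."""
        if self.n_cols > 1:
            px = float(self.centers[0, 1, 0] - self.centers[0, 0, 0])
        else:
            px = float(self.polygons[0, 0, 1, 0] - self.polygons[0, 0, 0, 0])
        if self.n_rows > 1:
            py = float(self.centers[1, 0, 1] - self.centers[0, 0, 1])
        else:
            py = float(self.polygons[0, 0, 2, 1] - self.polygons[0, 0, 1, 1])
        return px, py


@dataclass
class PressureFrameSeries:
    """Time series of pressure frames.

    values : (T, n_rows, n_cols) float array, kPa.
    sampling_rate : Hz.
    """

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a (T, n_rows, n_cols) array")
        self.sampling_rate = float(self.sampling_rate)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        """Trial duration in seconds, ``(T - 1) / sampling_rate``."""
        return (self.n_frames - 1) / self.sampling_rate


@dataclass
class EventList:
    """Ordered, non-overlapping inclusive ``(start_frame, end_frame)`` pairs."""

    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = [(int(a), int(b)) for a, b in self.intervals]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> tuple[int, int]:
        return self.intervals[i]

    def problems(self, n_frames: int | None = None) -> list[str]:
        out = []
        for i, (a, b) in enumerate(self.intervals):
            if a > b:
                out.append(f"event {i}: start {a} > end {b}")
            if a < 0:
                out.append(f"event {i}: start {a} < 0")
            if n_frames is not None and b > n_frames - 1:
                out.append(f"event {i}: end {b} beyond last frame {n_frames - 1}")
            if i and self.intervals[i - 1][1] >= a:
                out.append(f"events {i - 1} and {i} overlap or are unsorted")
        return out


@dataclass
class Mask:
    """A named anatomical region.

    Defined either by a polygon in grid coordinates (mm) or by an explicit
    set of ``(row, col)`` cells.  ``coverage_rule`` selects how partially
    covered sensors are treated when a polygon mask is assigned to cells:
    ``"center_in"`` includes a cell iff its center lies inside the polygon
    (boundary counts as inside); ``"fraction_ge"`` includes a cell iff
    (polygon ∩ cell area) / cell area ≥ ``fraction``.
    """

    name: str
    polygon: np.ndarray | None = None
    cells: frozenset[tuple[int, int]] | None = None
    coverage_rule: str = "center_in"
    fraction: float = 0.5

    def __post_init__(self) -> None:
        if (self.polygon is None) == (self.cells is None):
            raise ValueError("mask needs exactly one of polygon or cells")
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=float)
            verts = np.unique(self.polygon, axis=0)
            if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(verts) < 3:
                raise ValueError(
                    f"mask {self.name!r}: polygon needs >= 3 distinct (x, y) vertices"
                )
            if abs(_polygon_area_signed(self.polygon)) <= 0.0:
                raise ValueError(f"mask {self.name!r}: polygon vertices are collinear")
        if self.cells is not None:
            self.cells = frozenset((int(r), int(c)) for r, c in self.cells)
        if self.coverage_rule not in ("center_in", "fraction_ge"):
            raise ValueError(f"unknown coverage rule {self.coverage_rule!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")

    @property
    def is_polygon(self) -> bool:
        return self.polygon is not None


@dataclass
class PressureRecording:
    """The standardized recording object every module consumes and produces."""

    frames: PressureFrameSeries
    grid: SensorGrid
    system: System = System.SYNTHETIC
    side: Side = Side.UNKNOWN
    events: EventList = field(default_factory=EventList)
    masks: dict[str, Mask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.system = System(self.system)
        self.side = Side(self.side)

    @property
    def n_frames(self) -> int:
        return self.frames.n_frames

    @property
    def sampling_rate(self) -> float:
        return self.frames.sampling_rate

    def copy(self) -> "PressureRecording":
        return PressureRecording(
            frames=PressureFrameSeries(
                self.frames.values.copy(), self.frames.sampling_rate
            ),
            grid=SensorGrid(
                self.grid.centers.copy(),
                self.grid.polygons.copy(),
                self.grid.areas.copy(),
                self.grid.active.copy(),
            ),
            system=self.system,
            side=self.side,
            events=EventList(list(self.events.intervals)),
            masks={k: replace(m) for k, m in self.masks.items()},
        )

    def add_mask(self, mask: Mask, overwrite: bool = False) -> None:
        if not overwrite and mask.name in self.masks:
            raise ValueError(f"mask name {mask.name!r} already exists")
        self.masks[mask.name] = mask


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str]

    def __bool__(self) -> bool:
        return self.ok


def _point_in_polygon(point: np.ndarray, verts: np.ndarray) -> bool:
    """Even-odd point-in-polygon test; boundary points count as inside."""
    x, y = point
    n = len(verts)
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # boundary check: point on segment
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-9 and min(x1, x2) - 1e-9 <= x <= max(x1, x2) + 1e-9 and min(
            y1, y2
        ) - 1e-9 <= y <= max(y1, y2) + 1e-9:
            return True
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


def validate_recording(rec: PressureRecording) -> ValidationReport:
    """Check every data-model invariant; report all violations, mutate nothing.

    Checks, in order: frame-series shape/finite/non-negative values, positive
    sampling rate, grid geometry (positive finite active areas, simple
    polygons containing their centers), no pressure on inactive cells, event
    intervals within the frame range and non-overlapping, and mask/grid
    consistency (explicit cells in range, unique names).
    """
    v: list[str] = []
    fr, grid = rec.frames, rec.grid
    T = fr.n_frames
    if T < 1:
        v.append("frame series is empty (T < 1)")
    if fr.sampling_rate <= 0:
        v.append(f"sampling_rate {fr.sampling_rate} is not > 0")
    if fr.values.shape[1:] != grid.shape:
        v.append(
            f"frame grid shape {fr.values.shape[1:]} != sensor grid {grid.shape}"
        )
    bad = ~np.isfinite(fr.values)
    if bad.any():
        t, r, c = (int(i) for i in np.argwhere(bad)[0])
        v.append(f"non-finite pressure at (t={t}, r={r}, c={c})")
    neg = fr.values < 0
    if neg.any():
        t, r, c = (int(i) for i in np.argwhere(neg)[0])
        v.append(f"negative pressure at (t={t}, r={r}, c={c})")

    act = grid.active
    a = grid.areas[act]
    if a.size and (not np.isfinite(a).all() or (a <= 0).any()):
        v.append("active cell with non-positive or non-finite area")
    if not np.isfinite(grid.centers).all() or not np.isfinite(grid.polygons).all():
        v.append("non-finite grid geometry")
    else:
        for r, c in np.argwhere(act):
            quad = grid.polygons[r, c]
            if abs(_polygon_area_signed(quad)) <= 0:
                v.append(f"degenerate sensor polygon at (r={r}, c={c})")
                break
            if not _point_in_polygon(grid.centers[r, c], quad):
                v.append(f"center outside sensor polygon at (r={r}, c={c})")
                break

    if fr.values.shape[1:] == grid.shape and fr.values[:, ~act].any():
        t, flat = np.argwhere(fr.values[:, ~act] > 0)[0]
        v.append(f"inactive cell carries pressure (frame {int(t)})")

    v.extend(rec.events.problems(T))

    for name, mask in rec.masks.items():
        if name != mask.name:
            v.append(f"mask stored under {name!r} but named {mask.name!r}")
        if mask.cells is not None:
            for r, c in mask.cells:
                if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
                    v.append(f"mask {name!r} references out-of-grid cell ({r}, {c})")
                    break
    return ValidationReport(ok=not v, violations=v)


def recordings_equal(
    a: PressureRecording,
    b: PressureRecording,
    data_only: bool = False,
    rtol: float = 0.0,
    atol: float = 0.0,
) -> bool:
    """Field-for-field equality of two recordings.

    With ``data_only=True`` only frames, grid geometry and system are
    compared (vendor dialects carry no events, masks or side).
    """

    def close(x, y):
        return np.allclose(x, y, rtol=rtol, atol=atol)

    if not data_only and a.system != b.system:
        return False
    if a.frames.values.shape != b.frames.values.shape:
        return False
    if not close(a.frames.sampling_rate, b.frames.sampling_rate):
        return False
    if not close(a.frames.values, b.frames.values):
        return False
    g, h = a.grid, b.grid
    if g.shape != h.shape or (g.active != h.active).any():
        return False
    if not (close(g.centers, h.centers) and close(g.polygons, h.polygons) and close(g.areas, h.areas)):
        return False
    if data_only:
        return True
    if a.side != b.side or a.events.intervals != b.events.intervals:
        return False
    if set(a.masks) != set(b.masks):
        return False
    for name in a.masks:
        ma, mb = a.masks[name], b.masks[name]
        if ma.is_polygon != mb.is_polygon:
            return False
        if ma.is_polygon:
            if ma.polygon.shape != mb.polygon.shape or not close(ma.polygon, mb.polygon):
                return False
        elif ma.cells != mb.cells:
            return False
        if ma.coverage_rule != mb.coverage_rule or not close(ma.fraction, mb.fraction):
            return False
    return True
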