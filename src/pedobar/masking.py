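"""Regional masks: manual polygons and sensor sets, template insole schemes,
and the automatic 10-region barefoot masking algorithm.

The automatic barefoot scheme aligns the footprint to its principal axis,
orients it toe-ward from COP travel, splits the foot length into heel /
midfoot / forefoot / toes bands, then splits the forefoot mediolaterally
into the five metatarsal-head regions and the toes into hallux / toe2 /
toes3–5.  All split fractions are configurable; the defaults are
literature-typical proportions of foot length and regional width.  Boundary
cells are assigned to the more posterior (longitudinal splits) or more
medial (mediolateral splits) region, which guarantees the ten regions
partition the active footprint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from ._geometry import FootprintError, align_footprint
from .core import Mask, PressureRecording, SensorGrid, Side

__all__ = [
    "MaskingScheme",
    "SensorAssignment",
    "AUTOMASK_NOVEL",
    "AUTOMASK_REGIONS",
    "create_mask_manual",
    "create_mask_auto",
    "assign_sensors",
    "edit_mask",
]

#: Region names produced by the automatic barefoot scheme, posterior to
#: anterior and medial to lateral within each band.
AUTOMASK_REGIONS = (
    "heel",
    "midfoot",
    "MTH1",
    "MTH2",
    "MTH3",
    "MTH4",
    "MTH5",
    "hallux",
    "toe2",
    "toes3_5",
)

_FRACTION_EPS = 1e-9


@dataclass
class MaskingScheme:
    """Geometric rule parameters of the automatic barefoot scheme.

    ``longitudinal``: heel / midfoot / forefoot / toes fractions of foot
    length (posterior to anterior).  ``forefoot_widths``: MTH1..MTH5
    fractions of forefoot width, medial to lateral.  ``toe_widths``:
    hallux / toe2 / toes3-5 fractions of toe-band width.  Each group must
    sum to 1.
    """

    name: str = "automask_novel"
    longitudinal: tuple[float, ...] = (0.30, 0.25, 0.27, 0.18)
    forefoot_widths: tuple[float, ...] = (0.30, 0.20, 0.175, 0.175, 0.15)
    toe_widths: tuple[float, ...] = (0.35, 0.20, 0.45)
    labels: tuple[str, ...] = AUTOMASK_REGIONS

    def __post_init__(self) -> None:
        for part in (self.longitudinal, self.forefoot_widths, self.toe_widths):
            if abs(sum(part) - 1.0) > _FRACTION_EPS:
                raise ValueError(f"split fractions {part} must sum to 1")
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("region labels must be unique")


AUTOMASK_NOVEL = MaskingScheme()

PEDAR_SCHEMES = ("pedar_mask1", "pedar_mask2", "pedar_mask3")


@dataclass
class SensorAssignment:
    """Cells assigned to one mask, with per-cell coverage fractions."""

    mask_name: str
    cells: frozenset[tuple[int, int]]
    fractions: dict[tuple[int, int], float] = field(default_factory=dict)


def assign_sensors(mask: Mask, grid: SensorGrid) -> SensorAssignment:
    """Resolve a mask to concrete sensor cells.

    Polygon masks use the mask's coverage rule: ``center_in`` includes an
    active cell iff its center lies inside the polygon (boundary counts as
    inside); ``fraction_ge`` includes it iff the covered fraction of the
    cell's own polygon is at least ``mask.fraction`` (to within 1e-9, so a
    polygon that exactly tiles a cell passes ``fraction_ge(1.0)``).
    Explicit sensor-set masks resolve to exactly their cell set.
    """
    if not mask.is_polygon:
        return SensorAssignment(mask.name, mask.cells, {c: 1.0 for c in mask.cells})
    poly = Polygon(mask.polygon)
    cells: list[tuple[int, int]] = []
    fractions: dict[tuple[int, int], float] = {}
    if mask.coverage_rule == "center_in":
        prepared = prep(poly)
        for r, c in np.argwhere(grid.active):
            center = Point(grid.centers[r, c])
            if prepared.intersects(center):  # intersects == covers for a point
                cells.append((int(r), int(c)))
                fractions[(int(r), int(c))] = 1.0
    else:
        for r, c in np.argwhere(grid.active):
            cellpoly = Polygon(grid.polygons[r, c])
            frac = poly.intersection(cellpoly).area / cellpoly.area
            if frac + _FRACTION_EPS >= mask.fraction:
                cells.append((int(r), int(c)))
                fractions[(int(r), int(c))] = frac
    return SensorAssignment(mask.name, frozenset(cells), fractions)


def create_mask_manual(
    rec: PressureRecording,
    definitions: list,
    names: list[str],
    coverage_rule: str = "center_in",
    fraction: float = 0.5,
) -> PressureRecording:
    """Append manually defined masks to the recording.

    Each definition is either an (n ≥ 3, 2) array of polygon vertices in mm
    (programmatic coordinates in place of interactive clicks) or an iterable
    of explicit ``(row, col)`` sensor cells.
    """
    if len(definitions) != len(names):
        raise ValueError("need one name per mask definition")
    for name, definition in zip(names, definitions):
        arr = np.asarray(definition, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 2 and not _looks_like_cells(definition):
            mask = Mask(name=name, polygon=arr, coverage_rule=coverage_rule, fraction=fraction)
        else:
            mask = Mask(name=name, cells=frozenset(tuple(map(int, rc)) for rc in definition))
        rec.add_mask(mask)
    return rec


def _looks_like_cells(definition) -> bool:
    arr = np.asarray(definition)
    return arr.dtype.kind in "iu"


def _band_index(values: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Bin index per value; a value exactly on a boundary goes to the lower
    (more posterior / more medial) bin."""
    return np.searchsorted(boundaries, values, side="left")


def create_mask_auto(
    rec: PressureRecording,
    scheme: str = "automask_novel",
    foot_side: Side | str = "auto",
    threshold: float = 5.0,
    config: MaskingScheme | None = None,
) -> PressureRecording:
    """Automatically generate regional masks, replacing same-named ones.

    ``automask_novel`` is the 10-region geometric barefoot scheme (heel,
    midfoot, MTH1–5, hallux, toe2, toes3–5).  ``pedar_mask1/2/3`` apply the
    bundled template region tables to a trimmed insole layout; the shipped
    tables are labelled approximations (3, 9 and 10 regions) and can be
    edited or replaced.
    """
    if scheme == "automask_novel":
        return _automask_barefoot(rec, foot_side, threshold, config or AUTOMASK_NOVEL)
    if scheme in PEDAR_SCHEMES:
        return _apply_pedar_scheme(rec, scheme, foot_side)
    raise ValueError(f"unknown masking scheme {scheme!r}")


def _resolve_side(rec: PressureRecording, foot_side: Side | str) -> Side:
    if foot_side == "auto":
        from .preprocess import auto_detect_side

        side = rec.side if rec.side is not Side.UNKNOWN else auto_detect_side(rec)
    else:
        side = Side(foot_side)
    if side is Side.UNKNOWN:
        raise FootprintError("foot side undetermined; pass foot_side explicitly")
    return side


def _automask_barefoot(
    rec: PressureRecording,
    foot_side: Side | str,
    threshold: float,
    cfg: MaskingScheme,
) -> PressureRecording:
    axes = align_footprint(rec, threshold)  # raises if no footprint
    side = _resolve_side(rec, foot_side)
    L = axes.length
    long_bounds = L * np.cumsum(cfg.longitudinal)[:-1]  # heel|midfoot|forefoot|toes
    band = _band_index(axes.long_coord, long_bounds)

    # medial coordinate grows toward the medial border for either side:
    # the m axis points medially for a right foot, laterally for a left.
    med = axes.med_coord if side is Side.RIGHT else -axes.med_coord

    region_cells: dict[str, list[tuple[int, int]]] = {n: [] for n in cfg.labels}
    names = np.empty(len(axes.cells), dtype=object)
    names[band == 0] = cfg.labels[0]
    names[band == 1] = cfg.labels[1]
    for band_idx, width_fracs, labels in (
        (2, cfg.forefoot_widths, cfg.labels[2:7]),
        (3, cfg.toe_widths, cfg.labels[7:10]),
    ):
        sel = band == band_idx
        if not sel.any():
            continue
        # distance from the medial border of this band's footprint
        from_medial = med[sel].max() - med[sel]
        width = from_medial.max()
        bounds = width * np.cumsum(width_fracs)[:-1]
        sub = _band_index(from_medial, bounds)
        for i, label in enumerate(labels):
            names[np.flatnonzero(sel)[sub == i]] = label
    for cell, name in zip(axes.cells, names):
        region_cells[str(name)].append((int(cell[0]), int(cell[1])))

    rec.side = side
    for label in cfg.labels:
        rec.add_mask(Mask(name=label, cells=frozenset(region_cells[label])), overwrite=True)
    return rec


def _load_pedar_tables() -> dict:
    text = resources.files("pedobar.data").joinpath("pedar_schemes.json").read_text()
    return json.loads(text)


def _apply_pedar_scheme(
    rec: PressureRecording, scheme: str, foot_side: Side | str
) -> PressureRecording:
    side = _resolve_side(rec, foot_side)
    table = _load_pedar_tables()[scheme]
    act = np.argwhere(rec.grid.active)
    pts = rec.grid.centers[rec.grid.active]
    y0, y1 = pts[:, 1].min(), pts[:, 1].max()
    x0, x1 = pts[:, 0].min(), pts[:, 0].max()
    yn = (pts[:, 1] - y0) / (y1 - y0)
    # medial->lateral: the insole grid follows the platform convention
    # (foot axis +y); medial is -x for a right foot, +x for a left one.
    xn = (pts[:, 0] - x0) / (x1 - x0)  # 0 at the -x border == medial for right
    if side is Side.LEFT:
        xn = 1.0 - xn
    region_cells: dict[str, list[tuple[int, int]]] = {
        r["name"]: [] for r in table["regions"]
    }
    for (r, c), y, x in zip(act, yn, xn):
        for reg in table["regions"]:
            ylo, yhi = reg["y"]
            xlo, xhi = reg.get("x", (0.0, 1.0))
            y_ok = (ylo <= y < yhi) or (yhi >= 1.0 and y == 1.0)
            x_ok = (xlo <= x < xhi) or (xhi >= 1.0 and x == 1.0)
            if y_ok and x_ok:
                region_cells[reg["name"]].append((int(r), int(c)))
                break
    rec.side = side
    for name, cells in region_cells.items():
        rec.add_mask(Mask(name=name, cells=frozenset(cells)), overwrite=True)
    return rec


def edit_mask(
    rec: PressureRecording,
    mask_name: str,
    vertex_moves: list[tuple],
    snap_tolerance: float = 5.0,
) -> PressureRecording:
    """Move polygon-mask vertices: each item is ``(old_xy, new_xy)`` in mm.

    The old vertex must match an existing vertex within *snap_tolerance* mm
    (nearest wins).  Edits that would degenerate the polygon are rejected.
    """
    if mask_name not in rec.masks:
        raise KeyError(f"mask {mask_name!r} not found")
    mask = rec.masks[mask_name]
    if not mask.is_polygon:
        raise ValueError(f"mask {mask_name!r} is not polygon-defined")
    verts = mask.polygon.copy()
    for old, new in vertex_moves:
        d = np.linalg.norm(verts - np.asarray(old, dtype=float), axis=1)
        i = int(np.argmin(d))
        if d[i] > snap_tolerance:
            raise ValueError(
                f"no vertex of {mask_name!r} within {snap_tolerance} mm of {tuple(old)}"
            )
        verts[i] = new
    rec.masks[mask_name] = Mask(
        name=mask_name,
        polygon=verts,
        coverage_rule=mask.coverage_rule,
        fraction=mask.fraction,
    )
    return rec
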