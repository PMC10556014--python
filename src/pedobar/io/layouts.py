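"""Bundled insole sensor layouts.

In-shoe exports carry one column per sensor and no geometry, so sensor
positions, polygons and areas come from a registered layout table.  The
bundled ``pedar_99`` layout is a 16 × 7 grid trimmed to an insole outline
(99 active cells, 13 mm × 15.3 mm sensors); synthetic or custom layouts can
be registered at run time with :func:`register_layout`.

The sensor column order of an export is the layout's ``order``: active cells
row-major from the heel (row 0) upward, medial column first for the grid's
+y foot axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import SensorGrid

__all__ = ["InsoleLayout", "get_layout", "register_layout", "known_layouts", "find_layout_for_grid"]


@dataclass
class InsoleLayout:
    name: str
    grid: SensorGrid

    @property
    def n_sensors(self) -> int:
        return int(self.grid.active.sum())

    @property
    def order(self) -> np.ndarray:
        """(n_sensors, 2) array of (row, col) in export column order."""
        return np.argwhere(self.grid.active)


def _build_pedar_99() -> InsoleLayout:
    # per-row active widths, heel (narrow) to toes (wide); sums to 99
    widths = [4, 5, 6, 6, 6, 6, 6, 6, 6, 6, 7, 7, 7, 7, 7, 7]
    n_rows, n_cols = len(widths), 7
    active = np.zeros((n_rows, n_cols), dtype=bool)
    for r, w in enumerate(widths):
        start = (n_cols - w) // 2
        active[r, start : start + w] = True
    grid = SensorGrid.uniform(n_rows, n_cols, pitch_x=13.0, pitch_y=15.3, active=active)
    return InsoleLayout("pedar_99", grid)


_REGISTRY: dict[str, InsoleLayout] = {}


def register_layout(layout: InsoleLayout, overwrite: bool = False) -> None:
    if layout.name in _REGISTRY and not overwrite:
        raise ValueError(f"layout {layout.name!r} already registered")
    _REGISTRY[layout.name] = layout


def known_layouts() -> dict[str, int]:
    """Mapping of registered layout names to sensor counts."""
    return {name: lay.n_sensors for name, lay in _REGISTRY.items()}


def get_layout(name: str | None = None, n_sensors: int | None = None) -> InsoleLayout:
    """Look a layout up by name, or by unique sensor count."""
    if name is not None:
        if name not in _REGISTRY:
            raise KeyError(f"unknown insole layout {name!r}; known: {sorted(_REGISTRY)}")
        return _REGISTRY[name]
    matches = [l for l in _REGISTRY.values() if l.n_sensors == n_sensors]
    if len(matches) != 1:
        raise KeyError(
            f"no unique layout with {n_sensors} sensors; known layouts: {known_layouts()}"
        )
    return matches[0]


def find_layout_for_grid(grid: SensorGrid) -> InsoleLayout | None:
    """The registered layout whose geometry equals *grid*, if any."""
    for lay in _REGISTRY.values():
        g = lay.grid
        if (
            g.shape == grid.shape
            and (g.active == grid.active).all()
            and np.array_equal(g.centers, grid.centers)
            and np.array_equal(g.areas, grid.areas)
            and np.array_equal(g.polygons, grid.polygons)
        ):
            return lay
    return None


register_layout(_build_pedar_99())
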