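"""Vendor-export readers and fixture writers.

Supported dialects (one documented, strictly parsed dialect per hardware
family — see each loader's docstring and :data:`DIALECTS`):

========  ===========  ==========================================
system    extensions   layout
========  ===========  ==========================================
emed      .lst         frame blocks, uniform platform grid
pedar     .asc         sensor columns, registered insole layout
pliance   .asc         sensor columns, rectangular mat in header
tekscan   .asf/.csv    frame blocks, calibrated pressures only
footscan  .xls (TSV)   frame blocks, spreadsheet-style tables
========  ===========  ==========================================

``write_fixture`` emits a file in any dialect that the matching loader
parses back to an equal recording, which makes every loader testable
without proprietary sample data.
"""

from __future__ import annotations

import os

from ..canonical import read_canonical
from ..core import PressureRecording, System
from ._column_dialects import load_pedar, load_pliance, write_pedar, write_pliance
from ._common import DialectError, DialectSpec
from ._grid_dialects import (
    load_emed,
    load_footscan,
    load_tekscan,
    write_emed,
    write_footscan,
    write_tekscan,
)
from .layouts import InsoleLayout, get_layout, known_layouts, register_layout

__all__ = [
    "DIALECTS",
    "DialectError",
    "DialectSpec",
    "load_emed",
    "load_pedar",
    "load_pliance",
    "load_tekscan",
    "load_footscan",
    "load_any",
    "write_fixture",
    "InsoleLayout",
    "get_layout",
    "register_layout",
    "known_layouts",
]

DIALECTS: dict[str, DialectSpec] = {
    "emed": DialectSpec(
        "emed", (".lst",), "EMED-LST SIMPLIFIED EXPORT", "frame_blocks",
        "Platform export: key/value header, space-separated frame blocks.",
    ),
    "pedar": DialectSpec(
        "pedar", (".asc",), "PEDAR-ASC SIMPLIFIED EXPORT", "sensor_columns",
        "In-shoe export: one tab-separated column per insole sensor.",
    ),
    "pliance": DialectSpec(
        "pliance", (".asc",), "PLIANCE-ASC SIMPLIFIED EXPORT", "sensor_columns",
        "Mat export: rectangular grid in header, row-major sensor columns.",
    ),
    "tekscan": DialectSpec(
        "tekscan", (".asf", ".csv"), "TEKSCAN SIMPLIFIED ASCII EXPORT", "frame_blocks",
        "Calibrated ASCII export: upper-case header, comma-separated frames.",
    ),
    "footscan": DialectSpec(
        "footscan", (".xls",), "FOOTSCAN SIMPLIFIED EXPORT", "frame_blocks",
        "Spreadsheet-style export saved as tab-separated text.",
    ),
}

_LOADERS = {
    "emed": load_emed,
    "pedar": load_pedar,
    "pliance": load_pliance,
    "tekscan": load_tekscan,
    "footscan": load_footscan,
}

_WRITERS = {
    "emed": write_emed,
    "pedar": write_pedar,
    "pliance": write_pliance,
    "tekscan": write_tekscan,
    "footscan": write_footscan,
}


def write_fixture(
    rec: PressureRecording,
    system: str | System,
    path: str | os.PathLike,
    units: str = "kPa",
) -> None:
    """Write *rec* in a vendor dialect such that ``load_<system>`` round-trips.

    Vendor dialects carry pressures and geometry only: side, events and
    masks are not representable and are omitted.  Raises
    :class:`DialectError` when the recording's grid cannot be expressed in
    the target dialect (e.g. a trimmed insole grid in the emed dialect).
    """
    if isinstance(system, System):
        system = system.value
    if system not in _WRITERS:
        raise DialectError(f"no fixture dialect for system {system!r}")
    _WRITERS[system](rec, path, units=units)


def load_any(path: str | os.PathLike, system: str = "auto") -> PressureRecording:
    """Load a canonical or vendor file, sniffing the dialect when ``auto``.

    Sniffing reads the first line: each dialect (and the canonical format)
    declares itself there.
    """
    if system != "auto":
        if system == "canonical":
            return read_canonical(path)
        if system not in _LOADERS:
            raise DialectError(f"unknown system {system!r}")
        return _LOADERS[system](path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("PEDOBAR-CANONICAL"):
        return read_canonical(path)
    for name, spec in DIALECTS.items():
        if first == spec.magic:
            return _LOADERS[name](path)
    raise DialectError(f"unrecognized file format (first line {first!r})")
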