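"""Shared helpers for the vendor dialect parsers."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DialectError", "DialectSpec", "parse_number", "unit_factor", "fmt"]


class DialectError(ValueError):
    """A file does not conform to the documented dialect."""


@dataclass(frozen=True)
class DialectSpec:
    """Documentation record of one supported export dialect."""

    system: str
    extensions: tuple[str, ...]
    magic: str  # exact first line of the file
    layout: str  # "frame_blocks" or "sensor_columns"
    description: str


def parse_number(token: str) -> float:
    """Parse a decimal number, accepting a decimal comma when unambiguous.

    Tokens never contain thousands separators in the supported dialects, so
    a comma with no dot can only be a decimal comma (common in European
    exports).
    """
    try:
        return float(token)
    except ValueError:
        if "," in token and "." not in token:
            return float(token.replace(",", "."))
        raise DialectError(f"cannot parse number {token!r}") from None


def unit_factor(unit: str) -> float:
    """Multiplier converting declared pressure units to kPa."""
    norm = unit.strip().lower().replace("²", "2")
    if norm == "kpa":
        return 1.0
    if norm in ("n/cm2", "ncm2"):
        return 10.0  # 1 N/cm² = 10 kPa
    raise DialectError(f"unsupported pressure unit {unit!r} (expected kPa or N/cm2)")


def fmt(x: float) -> str:
    """Shortest decimal text that round-trips the float exactly."""
    return repr(float(x))
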