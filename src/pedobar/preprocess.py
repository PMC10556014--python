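"""Whole-recording curves, step detection, temporal interpolation, foot-side
detection, and center of pressure."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d

from ._geometry import FootprintError, align_footprint
from .core import EventList, PressureFrameSeries, PressureRecording, Side

__all__ = [
    "WholeCurve",
    "COPTrajectory",
    "whole_pressure_curve",
    "pressure_interp",
    "select_steps",
    "auto_detect_side",
    "cop",
    "crop_to_event",
]

CURVE_VARIABLES = ("force", "peak_pressure", "contact_area")
CURVE_UNITS = {"force": "N", "peak_pressure": "kPa", "contact_area": "cm2"}


@dataclass
class WholeCurve:
    """A per-frame whole-foot summary curve."""

    variable: str
    values: np.ndarray
    sampling_rate: float

    @property
    def units(self) -> str:
        return CURVE_UNITS[self.variable]

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sampling_rate


@dataclass
class COPTrajectory:
    """Per-frame center of pressure; ``points`` are NaN where invalid."""

    points: np.ndarray  # (T, 2) mm
    valid: np.ndarray  # (T,) bool


def whole_pressure_curve(
    rec: PressureRecording, variable: str = "force", area_threshold: float = 5.0
) -> WholeCurve:
    """Whole-foot curve over time.

    ``force``:  0.1 · Σ_cells p·a  (N, with p in kPa and a in cm²);
    ``peak_pressure``:  max over cells (kPa);
    ``contact_area``:  Σ a over cells with p > *area_threshold* kPa (cm²).
    """
    if variable not in CURVE_VARIABLES:
        raise ValueError(f"unknown variable {variable!r}; choose from {CURVE_VARIABLES}")
    p = rec.frames.values
    a = rec.grid.areas * rec.grid.active
    if variable == "force":
        vals = 0.1 * (p * a).sum(axis=(1, 2))
    elif variable == "peak_pressure":
        vals = (p * rec.grid.active).max(axis=(1, 2))
    else:
        vals = ((p > area_threshold) * a).sum(axis=(1, 2))
    return WholeCurve(variable, vals, rec.sampling_rate)


def pressure_interp(rec: PressureRecording, interp_to: int = 101) -> PressureRecording:
    """Linearly resample the frame series to exactly *interp_to* frames.

    Each sensor's time series is interpolated on a uniform parameter in
    [0, 1] (percent-of-stance convention), so the first and last frames are
    preserved exactly.  The sampling rate is rescaled to keep the trial
    duration; event frame indices are rescaled to the new frame grid.
    """
    T = rec.n_frames
    if T < 2:
        raise ValueError("need at least 2 frames to interpolate")
    if interp_to < 2:
        raise ValueError("interp_to must be >= 2")
    s_old = np.linspace(0.0, 1.0, T)
    s_new = np.linspace(0.0, 1.0, interp_to)
    vals = interp1d(s_old, rec.frames.values, axis=0, assume_sorted=True)(s_new)
    np.clip(vals, 0.0, None, out=vals)  # guard float residue between >= 0 knots
    vals[0] = rec.frames.values[0]
    vals[-1] = rec.frames.values[-1]
    scale = (interp_to - 1) / (T - 1)
    events = EventList(
        [(int(round(a * scale)), int(round(b * scale))) for a, b in rec.events]
    )
    out = rec.copy()
    out.frames = PressureFrameSeries(vals, rec.sampling_rate * scale)
    out.events = events
    return out


def select_steps(
    rec: PressureRecording,
    force_threshold: float = 10.0,
    min_duration: float = 0.15,
    discard_first: int = 0,
    keep: list[int] | None = None,
) -> EventList:
    """Detect steps as maximal runs of frames with force ≥ *force_threshold*.

    Runs shorter than *min_duration* seconds are dropped, then the first
    *discard_first* remaining runs (in-shoe trials often start with partial
    or settling steps).  ``keep`` — indices into the remaining runs —
    replaces the interactive keep/discard prompt of a GUI workflow.  The
    result is stored on ``rec.events`` and returned.
    """
    if force_threshold <= 0:
        raise ValueError("force_threshold must be > 0")
    force = whole_pressure_curve(rec, "force").values
    if force.max() < force_threshold:
        warnings.warn(
            f"force never reaches threshold {force_threshold} N; no steps found",
            stacklevel=2,
        )
        rec.events = EventList([])
        return rec.events
    above = force >= force_threshold
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.astype(int), [0]))))
    runs = [(int(a), int(b) - 1) for a, b in zip(edges[::2], edges[1::2])]
    min_frames = min_duration * rec.sampling_rate
    runs = [(a, b) for a, b in runs if (b - a + 1) >= min_frames]
    runs = runs[discard_first:]
    if keep is not None:
        runs = [runs[i] for i in keep]
    rec.events = EventList(runs)
    return rec.events


def crop_to_event(rec: PressureRecording, event_index: int = 0) -> PressureRecording:
    """A copy of the recording restricted to one detected step (inclusive)."""
    if not len(rec.events):
        raise ValueError("recording has no events; run select_steps first")
    a, b = rec.events[event_index]
    out = rec.copy()
    out.frames = PressureFrameSeries(
        rec.frames.values[a : b + 1].copy(), rec.sampling_rate
    )
    out.events = EventList([(0, b - a)])
    return out


def auto_detect_side(
    rec: PressureRecording,
    threshold: float = 5.0,
    margin_fraction: float = 0.05,
) -> Side:
    """Classify a barefoot footprint as left or right.

    The footprint is aligned to its principal axis and oriented toe-ward by
    the direction of COP travel.  The pressure-weighted centroid of the
    anterior third is then offset toward the medial side (hallux and MTH1
    carry most of the forefoot load); the sign of that offset separates the
    two feet.  When the offset is smaller than *margin_fraction* × footprint
    width the result is :attr:`Side.UNKNOWN` — never a silent guess.  A
    definite answer is also stored on ``rec.side``.
    """
    try:
        axes = align_footprint(rec, threshold)
    except FootprintError:
        return Side.UNKNOWN
    maxp = rec.frames.values.max(axis=0)
    w = maxp[axes.cells[:, 0], axes.cells[:, 1]]
    anterior = axes.long_coord >= (2.0 / 3.0) * axes.length
    if not anterior.any() or w[anterior].sum() <= 0:
        return Side.UNKNOWN
    offset = float(np.average(axes.med_coord[anterior], weights=w[anterior]))
    if abs(offset) < margin_fraction * axes.width:
        return Side.UNKNOWN
    side = Side.RIGHT if offset > 0 else Side.LEFT
    rec.side = side
    return side


def cop(rec: PressureRecording, force_threshold: float = 0.0) -> COPTrajectory:
    """Per-frame center of pressure.

    COP_t = Σ p·a·center / Σ p·a over active cells; frames whose force is
    below *force_threshold* N (or carry no load at all) are marked invalid
    and set to NaN.
    """
    a = rec.grid.areas * rec.grid.active
    w = (rec.frames.values * a).reshape(rec.n_frames, -1)
    tot = w.sum(axis=1)
    valid = (0.1 * tot >= force_threshold) & (tot > 0)
    pts = np.full((rec.n_frames, 2), np.nan)
    if valid.any():
        pts[valid] = (w[valid] @ rec.grid.centers.reshape(-1, 2)) / tot[valid, None]
    return COPTrajectory(points=pts, valid=valid)
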