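"""Regional and whole-foot pressure variables.

Exposes the classical regional metrics — spatial peak pressure, force
maximum, contact area and time, the force–time integral

    FTI = ∫ F dt        (trapezoidal, N·s)

and **two** pressure–time integrals under distinct names, because the
literature uses the same abbreviation for different quantities:

* ``pti_melai``  = FTI / A, where A is the region's peak contact area
  (N·s/cm²); and
* ``pti_peak``   = ∫ (regional spatial peak pressure) dt (kPa·s), the
  definition used by the novel software family.

Similarly ``press_peak_mean`` is explicitly the *temporal* mean of the
*spatial* peak over contact frames — "mean peak pressure" without a
qualifier is ambiguous and deliberately not provided.

Also implemented: the center-of-pressure excursion index (CPEI) and the
dynamic plantar loading index (DPLI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._geometry import align_footprint
from .core import Mask, PressureRecording, Side
from .masking import assign_sensors
from .preprocess import cop

__all__ = [
    "REGION_VARIABLES",
    "mask_analysis",
    "whole_foot_mask",
    "CPEIResult",
    "cpei",
    "dpli",
]

REGION_VARIABLES = {
    "press_peak_sensor": "kPa",
    "press_peak_mean": "kPa",
    "force_max": "N",
    "contact_area_peak": "cm2",
    "contact_time": "s",
    "fti": "N*s",
    "pti_melai": "N*s/cm2",
    "pti_peak": "kPa*s",
}


def whole_foot_mask(rec: PressureRecording, name: str = "whole_foot") -> Mask:
    """A sensor-set mask covering every active cell."""
    return Mask(
        name=name,
        cells=frozenset((int(r), int(c)) for r, c in np.argwhere(rec.grid.active)),
    )


def _region_metrics(
    rec: PressureRecording, cells: list[tuple[int, int]], activity_threshold: float
) -> dict[str, float]:
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    P = rec.frames.values[:, rows, cols]  # (T, n)
    a = rec.grid.areas[rows, cols]
    dt = 1.0 / rec.sampling_rate
    force = 0.1 * (P * a).sum(axis=1)
    spatial_peak = P.max(axis=1)
    contact = force > 0
    area_t = ((P > activity_threshold) * a).sum(axis=1)
    area_peak = float(area_t.max())
    fti = float(np.trapezoid(force, dx=dt))
    return {
        "press_peak_sensor": float(P.max()),
        "press_peak_mean": float(spatial_peak[contact].mean()) if contact.any() else 0.0,
        "force_max": float(force.max()),
        "contact_area_peak": area_peak,
        "contact_time": float(contact.sum() * dt),
        "fti": fti,
        "pti_melai": fti / area_peak if area_peak > 0 else float("nan"),
        "pti_peak": float(np.trapezoid(spatial_peak, dx=dt)),
    }


def mask_analysis(
    rec: PressureRecording,
    variable: str | list[str] = "press_peak_sensor",
    activity_threshold: float = 5.0,
) -> pd.DataFrame:
    """Compute regional variables for every mask on the recording.

    Returns a tidy table with one row per (region, metric): columns
    ``region``, ``metric``, ``value``, ``units``.  ``variable`` may be one
    metric name, a list, or ``"all"``.  Metrics run over the full frame
    range; crop the recording to an event first for per-step values.
    """
    if not rec.masks:
        raise ValueError("recording has no masks; create masks first")
    if variable == "all":
        wanted = list(REGION_VARIABLES)
    elif isinstance(variable, str):
        wanted = [variable]
    else:
        wanted = list(variable)
    for v in wanted:
        if v not in REGION_VARIABLES:
            raise ValueError(
                f"unknown variable {v!r}; choose from {sorted(REGION_VARIABLES)}"
            )
    records = []
    for name, mask in rec.masks.items():
        cells = sorted(assign_sensors(mask, rec.grid).cells)
        if not cells:
            raise ValueError(f"mask {name!r} has zero assigned cells")
        metrics = _region_metrics(rec, cells, activity_threshold)
        for v in wanted:
            records.append(
                {"region": name, "metric": v, "value": metrics[v], "units": REGION_VARIABLES[v]}
            )
    return pd.DataFrame.from_records(records, columns=["region", "metric", "value", "units"])


@dataclass
class CPEIResult:
    """Center-of-pressure excursion index and its construction geometry."""

    cpei: float  # percent; positive for lateral deviation
    cop_points: np.ndarray  # (N, 2) valid COP points, world mm
    construction_line: np.ndarray  # (2, 2) endpoints, world mm
    deviation: float  # signed mm at the anterior trisection
    forefoot_width: float  # mm
    side: Side


def cpei(
    rec: PressureRecording,
    force_threshold: float = 0.0,
    footprint_threshold: float = 5.0,
    method: str = "tangent",
) -> CPEIResult:
    """Center of pressure excursion index of a barefoot step.

    The footprint is aligned to its axis and the foot length trisected.  A
    construction line marks the medial border of the COP path: it joins the
    first COP point to the most medial COP point of the anterior third
    (``method="tangent"``, default) or to the last COP point
    (``method="chord"``).  CPEI is the perpendicular deviation of the COP
    path from that line at the anterior trisection boundary, as a
    percentage of forefoot width; lateral deviation is positive.
    """
    if method not in ("tangent", "chord"):
        raise ValueError("method must be 'tangent' or 'chord'")
    axes = align_footprint(rec, footprint_threshold)
    side = rec.side
    if side is Side.UNKNOWN:
        from .preprocess import auto_detect_side

        side = auto_detect_side(rec, footprint_threshold)
        if side is Side.UNKNOWN:
            raise ValueError("foot side undeterminable; set rec.side first")
    traj = cop(rec, force_threshold)
    pts_world = traj.points[traj.valid]
    if len(pts_world) < 3:
        raise ValueError("need >= 3 valid COP points")
    # foot coordinates: column 0 along the axis (0 at the posterior footprint
    # edge), column 1 along the m axis (medial side of a right foot)
    foot_pts = axes.to_foot(pts_world)
    med_sign = 1.0 if side is Side.RIGHT else -1.0
    med = med_sign * foot_pts[:, 1]  # medial positive

    L = axes.length
    y_b = (2.0 / 3.0) * L  # posterior boundary of the anterior trisection
    anterior = foot_pts[:, 0] >= y_b
    if method == "tangent":
        if not anterior.any():
            raise ValueError("COP path never enters the anterior third")
        i_end = int(np.argmax(np.where(anterior, med, -np.inf)))
    else:
        i_end = len(foot_pts) - 1
    A, B = foot_pts[0], foot_pts[i_end]
    chord = B - A
    norm = float(np.linalg.norm(chord))
    if norm < 1e-9:
        raise ValueError("degenerate COP path: construction line has zero length")

    Q = _cop_at_longitudinal(foot_pts, y_b)
    u = chord / norm
    perp = (Q - A) - ((Q - A) @ u) * u
    # sign: positive when Q lies lateral to the construction line
    lat_axis = np.array([0.0, -med_sign])
    deviation = float(np.linalg.norm(perp)) * float(np.sign(perp @ lat_axis) or 0.0)

    forefoot = _forefoot_width(axes)
    if forefoot <= 0:
        raise ValueError("zero forefoot width; cannot normalize CPEI")
    # map construction line endpoints back to world coordinates for plotting
    line_world = np.stack(
        [
            axes.origin + (A[0] + axes._long_offset) * axes.v + A[1] * axes.m,
            axes.origin + (B[0] + axes._long_offset) * axes.v + B[1] * axes.m,
        ]
    )
    return CPEIResult(
        cpei=100.0 * deviation / forefoot,
        cop_points=pts_world,
        construction_line=line_world,
        deviation=deviation,
        forefoot_width=forefoot,
        side=side,
    )


def _cop_at_longitudinal(foot_pts: np.ndarray, y_b: float) -> np.ndarray:
    """First crossing of the COP path through longitudinal position *y_b*,
    linearly interpolated along the path."""
    y = foot_pts[:, 0]
    exact = np.flatnonzero(np.isclose(y, y_b, atol=1e-12))
    for i in range(len(y) - 1):
        lo, hi = y[i], y[i + 1]
        if (lo - y_b) * (hi - y_b) <= 0:
            if hi == lo:
                return foot_pts[i]
            t = (y_b - lo) / (hi - lo)
            return foot_pts[i] + t * (foot_pts[i + 1] - foot_pts[i])
    if exact.size:
        return foot_pts[exact[0]]
    raise ValueError("COP path never crosses the anterior trisection boundary")


def _forefoot_width(axes) -> float:
    """Mediolateral footprint extent within the forefoot band (0.55–0.82 of
    foot length)."""
    sel = (axes.long_coord >= 0.55 * axes.length) & (axes.long_coord <= 0.82 * axes.length)
    if not sel.any():
        return 0.0
    m = axes.med_coord[sel]
    return float(m.max() - m.min())


def dpli(series: np.ndarray) -> float:
    """Dynamic plantar loading index of a peak-pressure-versus-time series.

    Fits a scaled Gaussian ``a·exp(−(t−μ)²/(2σ²))`` to the series by least
    squares (moment-based initialization: a = max, μ = argmax, σ from the
    half-width at half-maximum) and returns ``1 − R²`` of the fit, clipped
    to [0, 1]: 0 for a perfectly bell-shaped loading curve, larger for
    multimodal or skewed loading.  A constant series is the σ→∞ limit of a
    Gaussian and returns 0 by convention.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 5:
        raise ValueError("need a 1-D series of length >= 5")
    if (y < 0).any():
        raise ValueError("series must be non-negative")
    if y.max() <= 0:
        raise ValueError("series is identically zero")
    T = len(y)
    t = np.arange(T, dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 1e-12 * T * y.max() ** 2:
        return 0.0

    a0 = float(y.max())
    mu0 = float(np.argmax(y))
    half = np.flatnonzero(y >= a0 / 2.0)
    hwhm = max((half[-1] - half[0]) / 2.0, 0.5)
    sig0 = hwhm / np.sqrt(2.0 * np.log(2.0))

    def gauss(t, a, mu, sig):
        return a * np.exp(-((t - mu) ** 2) / (2.0 * sig**2))

    best = float(((y - gauss(t, a0, mu0, sig0)) ** 2).sum())
    try:
        popt, _ = curve_fit(
            gauss,
            t,
            y,
            p0=(a0, mu0, sig0),
            bounds=([1e-9, -T, 1e-3], [10.0 * a0, 2.0 * T, 10.0 * T]),
            maxfev=10000,
        )
        best = min(best, float(((y - gauss(t, *popt)) ** 2).sum()))
    except RuntimeError:
        pass  # keep the moment-initialized fit
    return float(np.clip(best / ss_tot, 0.0, 1.0))
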