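"""Synthetic gait recordings with known ground truth.

Every downstream module is tested against recordings produced here: a
parametric foot model places anatomical pressure sites (heel, midfoot,
MTH1–5, hallux, toe2, toes3–5) on a sensor grid, drives each with a smooth
stance-phase activation profile, and adds truncated sensor noise.  The
generator returns both the recording and the ground truth used to create it
(per-site cell sets, foot side, contact windows, the noise-free center of
pressure), so detection and masking algorithms can be scored exactly.

Each site is a compact quartic pressure pad

    p(d) = peak * (1 - (d / R)^2)^2   for d < R,  else 0,

which, unlike a Gaussian, has the steep pressure falloff of a real
skin-contact boundary; ``R`` is the pad radius in mm.  Temporal activation is
a raised-cosine bump rising from ``onset`` to 1 at ``peak_time`` and back to
zero at ``offset`` (all fractions of stance), giving the classic two-peak
vertical force curve when heel sites activate early and forefoot sites late.

The default foot is a right foot of length 250 mm and width 95 mm with
heel / MTH1 / hallux peaks of 400 / 450 / 350 kPa — typical adult barefoot
magnitudes used purely as fixture conventions.  Site positions follow
standard anatomical proportions (the "textbook foot" the automatic masking
scheme targets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    EventList,
    PressureFrameSeries,
    PressureRecording,
    SensorGrid,
    Side,
    System,
)

__all__ = [
    "SiteSpec",
    "FootModel",
    "GroundTruth",
    "generate_footprint",
    "generate_multistep",
    "mirror_recording",
]

#: Automask region each default site belongs to (site names == region names).
SITE_REGIONS = (
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

#: Ground-truth "core" membership: a cell belongs to a site when that site is
#: the dominant noise-free contributor and contributes at least this fraction
#: of the site's own peak.
GT_CORE_FRACTION = 0.30

#: Contact windows in ground truth are defined at this force threshold (N),
#: matching the step-detection default: contact below it is unmeasurable.
GT_CONTACT_FORCE_N = 10.0


@dataclass(frozen=True)
class SiteSpec:
    """One anatomical pressure site.

    ``x_frac`` runs medial (0) to lateral (1) across the foot width;
    ``y_frac`` runs heel (0) to toes (1) along the foot length.  ``radius_mm``
    is the pad radius R, ``peak_kpa`` the pressure at the pad center at full
    activation, and ``onset < peak_time < offset`` are stance fractions.
    """

    x_frac: float
    y_frac: float
    radius_mm: float
    peak_kpa: float
    onset: float
    peak_time: float
    offset: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_frac <= 1.0 and 0.0 <= self.y_frac <= 1.0):
            raise ValueError("site center fractions must lie in [0, 1]")
        if self.peak_kpa <= 0 or self.radius_mm <= 0:
            raise ValueError("site peak and radius must be positive")
        if not self.onset < self.peak_time < self.offset:
            raise ValueError("need onset < peak_time < offset")


def _default_sites() -> dict[str, SiteSpec]:
    s = SiteSpec
    return {
        "heel": s(0.500, 0.120, 25.0, 400.0, 0.00, 0.18, 0.58),
        "midfoot": s(0.600, 0.400, 13.0, 90.0, 0.12, 0.38, 0.72),
        "MTH1": s(0.147, 0.640, 12.0, 450.0, 0.35, 0.78, 0.99),
        "MTH2": s(0.428, 0.644, 10.0, 320.0, 0.32, 0.74, 0.98),
        "MTH3": s(0.615, 0.648, 10.0, 300.0, 0.32, 0.74, 0.98),
        "MTH4": s(0.790, 0.644, 9.0, 250.0, 0.32, 0.72, 0.97),
        "MTH5": s(0.938, 0.636, 9.0, 220.0, 0.30, 0.70, 0.96),
        "hallux": s(0.126, 0.860, 10.0, 350.0, 0.45, 0.83, 1.00),
        "toe2": s(0.382, 0.852, 6.5, 150.0, 0.50, 0.80, 0.98),
        "toes3_5": s(0.726, 0.840, 9.0, 120.0, 0.50, 0.78, 0.98),
    }


@dataclass
class FootModel:
    """Parametric foot used by the generators."""

    foot_length_mm: float = 250.0
    foot_width_mm: float = 95.0
    side: Side = Side.RIGHT
    sites: dict[str, SiteSpec] = field(default_factory=_default_sites)
    noise_sd_kpa: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.side = Side(self.side)
        if self.side is Side.UNKNOWN:
            raise ValueError("foot model needs a definite side")
        if self.foot_length_mm <= 0 or self.foot_width_mm <= 0:
            raise ValueError("foot dimensions must be positive")
        if self.noise_sd_kpa < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows that the algorithms must recover."""

    side: Side
    site_cells: dict[str, frozenset[tuple[int, int]]]
    events: EventList
    cop_noise_free: np.ndarray  # (T, 2) mm, NaN where unloaded
    noise_free: np.ndarray  # (T, R, C) kPa before noise
    region_of_site: dict[str, str]


def _temporal_weight(s: np.ndarray, site: SiteSpec) -> np.ndarray:
    """Raised-cosine activation at stance fractions *s* (vectorized)."""
    w = np.zeros_like(s)
    rising = (s >= site.onset) & (s <= site.peak_time)
    falling = (s > site.peak_time) & (s <= site.offset)
    u = (s[rising] - site.onset) / (site.peak_time - site.onset)
    w[rising] = 0.5 - 0.5 * np.cos(np.pi * u)
    u = (s[falling] - site.peak_time) / (site.offset - site.peak_time)
    w[falling] = 0.5 + 0.5 * np.cos(np.pi * u)
    return w


def _site_fields(
    model: FootModel,
    grid: SensorGrid,
    foot_origin: np.ndarray,
    v: np.ndarray,
) -> dict[str, np.ndarray]:
    """Static (R, C) pressure field of each site at full activation.

    ``foot_origin`` is the world position of the heel end of the foot axis;
    ``v`` the unit vector pointing toe-ward.  The lateral unit vector is
    ``rot90_cw(v)`` for a right foot and ``rot90_ccw(v)`` for a left one, so
    that the medial border (``x_frac = 0``) falls on the anatomically correct
    side for either foot.
    """
    u_lat = np.array([v[1], -v[0]]) if model.side is Side.RIGHT else np.array([-v[1], v[0]])
    fields = {}
    for name, site in model.sites.items():
        center = (
            foot_origin
            + site.y_frac * model.foot_length_mm * v
            + (site.x_frac - 0.5) * model.foot_width_mm * u_lat
        )
        d2 = ((grid.centers - center) ** 2).sum(axis=-1)
        g = np.clip(1.0 - d2 / site.radius_mm**2, 0.0, None) ** 2
        fields[name] = site.peak_kpa * g * grid.active
    return fields


def _check_resolution(model: FootModel, pitch: float) -> None:
    """Reject grids whose pitch exceeds a site's pad diameter — such a pad
    could fall entirely between sensor centers and vanish."""
    worst = min(s.radius_mm for s in model.sites.values())
    if 2.0 * worst < pitch:
        raise ValueError(
            f"grid too coarse to resolve sites: smallest pad diameter "
            f"{2 * worst:.1f} mm is below the {pitch:.1f} mm sensor pitch"
        )


def _ground_truth_cells(
    fields: dict[str, np.ndarray], model: FootModel
) -> dict[str, frozenset[tuple[int, int]]]:
    names = list(fields)
    stack = np.stack([fields[n] for n in names])  # (S, R, C)
    dominant = stack.argmax(axis=0)
    out = {}
    for i, name in enumerate(names):
        level = GT_CORE_FRACTION * model.sites[name].peak_kpa
        sel = (dominant == i) & (stack[i] >= level)
        out[name] = frozenset((int(r), int(c)) for r, c in np.argwhere(sel))
    return out


def _cop_noise_free(values: np.ndarray, grid: SensorGrid) -> np.ndarray:
    w = (values * grid.areas).reshape(values.shape[0], -1)
    tot = w.sum(axis=1)
    pts = np.full((values.shape[0], 2), np.nan)
    ok = tot > 0
    if ok.any():
        pts[ok] = (w[ok] @ grid.centers.reshape(-1, 2)) / tot[ok, None]
    return pts


def _events_from_force(values: np.ndarray, grid: SensorGrid) -> EventList:
    force = 0.1 * (values * grid.areas).sum(axis=(1, 2))
    above = force >= GT_CONTACT_FORCE_N
    idx = np.flatnonzero(np.diff(np.concatenate(([0], above.astype(int), [0]))))
    return EventList([(int(a), int(b) - 1) for a, b in zip(idx[::2], idx[1::2])])


def _add_noise(
    noise_free: np.ndarray, sd: float, rng: np.random.Generator, floor: float
) -> np.ndarray:
    """Additive truncated-at-zero Gaussian noise plus a hardware-style
    noise floor: readings below *floor* kPa are zeroed, as pressure systems
    do to suppress unloaded-sensor chatter."""
    if sd:
        values = noise_free + rng.normal(0.0, sd, noise_free.shape)
    else:
        values = noise_free.copy()
    np.clip(values, 0.0, None, out=values)
    values[values < floor] = 0.0
    return values


def generate_footprint(
    model: FootModel | None = None,
    grid_shape: tuple[int, int] = (56, 36),
    pitch_mm: float = 5.0,
    sampling_rate: float = 100.0,
    stance_duration: float = 0.6,
    rotation_deg: float = 0.0,
    noise_floor_kpa: float = 4.0,
    seed: int | None = None,
) -> tuple[PressureRecording, GroundTruth]:
    """Simulate one barefoot step on a pressure platform.

    Returns the (noisy) recording and its :class:`GroundTruth`.  The foot is
    centered on the grid, axis rotated by *rotation_deg* from the +y (row)
    direction.  ``seed`` overrides ``model.seed``.
    """
    model = model or FootModel()
    _check_resolution(model, pitch_mm)
    n_rows, n_cols = grid_shape
    grid = SensorGrid.uniform(n_rows, n_cols, pitch_mm, pitch_mm)
    theta = math.radians(rotation_deg)
    v = np.array([math.sin(theta), math.cos(theta)])
    grid_center = np.array(
        [(n_cols - 1) * pitch_mm / 2.0, (n_rows - 1) * pitch_mm / 2.0]
    )
    foot_origin = grid_center - 0.5 * model.foot_length_mm * v

    fields = _site_fields(model, grid, foot_origin, v)
    T = int(round(sampling_rate * stance_duration)) + 1
    s = np.linspace(0.0, 1.0, T)
    noise_free = np.zeros((T, n_rows, n_cols))
    for name, f in fields.items():
        noise_free += _temporal_weight(s, model.sites[name])[:, None, None] * f

    rng = np.random.default_rng(model.seed if seed is None else seed)
    values = _add_noise(noise_free, model.noise_sd_kpa, rng, noise_floor_kpa)

    rec = PressureRecording(
        frames=PressureFrameSeries(values, sampling_rate),
        grid=grid,
        system=System.SYNTHETIC,
        side=Side.UNKNOWN,
    )
    gt = GroundTruth(
        side=model.side,
        site_cells=_ground_truth_cells(fields, model),
        events=_events_from_force(noise_free, grid),
        cop_noise_free=_cop_noise_free(noise_free, grid),
        noise_free=noise_free,
        region_of_site={n: n for n in fields},
    )
    return rec, gt


def generate_multistep(
    model: FootModel | None = None,
    n_steps: int = 3,
    cadence_hz: float = 0.9,
    swing_fraction: float = 0.38,
    sampling_rate: float = 50.0,
    grid: SensorGrid | None = None,
    noise_sd_kpa: float = 0.5,
    noise_floor_kpa: float = 2.0,
    lead_s: float = 0.25,
    seed: int | None = None,
) -> tuple[PressureRecording, GroundTruth]:
    """Simulate an in-shoe trial of *n_steps* stance/swing cycles.

    ``cadence_hz`` is cycles per second for this foot; each cycle is split
    into stance (``1 - swing_fraction``) and a zero-pressure swing.  Without
    an explicit *grid* the bundled pedar 99-sensor insole layout is used.
    In-shoe noise defaults lower than the platform default (insoles are
    low-range capacitive arrays with a suppressed noise floor).
    """
    model = model or FootModel()
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0.0 < swing_fraction < 1.0:
        raise ValueError("swing_fraction must lie strictly between 0 and 1")
    if grid is None:
        from .io.layouts import get_layout

        grid = get_layout("pedar_99").grid
    px, py = grid.pitch()
    _check_resolution(model, min(px, py))

    cycle = 1.0 / cadence_hz
    stance = cycle * (1.0 - swing_fraction)
    total = lead_s + (n_steps - 1) * cycle + stance + lead_s
    T = int(round(sampling_rate * total)) + 1
    t = np.arange(T) / sampling_rate

    # insole: foot axis is the grid +y axis, centered on the active cells
    act_pts = grid.centers[grid.active]
    center = 0.5 * (act_pts.min(axis=0) + act_pts.max(axis=0))
    v = np.array([0.0, 1.0])
    foot_origin = center - 0.5 * model.foot_length_mm * v
    fields = _site_fields(model, grid, foot_origin, v)

    noise_free = np.zeros((T, grid.n_rows, grid.n_cols))
    for k in range(n_steps):
        t0 = lead_s + k * cycle
        s = (t - t0) / stance
        inside = (s >= 0.0) & (s <= 1.0)
        if not inside.any():
            continue
        for name, f in fields.items():
            w = _temporal_weight(s[inside], model.sites[name])
            noise_free[inside] += w[:, None, None] * f

    rng = np.random.default_rng(model.seed if seed is None else seed)
    values = _add_noise(noise_free, noise_sd_kpa, rng, noise_floor_kpa)
    values *= grid.active  # trimmed insole cells stay empty

    rec = PressureRecording(
        frames=PressureFrameSeries(values, sampling_rate),
        grid=grid,
        system=System.SYNTHETIC,
        side=Side.UNKNOWN,
    )
    gt = GroundTruth(
        side=model.side,
        site_cells=_ground_truth_cells(fields, model),
        events=_events_from_force(noise_free, grid),
        cop_noise_free=_cop_noise_free(noise_free, grid),
        noise_free=noise_free,
        region_of_site={n: n for n in fields},
    )
    return rec, gt


def mirror_recording(rec: PressureRecording) -> PressureRecording:
    """Mirror a recording about its vertical (y) axis.

    Pressure columns are reversed and the geometry reflected so that a right
    foot becomes an anatomically consistent left foot.  Masks and events are
    dropped (they refer to the unmirrored geometry); the side label flips.
    """
    g = rec.grid
    x_max = g.centers[..., 0].max() + g.centers[..., 0].min()
    centers = g.centers[:, ::-1].copy()
    centers[..., 0] = x_max - centers[..., 0]
    polygons = g.polygons[:, ::-1].copy()
    polygons[..., 0] = x_max - polygons[..., 0]
    polygons = polygons[:, :, ::-1]  # restore counter-clockwise order
    grid = SensorGrid(
        centers=centers,
        polygons=polygons,
        areas=g.areas[:, ::-1].copy(),
        active=g.active[:, ::-1].copy(),
    )
    return PressureRecording(
        frames=PressureFrameSeries(
            rec.frames.values[:, :, ::-1].copy(), rec.frames.sampling_rate
        ),
        grid=grid,
        system=rec.system,
        side=rec.side.opposite,
    )
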