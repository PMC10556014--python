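"""Internal footprint-geometry helpers shared by preprocessing, masking and
metrics: footprint detection, principal-axis alignment and toe-ward
orientation.

The aligned foot frame is defined by a unit vector ``v`` pointing from heel
to toes (longitudinal axis) and ``m = rot90_ccw(v)``.  With the foot pointing
in +y, ``m`` points in −x, which for a right foot (subject walking toward +y,
plate seen from above) is the medial side; the signed coordinate along ``m``
therefore separates left from right feet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import PressureRecording

FOOTPRINT_THRESHOLD_KPA = 5.0


class FootprintError(ValueError):
    """No usable footprint or orientation could be derived."""


def footprint_cells(
    rec: PressureRecording,
    threshold: float = FOOTPRINT_THRESHOLD_KPA,
    min_component_cells: int = 3,
) -> np.ndarray:
    """Boolean (n_rows, n_cols) map of the footprint.

    A cell belongs to the footprint when it is active and its max-over-time
    pressure exceeds *threshold* kPa.  8-connected components smaller than
    *min_component_cells* are discarded as sensor-noise specks; larger
    separate islands are kept — toes routinely print as islands detached
    from the forefoot pad.
    """
    maxp = rec.frames.values.max(axis=0)
    above = rec.grid.active & (maxp > threshold)
    if not above.any():
        return above
    labels, n = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_component_cells) + 1
        if small.size:
            above &= ~np.isin(labels, small)
    return above


@dataclass
class FootAxes:
    """Principal-axis alignment of a footprint."""

    origin: np.ndarray  # centroid of footprint cell centers, mm
    v: np.ndarray  # unit vector, heel -> toes
    m: np.ndarray  # unit vector, rot90_ccw(v); medial side for a right foot
    cells: np.ndarray  # (N, 2) int array of footprint (row, col)
    long_coord: np.ndarray  # (N,) coordinate along v, shifted so min == 0
    med_coord: np.ndarray  # (N,) coordinate along m (not shifted)
    length: float  # footprint extent along v, mm
    width: float  # footprint extent along m, mm

    def to_foot(self, points: np.ndarray) -> np.ndarray:
        """Map world (x, y) points to (long, med) foot coordinates."""
        p = np.atleast_2d(points) - self.origin
        out = np.stack([p @ self.v - self._long_offset, p @ self.m], axis=-1)
        return out.reshape(np.shape(points))

    _long_offset: float = 0.0


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the covariance of (N, 2) points (sign-free)."""
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    return vecs[:, -1]  # eigh sorts ascending


def align_footprint(
    rec: PressureRecording,
    threshold: float = FOOTPRINT_THRESHOLD_KPA,
    min_travel_mm: float = 0.5,
) -> FootAxes:
    """Align the footprint to its principal axis, oriented toe-ward.

    The toe-ward sign of the axis comes from the direction of travel of the
    center of pressure between the first and last loaded frames: during
    stance the COP moves from heel strike to toe-off.

    Raises
    ------
    FootprintError
        If no footprint exceeds *threshold* or the COP travel along the axis
        is below *min_travel_mm* (orientation would be a guess).
    """
    fp = footprint_cells(rec, threshold)
    if not fp.any():
        raise FootprintError(f"no footprint detected above {threshold} kPa")
    cells = np.argwhere(fp)
    pts = rec.grid.centers[fp]  # (N, 2)
    origin = pts.mean(axis=0)
    v = principal_axis(pts)

    # toe-ward orientation from COP travel between the first and last
    # substantially loaded frames (>= 10% of the force maximum, so the
    # endpoints are not dominated by sensor noise at contact/lift-off)
    p = rec.frames.values * rec.grid.areas  # (T, R, C) weights
    w = p.reshape(rec.n_frames, -1)
    tot = w.sum(axis=1)
    loaded = np.flatnonzero(tot >= 0.1 * tot.max())
    if loaded.size < 2:
        raise FootprintError("cannot orient footprint: fewer than 2 loaded frames")
    flat_centers = rec.grid.centers.reshape(-1, 2)
    cop_first = w[loaded[0]] @ flat_centers / tot[loaded[0]]
    cop_last = w[loaded[-1]] @ flat_centers / tot[loaded[-1]]
    travel = float((cop_last - cop_first) @ v)
    if abs(travel) < min_travel_mm:
        raise FootprintError(
            f"cannot orient footprint: COP travel along axis {travel:.3g} mm "
            f"is below {min_travel_mm} mm"
        )
    if travel < 0:
        v = -v
    m = np.array([-v[1], v[0]])  # rot90 counter-clockwise

    rel = pts - origin
    long_c = rel @ v
    med_c = rel @ m
    lo = float(long_c.min())
    axes = FootAxes(
        origin=origin,
        v=v,
        m=m,
        cells=cells,
        long_coord=long_c - lo,
        med_coord=med_c,
        length=float(long_c.max() - lo),
        width=float(med_c.max() - med_c.min()),
    )
    axes._long_offset = lo
    return axes
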