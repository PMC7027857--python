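"""Vector geometry for root centerlines and cylindrical macropores.

Coordinate convention: right-handed, ``z`` is depth in mm measured downward
from the soil surface (so "deeper" means larger ``z``); ``x`` and ``y`` are
centered on the column axis.  All distances are millimetres.

Roots are ordered 3D polylines (proximal -> distal, i.e. in the direction of
growth); artificial macropores are finite cylinders, vertical in the default
column design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RootPolyline",
    "Cylinder",
    "InsufficientArcError",
    "arc_length",
    "cumulative_arc_length",
    "resample_polyline",
    "point_at_arc",
    "direction_at",
    "angle_between",
    "point_cylinder_surface_distance",
    "min_surface_distance",
]


class InsufficientArcError(ValueError):
    """Raised when a direction fit is requested on too short an arc window."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) point array, got shape {pts.shape}")
    return pts


@dataclass
class RootPolyline:
    """Ordered 3D root centerline.

    Parameters
    ----------
    root_id : str
        Identifier of the root axis.
    points : (n, 3) array
        Ordered centerline points in mm, columns ``x, y, z`` (z = depth),
        proximal first.  At least two points; consecutive points distinct.
    radius_mm : float
        Representative root radius in mm (wheat seminal axes are a few
        tenths of a millimetre).
    """

    root_id: str
    points: np.ndarray
    radius_mm: float = 0.25

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if len(self.points) < 2:
            raise ValueError("polyline needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("polyline contains non-finite coordinates")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValueError("consecutive polyline points must be distinct")
        if not self.radius_mm > 0:
            raise ValueError("radius_mm must be positive")

    @property
    def arc(self) -> np.ndarray:
        """Cumulative arc length at each vertex (mm), starting at 0."""
        return cumulative_arc_length(self.points)

    @property
    def length_mm(self) -> float:
        return float(self.arc[-1])


@dataclass
class Cylinder:
    """Finite cylinder (an artificial macropore).

    ``top`` and ``bottom`` are 3-vectors in mm with ``top[2] < bottom[2]``
    (the top is shallower).  Default-column pores are vertical.
    """

    pore_id: str
    top: np.ndarray
    bottom: np.ndarray
    radius_mm: float

    def __post_init__(self) -> None:
        self.top = np.asarray(self.top, dtype=float)
        self.bottom = np.asarray(self.bottom, dtype=float)
        if self.top.shape != (3,) or self.bottom.shape != (3,):
            raise ValueError("top/bottom must be 3-vectors")
        if not self.top[2] < self.bottom[2]:
            raise ValueError("cylinder top must be shallower than bottom")
        if not self.radius_mm > 0:
            raise ValueError("radius_mm must be positive")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(self.bottom - self.top))

    @property
    def is_vertical(self) -> bool:
        return bool(np.allclose(self.top[:2], self.bottom[:2]))


def cumulative_arc_length(points) -> np.ndarray:
    pts = _as_points(points)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def arc_length(poly: RootPolyline) -> float:
    """Total arc length of a polyline in mm."""
    return float(cumulative_arc_length(poly.points)[-1])


def resample_polyline(points, step_mm: float) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arc-length spacing.

    Returns points at arc positions ``0, h, 2h, ..., L`` where ``h`` is
    chosen <= step_mm so the endpoints are always included.
    """
    pts = _as_points(points)
    arc = cumulative_arc_length(pts)
    total = arc[-1]
    if total == 0:
        return pts[:1].copy()
    n = max(int(np.ceil(total / step_mm)), 1)
    s = np.linspace(0.0, total, n + 1)
    return _interp_along(pts, arc, s)


def _interp_along(pts: np.ndarray, arc: np.ndarray, s: np.ndarray) -> np.ndarray:
    out = np.empty((len(s), 3))
    for k in range(3):
        out[:, k] = np.interp(s, arc, pts[:, k])
    return out


def point_at_arc(poly: RootPolyline, s_mm: float) -> np.ndarray:
    """Point on the centerline at arc position ``s_mm`` (clamped to ends)."""
    arc = poly.arc
    s = float(np.clip(s_mm, 0.0, arc[-1]))
    return _interp_along(poly.points, arc, np.array([s]))[0]


def direction_at(
    poly: RootPolyline,
    s_mm: float,
    window_mm: float = 20.0,
    side: str = "pre",
    step_mm: float = 0.5,
    min_window_mm: float = 5.0,
) -> np.ndarray:
    """Growth direction at arc position ``s_mm``, as a unit 3-vector.

    The direction is the principal axis of a total-least-squares 3D line fit
    to the centerline resampled at ``step_mm`` within the arc window
    ``[s - window, s]`` (side="pre") or ``[s, s + window]`` (side="post"),
    oriented in the direction of growth (increasing arc length).  Windows
    are clipped to the polyline; if less than ``min_window_mm`` of arc is
    available on the requested side an :class:`InsufficientArcError` is
    raised (callers map this to "indeterminate").
    """
    if side not in ("pre", "post"):
        raise ValueError("side must be 'pre' or 'post'")
    arc = poly.arc
    total = arc[-1]
    s = float(np.clip(s_mm, 0.0, total))
    if side == "pre":
        lo, hi = max(0.0, s - window_mm), s
    else:
        lo, hi = s, min(total, s + window_mm)
    if hi - lo < min_window_mm:
        raise InsufficientArcError(
            f"only {hi - lo:.2f} mm of arc available on the {side} side "
            f"(need >= {min_window_mm} mm)"
        )
    n = max(int(np.ceil((hi - lo) / step_mm)), 2)
    svals = np.linspace(lo, hi, n + 1)
    pts = _interp_along(poly.points, arc, svals)
    centered = pts - pts.mean(axis=0)
    # principal axis via SVD = total least squares line fit
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    if np.dot(d, pts[-1] - pts[0]) < 0:
        d = -d
    return d / np.linalg.norm(d)


def angle_between(u, v) -> float:
    """Angle between two 3-vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("angle with a zero vector is undefined")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def point_cylinder_surface_distance(points, cyl: Cylinder) -> np.ndarray:
    """Distance from each point to the surface of a solid finite cylinder.

    Zero for points inside the cylinder.  Handles the lateral surface, the
    end caps and the rim (edge) region.
    """
    pts = _as_points(points)
    a = cyl.top
    u = cyl.bottom - cyl.top
    L = np.linalg.norm(u)
    u = u / L
    rel = pts - a
    t = rel @ u
    radial = rel - np.outer(t, u)
    r = np.linalg.norm(radial, axis=1)
    R = cyl.radius_mm
    dz = np.maximum(np.maximum(-t, t - L), 0.0)  # axial overshoot past caps
    dr = np.maximum(r - R, 0.0)
    d = np.hypot(dz, dr)
    return d


def min_surface_distance(
    poly: RootPolyline,
    cyl: Cylinder,
    coarse_step_mm: float = 0.1,
    fine_step_mm: float = 0.005,
) -> float:
    """Minimum surface-to-surface distance between a root and a pore, mm.

    Surface-to-surface: (centerline-to-cylinder-surface distance) minus the
    root radius, floored at 0 when the tubes touch or overlap.  Evaluated by
    coarse arc-length sampling followed by local refinement; the distance
    field is 1-Lipschitz along the arc so the result is accurate to well
    under ``fine_step_mm``.
    """
    arc = cumulative_arc_length(poly.points)
    n = max(int(np.ceil(arc[-1] / coarse_step_mm)), 1)
    s_coarse = np.linspace(0.0, arc[-1], n + 1)
    pts = _interp_along(poly.points, arc, s_coarse)
    d = point_cylinder_surface_distance(pts, cyl) - poly.radius_mm
    dmin = d.min()
    if dmin <= 0.0:
        return 0.0
    # refine every coarse sample whose value could hide the true minimum
    cand = np.where(d <= dmin + coarse_step_mm)[0]
    best = dmin
    for i in cand:
        lo = max(0.0, s_coarse[i] - coarse_step_mm)
        hi = min(arc[-1], s_coarse[i] + coarse_step_mm)
        n = max(int(np.ceil((hi - lo) / fine_step_mm)), 1)
        s = np.linspace(lo, hi, n + 1)
        fine = _interp_along(poly.points, arc, s)
        df = point_cylinder_surface_distance(fine, cyl) - poly.radius_mm
        best = min(best, df.min())
    return float(max(best, 0.0))
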