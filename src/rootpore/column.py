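"""Parametric mesocosm construction and voxelization.

The experimental unit is a repacked two-layer soil column: a 64 mm internal
diameter, 170 mm tall outer column whose bottom 55 mm is subsoil packed at
1.2 (loose) or 1.6 (compacted) g cm^-3, overlain by topsoil at 1.1 g cm^-3.
Nine vertical artificial macropores (0.8 mm diameter, 45 mm long) are formed
in the subsoil from the column base upward, leaving a 10 mm undisturbed soil
cap between the pore tops and the topsoil boundary.  A 20 mm inner guide
column funnels roots toward the pore field; seeds are planted 20 mm deep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import Cylinder, RootPolyline, resample_polyline

__all__ = [
    "ColumnSpec",
    "VoxelVolume",
    "LABELS",
    "build_pores",
    "voxelize",
    "synthesize_grayscale",
    "default_intensities",
]

#: Integer labels used in synthetic label volumes.
LABELS = {
    "background": 0,
    "topsoil": 1,
    "subsoil": 2,
    "pore": 3,
    "root": 4,
    "inner_wall": 5,
}

MAX_VOXELS = 2_000_000_000


@dataclass
class ColumnSpec:
    """Full parametric description of the soil column mesocosm (mm, g cm^-3)."""

    outer_diameter_mm: float = 64.0
    outer_height_mm: float = 170.0
    subsoil_height_mm: float = 55.0
    subsoil_bulk_density_g_cm3: float = 1.6
    topsoil_bulk_density_g_cm3: float = 1.1
    inner_diameter_mm: float = 20.0
    inner_length_mm: float = 120.0
    pore_count: int = 9
    pore_diameter_mm: float = 0.8
    pore_length_mm: float = 45.0
    pore_top_gap_mm: float = 10.0
    planting_depth_mm: float = 20.0

    def __post_init__(self) -> None:
        vals = asdict(self)
        for k, v in vals.items():
            if not v > 0:
                raise ValueError(f"{k} must be positive, got {v}")
        if self.pore_length_mm + self.pore_top_gap_mm > self.subsoil_height_mm:
            raise ValueError(
                "pore length + soil cap must fit inside the subsoil layer"
            )
        if self.inner_diameter_mm >= self.outer_diameter_mm:
            raise ValueError("inner column must be narrower than outer column")

    @property
    def subsoil_top_depth_mm(self) -> float:
        """Depth of the topsoil/subsoil boundary (115 mm by default)."""
        return self.outer_height_mm - self.subsoil_height_mm

    @property
    def pore_top_depth_mm(self) -> float:
        """Depth of the pore tops (125 mm by default: base-inserted rods)."""
        return self.outer_height_mm - self.pore_length_mm

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ColumnSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


def build_pores(
    spec: ColumnSpec,
    ring_radius_mm: float = 8.0,
    include_axial: bool = True,
) -> list[Cylinder]:
    """Construct the artificial macropore field per the pore jig.

    The jig pattern is one axial pore plus the remaining pores equally
    spaced on a circle of ``ring_radius_mm`` (8 mm default keeps the whole
    field under the 20 mm inner-column footprint through which roots are
    funneled).  Pores run from ``pore_top_depth`` to the column base, since
    they are formed by rods inserted through the bottom of the column.
    """
    r = spec.pore_diameter_mm / 2.0
    z_top = spec.pore_top_depth_mm
    z_bot = spec.outer_height_mm
    n = spec.pore_count
    centers: list[tuple[float, float]] = []
    if n == 1:
        centers.append((0.0, 0.0))
    else:
        n_ring = n - 1 if include_axial else n
        if include_axial:
            centers.append((0.0, 0.0))
        ang = 2.0 * np.pi * np.arange(n_ring) / n_ring
        centers.extend(zip(ring_radius_mm * np.cos(ang), ring_radius_mm * np.sin(ang)))
    # feasibility: inside the column, pairwise non-overlapping
    outer_r = spec.outer_diameter_mm / 2.0
    for cx, cy in centers:
        if np.hypot(cx, cy) + r >= outer_r:
            raise ValueError("pore layout extends outside the outer column")
    pts = np.asarray(centers)
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if np.linalg.norm(pts[i] - pts[j]) <= 2 * r:
                raise ValueError("pore layout infeasible: pores overlap")
    return [
        Cylinder(
            pore_id=f"P{i}",
            top=np.array([cx, cy, z_top]),
            bottom=np.array([cx, cy, z_bot]),
            radius_mm=r,
        )
        for i, (cx, cy) in enumerate(centers)
    ]


@dataclass
class VoxelVolume:
    """Labeled or grayscale 3D grid with physical voxel size and origin.

    ``data`` is indexed ``(z, y, x)``; ``origin_mm`` is the physical
    (x, y, z) position of the center of voxel (0, 0, 0).
    """

    voxel_size_um: float
    data: np.ndarray
    origin_mm: np.ndarray
    label_map: dict | None = None

    def __post_init__(self) -> None:
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D (z, y, x)")

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical center coordinates along (z, y, x) axes, in mm."""
        h = self.voxel_size_mm
        nz, ny, nx = self.data.shape
        z = self.origin_mm[2] + h * np.arange(nz)
        y = self.origin_mm[1] + h * np.arange(ny)
        x = self.origin_mm[0] + h * np.arange(nx)
        return z, y, x


def voxelize(
    spec: ColumnSpec,
    pores: list[Cylinder] | None = None,
    roots: list[RootPolyline] | None = None,
    voxel_size_um: float = 200.0,
    bounds_mm: tuple | None = None,
    inner_wall_thickness_mm: float = 1.0,
) -> VoxelVolume:
    """Voxelize the column into a label volume.

    Each voxel is labeled by the region containing its center point, with
    precedence root > pore > inner wall > soil layer > background.
    ``bounds_mm`` is ``(xmin, xmax, ymin, ymax, zmin, zmax)``; the default
    covers the whole column.  Refuses grids larger than 2e9 voxels — crop
    with ``bounds_mm`` or coarsen the voxel size instead.
    """
    h = voxel_size_um / 1000.0
    R = spec.outer_diameter_mm / 2.0
    if bounds_mm is None:
        bounds_mm = (-R, R, -R, R, 0.0, spec.outer_height_mm)
    xmin, xmax, ymin, ymax, zmin, zmax = bounds_mm
    nx = max(int(np.ceil((xmax - xmin) / h)), 1)
    ny = max(int(np.ceil((ymax - ymin) / h)), 1)
    nz = max(int(np.ceil((zmax - zmin) / h)), 1)
    if nx * ny * nz > MAX_VOXELS:
        raise ValueError(
            f"{nx * ny * nz:.2e} voxels exceeds the 2e9 limit; "
            "crop with bounds_mm or use a coarser voxel size"
        )
    x = xmin + h * (np.arange(nx) + 0.5)
    y = ymin + h * (np.arange(ny) + 0.5)
    z = zmin + h * (np.arange(nz) + 0.5)
    origin = np.array([x[0], y[0], z[0]])

    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    r2_xy = y[:, None] ** 2 + x[None, :] ** 2  # (ny, nx)
    in_col = r2_xy <= R**2
    in_z = (z >= 0.0) & (z <= spec.outer_height_mm)
    topsoil_z = z < spec.subsoil_top_depth_mm
    soil = in_col[None, :, :] & in_z[:, None, None]
    labels[soil & topsoil_z[:, None, None]] = LABELS["topsoil"]
    labels[soil & ~topsoil_z[:, None, None]] = LABELS["subsoil"]

    # inner guide column wall (annulus from the surface down its length)
    ri = spec.inner_diameter_mm / 2.0
    wall_xy = (r2_xy >= ri**2) & (r2_xy <= (ri + inner_wall_thickness_mm) ** 2)
    wall_z = in_z & (z <= spec.inner_length_mm)
    labels[wall_z[:, None, None] & wall_xy[None, :, :] & soil] = LABELS["inner_wall"]

    for cyl in pores or []:
        _rasterize_pore(labels, cyl, x, y, z, h)

    for root in roots or []:
        _stamp_tube(labels, root, h, origin, LABELS["root"])

    return VoxelVolume(voxel_size_um=voxel_size_um, data=labels,
                       origin_mm=origin, label_map=dict(LABELS))


def _pore_xy_coverage(x, y, cx, cy, radius, h, sub: int = 7) -> np.ndarray:
    """Fractional (ny, nx) in-circle coverage of each voxel footprint."""
    off = (np.arange(sub) + 0.5) / sub * h - h / 2.0
    cov = np.zeros((len(y), len(x)))
    for oy in off:
        for ox in off:
            cov += (y[:, None] + oy - cy) ** 2 + (x[None, :] + ox - cx) ** 2 <= radius**2
    return cov / (sub * sub)


def _rasterize_pore(labels, cyl: Cylinder, x, y, z, h) -> None:
    """Volume-preserving rasterization of a (possibly sub-voxel) vertical tube.

    The pore diameter (0.8 mm) is below typical working voxel sizes, so
    labeling by voxel centers can misstate the pore volume by tens of
    percent depending on grid alignment.  Instead, voxel footprints are
    ranked by their analytic in-circle coverage and exactly as many are
    labeled per slice as match the true cross-section area.
    """
    cx, cy = cyl.top[:2]
    zsel = np.flatnonzero((z >= cyl.top[2]) & (z <= cyl.bottom[2]))
    if len(zsel) == 0:
        return
    cov = _pore_xy_coverage(x, y, cx, cy, cyl.radius_mm, h)
    order = np.argsort(cov, axis=None)[::-1]
    area_vox = np.pi * cyl.radius_mm**2 / h**2  # target voxels per slice
    n_total = int(round(area_vox * len(zsel)))
    n_base, n_extra = divmod(n_total, len(zsel))
    iy, ix = np.unravel_index(order, cov.shape)
    for k, zi in enumerate(zsel):
        n_k = n_base + (1 if k < n_extra else 0)
        n_k = min(n_k, int((cov > 0).sum()))
        labels[zi, iy[:n_k], ix[:n_k]] = LABELS["pore"]


def _stamp_tube(labels, root: RootPolyline, h: float, origin, value: int) -> None:
    """Mark voxels whose centers lie within the root radius of the centerline."""
    nz, ny, nx = labels.shape
    r = root.radius_mm
    step = min(h / 2.0, r / 2.0)
    samples = resample_polyline(root.points, step)
    # ball of voxel offsets covering radius r (+ half-sample margin)
    reach = int(np.ceil((r + step) / h)) + 1
    off = np.arange(-reach, reach + 1)
    oz, oy, ox = np.meshgrid(off, off, off, indexing="ij")
    offsets = np.stack([oz.ravel(), oy.ravel(), ox.ravel()], axis=1)
    for p in samples:
        idx = np.round((p[::-1] - origin[::-1]) / h).astype(int)  # (z, y, x)
        cand = offsets + idx
        ok = (
            (cand[:, 0] >= 0) & (cand[:, 0] < nz)
            & (cand[:, 1] >= 0) & (cand[:, 1] < ny)
            & (cand[:, 2] >= 0) & (cand[:, 2] < nx)
        )
        cand = cand[ok]
        centers = origin[::-1] + cand * h  # (z, y, x) mm
        d = np.linalg.norm(centers[:, ::-1] - p, axis=1)
        hit = cand[d <= r]
        labels[hit[:, 0], hit[:, 1], hit[:, 2]] = value


def default_intensities(spec: ColumnSpec) -> dict[int, float]:
    """Default per-label grayscale means for the synthetic CT phantom.

    Attenuation increases with bulk density: air-filled pores are darkest,
    roots (mostly water) dark, soil brighter, subsoil scaled by its packing
    density relative to topsoil, PVC wall brightest.
    """
    rho_ratio = spec.subsoil_bulk_density_g_cm3 / spec.topsoil_bulk_density_g_cm3
    return {
        LABELS["background"]: 0.0,
        LABELS["pore"]: 0.05,
        LABELS["root"]: 0.25,
        LABELS["topsoil"]: 0.55,
        LABELS["subsoil"]: 0.55 * rho_ratio,
        LABELS["inner_wall"]: 0.9,
    }


def synthesize_grayscale(
    labels: VoxelVolume,
    intensity_map: dict[int, float] | None = None,
    noise_sd: float = 0.03,
    seed: int = 0,
    spec: ColumnSpec | None = None,
) -> VoxelVolume:
    """Turn a label volume into a grayscale synthetic CT phantom.

    Each label is given its mean intensity plus iid Gaussian noise of
    standard deviation ``noise_sd``; reproducible for a fixed ``seed``.
    """
    if intensity_map is None:
        intensity_map = default_intensities(spec or ColumnSpec())
    gray = np.zeros(labels.data.shape, dtype=np.float32)
    for lab, mean in intensity_map.items():
        gray[labels.data == lab] = mean
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        gray = gray + rng.normal(0.0, noise_sd, size=gray.shape).astype(np.float32)
    return VoxelVolume(voxel_size_um=labels.voxel_size_um, data=gray,
                       origin_mm=labels.origin_mm.copy(), label_map=None)
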