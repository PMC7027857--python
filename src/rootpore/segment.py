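"""Recovery of root and pore geometry from grayscale CT volumes.

Seeded region growing (a deterministic running-mean variant of the
interactive tool workflow used for real scans) extracts root and pore
masks; 3D topological thinning reduces a mask to a one-voxel skeleton,
whose longest geodesic path per component becomes an ordered centerline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .column import VoxelVolume
from .geometry import Cylinder, RootPolyline, cumulative_arc_length, resample_polyline

__all__ = [
    "SeedPoint",
    "region_grow",
    "skeletonize_mask",
    "extract_centerlines",
    "fit_pore_cylinders",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SeedPoint:
    """A user-style seed: voxel index (z, y, x) plus its expected material."""

    index: tuple[int, int, int]
    expected: str = "root"  # root | pore


def region_grow(
    volume: VoxelVolume,
    seeds: list[SeedPoint] | list[tuple[int, int, int]],
    tolerance: float,
) -> np.ndarray:
    """Grow a 26-connected region of similar intensity from seed voxels.

    The region is expanded frontier by frontier: a neighboring voxel joins
    if its intensity is within ``tolerance`` of the running mean of the
    region accepted so far.  Deterministic given inputs.  Returns a boolean
    mask; seeds whose intensity is immediately out of tolerance yield an
    empty mask with a warning.
    """
    data = np.asarray(volume.data, dtype=float)
    mask = np.zeros(data.shape, dtype=bool)
    idx = [s.index if isinstance(s, SeedPoint) else tuple(s) for s in seeds]
    for i in idx:
        if not all(0 <= i[k] < data.shape[k] for k in range(3)):
            raise ValueError(f"seed {i} outside volume of shape {data.shape}")
    seed_vals = np.array([data[i] for i in idx])
    mean = seed_vals.mean()
    ok = np.abs(seed_vals - mean) <= tolerance
    if not ok.any():
        warnings.warn("all seeds out of tolerance; returning empty mask")
        return mask
    for i, good in zip(idx, ok):
        if good:
            mask[i] = True
    total = data[mask].sum()
    count = int(mask.sum())
    while True:
        frontier = ndimage.binary_dilation(mask, structure=_STRUCT26) & ~mask
        accept = frontier & (np.abs(data - total / count) <= tolerance)
        n_new = int(accept.sum())
        if n_new == 0:
            break
        mask |= accept
        total += data[accept].sum()
        count += n_new
    return mask


def skeletonize_mask(mask: np.ndarray, volume: VoxelVolume | None = None,
                     voxel_size_um: float | None = None,
                     origin_mm=None) -> nx.Graph:
    """3D topological thinning of a binary mask to a skeleton graph.

    Nodes are skeleton voxel indices (z, y, x) carrying their physical
    position (``pos_mm``, x/y/z order) and a local radius estimate from the
    Euclidean distance to the background; edges join 26-adjacent skeleton
    voxels weighted by their physical distance.  Preserves the number of
    connected components of the mask.
    """
    if volume is not None:
        voxel_size_um = volume.voxel_size_um
        origin_mm = volume.origin_mm
    h = (voxel_size_um or 1000.0) / 1000.0
    origin = np.asarray(origin_mm if origin_mm is not None else [0.0, 0.0, 0.0])
    g = nx.Graph()
    if not mask.any():
        return g
    skel = skeletonize(mask)
    if not skel.any():
        # thinning can annihilate objects that are perfectly grid-symmetric
        # (no unique medial voxel); break the symmetry by a one-voxel
        # one-sided dilation, at the cost of a half-voxel axis shift
        st = np.zeros((1, 2, 1), dtype=bool)
        st[0, :, 0] = True
        skel = skeletonize(ndimage.binary_dilation(mask, structure=st))
    dist = ndimage.distance_transform_edt(mask, sampling=h)
    coords = np.argwhere(skel)
    for c in coords:
        czyx = tuple(int(v) for v in c)
        pos = origin + h * c[::-1]
        g.add_node(czyx, pos_mm=pos, radius_mm=float(dist[czyx]))
    cs = set(g.nodes)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for c in cs:
        for off in offsets:
            nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            if nb in cs:
                g.add_edge(c, nb, weight=h * float(np.linalg.norm(off)))
    return g


def _longest_geodesic(g: nx.Graph, component) -> list:
    """Approximate longest shortest-path in a component via double sweep."""
    start = next(iter(component))
    lengths = nx.single_source_dijkstra_path_length(g, start, weight="weight")
    a = max((n for n in component), key=lambda n: lengths.get(n, 0.0))
    lengths, paths = nx.single_source_dijkstra(g, a, weight="weight")
    b = max((n for n in component), key=lambda n: lengths.get(n, 0.0))
    return paths[b]


def extract_centerlines(
    g: nx.Graph,
    smooth_window_mm: float = 1.0,
    min_length_mm: float = 2.0,
) -> list[RootPolyline]:
    """Ordered centerlines: per component, the longest geodesic path.

    Paths are ordered proximal (shallowest endpoint) to distal, smoothed by
    a ~1 mm moving average, and carry the mean node radius.  Components
    shorter than ``min_length_mm`` are dropped as noise.
    """
    out: list[RootPolyline] = []
    for k, comp in enumerate(nx.connected_components(g)):
        if len(comp) < 2:
            continue
        path = _longest_geodesic(g, comp)
        pts = np.array([g.nodes[n]["pos_mm"] for n in path])
        if pts[0, 2] > pts[-1, 2]:
            pts = pts[::-1]
        arc = cumulative_arc_length(pts)
        if arc[-1] < min_length_mm:
            continue
        # resample uniformly, then moving-average over ~smooth_window_mm
        step = 0.2
        pts = resample_polyline(pts, step)
        w = int(round(smooth_window_mm / step)) | 1
        if w >= 3 and len(pts) > w:
            sm = np.column_stack(
                [
                    ndimage.uniform_filter1d(pts[:, k2], size=w, mode="nearest")
                    for k2 in range(3)
                ]
            )
            keep = np.concatenate(
                [[True], np.linalg.norm(np.diff(sm, axis=0), axis=1) > 1e-9]
            )
            pts = sm[keep]
        radius = float(np.mean([g.nodes[n]["radius_mm"] for n in path]))
        out.append(RootPolyline(f"S{k}", pts, radius_mm=max(radius, 1e-3)))
    out.sort(key=lambda p: (p.points[0, 2], p.root_id))
    return out


def fit_pore_cylinders(
    mask: np.ndarray,
    volume: VoxelVolume | None = None,
    voxel_size_um: float | None = None,
    origin_mm=None,
    min_aspect: float = 3.0,
) -> list[Cylinder]:
    """Fit vertical cylinders to the tubes of a pore mask.

    Each 26-connected component becomes a cylinder with axis at the (x, y)
    centroid, the component's z-extent, and radius inferred from voxel
    count / length.  Components whose z-extent is less than ``min_aspect``
    times their lateral extent are flagged as non-tubular and skipped.
    """
    if volume is not None:
        voxel_size_um = volume.voxel_size_um
        origin_mm = volume.origin_mm
    h = (voxel_size_um or 1000.0) / 1000.0
    origin = np.asarray(origin_mm if origin_mm is not None else [0.0, 0.0, 0.0])
    labeled, n = ndimage.label(mask, structure=_STRUCT26)
    out: list[Cylinder] = []
    for i in range(1, n + 1):
        coords = np.argwhere(labeled == i)  # (m, 3) in (z, y, x)
        xyz = origin + h * coords[:, ::-1]
        z_lo, z_hi = xyz[:, 2].min() - h / 2, xyz[:, 2].max() + h / 2
        length = z_hi - z_lo
        lat = max(np.ptp(xyz[:, 0]), np.ptp(xyz[:, 1])) + h
        if length < min_aspect * lat:
            warnings.warn(f"component {i} is not tubular (aspect too low); skipped")
            continue
        cx, cy = xyz[:, 0].mean(), xyz[:, 1].mean()
        vol = len(coords) * h**3
        radius = float(np.sqrt(vol / (np.pi * length)))
        out.append(
            Cylinder(
                pore_id=f"FP{len(out)}",
                top=np.array([cx, cy, z_lo]),
                bottom=np.array([cx, cy, z_hi]),
                radius_mm=radius,
            )
        )
    return out
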