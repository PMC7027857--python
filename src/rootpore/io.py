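"""On-disk formats: centerline/pore/event CSVs, TIFF volumes, config files.

Volumes are stored as multi-page TIFF (one page per z slice) with a JSON
sidecar carrying the physical metadata (voxel size, origin, axis order and
label map); centerlines and pores travel as plain CSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .column import ColumnSpec, VoxelVolume
from .geometry import Cylinder, RootPolyline
from .simulate import BehaviorProfile, RootSystem

__all__ = [
    "write_centerlines_csv", "read_centerlines_csv",
    "write_pores_csv", "read_pores_csv",
    "write_volume", "read_volume",
    "write_profiles_yaml", "read_profiles_yaml",
    "write_spec_yaml", "read_spec_yaml",
]


def write_centerlines_csv(path, systems: list[RootSystem] | RootSystem) -> None:
    """Centerline CSV: column_id, root_id, point_index, x/y/z_mm, radius_mm."""
    if isinstance(systems, RootSystem):
        systems = [systems]
    rows = []
    for sys_ in systems:
        for root in sys_.roots:
            for i, p in enumerate(root.points):
                rows.append(
                    (sys_.column_id, root.root_id, i, p[0], p[1], p[2],
                     root.radius_mm)
                )
    pd.DataFrame(
        rows,
        columns=["column_id", "root_id", "point_index", "x_mm", "y_mm",
                 "z_mm", "radius_mm"],
    ).to_csv(path, index=False)


def read_centerlines_csv(path) -> list[RootSystem]:
    df = pd.read_csv(path)
    out = []
    for cid, cdf in df.groupby("column_id", sort=True):
        roots = []
        for rid, rdf in cdf.groupby("root_id", sort=True):
            rdf = rdf.sort_values("point_index")
            roots.append(
                RootPolyline(
                    str(rid),
                    rdf[["x_mm", "y_mm", "z_mm"]].to_numpy(),
                    radius_mm=float(rdf["radius_mm"].iloc[0]),
                )
            )
        out.append(RootSystem(str(cid), roots))
    return out


def write_pores_csv(path, pores: list[Cylinder], column_id: str = "C0") -> None:
    """Pore CSV: column_id, pore_id, x/y_mm, z_top/bottom_mm, radius_mm."""
    pd.DataFrame(
        [
            (column_id, p.pore_id, p.top[0], p.top[1], p.top[2], p.bottom[2],
             p.radius_mm)
            for p in pores
        ],
        columns=["column_id", "pore_id", "x_mm", "y_mm", "z_top_mm",
                 "z_bottom_mm", "radius_mm"],
    ).to_csv(path, index=False)


def read_pores_csv(path) -> dict[str, list[Cylinder]]:
    df = pd.read_csv(path)
    out: dict[str, list[Cylinder]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.column_id), []).append(
            Cylinder(
                pore_id=str(row.pore_id),
                top=np.array([row.x_mm, row.y_mm, row.z_top_mm]),
                bottom=np.array([row.x_mm, row.y_mm, row.z_bottom_mm]),
                radius_mm=float(row.radius_mm),
            )
        )
    return out


def write_volume(vol: VoxelVolume, path) -> None:
    """Multi-page TIFF (z pages) plus a ``.json`` metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, vol.data)
    meta = {
        "voxel_size_um": vol.voxel_size_um,
        "origin_mm": [float(v) for v in vol.origin_mm],
        "axis_order": "zyx",
        "label_map": vol.label_map,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_volume(path) -> VoxelVolume:
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return VoxelVolume(
        voxel_size_um=meta["voxel_size_um"],
        data=data,
        origin_mm=np.asarray(meta["origin_mm"]),
        label_map=meta.get("label_map"),
    )


def write_profiles_yaml(path, profiles: dict[tuple[str, str], BehaviorProfile]) -> None:
    payload = {
        f"{t}|{g}": {
            "treatment": p.treatment,
            "genotype": p.genotype,
            "p_colonize": p.p_colonize,
            "p_change_overall": p.p_change_overall,
            "interaction_rate": p.interaction_rate,
            "max_interactions": p.max_interactions,
            "change_deflection_deg": list(p.change_deflection_deg),
            "nochange_deflection_deg": list(p.nochange_deflection_deg),
        }
        for (t, g), p in profiles.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_profiles_yaml(path) -> dict[tuple[str, str], BehaviorProfile]:
    payload = yaml.safe_load(Path(path).read_text())
    out = {}
    for _, d in payload.items():
        p = BehaviorProfile(
            treatment=d["treatment"],
            genotype=d["genotype"],
            p_colonize=d["p_colonize"],
            p_change_overall=d["p_change_overall"],
            interaction_rate=d.get("interaction_rate", 1.78),
            max_interactions=d.get("max_interactions", 7),
            change_deflection_deg=tuple(d.get("change_deflection_deg", (8.0, 45.0))),
            nochange_deflection_deg=tuple(
                d.get("nochange_deflection_deg", (0.0, 1.5))
            ),
        )
        out[(p.treatment, p.genotype)] = p
    return out


def write_spec_yaml(path, spec: ColumnSpec) -> None:
    from dataclasses import asdict

    Path(path).write_text(yaml.safe_dump(asdict(spec), sort_keys=False))


def read_spec_yaml(path) -> ColumnSpec:
    return ColumnSpec(**yaml.safe_load(Path(path).read_text()))
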