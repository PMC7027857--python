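"""Stochastic generation of root systems with known pore-interaction behavior.

The simulator is event-driven: the number of root-macropore interactions per
column is drawn first (truncated Poisson), then for each interaction a root
polyline is constructed that actually realizes the drawn outcome — either
colonizing a pore (entering at the mouth and following the axis to the pore
bottom; colonizing roots never exit) or crossing it (touching the pore
surface and continuing past, deflected by a drawn angle).  Every generated
interaction is recorded in a ground-truth log so the geometric classifiers
can be validated event by event.

Behavior profiles package the observed per-treatment (1.2 vs 1.6 g cm^-3)
and per-genotype (Rht-B1a tall vs Rht-B1c dwarf) interaction statistics:
colonization probability, overall trajectory-change probability, and the
mean interaction count per column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .column import ColumnSpec, build_pores
from .geometry import (
    Cylinder,
    RootPolyline,
    cumulative_arc_length,
    point_cylinder_surface_distance,
    resample_polyline,
)

__all__ = [
    "BehaviorProfile",
    "GrowthParams",
    "ExperimentDesign",
    "RootSystem",
    "SimulatedColumn",
    "ExperimentDataset",
    "DEFAULT_PROFILES",
    "derive_conditional_change",
    "simulate_column",
    "simulate_events",
    "simulate_experiment",
]

TRUTH_COLUMNS = [
    "column_id", "root_id", "pore_id", "contact_arclength_mm",
    "outcome_colonize", "outcome_change", "deflection_deg",
]


@dataclass(frozen=True)
class BehaviorProfile:
    """Per (treatment, genotype) probabilities driving the simulator.

    ``p_change_overall`` is the overall probability that an interaction
    changes the root's growth trajectory; since colonization counts as a
    trajectory change by definition, it must be >= ``p_colonize`` and the
    conditional change probability for crossing events is derived from the
    pair (see :func:`derive_conditional_change`).
    """

    treatment: str
    genotype: str
    p_colonize: float
    p_change_overall: float
    interaction_rate: float = 1.78
    max_interactions: int = 7
    change_deflection_deg: tuple[float, float] = (8.0, 45.0)
    nochange_deflection_deg: tuple[float, float] = (0.0, 1.5)

    def __post_init__(self) -> None:
        for name in ("p_colonize", "p_change_overall"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.p_change_overall < self.p_colonize:
            raise ValueError(
                "p_change_overall must be >= p_colonize "
                "(colonization implies a trajectory change)"
            )
        if self.interaction_rate < 0:
            raise ValueError("interaction_rate must be >= 0")


#: Packaged behavior profiles keyed by (treatment, genotype).  Colonization
#: and overall change rates for the combined data: 68.8% / 76.0% in
#: compacted soil, 12.5% / 21.0% in loose soil; genotype-resolved rates for
#: the tall (Rht-B1a) and dwarf (Rht-B1c) near-isogenic lines.
DEFAULT_PROFILES: dict[tuple[str, str], BehaviorProfile] = {
    (t, g): BehaviorProfile(t, g, pc, ch)
    for (t, g), (pc, ch) in {
        ("compact_1.6", "combined"): (0.688, 0.760),
        ("loose_1.2", "combined"): (0.125, 0.210),
        ("compact_1.6", "Rht-B1a"): (0.800, 0.929),
        ("compact_1.6", "Rht-B1c"): (0.625, 0.786),
        ("loose_1.2", "Rht-B1a"): (0.077, 0.200),
        ("loose_1.2", "Rht-B1c"): (0.150, 0.250),
    }.items()
}

TREATMENT_DENSITY = {"loose_1.2": 1.2, "compact_1.6": 1.6}


@dataclass(frozen=True)
class GrowthParams:
    """Tunables of the geometric root-construction model (mm, degrees)."""

    step_mm: float = 0.5
    jitter_sd_deg: float = 0.4          # per-step wobble around the heading
    approach_length_mm: float = 25.0    # straight run before pore contact
    post_length_mm: float = 25.0        # run past the pore for crossers
    cross_angle_deg: tuple[float, float] = (5.0, 15.0)   # approach tilt
    colonize_angle_deg: tuple[float, float] = (3.0, 8.0)
    max_retries: int = 40


def derive_conditional_change(profile: BehaviorProfile) -> float:
    """Probability that a *crossing* event changes trajectory.

    Colonization always counts as a trajectory change, so with overall
    change probability ``q`` and colonization probability ``c`` the
    conditional crossing-change probability is ``(q - c) / (1 - c)``,
    clamped to [0, 1].
    """
    c, q = profile.p_colonize, profile.p_change_overall
    if c == 1.0:
        if q < 1.0:
            raise ValueError("p_colonize=1 is inconsistent with p_change_overall<1")
        return 1.0
    return float(np.clip((q - c) / (1.0 - c), 0.0, 1.0))


# ---------------------------------------------------------------------------
# low-level path construction


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(d, helper))
    e2 = np.cross(d, e1)
    return e1, e2


def _rotate(v: np.ndarray, axis: np.ndarray, deg: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis`` by ``deg`` degrees."""
    th = np.radians(deg)
    return (
        v * np.cos(th)
        + np.cross(axis, v) * np.sin(th)
        + axis * np.dot(axis, v) * (1.0 - np.cos(th))
    )


def _tilted_direction(tilt_deg: float, azimuth_rad: float) -> np.ndarray:
    s = np.sin(np.radians(tilt_deg))
    return np.array(
        [s * np.cos(azimuth_rad), s * np.sin(azimuth_rad), np.cos(np.radians(tilt_deg))]
    )


def _jittered_run(
    start: np.ndarray,
    direction: np.ndarray,
    length_mm: float,
    params: GrowthParams,
    rng: np.random.Generator,
    end: np.ndarray | None = None,
) -> np.ndarray:
    """Polyline marching along ``direction`` with per-step angular wobble.

    The wobble is an independent perturbation of the persistent base heading
    at each step (not an accumulating walk), so the fitted direction over a
    window equals the base heading to well under a degree.  If ``end`` is
    given the path is linearly warped to land exactly on it.
    """
    n = max(int(round(length_mm / params.step_mm)), 2)
    e1, e2 = _perp_basis(direction)
    th = rng.normal(0.0, np.radians(params.jitter_sd_deg), size=n)
    ph = rng.uniform(0.0, 2 * np.pi, size=n)
    dirs = (
        direction[None, :] * np.cos(th)[:, None]
        + (e1[None, :] * np.cos(ph)[:, None] + e2[None, :] * np.sin(ph)[:, None])
        * np.sin(th)[:, None]
    )
    steps = params.step_mm * dirs
    pts = np.vstack([start, start + np.cumsum(steps, axis=0)])
    if end is not None:
        w = np.linspace(0.0, 1.0, len(pts))[:, None]
        pts = pts + w * (end - pts[-1])
    return pts


def _bezier(p0, t0, p1, t1, step_mm: float) -> np.ndarray:
    """Cubic Bezier from p0 (tangent t0) to p1 (tangent t1), arc-resampled."""
    k = np.linalg.norm(p1 - p0) / 3.0
    c = np.array([p0, p0 + k * t0, p1 - k * t1, p1])
    t = np.linspace(0.0, 1.0, 200)[:, None]
    pts = (
        (1 - t) ** 3 * c[0] + 3 * (1 - t) ** 2 * t * c[1]
        + 3 * (1 - t) * t**2 * c[2] + t**3 * c[3]
    )
    return resample_polyline(pts, step_mm)


def _concat_paths(*paths: np.ndarray) -> np.ndarray:
    out = [paths[0]]
    for p in paths[1:]:
        if np.linalg.norm(p[0] - out[-1][-1]) < 1e-9:
            out.append(p[1:])
        else:
            out.append(p)
    pts = np.vstack(out)
    # drop accidental duplicate vertices
    keep = np.concatenate(
        [[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9]
    )
    return pts[keep]


# ---------------------------------------------------------------------------
# per-event root construction


def _seed_point(spec: ColumnSpec, rng: np.random.Generator) -> np.ndarray:
    r = 3.0 * np.sqrt(rng.uniform())
    a = rng.uniform(0.0, 2 * np.pi)
    return np.array([r * np.cos(a), r * np.sin(a), spec.planting_depth_mm])


def _lateral_azimuth(pore: Cylinder, rng: np.random.Generator) -> float:
    """Approach azimuth: roughly radially outward toward the pore."""
    cx, cy = pore.top[:2]
    if np.hypot(cx, cy) < 1e-6:
        return rng.uniform(0.0, 2 * np.pi)
    return np.arctan2(cy, cx) + rng.uniform(-np.pi / 6, np.pi / 6)


def _build_crosser(
    spec: ColumnSpec,
    pore: Cylinder,
    deflection_deg: float,
    root_radius: float,
    params: GrowthParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Root touching the pore surface and continuing, deflected at contact.

    Returns (points, contact_arclength).
    """
    z_top = pore.top[2]
    z_c = z_top + rng.uniform(2.0, 12.0)
    tilt = rng.uniform(*params.cross_angle_deg)
    az = _lateral_azimuth(pore, rng)
    d_pre = _tilted_direction(tilt, az)
    u_lat = np.array([np.cos(az), np.sin(az), 0.0])
    contact = np.array([pore.top[0], pore.top[1], z_c]) - (
        pore.radius_mm + root_radius
    ) * u_lat
    approach_start = contact - params.approach_length_mm * d_pre
    seed = _seed_point(spec, rng)
    shaft = _bezier(seed, np.array([0.0, 0.0, 1.0]), approach_start, d_pre,
                    params.step_mm)
    approach = _jittered_run(approach_start, d_pre, params.approach_length_mm,
                             params, rng, end=contact)
    # deflect about a random axis perpendicular to the heading, keeping the
    # post-contact course downward-dominant
    for _ in range(20):
        phi = rng.uniform(0.0, 2 * np.pi)
        e1, e2 = _perp_basis(d_pre)
        axis = e1 * np.cos(phi) + e2 * np.sin(phi)
        d_post = _unit(_rotate(d_pre, axis, deflection_deg))
        if d_post[2] >= 0.5:
            break
    post = _jittered_run(contact, d_post, params.post_length_mm, params, rng)
    pts = _concat_paths(shaft, approach, post)
    contact_arc = float(
        cumulative_arc_length(pts)[np.argmin(np.linalg.norm(pts - contact, axis=1))]
    )
    return pts, contact_arc


def _build_colonizer(
    spec: ColumnSpec,
    pore: Cylinder,
    root_radius: float,
    params: GrowthParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, float]:
    """Root entering the pore mouth and following the axis to the pore bottom.

    Returns (points, contact_arclength, approach_tilt_deg).
    """
    mouth = np.array([pore.top[0], pore.top[1], pore.top[2]])
    tilt = rng.uniform(*params.colonize_angle_deg)
    az = _lateral_azimuth(pore, rng)
    d_pre = _tilted_direction(tilt, az)
    approach_start = mouth - params.approach_length_mm * d_pre
    seed = _seed_point(spec, rng)
    shaft = _bezier(seed, np.array([0.0, 0.0, 1.0]), approach_start, d_pre,
                    params.step_mm)
    approach = _jittered_run(approach_start, d_pre, params.approach_length_mm,
                             params, rng, end=mouth)
    down = np.array([0.0, 0.0, 1.0])
    blend_end = mouth + np.array([0.0, 0.0, 3.0])
    blend = _bezier(mouth, d_pre, blend_end, down, 0.25)
    # in-pore run: down the axis with a small bounded wobble
    z_end = pore.bottom[2] - 0.5
    z = np.arange(blend_end[2], z_end, params.step_mm)
    z = np.append(z, z_end)
    ph = rng.uniform(0.0, 2 * np.pi)
    amp = 0.05
    wob = amp * np.sin(2 * np.pi * (z - z[0]) / 12.0 + ph)
    in_pore = np.stack(
        [mouth[0] + wob * np.cos(ph), mouth[1] + wob * np.sin(ph), z], axis=1
    )
    pts = _concat_paths(shaft, approach, blend, in_pore)
    arc = cumulative_arc_length(pts)
    mouth_arc = float(arc[np.argmin(np.linalg.norm(pts - mouth, axis=1))])
    # first contact is just above the mouth where the cap gap reaches zero
    contact_arc = max(mouth_arc - root_radius, 0.0)
    return pts, contact_arc, tilt


def _coarse_clearances(
    points: np.ndarray,
    radius_mm: float,
    pores: list[Cylinder],
    step_mm: float = 0.2,
) -> dict[str, float]:
    """Lower bound on surface clearance per pore (Lipschitz coarse sampling)."""
    pts = resample_polyline(points, step_mm)
    out = {}
    for p in pores:
        d = point_cylinder_surface_distance(pts, p) - radius_mm
        out[p.pore_id] = float(d.min()) - step_mm / 2.0
    return out


def _build_filler(
    spec: ColumnSpec,
    pores: list[Cylinder],
    root_radius: float,
    params: GrowthParams,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Non-interacting root descending between the pores; None if no safe path."""
    for _ in range(params.max_retries):
        az = rng.uniform(0.0, 2 * np.pi)
        u = np.array([np.cos(az), np.sin(az), 0.0])
        seed = _seed_point(spec, rng)
        w1 = 7.0 * u + np.array([0.0, 0.0, spec.subsoil_top_depth_mm])
        w2 = 13.0 * u + np.array([0.0, 0.0, spec.outer_height_mm - 8.0])
        d1 = _unit(w2 - w1)
        upper = _bezier(seed, np.array([0.0, 0.0, 1.0]), w1, d1, params.step_mm)
        lower = _jittered_run(w1, d1, np.linalg.norm(w2 - w1), params, rng, end=w2)
        pts = _concat_paths(upper, lower)
        if all(c > 1.0 for c in _coarse_clearances(pts, root_radius, pores).values()):
            return pts
    return None


# ---------------------------------------------------------------------------
# column- and experiment-level simulation


@dataclass
class RootSystem:
    """All root centerlines recovered or generated for one column."""

    column_id: str
    roots: list[RootPolyline] = field(default_factory=list)


@dataclass
class SimulatedColumn:
    column_id: str
    roots: RootSystem
    pores: list[Cylinder]
    truth: pd.DataFrame


def _check_root(
    poly: RootPolyline,
    spec: ColumnSpec,
    pores: list[Cylinder],
    target: Cylinder | None,
    clearance_mm: float = 0.2,
) -> bool:
    """Root stays inside the column and clear of every non-target pore."""
    r_xy = np.hypot(poly.points[:, 0], poly.points[:, 1])
    if np.any(r_xy > spec.outer_diameter_mm / 2.0 - poly.radius_mm):
        return False
    if np.any(poly.points[:, 2] > spec.outer_height_mm) or np.any(
        poly.points[:, 2] < 0
    ):
        return False
    others = [p for p in pores if target is None or p.pore_id != target.pore_id]
    clear = _coarse_clearances(poly.points, poly.radius_mm, others)
    return all(c > clearance_mm for c in clear.values())


def simulate_column(
    spec: ColumnSpec,
    pores: list[Cylinder],
    profile: BehaviorProfile,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_events: int | None = None,
    n_filler: int = 1,
    growth: GrowthParams = GrowthParams(),
    root_radius_mm: float = 0.25,
    column_id: str = "C0",
) -> tuple[RootSystem, pd.DataFrame]:
    """Generate one column's root system and its ground-truth event log.

    The interaction count is drawn from a Poisson with the profile's mean,
    redrawn while it exceeds ``max_interactions`` (the observed counts
    ranged 0-7); each interaction gets its own root whose geometry realizes
    the drawn colonize/cross and change/no-change outcome.  Pass
    ``n_events`` to force the count (used for large event-level runs).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_events is None:
        n = int(rng.poisson(profile.interaction_rate))
        while n > profile.max_interactions:
            n = int(rng.poisson(profile.interaction_rate))
    else:
        n = n_events
    p_cond = derive_conditional_change(profile)
    roots: list[RootPolyline] = []
    records: list[dict] = []
    for i in range(n):
        root_id = f"{column_id}_R{i}"
        for attempt in range(growth.max_retries):
            pore = pores[rng.integers(len(pores))]
            colonize = bool(rng.uniform() < profile.p_colonize)
            if colonize:
                pts, contact_arc, defl = _build_colonizer(
                    spec, pore, root_radius_mm, growth, rng
                )
                change = True
            else:
                change = bool(rng.uniform() < p_cond)
                band = (
                    profile.change_deflection_deg
                    if change
                    else profile.nochange_deflection_deg
                )
                defl = float(rng.uniform(*band))
                pts, contact_arc = _build_crosser(
                    spec, pore, defl, root_radius_mm, growth, rng
                )
            poly = RootPolyline(root_id, pts, radius_mm=root_radius_mm)
            if _check_root(poly, spec, pores, target=pore):
                break
        else:
            raise RuntimeError(
                f"could not construct a valid root for {root_id} "
                f"after {growth.max_retries} attempts"
            )
        roots.append(poly)
        records.append(
            dict(
                column_id=column_id,
                root_id=root_id,
                pore_id=pore.pore_id,
                contact_arclength_mm=contact_arc,
                outcome_colonize=colonize,
                outcome_change=change,
                deflection_deg=defl,
            )
        )
    for j in range(n_filler):
        pts = _build_filler(spec, pores, root_radius_mm, growth, rng)
        if pts is not None:
            roots.append(
                RootPolyline(f"{column_id}_F{j}", pts, radius_mm=root_radius_mm)
            )
    truth = pd.DataFrame(records, columns=TRUTH_COLUMNS)
    return RootSystem(column_id, roots), truth


def simulate_events(
    n_events: int,
    profile: BehaviorProfile,
    spec: ColumnSpec | None = None,
    pores: list[Cylinder] | None = None,
    seed: int | None = None,
    events_per_column: int = 5,
    growth: GrowthParams = GrowthParams(),
    column_prefix: str = "E",
) -> list[SimulatedColumn]:
    """Generate exactly ``n_events`` interactions spread over pseudo-columns.

    Convenience for event-level parameter-recovery runs where the per-column
    Poisson count is irrelevant and a fixed number of interactions is wanted.
    """
    spec = spec or ColumnSpec(
        subsoil_bulk_density_g_cm3=TREATMENT_DENSITY.get(profile.treatment, 1.6)
    )
    pores = pores or build_pores(spec)
    rng = np.random.default_rng(seed)
    out: list[SimulatedColumn] = []
    done = 0
    k = 0
    while done < n_events:
        m = min(events_per_column, n_events - done)
        cid = f"{column_prefix}{k}"
        roots, truth = simulate_column(
            spec, pores, profile, rng=rng, n_events=m, n_filler=0,
            growth=growth, column_id=cid,
        )
        out.append(SimulatedColumn(cid, roots, pores, truth))
        done += m
        k += 1
    return out


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout: genotypes x treatments x replicates, in blocks.

    The default mirrors the glasshouse experiment: 2 genotypes x 2 bulk
    densities x 10 replicates = 40 columns, staggered over 6 days (blocks)
    by seeded randomization.
    """

    genotypes: tuple[str, ...] = ("Rht-B1a", "Rht-B1c")
    treatments: tuple[str, ...] = ("loose_1.2", "compact_1.6")
    replicates_per_cell: int = 10
    n_blocks: int = 6

    @property
    def n_columns(self) -> int:
        return len(self.genotypes) * len(self.treatments) * self.replicates_per_cell


@dataclass
class ExperimentDataset:
    design: ExperimentDesign
    manifest: pd.DataFrame
    columns: dict[str, SimulatedColumn]

    def all_truth(self) -> pd.DataFrame:
        frames = [c.truth for c in self.columns.values() if len(c.truth)]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=TRUTH_COLUMNS
        )


def simulate_experiment(
    design: ExperimentDesign | None = None,
    spec: ColumnSpec | None = None,
    profiles: dict[tuple[str, str], BehaviorProfile] | None = None,
    seed: int | None = None,
    n_filler: int = 1,
    growth: GrowthParams = GrowthParams(),
) -> ExperimentDataset:
    """Simulate a full randomized-block factorial experiment.

    One column per design slot; per-column seeds are derived from the master
    seed so the dataset is reproducible; block labels are assigned by a
    seeded shuffle of a balanced block vector.
    """
    design = design or ExperimentDesign()
    profiles = profiles or DEFAULT_PROFILES
    rng = np.random.default_rng(seed)
    slots = [
        (g, t)
        for g in design.genotypes
        for t in design.treatments
        for _ in range(design.replicates_per_cell)
    ]
    for g, t in {(g, t) for g, t in slots}:
        if (t, g) not in profiles:
            raise KeyError(f"no behavior profile for treatment={t}, genotype={g}")
    blocks = np.resize(np.arange(1, design.n_blocks + 1), len(slots))
    rng.shuffle(blocks)
    col_seeds = rng.integers(0, 2**31 - 1, size=len(slots))
    manifest_rows = []
    columns: dict[str, SimulatedColumn] = {}
    for i, ((g, t), blk, cseed) in enumerate(zip(slots, blocks, col_seeds)):
        cid = f"C{i:03d}"
        cspec = spec or ColumnSpec(subsoil_bulk_density_g_cm3=TREATMENT_DENSITY[t])
        pores = build_pores(cspec)
        roots, truth = simulate_column(
            cspec, pores, profiles[(t, g)], seed=int(cseed),
            n_filler=n_filler, growth=growth, column_id=cid,
        )
        columns[cid] = SimulatedColumn(cid, roots, pores, truth)
        manifest_rows.append(
            dict(column_id=cid, genotype=g, treatment=t, block=int(blk),
                 seed=int(cseed))
        )
    manifest = pd.DataFrame(manifest_rows)
    return ExperimentDataset(design, manifest, columns)
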