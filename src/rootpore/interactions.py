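"""Detection and classification of root-macropore interactions.

An interaction is a root meeting a pore with at most one voxel of
surface-to-surface separation (default voxel 45 um, the scan resolution).
Each interaction is classified as *colonize* (the root grows inside the
pore for more than 15 mm after contact) or *cross* (it continues across or
away within 15 mm), and its growth trajectory as *changed* or *unchanged*
by comparing least-squares direction fits over 20 mm of root before and
after the interaction against a 3 degree threshold.  Colonization counts as
a trajectory change by definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    Cylinder,
    InsufficientArcError,
    RootPolyline,
    angle_between,
    cumulative_arc_length,
    direction_at,
    point_cylinder_surface_distance,
    resample_polyline,
    _interp_along,
)
from .simulate import RootSystem

__all__ = [
    "InteractionEvent",
    "ColumnResult",
    "detect_interactions",
    "inside_arc_length",
    "classify_colonization",
    "classify_trajectory",
    "classify_events",
    "analyze_column",
    "events_to_frame",
    "COLONIZE_MIN_MM",
    "TRAJECTORY_THRESHOLD_DEG",
    "PRE_POST_WINDOW_MM",
]

COLONIZE_MIN_MM = 15.0          # strictly more than this inside the pore
TRAJECTORY_THRESHOLD_DEG = 3.0  # strictly more than this is "changed"
PRE_POST_WINDOW_MM = 20.0
MERGE_GAP_MM = 15.0


@dataclass
class InteractionEvent:
    """One root-pore contact with its geometry and classifications."""

    column_id: str
    root_id: str
    pore_id: str
    contact_arclength_mm: float
    contact_point: np.ndarray
    min_separation_mm: float
    inside_length_mm: float = float("nan")
    classification: str = ""     # colonize | cross
    trajectory: str = ""         # changed | unchanged | indeterminate
    deflection_deg: float = float("nan")


@dataclass
class ColumnResult:
    """Per-column interaction counts (colonize + cross = interactions)."""

    column_id: str
    n_interactions: int = 0
    n_colonize: int = 0
    n_cross: int = 0
    n_changed: int = 0
    n_unchanged: int = 0
    n_indeterminate: int = 0
    events: list[InteractionEvent] = field(default_factory=list)


def _root_pore_profile(
    root: RootPolyline, pore: Cylinder, step_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """(arc positions, surface separation) sampled along the root."""
    pts = resample_polyline(root.points, step_mm)
    s = cumulative_arc_length(pts)
    d = point_cylinder_surface_distance(pts, pore) - root.radius_mm
    return s, np.maximum(d, 0.0)


def detect_interactions(
    roots: RootSystem | list[RootPolyline],
    pores: list[Cylinder],
    voxel_size_um: float = 45.0,
    step_mm: float = 0.05,
    merge_gap_mm: float = MERGE_GAP_MM,
) -> list[InteractionEvent]:
    """Find root-pore contact events under the one-voxel separation rule.

    A contact episode is a contiguous arc stretch where the surface-to-
    surface separation is <= one voxel; episodes on the same pore separated
    by less than ``merge_gap_mm`` of arc are merged into one event, keeping
    the first contact.  Returns one event per (root, pore) contact episode,
    ordered by root then contact arc length.
    """
    root_list = roots.roots if isinstance(roots, RootSystem) else roots
    column_id = roots.column_id if isinstance(roots, RootSystem) else ""
    threshold = voxel_size_um / 1000.0
    events: list[InteractionEvent] = []
    for root in root_list:
        arc = root.arc
        for pore in pores:
            s, d = _root_pore_profile(root, pore, step_mm)
            below = d <= threshold
            if not below.any():
                continue
            # contiguous below-threshold runs -> (start, end) arc intervals
            edges = np.flatnonzero(np.diff(below.astype(np.int8)))
            starts = [0] if below[0] else []
            starts += [int(e) + 1 for e in edges if not below[e]]
            ends = [int(e) for e in edges if below[e]]
            if below[-1]:
                ends.append(len(below) - 1)
            episodes = list(zip(starts, ends))
            merged = [episodes[0]]
            for a, b in episodes[1:]:
                if s[a] - s[merged[-1][1]] < merge_gap_mm:
                    merged[-1] = (merged[-1][0], b)
                else:
                    merged.append((a, b))
            for a, b in merged:
                sep = float(d[a : b + 1].min())
                contact_s = float(s[a])
                contact_pt = _interp_along(
                    root.points, arc, np.array([contact_s])
                )[0]
                events.append(
                    InteractionEvent(
                        column_id=column_id,
                        root_id=root.root_id,
                        pore_id=pore.pore_id,
                        contact_arclength_mm=contact_s,
                        contact_point=contact_pt,
                        min_separation_mm=sep,
                    )
                )
    events.sort(key=lambda e: (e.root_id, e.contact_arclength_mm))
    return events


def inside_arc_length(
    root: RootPolyline,
    pore: Cylinder,
    contact_arclength_mm: float,
    step_mm: float = 0.1,
) -> float:
    """Longest contiguous arc (mm) the centerline spends inside the pore.

    "Inside" means within the pore radius of its axis and within the pore's
    z-extent; only stretches starting at or after the contact arc count.
    """
    pts = resample_polyline(root.points, step_mm)
    s = cumulative_arc_length(pts)
    a, u = pore.top, pore.bottom - pore.top
    L = np.linalg.norm(u)
    u = u / L
    rel = pts - a
    t = rel @ u
    radial = np.linalg.norm(rel - np.outer(t, u), axis=1)
    inside = (radial <= pore.radius_mm) & (t >= 0.0) & (t <= L)
    inside &= s >= contact_arclength_mm - step_mm
    if not inside.any():
        return 0.0
    edges = np.flatnonzero(np.diff(inside.astype(np.int8)))
    starts = ([0] if inside[0] else []) + [int(e) + 1 for e in edges if not inside[e]]
    ends = [int(e) for e in edges if inside[e]] + (
        [len(inside) - 1] if inside[-1] else []
    )
    best = max(s[b] - s[a0] for a0, b in zip(starts, ends))
    return float(best)


def classify_colonization(event: InteractionEvent) -> str:
    """'colonize' iff the root ran strictly more than 15 mm inside the pore."""
    if not np.isfinite(event.inside_length_mm):
        raise ValueError("inside_length_mm must be computed before classification")
    return "colonize" if event.inside_length_mm > COLONIZE_MIN_MM else "cross"


def classify_trajectory(
    root: RootPolyline,
    event: InteractionEvent,
    window_mm: float = PRE_POST_WINDOW_MM,
    threshold_deg: float = TRAJECTORY_THRESHOLD_DEG,
) -> tuple[str, float]:
    """Classify the growth trajectory across the interaction.

    Colonizers changed trajectory by definition.  For crossers the pre
    direction is fitted over ``window_mm`` of arc before contact and the
    post direction over ``window_mm`` after leaving the pore (contact arc +
    in-pore length); the event is 'changed' iff the angle between the two
    fits strictly exceeds ``threshold_deg``.  If either window offers less
    than 5 mm of root the event is 'indeterminate'.

    Returns (trajectory, deflection_deg); the deflection is NaN when it
    cannot be measured.
    """
    pre_s = event.contact_arclength_mm
    post_s = event.contact_arclength_mm + max(event.inside_length_mm, 0.0)
    try:
        d_pre = direction_at(root, pre_s, window_mm, side="pre")
        d_post = direction_at(root, post_s, window_mm, side="post")
        deflection = angle_between(d_pre, d_post)
    except InsufficientArcError:
        if event.classification == "colonize":
            return "changed", float("nan")
        return "indeterminate", float("nan")
    if event.classification == "colonize":
        return "changed", deflection
    return ("changed" if deflection > threshold_deg else "unchanged"), deflection


def classify_events(
    roots: RootSystem | list[RootPolyline],
    pores: list[Cylinder],
    voxel_size_um: float = 45.0,
) -> list[InteractionEvent]:
    """Full per-root pipeline: detect, measure in-pore arc, classify."""
    root_list = roots.roots if isinstance(roots, RootSystem) else roots
    by_id = {r.root_id: r for r in root_list}
    pore_by_id = {p.pore_id: p for p in pores}
    events = detect_interactions(roots, pores, voxel_size_um=voxel_size_um)
    for ev in events:
        root = by_id[ev.root_id]
        pore = pore_by_id[ev.pore_id]
        ev.inside_length_mm = inside_arc_length(root, pore, ev.contact_arclength_mm)
        ev.classification = classify_colonization(ev)
        ev.trajectory, ev.deflection_deg = classify_trajectory(root, ev)
    return events


def analyze_column(
    roots: RootSystem | list[RootPolyline],
    pores: list[Cylinder],
    voxel_size_um: float = 45.0,
    column_id: str | None = None,
) -> ColumnResult:
    """Classify all interactions in one column and tally the counts."""
    if column_id is None:
        column_id = roots.column_id if isinstance(roots, RootSystem) else ""
    events = classify_events(roots, pores, voxel_size_um=voxel_size_um)
    res = ColumnResult(column_id=column_id, events=events)
    res.n_interactions = len(events)
    res.n_colonize = sum(e.classification == "colonize" for e in events)
    res.n_cross = sum(e.classification == "cross" for e in events)
    res.n_changed = sum(e.trajectory == "changed" for e in events)
    res.n_unchanged = sum(e.trajectory == "unchanged" for e in events)
    res.n_indeterminate = sum(e.trajectory == "indeterminate" for e in events)
    return res


def events_to_frame(events: list[InteractionEvent]) -> pd.DataFrame:
    """Events as a tidy table (one row per interaction)."""
    return pd.DataFrame(
        [
            dict(
                column_id=e.column_id,
                root_id=e.root_id,
                pore_id=e.pore_id,
                contact_arclength_mm=e.contact_arclength_mm,
                min_separation_mm=e.min_separation_mm,
                inside_length_mm=e.inside_length_mm,
                classification=e.classification,
                trajectory=e.trajectory,
                deflection_deg=e.deflection_deg,
            )
            for e in events
        ],
        columns=[
            "column_id", "root_id", "pore_id", "contact_arclength_mm",
            "min_separation_mm", "inside_length_mm", "classification",
            "trajectory", "deflection_deg",
        ],
    )
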