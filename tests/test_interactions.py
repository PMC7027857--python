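"""Detection and classification of root-pore interactions."""

import numpy as np
import pandas as pd
import pytest

import rootpore as rp
from rootpore.interactions import InteractionEvent

from conftest import straight_root


def grazing_root(pore, touch_arcs, z0=128.0, radius=0.25, step=0.1):
    """Vertical root beside a pore that dips to surface contact at given arcs.

    The root runs parallel to the pore axis at 2 mm surface clearance and
    swings in to touch (surface distance 0) around each requested arc.
    """
    gap = 2.0
    z = np.arange(z0, 169.0, step)
    s = z - z0
    offset = np.full_like(z, pore.radius_mm + radius + gap)
    for sa in touch_arcs:
        bump = gap * np.exp(-((s - sa) ** 2) / (2 * 1.0**2))
        offset = np.minimum(offset, pore.radius_mm + radius + gap - bump)
    pts = np.column_stack(
        [pore.top[0] + offset, np.full_like(z, pore.top[1]), z]
    )
    return rp.RootPolyline("graze", pts, radius_mm=radius)


class TestDetectInteractions:
    def test_distant_root_yields_nothing(self, pores):
        root = straight_root(x=25.0, z0=20, z1=160)
        assert rp.detect_interactions([root], pores) == []

    def test_touching_root_detected_under_one_voxel_rule(self, pores):
        pore = pores[1]
        # parallel root whose surface sits 0.02 mm from the pore surface
        x = pore.top[0] + pore.radius_mm + 0.25 + 0.02
        root = straight_root(x=x, y=pore.top[1], z0=100, z1=168)
        events = rp.detect_interactions([root], pores, voxel_size_um=45.0)
        assert len(events) == 1
        assert events[0].pore_id == pore.pore_id
        assert events[0].min_separation_mm <= 0.045

    def test_merge_rule_on_repeated_grazing(self, pores):
        pore = pores[0]
        near = grazing_root(pore, [20.0, 28.0])
        far = grazing_root(pore, [20.0, 40.0])
        ev_near = rp.detect_interactions([near], [pore])
        ev_far = rp.detect_interactions([far], [pore])
        assert len(ev_near) == 1  # 8 mm apart -> merged, first contact kept
        assert len(ev_far) == 2   # 20 mm apart -> two events
        assert ev_near[0].contact_arclength_mm < 22.0

    def test_threshold_monotonicity(self, spec, pores, compact_profile):
        cols = rp.simulate_events(40, compact_profile, spec, pores, seed=21)
        for c in cols:
            n_small = len(rp.detect_interactions(c.roots, pores, 45.0))
            n_large = len(rp.detect_interactions(c.roots, pores, 200.0))
            assert n_large >= n_small


class TestInsideArcLength:
    def test_axis_follower(self, pores):
        pore = pores[0]
        root = straight_root(x=pore.top[0], y=pore.top[1], z0=100.0,
                             z1=pore.top[2] + 30.0, step=0.5)
        inside = rp.inside_arc_length(root, pore, contact_arclength_mm=24.0)
        assert inside == pytest.approx(30.0, abs=0.2)

    def test_perpendicular_crosser_chord(self, pores):
        pore = pores[0]
        x = np.linspace(-5, 5, 401)
        pts = np.column_stack(
            [pore.top[0] + x, np.full_like(x, pore.top[1]),
             np.full_like(x, 140.0)]
        )
        root = rp.RootPolyline("perp", pts, radius_mm=0.25)
        inside = rp.inside_arc_length(root, pore, contact_arclength_mm=0.0)
        assert inside <= 0.9

    def test_no_inside_points(self, pores):
        root = straight_root(x=20.0, z0=20, z1=160)
        assert rp.inside_arc_length(root, pores[0], 0.0) == 0.0


class TestClassification:
    @pytest.mark.parametrize(
        "inside,expected",
        [(30.0, "colonize"), (0.8, "cross"), (15.0, "cross"), (15.01, "colonize")],
    )
    def test_colonization_threshold_strict(self, inside, expected):
        ev = InteractionEvent("c", "r", "p", 10.0, np.zeros(3), 0.0,
                              inside_length_mm=inside)
        assert rp.classify_colonization(ev) == expected

    def make_crosser_event(self, deflection_deg):
        """Straight 40 mm descent, kink of given angle, 40 mm more."""
        th = np.radians(deflection_deg)
        d1 = np.array([0.0, 0.0, 1.0])
        d2 = np.array([np.sin(th), 0.0, np.cos(th)])
        s = np.arange(0, 40.0, 0.5)[:, None]
        leg1 = s * d1
        leg2 = leg1[-1] + np.arange(0.5, 40.0, 0.5)[:, None] * d2
        root = rp.RootPolyline("k", np.vstack([leg1, leg2]), radius_mm=0.25)
        ev = InteractionEvent("c", "k", "p", 39.5, leg1[-1], 0.0,
                              inside_length_mm=0.0, classification="cross")
        return root, ev

    @pytest.mark.parametrize(
        "deflection,expected",
        [(0.0, "unchanged"), (20.0, "changed"), (3.0, "unchanged"), (3.2, "changed")],
    )
    def test_trajectory_threshold_strict(self, deflection, expected):
        root, ev = self.make_crosser_event(deflection)
        traj, measured = rp.classify_trajectory(root, ev)
        assert traj == expected
        assert measured == pytest.approx(deflection, abs=0.1)

    def test_colonizer_changed_by_definition(self, spec, pores):
        prof = rp.BehaviorProfile("compact_1.6", "combined", 1.0, 1.0)
        roots, truth = rp.simulate_column(spec, pores, prof, seed=2,
                                          n_events=3, n_filler=0)
        events = rp.classify_events(roots, pores)
        assert all(e.classification == "colonize" for e in events)
        assert all(e.trajectory == "changed" for e in events)

    def test_short_root_indeterminate(self, pores):
        pore = pores[0]
        # root that only just reaches the pore: too little pre-window arc
        root = straight_root(x=pore.top[0] + pore.radius_mm + 0.25,
                             y=pore.top[1], z0=137.0, z1=168.0)
        events = rp.classify_events([root], [pore])
        assert len(events) == 1
        assert events[0].trajectory == "indeterminate"


class TestAnalyzeColumn:
    def test_empty_column(self, pores):
        res = rp.analyze_column(rp.RootSystem("C9", []), pores)
        assert res.n_interactions == res.n_colonize == res.n_cross == 0

    def test_counts_match_truth(self, spec, pores, compact_profile):
        roots, truth = rp.simulate_column(spec, pores, compact_profile,
                                          seed=13, n_events=6, n_filler=1)
        res = rp.analyze_column(roots, pores)
        assert res.n_interactions == len(truth) == 6
        assert res.n_colonize == int(truth.outcome_colonize.sum())
        assert res.n_cross == int((~truth.outcome_colonize).sum())
        assert res.n_changed == int(truth.outcome_change.sum())
        assert res.n_colonize + res.n_cross == res.n_interactions

    def test_invariant_under_root_relabeling(self, spec, pores,
                                             compact_profile):
        roots, _ = rp.simulate_column(spec, pores, compact_profile,
                                      seed=4, n_events=4, n_filler=0)
        res1 = rp.analyze_column(roots, pores)
        renamed = rp.RootSystem(
            roots.column_id,
            [rp.RootPolyline(f"x{i}", r.points, r.radius_mm)
             for i, r in enumerate(reversed(roots.roots))],
        )
        res2 = rp.analyze_column(renamed, pores)
        for attr in ("n_interactions", "n_colonize", "n_cross", "n_changed",
                     "n_unchanged", "n_indeterminate"):
            assert getattr(res1, attr) == getattr(res2, attr)


def test_compact_exceeds_loose_colonization(spec, pores, compact_profile,
                                            loose_profile):
    fracs = {}
    for name, prof in [("compact", compact_profile), ("loose", loose_profile)]:
        cols = rp.simulate_events(200, prof, spec, pores, seed=99)
        events = []
        for c in cols:
            events += rp.classify_events(c.roots, pores)
        df = rp.events_to_frame(events)
        fracs[name] = (df.classification == "colonize").mean()
    assert fracs["compact"] > fracs["loose"]
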