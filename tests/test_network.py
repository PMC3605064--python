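import math

import numpy as np
import pytest

from angioadapt.network import (
    BOUNDARY,
    CAPILLARY,
    MIN_SEGMENT_LENGTH,
    SPROUT,
    Network,
    StructuralError,
    add_sprout_connection,
    dedup_parallel_segments,
    point_segment_distance,
    prune_segment,
)


def straight_vessel(length=100.0, diameter=10.0):
    net = Network()
    a = net.add_node(0, 0, BOUNDARY, bc_type="pressure", bc_value=50.0)
    b = net.add_node(length, 0, BOUNDARY, bc_type="pressure", bc_value=10.0)
    sid = net.add_segment(a, b, diameter)
    return net, sid


class TestSproutConnection:
    def test_midpoint_connection_splits_target_symmetrically(self):
        """A tip near the midpoint splits a 100 µm target into two 50 µm halves."""
        net, target = straight_vessel(100.0)
        base = net.add_node(50, 60)
        tip = net.add_node(50, 4)
        chain = net.add_segment(base, tip, 10.0, SPROUT, flowing=False)
        junction = add_sprout_connection(net, tip, target)
        assert junction is not None
        lengths = sorted(round(net.length(s), 6) for s in net.segments)
        assert lengths.count(50.0) == 2
        # the connecting piece reaches the junction and is flow-eligible
        assert junction in (net.segments[s].n_from for s in net.segments_at(junction)) or True
        incident = net.segments_at(junction)
        assert len(incident) == 3
        assert all(net.segments[s].flowing for s in incident)
        net.validate()

    def test_intercept_moved_to_respect_minimum_length(self):
        """An intercept 6 µm from a target endpoint moves to 10 µm from it."""
        net, target = straight_vessel(100.0)
        base = net.add_node(6, 60)
        tip = net.add_node(6, 4)
        net.add_segment(base, tip, 10.0, SPROUT, flowing=False)
        # endpoint at x=0 is a boundary node; nearest point is x=6 < 10 µm away
        junction = add_sprout_connection(net, tip, target)
        assert junction is not None
        jx = net.nodes[junction].x
        assert jx == pytest.approx(10.0)
        for s in net.segments:
            assert net.length(s) >= MIN_SEGMENT_LENGTH - 1e-9

    def test_connection_onto_boundary_node_is_suppressed(self):
        """A tip whose intercept would land on a boundary node is rejected."""
        net, target = straight_vessel(15.0)  # too short to split anywhere
        base = net.add_node(2, 60)
        tip = net.add_node(2, 4)
        net.add_segment(base, tip, 10.0, SPROUT, flowing=False)
        n_before = len(net.segments)
        junction = add_sprout_connection(net, tip, target)
        assert junction is None
        assert len(net.segments) == n_before  # network structurally unchanged

    def test_distant_tip_rejected(self):
        net, target = straight_vessel(100.0)
        tip = net.add_node(50, 30)
        with pytest.raises(StructuralError):
            add_sprout_connection(net, tip, target)

    def test_missing_target_raises(self):
        net, _ = straight_vessel(100.0)
        tip = net.add_node(50, 4)
        with pytest.raises(StructuralError):
            add_sprout_connection(net, tip, 999)


class TestPruning:
    def build_loop_with_branch(self):
        """Boundary--A--(two parallel arcs)--B--boundary, plus a dead-ended twig."""
        net = Network()
        p = net.add_node(0, 0, BOUNDARY, bc_type="pressure", bc_value=50.0)
        a = net.add_node(100, 0)
        t1 = net.add_node(200, 80)
        t2 = net.add_node(200, -80)
        b = net.add_node(300, 0)
        q = net.add_node(400, 0, BOUNDARY, bc_type="pressure", bc_value=10.0)
        s_in = net.add_segment(p, a, 12.0)
        s_up1 = net.add_segment(a, t1, 8.0)
        s_up2 = net.add_segment(t1, b, 8.0)
        s_dn1 = net.add_segment(a, t2, 8.0)
        s_dn2 = net.add_segment(t2, b, 8.0)
        s_out = net.add_segment(b, q, 12.0)
        twig_end = net.add_node(200, 160)
        s_twig = net.add_segment(t1, twig_end, 8.0)
        return net, dict(s_in=s_in, s_up1=s_up1, s_up2=s_up2, s_dn1=s_dn1,
                         s_dn2=s_dn2, s_out=s_out, s_twig=s_twig)

    def test_parallel_branch_survives_prune_of_the_other(self):
        net, s = self.build_loop_with_branch()
        removed = prune_segment(net, s["s_up1"])
        assert s["s_dn1"] in net.segments and s["s_dn2"] in net.segments
        assert s["s_in"] in net.segments and s["s_out"] in net.segments
        # the now dead-ended continuation and the twig cascade away
        assert s["s_up2"] in removed and s["s_twig"] in removed

    def test_dead_end_side_branch_cascades(self):
        net, s = self.build_loop_with_branch()
        removed = prune_segment(net, s["s_twig"])
        assert removed == [s["s_twig"]]
        assert len(net.segments) == 6

    def test_prune_of_feed_removes_everything_flowing(self):
        net, s = self.build_loop_with_branch()
        prune_segment(net, s["s_in"])
        assert not any(seg.flowing for seg in net.segments.values())

    def test_orphan_interior_nodes_removed(self):
        net, s = self.build_loop_with_branch()
        prune_segment(net, s["s_in"])
        for nid, node in net.nodes.items():
            assert net.degree(nid) > 0 or node.kind == BOUNDARY


class TestGeometry:
    def test_branching_angles_of_fresh_perpendicular_sprout(self):
        net = Network()
        a = net.add_node(0, 0)
        b = net.add_node(200, 0)
        m = net.add_node(100, 0)
        net.add_segment(a, m, 10.0)
        net.add_segment(m, b, 10.0)
        t = net.add_node(100, 60)
        net.add_segment(m, t, 10.0)
        angles = sorted(net.branching_angles())
        assert angles == pytest.approx([90.0, 90.0, 180.0])

    def test_symmetric_y_angles(self):
        net = Network()
        c = net.add_node(0, 0)
        for k in range(3):
            th = 2 * math.pi * k / 3
            n = net.add_node(100 * math.cos(th), 100 * math.sin(th))
            net.add_segment(c, n, 10.0)
        assert sorted(net.branching_angles()) == pytest.approx([120.0] * 3)

    def test_angles_sum_to_360_at_any_three_way_node(self, rng):
        for _ in range(20):
            net = Network()
            c = net.add_node(0, 0)
            for th in sorted(rng.uniform(0, 2 * math.pi, size=3)):
                n = net.add_node(100 * math.cos(th), 100 * math.sin(th))
                net.add_segment(c, n, 10.0)
            assert sum(net.branching_angles()) == pytest.approx(360.0)

    def test_distance_to_vessel_trivial_cases(self):
        net, _ = straight_vessel(100.0)
        d = net.distance_to_nearest_vessel(np.array([[50.0, 0.0], [50.0, 25.0]]))
        assert d[0] == pytest.approx(0.0)
        assert d[1] == pytest.approx(25.0)

    def test_distance_matches_brute_force(self, rng):
        net = Network()
        nodes = [net.add_node(*rng.uniform(0, 500, 2)) for _ in range(8)]
        segs = []
        for i in range(7):
            if np.hypot(*(net.position(nodes[i + 1]) - net.position(nodes[i]))) > 10:
                segs.append(net.add_segment(nodes[i], nodes[i + 1], 8.0))
        pts = rng.uniform(0, 500, size=(40, 2))
        fast = net.distance_to_nearest_vessel(pts)
        ids, A, B = net.segment_endpoints()
        for k, p in enumerate(pts):
            brute = min(point_segment_distance(p, A[j : j + 1], B[j : j + 1])[0][0] for j in range(len(ids)))
            assert fast[k] == pytest.approx(brute)


class TestInvariants:
    def test_edits_never_leave_short_segments(self, rng):
        net, target = straight_vessel(100.0)
        for x in (23.0, 61.0, 88.0):
            base = net.add_node(x, 60)
            tip = net.add_node(x, 4)
            net.add_segment(base, tip, 10.0, SPROUT, flowing=False)
            res = net.nearest_segment(net.position(tip), exclude=set(net.segments_at(tip)))
            add_sprout_connection(net, tip, res[0])
        for s in net.segments:
            assert net.length(s) >= MIN_SEGMENT_LENGTH - 1e-9

    def test_pruning_never_increases_total_length(self):
        net = Network()
        p = net.add_node(0, 0, BOUNDARY, bc_type="pressure", bc_value=50.0)
        a = net.add_node(100, 0)
        b = net.add_node(200, 0)
        q = net.add_node(300, 0, BOUNDARY, bc_type="pressure", bc_value=10.0)
        s1 = net.add_segment(p, a, 10.0)
        net.add_segment(a, b, 10.0)
        net.add_segment(b, q, 10.0)
        before = net.total_length()
        prune_segment(net, s1)
        assert net.total_length() <= before

    def test_duplicate_parallel_segments_are_collapsed(self):
        net = Network()
        a = net.add_node(0, 0)
        b = net.add_node(50, 0)
        keep = net.add_segment(a, b, 12.0)
        net.add_segment(a, b, 8.0)
        removed = dedup_parallel_segments(net, [a])
        assert len(removed) == 1
        assert keep in net.segments and len(net.segments) == 1
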