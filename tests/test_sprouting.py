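import math

import numpy as np
import pytest

from angioadapt.network import BOUNDARY, SPROUT, Network, Sprout
from angioadapt.params import AngiogenesisParameters
from angioadapt.sprouting import (
    advance_sprout,
    homing_vector,
    spawn_sprout,
    sprout_formation_probability,
    sprout_rate,
)
from angioadapt.tissue import rectangle_domain
from angioadapt.vegf import VegfState


@pytest.fixture
def params():
    return AngiogenesisParameters()


def parent_vessel(length=200.0):
    net = Network()
    a = net.add_node(0, 200, BOUNDARY, bc_type="pressure", bc_value=50.0)
    b = net.add_node(length, 200, BOUNDARY, bc_type="pressure", bc_value=10.0)
    sid = net.add_segment(a, b, 12.0)
    return net, sid


class TestFormationProbability:
    def test_zero_at_and_below_threshold(self, params):
        assert sprout_formation_probability(0.8, 100.0, params) == 0.0
        assert sprout_formation_probability(0.3, 100.0, params) == 0.0

    def test_saturates_at_maximal_rate_and_caps_at_one(self, params):
        # far above threshold on a 1000 µm segment: k_sprout·L·dt = 2 -> capped
        assert sprout_formation_probability(1e6, 1000.0, params) == 1.0
        assert sprout_rate(1e6, params) == pytest.approx(params.k_sprout, rel=1e-4)

    def test_half_rate_one_half_saturation_above_threshold(self, params):
        c = params.C_th + params.C_th50
        assert sprout_rate(c, params) == pytest.approx(params.k_sprout / 2)


class TestSpawn:
    def test_sample_near_endpoint_attaches_to_that_node(self, params, rng):
        net, sid = parent_vessel()
        seg = net.segments[sid]
        sprout = spawn_sprout(net, sid, 4.0 / 200.0, rng, params)
        # boundary endpoint -> suppressed
        assert sprout is None
        # near an interior node instead
        net2 = Network()
        a = net2.add_node(0, 0)
        m = net2.add_node(100, 0)
        b = net2.add_node(200, 0)
        net2.add_segment(a, m, 10.0)
        s2 = net2.add_segment(m, b, 10.0)
        sp = spawn_sprout(net2, s2, 4.0 / 100.0, rng, params)
        assert sp is not None and sp.attachment_node == m

    def test_existing_branch_point_suppresses(self, params, rng):
        net = Network()
        m = net.add_node(100, 0)
        for pos in ((0, 0), (200, 0), (100, 100)):
            n = net.add_node(*pos)
            net.add_segment(m, n, 10.0)
        sid = net.segments_at(m)[0]
        sp = spawn_sprout(net, sid, 0.02, rng, params)
        assert sp is None

    def test_direction_is_perpendicular_fair_coin(self, params):
        rng = np.random.default_rng(0)
        ups = 0
        trials = 400
        for _ in range(trials):
            net, sid = parent_vessel()
            sp = spawn_sprout(net, sid, 0.5, rng, params)
            assert abs(sp.direction @ np.array([1.0, 0.0])) < 1e-12
            ups += sp.direction[1] > 0
        assert 0.4 < ups / trials < 0.6


class TestHoming:
    def build_sprout(self, tip=(100.0, 100.0), direction=(0.0, 1.0)):
        net = Network()
        a = net.add_node(100, 0)
        b = net.add_node(100, tip[1])
        net.add_segment(a, b, 10.0, SPROUT, flowing=False)
        sp = Sprout(attachment_node=a, tip_node=b, direction=np.array(direction, float))
        return net, sp

    def test_empty_sector_gives_zero(self, params):
        net, sp = self.build_sprout()
        assert np.allclose(homing_vector(net, sp, params), 0.0)

    def test_target_at_sensing_radius_contributes_nothing(self, params):
        net, sp = self.build_sprout()
        c = net.add_node(95, 200.0)   # exactly R_max ahead of the tip
        d = net.add_node(105, 200.0)
        net.add_segment(c, d, 10.0)
        V = homing_vector(net, sp, params)
        assert np.linalg.norm(V) < 1e-3

    def test_symmetric_targets_give_forward_vector(self, params):
        net, sp = self.build_sprout()
        for sign in (-1, 1):
            c = net.add_node(100 + sign * 40, 140)
            d = net.add_node(100 + sign * 40, 160)
            net.add_segment(c, d, 10.0)
        V = homing_vector(net, sp, params)
        assert abs(V[0]) < 1e-9
        assert V[1] > 0


class TestAdvance:
    def test_straight_growth_without_noise_or_targets(self, params):
        net, sp = TestHoming().build_sprout()
        params.sigma_s = 0.0
        dom = rectangle_domain(2000, 2000)
        rng = np.random.default_rng(1)
        ev = advance_sprout(net, sp, dom, params, rng)
        assert ev.outcome == "grew"
        assert net.position(sp.tip_node)[1] == pytest.approx(150.0)
        assert net.position(sp.tip_node)[0] == pytest.approx(100.0)

    def test_homing_rotates_growth_toward_target(self, params):
        net, sp = TestHoming().build_sprout()
        params.sigma_s = 0.0
        # target 30 degrees off-axis inside the sector
        cx = 100 + 60 * math.sin(math.pi / 6)
        cy = 100 + 60 * math.cos(math.pi / 6)
        c = net.add_node(cx, cy - 10)
        d = net.add_node(cx, cy + 10)
        net.add_segment(c, d, 10.0)
        dom = rectangle_domain(2000, 2000)
        before = math.atan2(cx - 100, cy - 100)  # angle of target off +y axis
        advance_sprout(net, sp, dom, params, np.random.default_rng(1))
        after_dir = sp.direction
        ang_to_y = math.atan2(after_dir[0], after_dir[1])
        assert 0 < ang_to_y <= before + 1e-9  # rotated toward the target

    def test_boundary_crossing_suppresses_sprout(self, params):
        net, sp = TestHoming().build_sprout(direction=(0.0, 1.0))
        params.sigma_s = 0.0
        dom = rectangle_domain(300, 130)  # tip at y=100 heading for the wall
        ev = advance_sprout(net, sp, dom, params, np.random.default_rng(1))
        assert ev.outcome == "suppressed"
        assert not sp.active
        assert all(seg.type != SPROUT for seg in net.segments.values())

    def test_connection_event_on_passing_vessel(self, params):
        net, sp = TestHoming().build_sprout()
        params.sigma_s = 0.0
        c = net.add_node(50, 130)
        d = net.add_node(150, 130)
        target = net.add_segment(c, d, 10.0)
        dom = rectangle_domain(2000, 2000)
        ev = advance_sprout(net, sp, dom, params, np.random.default_rng(1))
        assert ev.outcome == "connected"
        assert ev.junction is not None
        # the chain is now flow-eligible capillary
        assert all(seg.type != SPROUT or not seg.flowing for seg in net.segments.values())
        assert not sp.active

    def test_growth_not_biased_by_uniform_vegf(self, params):
        """In a uniform above-threshold field, left/right headings stay symmetric."""
        dom = rectangle_domain(3000, 3000)
        rng = np.random.default_rng(5)
        lateral = []
        for _ in range(120):
            net = Network()
            a = net.add_node(1500, 1400)
            b = net.add_node(1500, 1500)
            net.add_segment(a, b, 10.0, SPROUT, flowing=False)
            sp = Sprout(attachment_node=a, tip_node=b, direction=np.array([0.0, 1.0]))
            advance_sprout(net, sp, dom, params, rng)
            lateral.append(net.position(sp.tip_node)[0] - 1500)
        lateral = np.array(lateral)
        # mean lateral displacement consistent with zero
        assert abs(lateral.mean()) < 3 * lateral.std() / math.sqrt(len(lateral))


def test_expected_sprout_count_matches_rate(rng):
    """Over many seeded trials the formation count is binomial with p = rate·L·dt."""
    from angioadapt.sprouting import try_form_sprout

    params = AngiogenesisParameters()
    dom = rectangle_domain(600, 600)
    C = 5.0  # far above threshold
    conc = np.full(dom.n_points, C)
    veg = VegfState(conc, conc > params.C_th)
    L = 150.0
    p_expected = sprout_formation_probability(C, L, params)
    n = 600
    fired = 0
    for k in range(n):
        net = Network()
        a = net.add_node(200, 300)
        b = net.add_node(200 + L, 300)
        sid = net.add_segment(a, b, 10.0)
        sprout, did = try_form_sprout(net, sid, veg, dom, params, rng)
        fired += did
    # three-sigma binomial band
    sd = math.sqrt(n * p_expected * (1 - p_expected))
    assert abs(fired - n * p_expected) < 3 * sd + 1
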