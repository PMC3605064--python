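import math

import numpy as np
import pytest

from angioadapt import adaptation as ad
from angioadapt import hemodynamics as hd
from angioadapt.fixtures import toy_network
from angioadapt.network import BOUNDARY, Network
from angioadapt.params import AdaptationParameters


@pytest.fixture
def params():
    return AdaptationParameters()


class TestShearSetpoint:
    def test_monotone_increasing(self):
        assert ad.pressure_shear_setpoint(60.0) > ad.pressure_shear_setpoint(25.0)

    def test_saturation_at_arterial_pressure(self):
        assert ad.pressure_shear_setpoint(100.0) / ad.pressure_shear_setpoint(200.0) > 0.9

    def test_continuous_over_pressure_range(self):
        P = np.arange(10.0, 121.0, 1.0)
        tau = ad.pressure_shear_setpoint(P)
        assert np.all(np.isfinite(tau))
        assert np.all(np.abs(np.diff(tau)) < 5.0)
        assert np.all(np.diff(tau) >= 0)


class TestMetabolicSignal:
    def test_reference_and_anoxic_endpoints(self, params):
        assert ad.metabolic_signal_local(params.PO2_ref, params) == 0.0
        assert ad.metabolic_signal_local(0.0, params) == 1.0
        assert ad.metabolic_signal_local(2 * params.PO2_ref, params) == 0.0

    def test_n2_more_sensitive_than_n1_at_low_po2(self, params):
        """The quadratic oxygen exponent steepens the response where it matters."""
        import dataclasses

        p1 = dataclasses.replace(params, N_oxy=1)
        p2 = dataclasses.replace(params, N_oxy=2)
        eps = 0.01

        def slope(p):
            return abs(
                ad.metabolic_signal_local(5.0 + eps, p) - ad.metabolic_signal_local(5.0 - eps, p)
            ) / (2 * eps)

        assert slope(p2) > slope(p1)


class TestConvection:
    def test_zero_signal_everywhere_gives_zero(self, params, y_bifurcation):
        flow = hd.solve_flow(y_bifurcation)
        J = {s: 0.0 for s in flow.flow}
        acc, S_m = ad.convect_metabolic(y_bifurcation, flow, J, params)
        assert all(v == 0.0 for v in acc.values())
        assert all(v == 0.0 for v in S_m.values())

    def test_unbranched_path_accumulates_linearly(self, params, single_segment):
        flow = hd.solve_flow(single_segment)
        sid = next(iter(flow.flow))
        J = {sid: 0.5}
        acc, _ = ad.convect_metabolic(single_segment, flow, J, params)
        assert acc[sid] == pytest.approx(0.5 * single_segment.length(sid))

    def test_diverging_node_conserves_accumulated_flux(self, params, y_bifurcation):
        flow = hd.solve_flow(y_bifurcation)
        J = {s: 0.7 for s in flow.flow}
        acc, _ = ad.convect_metabolic(y_bifurcation, flow, J, params)
        parent = max(flow.flow, key=lambda s: abs(flow.flow[s]))
        daughters = [s for s in flow.flow if s != parent]
        inherited = sum(
            acc[d] - J[d] * y_bifurcation.length(d) for d in daughters
        )
        assert inherited == pytest.approx(acc[parent], rel=1e-9)

    def test_conservation_on_random_meshes(self, params, grid_mesh):
        flow = hd.solve_flow(grid_mesh)
        J = {s: 0.3 for s in flow.flow}
        acc, _ = ad.convect_metabolic(grid_mesh, flow, J, params)
        # total generated equals total arriving at the single outflow
        generated = sum(J[s] * grid_mesh.length(s) for s in flow.flow if abs(flow.flow[s]) > 1e-9)
        outflow_seg = grid_mesh.segments_at(
            next(n for n in grid_mesh.boundary_nodes
                 if grid_mesh.nodes[n].bc_value == 15.0)
        )[0]
        assert acc[outflow_seg] == pytest.approx(generated, rel=1e-9)


class TestConduction:
    def test_half_saturation_at_j01(self, params):
        # S_c = J/(J+J01): by construction equals 1/2 at J = J01
        assert params.J_01 / (params.J_01 + params.J_01) == 0.5

    def test_attenuation_over_length_constant(self, params, single_segment):
        """A source one length-constant upstream arrives attenuated by 1/e."""
        import dataclasses

        net = Network()
        a = net.add_node(0, 0, BOUNDARY, bc_type="pressure", bc_value=50.0)
        m = net.add_node(1000, 0)
        b = net.add_node(2000, 0, BOUNDARY, bc_type="pressure", bc_value=10.0)
        up = net.add_segment(a, m, 10.0)
        down = net.add_segment(m, b, 10.0)
        flow = hd.solve_flow(net)
        p = dataclasses.replace(params, L_c=net.length(down))
        S_m = {up: 0.0, down: 1.0}
        J_c, S_c = ad.conduct_upstream(net, flow, S_m, p)
        # signal measured at the upstream end of `down`, then decayed across it
        own = p.L_c * (1 - math.exp(-net.length(down) / p.L_c))
        assert J_c[down] == pytest.approx(own)
        assert J_c[up] == pytest.approx(own * math.exp(-net.length(up) / p.L_c), rel=1e-9)

    def test_signal_divides_equally_among_upstream_vessels(self, params, parallel_loop):
        flow = hd.solve_flow(parallel_loop)
        venule = max(
            (s for s in flow.flow),
            key=lambda s: flow.node_pressure[flow.downstream_node(parallel_loop, s)] * -1
            if parallel_loop.segments[s].type == "venule"
            else -1e9,
        )
        S_m = {s: (1.0 if parallel_loop.segments[s].type == "venule" else 0.0) for s in flow.flow}
        J_c, _ = ad.conduct_upstream(parallel_loop, flow, S_m, params)
        arms = [s for s in flow.flow if parallel_loop.segments[s].type == "capillary"]
        upstream_arms = [
            s for s in arms
            if flow.node_pressure[flow.downstream_node(parallel_loop, s)]
            < flow.node_pressure[flow.upstream_node(parallel_loop, s)]
        ]
        downstream_pair = [
            s for s in upstream_arms
            if any(
                flow.downstream_node(parallel_loop, s) == flow.upstream_node(parallel_loop, v)
                for v in flow.flow
                if parallel_loop.segments[v].type == "venule"
            )
        ]
        vals = sorted(J_c[s] for s in downstream_pair)
        assert vals[0] == pytest.approx(vals[-1], rel=1e-9)

    def test_saturation_of_conducted_response(self, params, single_segment):
        flow = hd.solve_flow(single_segment)
        sid = next(iter(flow.flow))
        _, S_c = ad.conduct_upstream(single_segment, flow, {sid: 1e9}, params)
        assert 0.999 < S_c[sid] < 1.0


class TestDiameterUpdate:
    def test_zero_stimulus_leaves_diameter(self, single_segment, params):
        flow = hd.solve_flow(single_segment)
        stim = ad.StimulusBreakdown()
        sid = next(iter(flow.flow))
        stim.delta_D[sid] = 0.0
        before = single_segment.segments[sid].diameter
        ad.update_diameters(single_segment, stim, params)
        assert single_segment.segments[sid].diameter == before

    def test_constant_negative_stimulus_shrinks_geometrically(self, params):
        """S_tot = -0.1 with Δt = 1 d, T = 4.5 d multiplies D by (1 - 0.1/4.5)."""
        D = 10.0
        factor = 1 - 0.1 / params.T
        for _ in range(5):
            D_next = D + D * (-0.1) * 1.0 / params.T
            assert D_next / D == pytest.approx(factor)
            D = D_next
        assert D == pytest.approx(10.0 * factor**5)

    def test_deterministic_without_random_component(self, params, parallel_loop):
        """With the k_s perturbation disabled, the update is a pure function."""
        flow = hd.solve_flow(parallel_loop)
        from angioadapt.oxygen import OxygenParameters, solve_oxygen
        from angioadapt.tissue import rectangle_domain

        dom = rectangle_domain(800, 400)
        oxy = solve_oxygen(parallel_loop, flow, dom, OxygenParameters(M0=1.0))
        s1 = ad.compute_stimuli(parallel_loop, flow, oxy.vessel_po2, params, rng=None)
        s2 = ad.compute_stimuli(parallel_loop, flow, oxy.vessel_po2, params, rng=None)
        assert s1.total == s2.total
        assert s1.delta_D == s2.delta_D
        assert all(v == 0.0 for v in s1.random_ks.values())

    def test_signal_decomposition_sums_to_total(self, params, y_bifurcation):
        flow = hd.solve_flow(y_bifurcation)
        from angioadapt.oxygen import OxygenParameters, solve_oxygen
        from angioadapt.tissue import rectangle_domain

        dom = rectangle_domain(700, 500)
        oxy = solve_oxygen(y_bifurcation, flow, dom, OxygenParameters(M0=1.0))
        rng = np.random.default_rng(3)
        stim = ad.compute_stimuli(y_bifurcation, flow, oxy.vessel_po2, params, rng)
        for sid in stim.total:
            recomposed = (
                stim.shear[sid]
                + stim.pressure[sid]
                + stim.metabolic[sid]
                + stim.conducted[sid]
                + stim.random_ks[sid]
                - params.k_shrink
            )
            assert stim.total[sid] == pytest.approx(recomposed, abs=1e-12)

    def test_fixed_diameter_segments_untouched(self, params):
        net = toy_network("shunt_pair")
        flow = hd.solve_flow(net)
        from angioadapt.oxygen import OxygenParameters, solve_oxygen
        from angioadapt.tissue import rectangle_domain

        dom = rectangle_domain(1250, 800)
        oxy = solve_oxygen(net, flow, dom, OxygenParameters(M0=1.0))
        stim = ad.compute_stimuli(net, flow, oxy.vessel_po2, params, None)
        fixed = [s for s, seg in net.segments.items() if seg.fixed_diameter]
        assert all(s not in stim.delta_D for s in fixed)
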