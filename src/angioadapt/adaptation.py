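"""Structural diameter adaptation of flowing segments, and the pruning trigger.

Each flowing segment integrates a total stimulus combining: a wall-shear
term (growth with shear), a pressure term (the shear set-point τ_e(P) rises
with intravascular pressure, shrinking high-pressure vessels), a local
metabolic signal carried downstream by the blood, a conducted metabolic
response propagated upstream along the vessel wall with exponential decay,
and a constant shrinking tendency with a small per-step random component.
Diameters relax on the time scale T; segments falling below the red-cell
passage minimum are pruned together with everything whose flow ceases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .hemodynamics import HemodynamicState
from .network import Network
from .params import AdaptationParameters


class FlowOrientationError(Exception):
    pass


# ------------------------------------------------------------- components
def pressure_shear_setpoint(P, params: Optional[AdaptationParameters] = None):
    """Expected wall shear stress τ_e (dyn/cm²) at intravascular pressure P (mmHg).

    The published sigmoidal correlation of shear with pressure: low plateau
    in the venous range, steep rise through the arteriolar range, saturation
    near 100 dyn/cm² at arterial pressures. Pressures are clipped to
    > 10 mmHg, the domain of the double-log form.
    """
    P = np.maximum(np.asarray(P, dtype=float), 10.0 + 1e-6)
    return 100.0 - 86.0 * np.exp(-5000.0 * np.log10(np.log10(P)) ** 5.4)


def metabolic_signal_local(P_O2, params: AdaptationParameters):
    """Local metabolic stimulus J_m ∈ [0, 1], decreasing with vessel PO2.

    J_m = max(0, 1 − PO2/PO2_ref)^N; N = 2 steepens the response at low PO2
    (|dJ/dP| at low PO2 exceeds the N = 1 case), which protects poorly
    oxygenated vessels from pruning.
    """
    P = np.asarray(P_O2, dtype=float)
    base = np.maximum(1.0 - P / params.PO2_ref, 0.0)
    return base**params.N_oxy


def _flow_dag(net: Network, state: HemodynamicState, min_flow: float = 1e-9):
    """Segments ordered downstream (by falling upstream-node pressure)."""
    sids = [s for s, q in state.flow.items() if abs(q) > min_flow and s in net.segments]
    order = sorted(
        sids,
        key=lambda s: (-state.node_pressure[state.upstream_node(net, s)], s),
    )
    return order


def convect_metabolic(
    net: Network,
    state: HemodynamicState,
    J_m: Dict[int, float],
    params: AdaptationParameters,
) -> Tuple[Dict[int, float], Dict[int, float]]:
    """Accumulate J_m·l_seg downstream with the flow; return (Ĵ, S_m).

    Each segment adds J_m·l_seg to the running flux; at diverging nodes the
    accumulated flux splits in proportion to outflow, at converging nodes it
    sums. S_m = log10(1 + Ĵ/(Q + Q_ref)) saturates with the accumulated
    flux (µm) and falls with local flow (nl/min, reference Q_ref).
    """
    order = _flow_dag(net, state)
    node_in: Dict[int, float] = {}
    acc: Dict[int, float] = {}
    node_outflow: Dict[int, float] = {}
    for sid in order:
        up = state.upstream_node(net, sid)
        node_outflow[up] = node_outflow.get(up, 0.0) + abs(state.flow[sid])
    for sid in order:
        up = state.upstream_node(net, sid)
        down = state.downstream_node(net, sid)
        if state.node_pressure[up] <= state.node_pressure[down]:
            raise FlowOrientationError(f"segment {sid} is not pressure-oriented")
        inherited = node_in.get(up, 0.0) * abs(state.flow[sid]) / node_outflow[up]
        total = inherited + J_m.get(sid, 0.0) * net.length(sid)
        acc[sid] = total
        node_in[down] = node_in.get(down, 0.0) + total
    S_m = {}
    for sid in order:
        S_m[sid] = math.log10(1.0 + acc[sid] / (abs(state.flow[sid]) + params.Q_ref))
    return acc, S_m


def conduct_upstream(
    net: Network,
    state: HemodynamicState,
    S_m: Dict[int, float],
    params: AdaptationParameters,
) -> Tuple[Dict[int, float], Dict[int, float]]:
    """Propagate the conducted response upstream; return (J_c, S_c).

    Each segment injects ∫ S_m·e^(−x/L_c) dx of signal; signals travel
    against the flow decaying as exp(−s/L_c), summing where conducted
    streams meet and dividing equally among multiple upstream vessels.
    J_c is evaluated at the upstream end of each segment;
    S_c = J_c/(J_c + J_01) ∈ [0, 1).
    """
    order = _flow_dag(net, state)
    n_in: Dict[int, int] = {}
    for sid in order:
        down = state.downstream_node(net, sid)
        n_in[down] = n_in.get(down, 0) + 1
    node_sig: Dict[int, float] = {}
    J_c: Dict[int, float] = {}
    for sid in reversed(order):
        down = state.downstream_node(net, sid)
        up = state.upstream_node(net, sid)
        L = net.length(sid)
        decay = math.exp(-L / params.L_c)
        own = S_m.get(sid, 0.0) * params.L_c * (1.0 - decay)
        incoming = node_sig.get(down, 0.0) / max(n_in.get(down, 1), 1)
        J_c[sid] = own + incoming * decay
        node_sig[up] = node_sig.get(up, 0.0) + J_c[sid]
    S_c = {sid: J_c[sid] / (J_c[sid] + params.J_01) for sid in J_c}
    return J_c, S_c


# ------------------------------------------------------------------ update
@dataclass
class StimulusBreakdown:
    shear: Dict[int, float] = field(default_factory=dict)
    pressure: Dict[int, float] = field(default_factory=dict)
    metabolic: Dict[int, float] = field(default_factory=dict)
    conducted: Dict[int, float] = field(default_factory=dict)
    random_ks: Dict[int, float] = field(default_factory=dict)
    total: Dict[int, float] = field(default_factory=dict)
    delta_D: Dict[int, float] = field(default_factory=dict)


def compute_stimuli(
    net: Network,
    state: HemodynamicState,
    vessel_po2: Dict[int, float],
    params: AdaptationParameters,
    rng: Optional[np.random.Generator] = None,
    dt: float = 1.0,
) -> StimulusBreakdown:
    """All stimulus components for the flowing, adaptable segments.

    S_tot = log10(τ_w + τ_ref) − k_p·log10(τ_e(P)) + k_m·(S_m + k_c·S_c)
            − (k_s + ξ),  ξ ~ N(0, Ran_ks²) redrawn per segment per step.
    """
    J_m = {
        sid: float(metabolic_signal_local(vessel_po2.get(sid, 0.0), params))
        for sid in state.flow
        if sid in net.segments
    }
    _, S_m = convect_metabolic(net, state, J_m, params)
    _, S_c = conduct_upstream(net, state, S_m, params)

    out = StimulusBreakdown()
    for sid in sorted(state.flow):
        if sid not in net.segments:
            continue
        seg = net.segments[sid]
        if not seg.flowing or seg.fixed_diameter:
            continue
        tau = state.wall_shear.get(sid, 0.0)
        P_mid = 0.5 * (
            state.node_pressure[seg.n_from] + state.node_pressure[seg.n_to]
        )
        shear = math.log10(tau + params.tau_ref)
        pressure = -params.k_pressure * math.log10(float(pressure_shear_setpoint(P_mid)))
        metabolic = params.k_metabolic * (
            S_m.get(sid, 0.0) + params.k_conducted * S_c.get(sid, 0.0)
        )
        xi = float(rng.normal(0.0, params.ran_ks)) if rng is not None else 0.0
        total = shear + pressure + metabolic - (params.k_shrink + xi)
        out.shear[sid] = shear
        out.pressure[sid] = pressure
        out.metabolic[sid] = params.k_metabolic * S_m.get(sid, 0.0)
        out.conducted[sid] = params.k_metabolic * params.k_conducted * S_c.get(sid, 0.0)
        out.random_ks[sid] = -xi
        out.total[sid] = total
        out.delta_D[sid] = seg.diameter * total * dt / params.T
    return out


def update_diameters(
    net: Network,
    stimuli: StimulusBreakdown,
    params: AdaptationParameters,
) -> List[int]:
    """Apply ΔD = D·S_tot·Δt/T synchronously; return segments to prune (D < D_min)."""
    prune: List[int] = []
    for sid, dD in stimuli.delta_D.items():
        if sid not in net.segments:
            continue
        seg = net.segments[sid]
        seg.diameter = max(seg.diameter + dD, 0.1)
        if seg.diameter < params.D_min:
            prune.append(sid)
    return prune
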