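"""Steady network hemodynamics.

Nodal pressures follow from mass conservation with Poiseuille segment
resistances; the apparent viscosity of blood in each segment follows the
published diameter/hematocrit-dependent empirical laws, and red cells
partition non-uniformly at diverging bifurcations (phase separation). Since
resistance depends on hematocrit, pressures, flows and hematocrits are
iterated to a self-consistent fixed point.

Unit conventions: lengths/diameters µm, pressures mmHg, flows nl/min,
viscosities cP, wall shear stress dyn/cm².
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .network import Network, BOUNDARY
from .params import HemodynamicsParameters

MMHG_PER_PA = 1.0 / 133.322
PA_S_PER_CP = 1e-3
M3_PER_S_PER_NL_MIN = 1e-12 / 60.0

DEFAULT_INFLOW_HEMATOCRIT = 0.4


class ConvergenceError(Exception):
    pass


class SingularSystemError(Exception):
    pass


# ------------------------------------------------------------------ rheology
def segment_resistance(L: float, D: float, eta_app: float) -> float:
    """Poiseuille flow resistance 128ηL/(πD⁴) in mmHg/(nl/min).

    L, D in µm, eta_app in cP.
    """
    if L <= 0 or D <= 0:
        raise ValueError("segment length and diameter must be positive")
    R_si = 128.0 * (eta_app * PA_S_PER_CP) * (L * 1e-6) / (math.pi * (D * 1e-6) ** 4)
    return R_si * M3_PER_S_PER_NL_MIN * MMHG_PER_PA


def _eta_45_invitro(D: np.ndarray) -> np.ndarray:
    return 220.0 * np.exp(-1.3 * D) + 3.2 - 2.44 * np.exp(-0.06 * D**0.645)


def _eta_45_invivo(D: np.ndarray) -> np.ndarray:
    return 6.0 * np.exp(-0.085 * D) + 3.2 - 2.44 * np.exp(-0.06 * D**0.645)


def _shape_C(D: np.ndarray) -> np.ndarray:
    tail = 1.0 / (1.0 + 1e-11 * D**12)
    return (0.8 + np.exp(-0.075 * D)) * (-1.0 + tail) + tail


def relative_viscosity(D, H_D, law: str = "invivo"):
    """Relative apparent viscosity of blood in a tube of diameter D (µm).

    ``law="invitro"`` is the glass-tube fit (Fåhræus–Lindqvist minimum near
    7 µm); ``law="invivo"`` additionally accounts for the endothelial surface
    layer through the (D/(D-1.1))² factor and a steeper low-diameter rise.
    """
    D = np.asarray(D, dtype=float)
    H = np.asarray(H_D, dtype=float)
    if np.any(H >= 1.0) or np.any(H < 0.0):
        raise ValueError("discharge hematocrit must lie in [0, 1)")
    C = _shape_C(D)
    frac = (np.power(1.0 - H, C) - 1.0) / ((1.0 - 0.45) ** C - 1.0)
    if law == "invitro":
        eta = 1.0 + (_eta_45_invitro(D) - 1.0) * frac
    elif law == "invivo":
        wall = (D / (D - 1.1)) ** 2
        eta = (1.0 + (_eta_45_invivo(D) - 1.0) * frac * wall) * wall
    else:
        raise ValueError(f"unknown viscosity law {law!r}")
    return eta


def apparent_viscosity(D, H_D, params: Optional[HemodynamicsParameters] = None):
    """Apparent viscosity in cP (relative viscosity × plasma viscosity)."""
    params = params or HemodynamicsParameters()
    return relative_viscosity(D, H_D, params.viscosity_law) * params.plasma_viscosity


# ------------------------------------------------------------ phase separation
def phase_separation(
    parent_H_D: float,
    parent_D: float,
    daughter_Ds: Tuple[float, float],
    daughter_flows: Tuple[float, float],
) -> Tuple[float, float]:
    """Discharge hematocrits of two daughters at a diverging bifurcation.

    Empirical logit partition law: the red-cell flux fraction into daughter 1
    depends on its blood-flow fraction, the diameter ratio, the feeding
    diameter, and the feeding hematocrit. Red-cell flux is conserved; each
    daughter H_D is clamped to [0, 1] with excess flux redistributed.
    """
    Q1, Q2 = float(daughter_flows[0]), float(daughter_flows[1])
    D1, D2 = float(daughter_Ds[0]), float(daughter_Ds[1])
    if Q1 < 0 or Q2 < 0:
        raise ValueError("daughter flows must be non-negative (oriented out of the parent)")
    Qp = Q1 + Q2
    if Qp <= 0:
        return 0.0, 0.0
    if parent_H_D <= 0:
        return 0.0, 0.0

    FQB = Q1 / Qp
    X0 = 0.4 / parent_D
    if FQB <= X0:
        FQE = 0.0
    elif FQB >= 1.0 - X0:
        FQE = 1.0
    else:
        A = -6.96 * math.log(D1 / D2) / parent_D
        B = 1.0 + 6.98 * (1.0 - parent_H_D) / parent_D
        x = (FQB - X0) / (1.0 - 2.0 * X0)
        logit = A + B * math.log(x / (1.0 - x))
        FQE = 1.0 / (1.0 + math.exp(-logit))

    flux = Qp * parent_H_D
    f1 = FQE * flux
    f2 = flux - f1
    H1 = f1 / Q1 if Q1 > 0 else 0.0
    H2 = f2 / Q2 if Q2 > 0 else 0.0
    # clamp with redistribution so red-cell flux is conserved when possible
    if H1 > 1.0 and Q2 > 0:
        f1 = Q1
        H1 = 1.0
        H2 = min(1.0, (flux - f1) / Q2)
    elif H2 > 1.0 and Q1 > 0:
        f2 = Q2
        H2 = 1.0
        H1 = min(1.0, (flux - f2) / Q1)
    return max(0.0, H1), max(0.0, H2)


# ----------------------------------------------------------------- solution
@dataclass
class HemodynamicState:
    node_pressure: Dict[int, float]
    flow: Dict[int, float]             # signed, positive n_from -> n_to, nl/min
    hematocrit: Dict[int, float]       # discharge hematocrit per segment
    viscosity: Dict[int, float]        # apparent viscosity, cP
    wall_shear: Dict[int, float]       # dyn/cm²
    pressure_drop: Dict[int, float]    # P(n_from) - P(n_to), mmHg
    iterations: int = 0

    def upstream_node(self, net: Network, sid: int) -> int:
        seg = net.segments[sid]
        return seg.n_from if self.flow[sid] >= 0 else seg.n_to

    def downstream_node(self, net: Network, sid: int) -> int:
        seg = net.segments[sid]
        return seg.n_to if self.flow[sid] >= 0 else seg.n_from


def wall_shear_stress(Q: float, D: float, eta_app: float) -> float:
    """τ_w = 32 η |Q| / (π D³) in dyn/cm² (Q nl/min, D µm, η cP)."""
    Q_cgs = abs(Q) * 1e-6 / 60.0          # cm³/s
    eta_cgs = eta_app * 0.01              # poise = dyn s/cm²
    D_cm = D * 1e-4
    return 32.0 * eta_cgs * Q_cgs / (math.pi * D_cm**3)


def _flow_subgraph(net: Network):
    sids = [s for s in sorted(net.segments) if net.segments[s].flowing]
    nids = sorted({net.segments[s].n_from for s in sids} | {net.segments[s].n_to for s in sids})
    return sids, nids


def _solve_pressures(net: Network, sids: List[int], nids: List[int], eta: Dict[int, float]):
    """Linear nodal-pressure solve at fixed viscosities."""
    fixed: Dict[int, float] = {}
    injections: Dict[int, float] = {}
    for nid in nids:
        node = net.nodes[nid]
        if node.kind == BOUNDARY and node.bc_type == "pressure":
            fixed[nid] = float(node.bc_value)
        elif node.kind == BOUNDARY and node.bc_type == "flow":
            injections[nid] = float(node.bc_value)  # positive = inflow
        elif node.kind == BOUNDARY:
            raise SingularSystemError(f"boundary node {nid} has no boundary condition")
    if not fixed:
        raise SingularSystemError("network needs at least one pressure boundary condition")

    free = [n for n in nids if n not in fixed]
    index = {n: k for k, n in enumerate(free)}
    n = len(free)
    rows: List[int] = []
    cols: List[int] = []
    vals: List[float] = []
    rhs = np.zeros(n)
    for nid, q in injections.items():
        rhs[index[nid]] += q

    g = {}
    for sid in sids:
        seg = net.segments[sid]
        gval = 1.0 / segment_resistance(net.length(sid), seg.diameter, eta[sid])
        g[sid] = gval
        u, v = seg.n_from, seg.n_to
        for a, b in ((u, v), (v, u)):
            if a in fixed:
                continue
            i = index[a]
            rows.append(i)
            cols.append(i)
            vals.append(gval)
            if b in fixed:
                rhs[i] += gval * fixed[b]
            else:
                rows.append(i)
                cols.append(index[b])
                vals.append(-gval)
    pressures = dict(fixed)
    if n:
        G = sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))
        P = spsolve(G, rhs)
        if not np.all(np.isfinite(P)):
            raise SingularSystemError("pressure solve produced non-finite values")
        pressures.update({nid: float(P[index[nid]]) for nid in free})
    flows = {}
    for sid in sids:
        seg = net.segments[sid]
        flows[sid] = g[sid] * (pressures[seg.n_from] - pressures[seg.n_to])
    return pressures, flows


def _propagate_hematocrit(
    net: Network,
    sids: List[int],
    nids: List[int],
    pressures: Dict[int, float],
    flows: Dict[int, float],
    min_flow: float,
) -> Dict[int, float]:
    """March discharge hematocrit from inflow boundaries through bifurcations."""
    H: Dict[int, float] = {sid: 0.0 for sid in sids}
    order = sorted(nids, key=lambda n: (-pressures[n], n))
    for nid in order:
        incoming = [s for s in net._adj[nid] if s in H and _flows_into(net, s, nid, flows)]
        outgoing = [
            s
            for s in net._adj[nid]
            if s in H and not _flows_into(net, s, nid, flows) and abs(flows[s]) > min_flow
        ]
        flux_in = sum(abs(flows[s]) * H[s] for s in incoming)
        Q_in = sum(abs(flows[s]) for s in incoming)
        node = net.nodes[nid]
        if node.kind == BOUNDARY and Q_in == 0.0 and outgoing:
            # inflow boundary: hematocrit prescribed there
            Hmix = node.bc_hematocrit if node.bc_hematocrit is not None else DEFAULT_INFLOW_HEMATOCRIT
            Q_in = sum(abs(flows[s]) for s in outgoing)
            flux_in = Hmix * Q_in
        Hmix = flux_in / Q_in if Q_in > 0 else 0.0
        if not outgoing:
            continue
        if len(outgoing) == 1:
            H[outgoing[0]] = min(1.0, Hmix)
            continue
        feed_D = (
            max((net.segments[s].diameter for s in incoming), default=None)
            if incoming
            else None
        )
        if feed_D is None:
            feed_D = max(net.segments[s].diameter for s in outgoing)
        # pairwise in descending-flow order
        rest = sorted(outgoing, key=lambda s: -abs(flows[s]))
        Hp = Hmix
        while len(rest) > 1:
            s1 = rest[0]
            others = rest[1:]
            Q1 = abs(flows[s1])
            Q2 = sum(abs(flows[s]) for s in others)
            D1 = net.segments[s1].diameter
            D2 = math.sqrt(
                sum(abs(flows[s]) * net.segments[s].diameter ** 2 for s in others) / Q2
            )
            h1, h2 = phase_separation(Hp, feed_D, (D1, D2), (Q1, Q2))
            H[s1] = h1
            Hp = h2
            rest = others
        H[rest[0]] = min(1.0, Hp)
    return H


def _flows_into(net: Network, sid: int, nid: int, flows: Dict[int, float]) -> bool:
    seg = net.segments[sid]
    q = flows[sid]
    return (seg.n_to == nid and q > 0) or (seg.n_from == nid and q < 0)


def solve_flow(net: Network, params: Optional[HemodynamicsParameters] = None) -> HemodynamicState:
    """Self-consistent pressures, flows, hematocrits and wall shear stresses."""
    params = params or HemodynamicsParameters()
    sids, nids = _flow_subgraph(net)
    if not sids:
        return HemodynamicState({}, {}, {}, {}, {}, {})

    # components without a pressure reference cannot carry flow; solve the rest
    dead_nodes: set = set()
    for comp in net.flowing_components():
        if not any(
            net.nodes[n].kind == BOUNDARY and net.nodes[n].bc_type == "pressure" for n in comp
        ):
            if any(
                net.nodes[n].kind == BOUNDARY and net.nodes[n].bc_type == "flow" for n in comp
            ):
                raise SingularSystemError(
                    "a network component has flow boundary conditions but no pressure reference"
                )
            dead_nodes |= comp
    dead_sids = [s for s in sids if net.segments[s].n_from in dead_nodes]
    sids = [s for s in sids if s not in set(dead_sids)]
    nids = [n for n in nids if n not in dead_nodes]
    if not sids:
        zero = {s: 0.0 for s in dead_sids}
        return HemodynamicState({n: 0.0 for n in dead_nodes}, zero, dict(zero), dict(zero), dict(zero), dict(zero))

    H = {sid: DEFAULT_INFLOW_HEMATOCRIT for sid in sids}
    flows_prev: Optional[Dict[int, float]] = None
    pressures: Dict[int, float] = {}
    flows: Dict[int, float] = {}
    eta: Dict[int, float] = {}
    for it in range(params.max_outer_iterations):
        eta = {
            sid: float(apparent_viscosity(net.segments[sid].diameter, min(H[sid], 0.99), params))
            for sid in sids
        }
        pressures, flows = _solve_pressures(net, sids, nids, eta)
        H_new = _propagate_hematocrit(net, sids, nids, pressures, flows, params.min_flow)
        # progressive damping: marginal bifurcations can flip which daughter
        # receives red cells, so late iterations damp harder
        d = params.hematocrit_damping
        if it >= 60:
            d = 0.9
        elif it >= 30:
            d = 0.75
        H_next = {sid: (1 - d) * H_new[sid] + d * H[sid] for sid in sids}

        scale = max(max(abs(q) for q in flows.values()), params.min_flow)
        dq = (
            max(abs(flows[s] - flows_prev[s]) for s in sids) / scale
            if flows_prev is not None
            else math.inf
        )
        dh = max(abs(H_next[s] - H[s]) for s in sids)
        H = H_next
        flows_prev = dict(flows)
        if dq < params.flow_tolerance and dh < params.flow_tolerance:
            break
    else:
        # a residual hematocrit flip in one marginal segment is accepted;
        # larger residuals are a genuine failure
        if dq > 10 * params.flow_tolerance or dh > 0.05:
            raise ConvergenceError(
                f"flow/hematocrit loop did not converge in {params.max_outer_iterations} "
                f"iterations (dQ={dq:.3e}, dH={dh:.3e})"
            )

    tau = {
        sid: wall_shear_stress(flows[sid], net.segments[sid].diameter, eta[sid]) for sid in sids
    }
    dp = {
        sid: pressures[net.segments[sid].n_from] - pressures[net.segments[sid].n_to]
        for sid in sids
    }
    for sid in dead_sids:
        flows[sid] = 0.0
        H[sid] = 0.0
        eta[sid] = float(apparent_viscosity(net.segments[sid].diameter, 0.0, params))
        tau[sid] = 0.0
        dp[sid] = 0.0
    for nid in dead_nodes:
        pressures[nid] = 0.0
    return HemodynamicState(pressures, flows, H, eta, tau, dp, iterations=it + 1)


def node_flow_residuals(net: Network, state: HemodynamicState) -> Dict[int, float]:
    """Net flow into each interior node (should vanish at convergence)."""
    out = {}
    for nid in state.node_pressure:
        if net.nodes[nid].kind == BOUNDARY:
            continue
        total = 0.0
        for sid in net._adj[nid]:
            if sid not in state.flow:
                continue
            q = state.flow[sid]
            total += q if net.segments[sid].n_to == nid else -q
        out[nid] = total
    return out
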