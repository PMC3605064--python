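"""Tension-induced lateral migration of network nodes.

Vessels carry longitudinal tension proportional to their diameter; the
resultant at each node pulls it through the interstitium, which yields by
continuous collagen turnover. Below a force threshold nothing moves (this
stabilizes curved vessels); above it nodes migrate at a speed rising to
v_max for a maximally unbalanced node. The mechanism smooths the initial
90°/90°/180° bifurcations toward the observed ~120° distribution, and slowly
shortens the network in the absence of sprouting.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .network import BOUNDARY, MIN_SEGMENT_LENGTH, Network
from .params import MigrationParameters
from .tissue import TissueDomain


def node_tension_force(net: Network, nid: int) -> np.ndarray:
    """Normalized tension resultant f_t = Σ(D_i·e_i)/Σ(D_i) at a node; |f_t| ≤ 1."""
    sids = net.segments_at(nid)
    if not sids:
        raise ValueError(f"node {nid} has no attached segments")
    num = np.zeros(2)
    den = 0.0
    for sid in sids:
        D = net.segments[sid].diameter
        num += D * net.unit_vector(sid, from_node=nid)
        den += D
    return num / den if den > 0 else np.zeros(2)


def migrate_nodes(
    net: Network,
    params: MigrationParameters,
    dt: float = 1.0,
    domain: Optional[TissueDomain] = None,
    fixed_nodes: Optional[set] = None,
) -> Dict[int, float]:
    """Move interior nodes along their tension resultant; returns displacements.

    Speed = v_max·(|f_t| − λ_t)/(1 − λ_t) above the threshold λ_t, zero
    below. All forces are evaluated on the frozen configuration and the
    moves applied synchronously. A move is scaled down so that no incident
    segment drops below the minimum length, and skipped if it would leave
    the tissue domain.
    """
    fixed = fixed_nodes or set()
    moves: Dict[int, np.ndarray] = {}
    for nid, node in net.nodes.items():
        if node.kind == BOUNDARY or nid in fixed or not net._adj[nid]:
            continue
        f = node_tension_force(net, nid)
        mag = float(np.hypot(f[0], f[1]))
        if mag <= params.lambda_t:
            continue
        speed = params.v_max * (mag - params.lambda_t) / (1.0 - params.lambda_t)
        step = speed * dt
        # cap so no incident segment falls below the minimum length
        slack = min(
            (net.length(sid) - MIN_SEGMENT_LENGTH) / 2.0 for sid in net._adj[nid]
        )
        step = min(step, max(slack, 0.0))
        if step <= 0.0:
            continue
        moves[nid] = (f / mag) * step

    applied: Dict[int, float] = {}
    for nid, dx in moves.items():
        node = net.nodes[nid]
        new = np.array([node.x, node.y]) + dx
        if domain is not None and not domain.contains(new):
            continue
        node.x, node.y = float(new[0]), float(new[1])
        applied[nid] = float(np.hypot(dx[0], dx[1]))
    return applied
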