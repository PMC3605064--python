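"""Stochastic sprout formation and persistent-direction elongation.

Sprouts form on existing vessels with a probability per length and time that
is zero below the VEGF threshold C_th and saturates at k_sprout well above
it. They elongate at a fixed rate in small increments, with a per-step
Gaussian randomization of direction (matrix heterogeneity) and filopodia-
mediated attraction toward vessels inside a forward sector, and connect to
any vessel passed within the connection distance. Growth is deliberately
NOT biased up the VEGF gradient: that traps sprouts in hypoxic maxima
instead of letting them bridge to other vessels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Set, Tuple

import numpy as np

from .network import (
    CAPILLARY,
    MIN_SEGMENT_LENGTH,
    SPROUT,
    Network,
    Sprout,
    add_sprout_connection,
    point_segment_distance,
)
from .params import AngiogenesisParameters
from .tissue import TissueDomain
from .vegf import VegfState, local_concentration


# ------------------------------------------------------------- formation
def sprout_rate(C_G, params: AngiogenesisParameters):
    """Sprout formation rate per vessel length (µm⁻¹ day⁻¹).

    Zero at or below the threshold C_th; saturating toward k_sprout with
    half-saturation increment C_th50 above the threshold.
    """
    C = np.asarray(C_G, dtype=float)
    excess = np.maximum(C - params.C_th, 0.0)
    return params.k_sprout * excess / (excess + params.C_th50)


def sprout_formation_probability(C_G: float, segment_length: float, params: AngiogenesisParameters) -> float:
    """Per-step probability that a segment sprouts at the sampled point."""
    p = float(sprout_rate(C_G, params)) * segment_length * params.dt
    return min(p, 1.0)


def spawn_sprout(
    net: Network,
    sid: int,
    t: float,
    rng: np.random.Generator,
    params: AngiogenesisParameters,
) -> Optional[Sprout]:
    """Attach a new sprout at parameter t of a segment.

    Within node_snap_distance of an existing node of the parent the
    attachment is moved to that node; at a boundary node or an existing
    branch point the sprout is suppressed. The initial direction is
    perpendicular to the parent, the sign an even coin flip.
    """
    seg = net.segments[sid]
    L = net.length(sid)
    axis = net.unit_vector(sid)
    if t * L < params.node_snap_distance:
        attach = seg.n_from
    elif (1.0 - t) * L < params.node_snap_distance:
        attach = seg.n_to
    else:
        attach = None

    if attach is not None:
        node = net.nodes[attach]
        if node.kind != "interior" or net.degree(attach) >= 3:
            return None
    else:
        attach = net.split_segment(sid, t)

    normal = np.array([-axis[1], axis[0]])
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return Sprout(attachment_node=attach, tip_node=attach, direction=sign * normal)


def try_form_sprout(
    net: Network,
    sid: int,
    vegf_state: VegfState,
    domain: TissueDomain,
    params: AngiogenesisParameters,
    rng: np.random.Generator,
) -> Tuple[Optional[Sprout], bool]:
    """One sprout-formation trial on a segment.

    A point is sampled uniformly on the segment, the local (interpolated)
    VEGF concentration read, and a Bernoulli trial made with the capped
    probability. Returns (sprout or None, trial_fired) — a fired trial may
    still yield None when the attachment is suppressed.
    """
    t = float(rng.random())
    seg = net.segments[sid]
    a = net.position(seg.n_from)
    b = net.position(seg.n_to)
    point = a + t * (b - a)
    C = local_concentration(vegf_state, domain, point)
    p = sprout_formation_probability(C, net.length(sid), params)
    if rng.random() >= p:
        return None, False
    return spawn_sprout(net, sid, t, rng, params), True


# ---------------------------------------------------------------- homing
def _excluded_segments(
    net: Network, sprout: Sprout, tip_pos: Optional[np.ndarray] = None
) -> Set[int]:
    """Segments a sprout may not connect to: its own chain and, while the
    tip is still close to the attachment, the parent segments there (a tip
    must not immediately re-join its point of origin; further away the
    parent is a legitimate target, otherwise a sprout curving back runs
    along it without ever anastomosing)."""
    excl = set(net.sprout_chain(sprout.tip_node))
    excl |= set(net._adj[sprout.tip_node])
    if sprout.attachment_node in net.nodes:
        near_attach = True
        if tip_pos is not None:
            d = tip_pos - net.position(sprout.attachment_node)
            near_attach = float(np.hypot(d[0], d[1])) < 20.0
        if near_attach:
            excl |= set(net._adj[sprout.attachment_node])
    return excl


def homing_vector(
    net: Network,
    sprout: Sprout,
    params: AngiogenesisParameters,
    exclude: Optional[Iterable[int]] = None,
) -> np.ndarray:
    """Filopodia attraction vector toward vessels in the forward sector.

    V = Σ_segments ∫ f(r)·g(θ)·û dl over the portions of segments with
    r < R_max and |θ| < θ_max, where f(r) = 1 − r/R_max and
    g(θ) = 1 − |θ|/θ_max fall to zero at the sector edge, and û points from
    the tip toward the integration point. Units: µm.
    """
    tip = net.position(sprout.tip_node)
    d = sprout.direction
    excl = set(exclude) if exclude is not None else _excluded_segments(net, sprout)
    V = np.zeros(2)
    for sid, seg in net.segments.items():
        if sid in excl:
            continue
        a = net.position(seg.n_from)
        b = net.position(seg.n_to)
        L = net.length(sid)
        if L <= 0:
            continue
        # quick reject: closest approach beyond R_max
        dist, _ = point_segment_distance(tip, a[None, :], b[None, :])
        if dist[0] >= params.R_max:
            continue
        n_sub = max(1, int(math.ceil(L / 5.0)))
        tm = (np.arange(n_sub) + 0.5) / n_sub
        mids = a[None, :] + tm[:, None] * (b - a)[None, :]
        rel = mids - tip
        r = np.hypot(rel[:, 0], rel[:, 1])
        ok = (r > 1e-9) & (r < params.R_max)
        if not ok.any():
            continue
        rel = rel[ok]
        r = r[ok]
        u = rel / r[:, None]
        cosang = np.clip(u @ d, -1.0, 1.0)
        theta = np.arccos(cosang)
        ok2 = theta < params.theta_max
        if not ok2.any():
            continue
        w = (L / n_sub) * (1.0 - r[ok2] / params.R_max) * (1.0 - theta[ok2] / params.theta_max)
        V += (w[:, None] * u[ok2]).sum(axis=0)
    return V


# ------------------------------------------------------------- elongation
@dataclass
class GrowthEvent:
    outcome: str                      # "grew" | "connected" | "suppressed"
    junction: Optional[int] = None    # node id for connections


def _rotate(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def remove_sprout_chain(net: Network, sprout: Sprout) -> None:
    """Delete a suppressed sprout's non-flowing chain from the network."""
    for sid in net.sprout_chain(sprout.tip_node):
        if sid in net.segments:
            net.remove_segment(sid, drop_orphans=True)
    sprout.active = False


def advance_sprout(
    net: Network,
    sprout: Sprout,
    domain: TissueDomain,
    params: AngiogenesisParameters,
    rng: np.random.Generator,
) -> GrowthEvent:
    """One daily growth step: randomize direction, home, elongate, connect.

    The direction is first rotated by a Gaussian angle (variance σ_s), then
    combined with the homing vector as d' = normalize(d + k_V·V). The tip
    advances V_g·dt in `substep` increments along the fixed daily direction;
    after each increment a vessel within the connection distance triggers a
    connection, and crossing the tissue boundary suppresses the sprout.
    """
    if not sprout.active:
        return GrowthEvent("suppressed")
    d = _rotate(sprout.direction, rng.normal(0.0, math.sqrt(params.sigma_s)))
    V = homing_vector(net, sprout, params)
    combo = d + params.k_V * V
    norm = float(np.hypot(combo[0], combo[1]))
    if norm > 1e-12:
        d = combo / norm
    sprout.direction = d

    start = net.position(sprout.tip_node)
    pos = start.copy()
    n_sub = max(1, int(round(params.V_g * params.dt / params.substep)))
    for k in range(1, n_sub + 1):
        new_pos = pos + params.substep * d
        if domain.crosses_boundary(pos, new_pos):
            remove_sprout_chain(net, sprout)
            return GrowthEvent("suppressed")
        pos = new_pos
        grown = k * params.substep
        if grown < MIN_SEGMENT_LENGTH and not sprout.segments:
            continue  # nothing long enough to connect with yet
        excl = _excluded_segments(net, sprout, tip_pos=pos)
        near = _nearest_other(net, pos, excl)
        if near is not None and near[1] < params.connect_distance:
            tip = _materialize(net, sprout, pos, params)
            junction = add_sprout_connection(
                net, tip, near[0], max_distance=params.connect_distance
            )
            if junction is None:
                remove_sprout_chain(net, sprout)
                return GrowthEvent("suppressed")
            sprout.active = False
            return GrowthEvent("connected", junction=junction)
    _materialize(net, sprout, pos, params)
    return GrowthEvent("grew")


def _nearest_other(net: Network, pos: np.ndarray, excl: Set[int]):
    res = net.nearest_segment(pos, exclude=excl)
    if res is None:
        return None
    return res[0], res[1]


def _materialize(net: Network, sprout: Sprout, pos: np.ndarray, params: AngiogenesisParameters) -> int:
    """Turn the current day's advance into a chain segment; returns tip node."""
    start = net.position(sprout.tip_node)
    adv = float(np.hypot(*(pos - start)))
    if adv < 1e-9:
        return sprout.tip_node
    tip = net.add_node(pos[0], pos[1])
    sid = net.add_segment(sprout.tip_node, tip, params.D_s, SPROUT, flowing=False)
    sprout.segments.append(sid)
    sprout.tip_node = tip
    return tip
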