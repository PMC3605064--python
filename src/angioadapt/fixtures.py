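"""Seed networks: the mesenteric skeleton and small deterministic test nets.

The skeleton emulates the topology class of the observed mesenteric region:
a thin sheet of tissue (area 4.23 mm², thickness 20 µm) bounded by an outer
loop of venules that converge on a single outflow, fed by two arterioles
that enter the interior, with five boundary nodes in total. The observed
geometry itself is not numerically published, so the generator reproduces
the boundary data and topology, not coordinates; initial interior diameters
are plausible mesenteric calibers and configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .network import ARTERIOLE, BOUNDARY, CAPILLARY, VENULE, Network
from .tissue import TissueDomain, rectangle_domain


@dataclass
class SkeletonSpec:
    """Boundary data of the seed skeleton (printed values for the region)."""

    area: float = 4.23e6               # µm²
    thickness: float = 20.0            # µm
    aspect: float = 1.25               # width/height of the rectangular sheet
    arteriole_pressure: float = 59.09  # mmHg, arteriole A
    arteriole_hematocrit: float = 0.3742
    arteriole_po2: float = 75.0        # mmHg, both arterioles
    arteriole_flow: float = 15.0       # nl/min, arteriole B
    venule_inflow: float = 28.1        # nl/min each, two venules
    venule_hematocrit: float = 0.4
    venule_po2: float = 38.0           # mmHg
    outflow_pressure: float = 15.0     # mmHg
    arteriole_D: Tuple[float, float] = (25.0, 12.0)   # µm, entry -> tip taper
    venule_D: Tuple[float, float] = (20.0, 35.0)      # µm, inflow -> outflow
    capillary_D: float = 8.0           # µm, skeleton connecting capillaries
    segment_length: float = 150.0      # µm, target subdivision of paths
    jitter: float = 25.0               # µm, lateral jitter of interior path nodes


def _polyline(
    net: Network,
    start_node: int,
    waypoints: List[Tuple[float, float]],
    diameters: Tuple[float, float],
    vtype: str,
    spec: SkeletonSpec,
    rng: np.random.Generator,
    fixed: bool = False,
    jitter: bool = True,
) -> int:
    """Chain of segments from start through waypoints; returns the final node."""
    pts = [np.array(net.position(start_node))]
    for w in waypoints:
        pts.append(np.asarray(w, dtype=float))
    # subdivide and jitter
    path = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        L = float(np.hypot(*(b - a)))
        n = max(1, int(round(L / spec.segment_length)))
        for k in range(1, n + 1):
            p = a + (b - a) * (k / n)
            if jitter and k < n:
                t = (b - a) / L
                normal = np.array([-t[1], t[0]])
                p = p + normal * rng.uniform(-spec.jitter, spec.jitter)
            path.append(p)
    total = sum(float(np.hypot(*(b - a))) for a, b in zip(path[:-1], path[1:]))
    node = start_node
    run = 0.0
    for a, b in zip(path[:-1], path[1:]):
        run += float(np.hypot(*(b - a)))
        nxt = net.add_node(b[0], b[1])
        D = diameters[0] + (diameters[1] - diameters[0]) * (run / total)
        net.add_segment(node, nxt, D, vtype, fixed_diameter=fixed)
        node = nxt
    return node


def generate_skeleton(
    spec: Optional[SkeletonSpec] = None,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> Tuple[Network, TissueDomain]:
    """Build the five-boundary-node seed skeleton and its tissue domain."""
    spec = spec or SkeletonSpec()
    rng = rng if rng is not None else np.random.default_rng(seed)

    H = math.sqrt(spec.area / spec.aspect)
    W = spec.aspect * H
    domain = rectangle_domain(W, H, thickness=spec.thickness)
    inset = 30.0  # µm: keep the bounding venules just inside the sheet
    net = Network()

    # boundary nodes (exactly five)
    o = net.add_node(W / 2, 0, BOUNDARY, bc_type="pressure", bc_value=spec.outflow_pressure)
    v1 = net.add_node(
        W / 2 - 250, H, BOUNDARY,
        bc_type="flow", bc_value=spec.venule_inflow,
        bc_hematocrit=spec.venule_hematocrit, bc_po2=spec.venule_po2,
    )
    v2 = net.add_node(
        W / 2 + 250, H, BOUNDARY,
        bc_type="flow", bc_value=spec.venule_inflow,
        bc_hematocrit=spec.venule_hematocrit, bc_po2=spec.venule_po2,
    )
    a1 = net.add_node(
        0, 0.55 * H, BOUNDARY,
        bc_type="pressure", bc_value=spec.arteriole_pressure,
        bc_hematocrit=spec.arteriole_hematocrit, bc_po2=spec.arteriole_po2,
    )
    a2 = net.add_node(
        W, 0.6 * H, BOUNDARY,
        bc_type="flow", bc_value=spec.arteriole_flow,
        bc_hematocrit=spec.arteriole_hematocrit, bc_po2=spec.arteriole_po2,
    )

    # bounding venular loop (fixed diameters): both inflows run around the
    # perimeter to the single outflow at bottom-center
    end_left = _polyline(
        net, v1,
        [(inset, H - inset), (inset, inset), (W / 2, inset)],
        spec.venule_D, VENULE, spec, rng, fixed=True, jitter=False,
    )
    net.add_segment(end_left, o, spec.venule_D[1], VENULE, fixed_diameter=True)
    end_right = _polyline(
        net, v2,
        [(W - inset, H - inset), (W - inset, inset), (W / 2 + spec.segment_length, inset)],
        spec.venule_D, VENULE, spec, rng, fixed=True, jitter=False,
    )
    net.add_segment(end_right, end_left, spec.venule_D[1], VENULE, fixed_diameter=True)

    # feeding arterioles reaching into the interior
    tip1 = _polyline(
        net, a1,
        [(0.28 * W, 0.6 * H), (0.4 * W, 0.5 * H)],
        spec.arteriole_D, ARTERIOLE, spec, rng,
    )
    tip2 = _polyline(
        net, a2,
        [(0.72 * W, 0.55 * H), (0.62 * W, 0.45 * H)],
        spec.arteriole_D, ARTERIOLE, spec, rng,
    )

    # minimal capillary connections from the arteriolar tips to the loop
    for tip, xfrac in ((tip1, 0.4), (tip2, 0.62)):
        p = net.position(tip)
        # route down to the bottom venule: find nearest venule segment there
        target_point = np.array([xfrac * W, inset])
        mid = net.add_node(p[0], 0.5 * (p[1] + inset))
        net.add_segment(tip, mid, spec.capillary_D, CAPILLARY)
        res = net.nearest_segment(target_point)
        sid, dist, foot, t = res
        junction = net.split_segment(sid, t)
        net.add_segment(mid, junction, spec.capillary_D, CAPILLARY)
    return net, domain


# ----------------------------------------------------------------- toy nets
def toy_network(kind: str) -> Network:
    """Small deterministic networks with hand-checkable solutions."""
    net = Network()
    if kind == "single_segment":
        a = net.add_node(0, 0, BOUNDARY, bc_type="pressure", bc_value=59.09,
                         bc_hematocrit=0.3742, bc_po2=75.0)
        b = net.add_node(500, 0, BOUNDARY, bc_type="pressure", bc_value=15.0)
        net.add_segment(a, b, 10.0, ARTERIOLE)
    elif kind == "Y_bifurcation":
        a = net.add_node(0, 0, BOUNDARY, bc_type="pressure", bc_value=50.0,
                         bc_hematocrit=0.4, bc_po2=75.0)
        j = net.add_node(300, 0)
        b = net.add_node(600, 200, BOUNDARY, bc_type="pressure", bc_value=15.0)
        c = net.add_node(600, -200, BOUNDARY, bc_type="pressure", bc_value=15.0)
        net.add_segment(a, j, 12.0, ARTERIOLE)
        net.add_segment(j, b, 9.0, CAPILLARY)
        net.add_segment(j, c, 9.0, CAPILLARY)
    elif kind == "parallel_loop":
        a = net.add_node(0, 0, BOUNDARY, bc_type="pressure", bc_value=50.0,
                         bc_hematocrit=0.4, bc_po2=75.0)
        j1 = net.add_node(200, 0)
        t1 = net.add_node(400, 150)
        t2 = net.add_node(400, -150)
        j2 = net.add_node(600, 0)
        b = net.add_node(800, 0, BOUNDARY, bc_type="pressure", bc_value=15.0)
        net.add_segment(a, j1, 12.0, ARTERIOLE)
        net.add_segment(j1, t1, 8.0, CAPILLARY)
        net.add_segment(t1, j2, 8.0, CAPILLARY)
        net.add_segment(j1, t2, 8.0, CAPILLARY)
        net.add_segment(t2, j2, 8.0, CAPILLARY)
        net.add_segment(j2, b, 12.0, VENULE)
    elif kind == "shunt_pair":
        # one short and one long arteriole->venule pathway; the long path
        # runs through remote (hypoxia-prone) tissue. Sized for a ~1 mm²
        # quarter-area domain so metabolic/conducted signal magnitudes are
        # comparable to the full tissue.
        a = net.add_node(0, 650, BOUNDARY, bc_type="pressure", bc_value=59.09,
                         bc_hematocrit=0.3742, bc_po2=75.0)
        j1 = net.add_node(250, 650)
        j2 = net.add_node(1000, 650)
        b = net.add_node(1250, 650, BOUNDARY, bc_type="pressure", bc_value=15.0)
        net.add_segment(a, j1, 20.0, ARTERIOLE, fixed_diameter=True)
        net.add_segment(j1, j2, 12.0, CAPILLARY)      # short shunt, 750 µm
        u1 = net.add_node(300, 250)
        u2 = net.add_node(625, 150)
        u3 = net.add_node(950, 250)
        net.add_segment(j1, u1, 10.0, CAPILLARY)      # long path through
        net.add_segment(u1, u2, 10.0, CAPILLARY)      # remote tissue
        net.add_segment(u2, u3, 10.0, CAPILLARY)
        net.add_segment(u3, j2, 10.0, CAPILLARY)
        net.add_segment(j2, b, 20.0, VENULE, fixed_diameter=True)
    elif kind == "grid_mesh":
        # 3x3 capillary mesh fed at one corner, drained at the other
        nid = {}
        for i in range(3):
            for j in range(3):
                nid[i, j] = net.add_node(100 + 150 * i, 100 + 150 * j)
        for i in range(3):
            for j in range(3):
                if i < 2:
                    net.add_segment(nid[i, j], nid[i + 1, j], 8.0, CAPILLARY)
                if j < 2:
                    net.add_segment(nid[i, j], nid[i, j + 1], 8.0, CAPILLARY)
        a = net.add_node(0, 100, BOUNDARY, bc_type="pressure", bc_value=45.0,
                         bc_hematocrit=0.4, bc_po2=75.0)
        b = net.add_node(500, 400, BOUNDARY, bc_type="pressure", bc_value=15.0)
        net.add_segment(a, nid[0, 0], 12.0, ARTERIOLE)
        net.add_segment(nid[2, 2], b, 12.0, VENULE)
    else:
        raise ValueError(f"unknown toy network kind {kind!r}")
    return net
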