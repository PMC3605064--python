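"""Vascular network graph model and structural edit operations.

The network is a planar graph of nodes (2-D positions in µm) and straight
segments (diameter, vessel type, flow eligibility). Tortuous vessels are
chains of short straight segments; a hard minimum segment length of 10 µm is
maintained by every edit operation, since very short segments destabilize the
convection--diffusion solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

MIN_SEGMENT_LENGTH = 10.0  # µm

INTERIOR = "interior"
BOUNDARY = "boundary"

ARTERIOLE = "arteriole"
CAPILLARY = "capillary"
VENULE = "venule"
SPROUT = "sprout"


class StructuralError(Exception):
    """Raised when an edit refers to a missing node or segment."""


@dataclass
class Node:
    id: int
    x: float
    y: float
    kind: str = INTERIOR
    bc_type: Optional[str] = None      # "pressure" (mmHg) or "flow" (nl/min, + into network)
    bc_value: Optional[float] = None
    bc_hematocrit: Optional[float] = None
    bc_po2: Optional[float] = None

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class Segment:
    id: int
    n_from: int
    n_to: int
    diameter: float
    type: str = CAPILLARY
    flowing: bool = True               # eligible for the flow system (False for sprouts)
    fixed_diameter: bool = False       # True for the bounding venules


@dataclass
class Sprout:
    """An actively growing, non-flowing sprout.

    The traversed path is stored as real (non-flowing) segments in the
    network; this object tracks the tip and growth direction.
    """

    attachment_node: int
    tip_node: int
    direction: np.ndarray              # unit vector
    segments: List[int] = field(default_factory=list)
    active: bool = True


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.hypot(v[0], v[1]))
    if n == 0.0:
        return np.array([0.0, 0.0])
    return v / n


class Network:
    """Mutable microvascular network."""

    def __init__(self) -> None:
        self.nodes: Dict[int, Node] = {}
        self.segments: Dict[int, Segment] = {}
        self._adj: Dict[int, Set[int]] = {}
        self._next_node = 0
        self._next_segment = 0

    # ---------------------------------------------------------------- basics
    def add_node(self, x: float, y: float, kind: str = INTERIOR, **bc) -> int:
        nid = self._next_node
        self._next_node += 1
        self.nodes[nid] = Node(nid, float(x), float(y), kind, **bc)
        self._adj[nid] = set()
        return nid

    def add_segment(
        self,
        n_from: int,
        n_to: int,
        diameter: float,
        type: str = CAPILLARY,
        flowing: bool = True,
        fixed_diameter: bool = False,
    ) -> int:
        if n_from not in self.nodes or n_to not in self.nodes:
            raise StructuralError(f"segment endpoints {n_from},{n_to} must exist")
        if n_from == n_to:
            raise StructuralError("degenerate segment (loop on one node)")
        sid = self._next_segment
        self._next_segment += 1
        self.segments[sid] = Segment(sid, n_from, n_to, float(diameter), type, flowing, fixed_diameter)
        self._adj[n_from].add(sid)
        self._adj[n_to].add(sid)
        return sid

    def remove_segment(self, sid: int, drop_orphans: bool = True) -> None:
        seg = self.segments.pop(sid)
        self._adj[seg.n_from].discard(sid)
        self._adj[seg.n_to].discard(sid)
        if drop_orphans:
            for nid in (seg.n_from, seg.n_to):
                if not self._adj[nid] and self.nodes[nid].kind == INTERIOR:
                    self.remove_node(nid)

    def remove_node(self, nid: int) -> None:
        if self._adj[nid]:
            raise StructuralError(f"node {nid} still has attached segments")
        del self.nodes[nid]
        del self._adj[nid]

    def segments_at(self, nid: int) -> List[int]:
        return sorted(self._adj[nid])

    def degree(self, nid: int) -> int:
        return len(self._adj[nid])

    def other_node(self, sid: int, nid: int) -> int:
        seg = self.segments[sid]
        return seg.n_to if seg.n_from == nid else seg.n_from

    def position(self, nid: int) -> np.ndarray:
        n = self.nodes[nid]
        return np.array([n.x, n.y])

    def length(self, sid: int) -> float:
        seg = self.segments[sid]
        a, b = self.nodes[seg.n_from], self.nodes[seg.n_to]
        return math.hypot(b.x - a.x, b.y - a.y)

    def unit_vector(self, sid: int, from_node: Optional[int] = None) -> np.ndarray:
        """Unit vector along a segment, oriented away from `from_node`."""
        seg = self.segments[sid]
        if from_node is None:
            from_node = seg.n_from
        a = self.position(from_node)
        b = self.position(self.other_node(sid, from_node))
        return _unit(b - a)

    @property
    def boundary_nodes(self) -> List[int]:
        return sorted(n.id for n in self.nodes.values() if n.kind == BOUNDARY)

    def total_length(self, flowing_only: bool = False) -> float:
        """Summed segment length in µm."""
        return sum(
            self.length(s.id)
            for s in self.segments.values()
            if (s.flowing or not flowing_only)
        )

    # ------------------------------------------------------------- geometry
    def segment_endpoints(self, sids: Optional[Sequence[int]] = None):
        """(ids, A, B) arrays for vectorized geometry queries."""
        if sids is None:
            sids = sorted(self.segments)
        ids = np.array(list(sids), dtype=int)
        A = np.empty((len(ids), 2))
        B = np.empty((len(ids), 2))
        for k, sid in enumerate(ids):
            seg = self.segments[sid]
            A[k] = (self.nodes[seg.n_from].x, self.nodes[seg.n_from].y)
            B[k] = (self.nodes[seg.n_to].x, self.nodes[seg.n_to].y)
        return ids, A, B

    def nearest_segment(
        self, point: np.ndarray, exclude: Iterable[int] = ()
    ) -> Optional[Tuple[int, float, np.ndarray, float]]:
        """Closest segment to a point: (sid, distance, foot point, param t)."""
        excl = set(exclude)
        sids = [s for s in self.segments if s not in excl]
        if not sids:
            return None
        ids, A, B = self.segment_endpoints(sids)
        d, t = point_segment_distance(np.asarray(point, float), A, B)
        k = int(np.argmin(d))
        foot = A[k] + t[k] * (B[k] - A[k])
        return int(ids[k]), float(d[k]), foot, float(t[k])

    def distance_to_nearest_vessel(self, points: np.ndarray) -> np.ndarray:
        """Per-point Euclidean distance (µm) to the nearest segment."""
        if not self.segments:
            raise StructuralError("network has no segments")
        ids, A, B = self.segment_endpoints()
        pts = np.atleast_2d(np.asarray(points, float))
        out = np.empty(len(pts))
        for i, p in enumerate(pts):
            d, _ = point_segment_distance(p, A, B)
            out[i] = d.min()
        return out

    def branching_angles(self) -> List[float]:
        """All pairwise angles (degrees) between adjacent directions at 3-way nodes.

        For each degree-3 node the three incident directions are sorted by
        polar angle and the three consecutive gaps reported; they sum to 360.
        """
        out: List[float] = []
        for nid, sids in self._adj.items():
            if len(sids) != 3:
                continue
            dirs = [self.unit_vector(sid, from_node=nid) for sid in sorted(sids)]
            ang = sorted(math.atan2(d[1], d[0]) for d in dirs)
            gaps = [ang[1] - ang[0], ang[2] - ang[1], 2 * math.pi - (ang[2] - ang[0])]
            out.extend(math.degrees(g) for g in gaps)
        return out

    # ------------------------------------------------------ edit operations
    def split_segment(self, sid: int, t: float) -> int:
        """Insert a node at parameter t along a segment; returns the new node id."""
        seg = self.segments[sid]
        a = self.position(seg.n_from)
        b = self.position(seg.n_to)
        p = a + t * (b - a)
        nid = self.add_node(p[0], p[1])
        self.remove_segment(sid, drop_orphans=False)
        self.add_segment(seg.n_from, nid, seg.diameter, seg.type, seg.flowing, seg.fixed_diameter)
        self.add_segment(nid, seg.n_to, seg.diameter, seg.type, seg.flowing, seg.fixed_diameter)
        return nid

    def merge_through_node(self, nid: int) -> int:
        """Replace the two segments at a degree-2 node by one segment."""
        s1, s2 = self.segments_at(nid)
        a = self.other_node(s1, nid)
        b = self.other_node(s2, nid)
        seg = self.segments[s1]
        self.remove_segment(s1, drop_orphans=False)
        self.remove_segment(s2, drop_orphans=False)
        new = self.add_segment(a, b, seg.diameter, seg.type, seg.flowing, seg.fixed_diameter)
        self.remove_node(nid)
        return new

    def sprout_chain(self, tip_node: int) -> List[int]:
        """Segment ids of the non-flowing chain ending at a sprout tip."""
        chain: List[int] = []
        node = tip_node
        prev = None
        while True:
            cands = [s for s in self._adj[node] if self.segments[s].type == SPROUT and s != prev]
            if len(cands) != 1:
                break
            sid = cands[0]
            chain.append(sid)
            node = self.other_node(sid, node)
            prev = sid
            if len(self._adj[node]) != 2:
                break
        return chain

    def flowing_components(self) -> List[Set[int]]:
        """Connected components (node sets) of the flow-eligible subgraph."""
        seen: Set[int] = set()
        comps = []
        for start in self.nodes:
            if start in seen:
                continue
            if not any(self.segments[s].flowing for s in self._adj[start]):
                continue
            comp = {start}
            stack = [start]
            seen.add(start)
            while stack:
                u = stack.pop()
                for sid in self._adj[u]:
                    if not self.segments[sid].flowing:
                        continue
                    v = self.other_node(sid, u)
                    if v not in seen:
                        seen.add(v)
                        comp.add(v)
                        stack.append(v)
            comps.append(comp)
        return comps

    def validate(self) -> None:
        """Check referential and geometric invariants; raise on violation."""
        for seg in self.segments.values():
            if seg.n_from not in self.nodes or seg.n_to not in self.nodes:
                raise StructuralError(f"segment {seg.id} has a dangling endpoint")
            if self.length(seg.id) < MIN_SEGMENT_LENGTH - 1e-6:
                raise StructuralError(
                    f"segment {seg.id} shorter than {MIN_SEGMENT_LENGTH} µm"
                )
        for node in self.nodes.values():
            if node.kind == BOUNDARY and len(self._adj[node.id]) != 1:
                raise StructuralError(f"boundary node {node.id} must have exactly one segment")

    def copy(self) -> "Network":
        import copy as _copy

        return _copy.deepcopy(self)


# ---------------------------------------------------------------- geometry
def point_segment_distance(
    p: np.ndarray, A: np.ndarray, B: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Distances from point p to segments A->B, and the foot parameters t in [0,1]."""
    AB = B - A
    denom = np.einsum("ij,ij->i", AB, AB)
    denom = np.where(denom == 0.0, 1.0, denom)
    t = np.clip(((p - A) * AB).sum(axis=1) / denom, 0.0, 1.0)
    foot = A + t[:, None] * AB
    d = np.hypot(*(p - foot).T)
    return d, t


def dedup_parallel_segments(net: Network, nodes: Iterable[int]) -> List[int]:
    """Collapse same-endpoint duplicate segments around the given nodes.

    Structural edits (junction snapping, merging short chain pieces) can
    produce two straight segments with identical endpoints; geometrically
    they are one vessel, and coincident elements destabilize the transport
    kernels. The wider segment is kept. Returns removed segment ids.
    """
    removed: List[int] = []
    for nid in nodes:
        if nid not in net.nodes:
            continue
        seen: Dict[frozenset, int] = {}
        for sid in list(net._adj[nid]):
            if sid not in net.segments:
                continue
            seg = net.segments[sid]
            key = frozenset((seg.n_from, seg.n_to))
            if key in seen and seen[key] in net.segments:
                keep = seen[key]
                drop = sid
                if net.segments[drop].diameter > net.segments[keep].diameter:
                    keep, drop = drop, keep
                net.remove_segment(drop, drop_orphans=False)
                removed.append(drop)
                seen[key] = keep
            else:
                seen[key] = sid
    return removed


# ------------------------------------------------------- sprout connection
def add_sprout_connection(
    net: Network,
    tip_node: int,
    target_sid: int,
    max_distance: float = 5.0,
) -> Optional[int]:
    """Connect a sprout tip to the nearest point of a target segment.

    The tip node is relocated onto the intercept point, so the final chain
    segment becomes the connecting segment (no sub-minimum connector is ever
    created). The intercept is moved along the target, or snapped to one of
    its endpoint nodes, so that no resulting segment is shorter than the
    10 µm minimum. Returns the id of the junction node, or None if the
    connection is suppressed (intercept at a network boundary node, or
    geometry that cannot honor the minimum length).
    """
    if target_sid not in net.segments:
        raise StructuralError(f"target segment {target_sid} does not exist")
    if tip_node not in net.nodes:
        raise StructuralError(f"tip node {tip_node} does not exist")

    seg = net.segments[target_sid]
    tip = net.position(tip_node)
    a = net.position(seg.n_from)
    b = net.position(seg.n_to)
    L = net.length(target_sid)
    d, t = point_segment_distance(tip, a[None, :], b[None, :])
    if d[0] > max_distance + 1e-9:
        raise StructuralError(
            f"tip is {d[0]:.2f} µm from target; connection requires <= {max_distance} µm"
        )
    t = float(t[0])

    snap_node: Optional[int] = None
    if L < 2 * MIN_SEGMENT_LENGTH:
        # target too short to split anywhere: use the nearer endpoint
        snap_node = seg.n_from if t < 0.5 else seg.n_to
    elif t <= 0.0 or t >= 1.0:
        snap_node = seg.n_from if t <= 0.0 else seg.n_to
    elif t * L < MIN_SEGMENT_LENGTH:
        t = MIN_SEGMENT_LENGTH / L
    elif (1 - t) * L < MIN_SEGMENT_LENGTH:
        t = 1 - MIN_SEGMENT_LENGTH / L

    if snap_node is not None and net.nodes[snap_node].kind == BOUNDARY:
        return None  # suppressed: never connect onto a boundary node

    chain = net.sprout_chain(tip_node)

    if snap_node is None:
        junction = net.split_segment(target_sid, t)
    else:
        junction = snap_node

    # relocate the tip onto the junction: rewire the last chain segment
    tip_segs = list(net._adj[tip_node])
    ok = True
    for sid in tip_segs:
        s = net.segments[sid]
        other = net.other_node(sid, tip_node)
        if other == junction:
            ok = False
            continue
        net.remove_segment(sid, drop_orphans=False)
        new_sid = net.add_segment(other, junction, s.diameter, s.type, s.flowing, s.fixed_diameter)
        if sid in chain:
            chain[chain.index(sid)] = new_sid
        # merge away sub-minimum connector pieces
        if net.length(new_sid) < MIN_SEGMENT_LENGTH:
            if net.degree(other) == 2 and net.nodes[other].kind == INTERIOR:
                merged = net.merge_through_node(other)
                prev = [c for c in chain if c in net.segments and c != new_sid]
                chain = [c for c in chain if c in net.segments]
                if merged not in chain:
                    chain.append(merged)
            else:
                ok = False
    if tip_node in net.nodes and not net._adj[tip_node]:
        net.remove_node(tip_node)
    if not ok and snap_node is None and net.degree(junction) == 2:
        # connection failed after split: undo the split
        net.merge_through_node(junction)
        return None

    # the chain becomes flow-eligible capillaries
    for sid in chain:
        if sid in net.segments:
            s = net.segments[sid]
            s.flowing = True
            if s.type == SPROUT:
                s.type = CAPILLARY
    touched = {junction}
    for sid in chain:
        if sid in net.segments:
            touched.add(net.segments[sid].n_from)
            touched.add(net.segments[sid].n_to)
    dedup_parallel_segments(net, touched)
    return junction


# ------------------------------------------------------------------ pruning
def prune_segment(net: Network, sid: int) -> List[int]:
    """Remove a segment and cascade-remove everything whose flow must cease.

    A flow-eligible segment can only carry flow if it lies on a path between
    two distinct boundary nodes through the flow-eligible subgraph. After the
    removal, components holding fewer than two boundary nodes are dropped and
    dead-end branches trimmed, iteratively. Non-flowing sprout chains survive
    only while their anchor node survives. Returns all removed segment ids.
    """
    removed = [sid]
    net.remove_segment(sid, drop_orphans=False)

    changed = True
    while changed:
        changed = False
        comps = net.flowing_components()
        for comp in comps:
            n_bound = sum(1 for n in comp if net.nodes[n].kind == BOUNDARY)
            if n_bound < 2:
                for n in comp:
                    for s in list(net._adj[n]):
                        if net.segments[s].flowing:
                            net.remove_segment(s, drop_orphans=False)
                            removed.append(s)
                            changed = True
        # trim dead ends: interior nodes with exactly one flow-eligible segment
        # and no non-flowing attachment that could later restore flow
        trimming = True
        while trimming:
            trimming = False
            for nid in list(net.nodes):
                if net.nodes[nid].kind != INTERIOR:
                    continue
                flowing = [s for s in net._adj[nid] if net.segments[s].flowing]
                if len(flowing) == 1 and len(net._adj[nid]) == len(flowing):
                    net.remove_segment(flowing[0], drop_orphans=False)
                    removed.append(flowing[0])
                    trimming = True
                    changed = True

    # drop sprout chains whose anchor vanished, then orphan nodes
    for s in list(net.segments.values()):
        if not s.flowing:
            # a non-flowing chain must ultimately attach to a flowing segment
            if not _chain_is_anchored(net, s.id):
                net.remove_segment(s.id, drop_orphans=False)
                removed.append(s.id)
    for nid in list(net.nodes):
        if not net._adj[nid] and net.nodes[nid].kind == INTERIOR:
            net.remove_node(nid)
    return removed


def _chain_is_anchored(net: Network, sid: int) -> bool:
    """True if a non-flowing segment connects (through other segments) to a flowing one."""
    seen = {sid}
    stack = [net.segments[sid].n_from, net.segments[sid].n_to]
    while stack:
        nid = stack.pop()
        for s in net._adj[nid]:
            if s in seen:
                continue
            if net.segments[s].flowing:
                return True
            seen.add(s)
            stack.append(net.other_node(s, nid))
    return False
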