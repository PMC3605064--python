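"""Network summary statistics: lengths, perfusion, oxygenation, geometry."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .hemodynamics import HemodynamicState
from .network import Network, SPROUT
from .oxygen import OxygenState
from .tissue import TissueDomain


@dataclass
class NetworkSummary:
    total_length_mm: float
    flowing_length_mm: float
    sprout_length_mm: float
    mean_vessel_distance_um: float
    total_inflow_nl_min: float          # all boundary inflows
    arteriolar_inflow_nl_min: float     # inflow through arteriolar boundaries
    mean_tissue_po2_mmHg: float
    hypoxic_fraction_pct: float
    branching_angles_deg: List[float] = field(default_factory=list)
    distance_histogram: Optional[Tuple[np.ndarray, np.ndarray]] = None
    po2_histogram: Optional[Tuple[np.ndarray, np.ndarray]] = None
    angle_histogram: Optional[Tuple[np.ndarray, np.ndarray]] = None

    def to_dict(self) -> dict:
        return {
            "total_length_mm": self.total_length_mm,
            "flowing_length_mm": self.flowing_length_mm,
            "sprout_length_mm": self.sprout_length_mm,
            "mean_vessel_distance_um": self.mean_vessel_distance_um,
            "total_inflow_nl_min": self.total_inflow_nl_min,
            "arteriolar_inflow_nl_min": self.arteriolar_inflow_nl_min,
            "mean_tissue_po2_mmHg": self.mean_tissue_po2_mmHg,
            "hypoxic_fraction_pct": self.hypoxic_fraction_pct,
        }


def boundary_inflows(net: Network, state: HemodynamicState) -> Dict[int, float]:
    """Signed flow (positive into the network) at each boundary node."""
    out = {}
    for nid in net.boundary_nodes:
        sids = net.segments_at(nid)
        total = 0.0
        for sid in sids:
            if sid not in state.flow:
                continue
            q = state.flow[sid]
            seg = net.segments[sid]
            total += q if seg.n_from == nid else -q
        out[nid] = total
    return out


def _histogram(values: np.ndarray, bin_width: float, vmax: Optional[float] = None):
    if len(values) == 0:
        return np.array([0.0, bin_width]), np.array([])
    top = vmax if vmax is not None else float(np.max(values)) + bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    freq, _ = np.histogram(values, bins=edges)
    total = freq.sum()
    return edges, freq / total if total else freq.astype(float)


def summarize(
    net: Network,
    oxygen_state: OxygenState,
    flow_state: HemodynamicState,
    domain: TissueDomain,
    distance_bin: float = 10.0,
    po2_bin: float = 5.0,
    angle_bin: float = 10.0,
) -> NetworkSummary:
    """Full summary of a solved network state."""
    if domain.n_points == 0:
        raise ValueError("tissue domain has no tissue points")
    total = net.total_length() / 1000.0
    flowing = net.total_length(flowing_only=True) / 1000.0
    sprout_len = (
        sum(net.length(s.id) for s in net.segments.values() if s.type == SPROUT and not s.flowing)
        / 1000.0
    )
    dists = net.distance_to_nearest_vessel(domain.points) if net.segments else np.array([])
    inflows = boundary_inflows(net, flow_state)
    total_in = sum(q for q in inflows.values() if q > 0)
    art_in = sum(
        q
        for nid, q in inflows.items()
        if q > 0
        and any(net.segments[s].type == "arteriole" for s in net.segments_at(nid))
    )
    angles = net.branching_angles()
    return NetworkSummary(
        total_length_mm=total,
        flowing_length_mm=flowing,
        sprout_length_mm=sprout_len,
        mean_vessel_distance_um=float(np.mean(dists)) if dists.size else float("nan"),
        total_inflow_nl_min=total_in,
        arteriolar_inflow_nl_min=art_in,
        mean_tissue_po2_mmHg=oxygen_state.mean_tissue_po2,
        hypoxic_fraction_pct=100.0 * oxygen_state.hypoxic_fraction,
        branching_angles_deg=angles,
        distance_histogram=_histogram(dists, distance_bin),
        po2_histogram=_histogram(oxygen_state.tissue_po2, po2_bin),
        angle_histogram=_histogram(np.asarray(angles), angle_bin, vmax=360.0),
    )


def replicate_stats(config, seeds: Sequence[int], setup=None) -> pd.DataFrame:
    """Mean ± s.d. of the final summary over independent seeded runs.

    `setup(config) -> (network, domain)` optionally supplies the starting
    structure (the default is the full seed skeleton). Returns a DataFrame
    indexed by summary field with columns mean/sd/n.
    """
    from .engine import Simulation  # local import: engine depends on metrics

    if len(seeds) < 2:
        raise ValueError("need at least two seeds for replicate statistics")
    rows = []
    for s in seeds:
        cfg = config.__class__.from_dict(config.to_dict())
        cfg.seed = int(s)
        if setup is not None:
            network, domain = setup(cfg)
            sim = Simulation(cfg, network=network, domain=domain)
        else:
            sim = Simulation(cfg)
        sim.run()
        rows.append(sim.final_summary().to_dict())
    df = pd.DataFrame(rows)
    return pd.DataFrame(
        {"mean": df.mean(), "sd": df.std(ddof=1), "n": float(len(seeds))}
    )
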