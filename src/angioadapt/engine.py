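"""Simulation engine: the daily time step and run orchestration.

Each daily step executes, in order: (1) flow and hematocrit solve;
(2) oxygen field; (3) VEGF field; (4) stochastic sprout formation;
(5) sprout elongation and connection; (6) structural adaptation of flowing
segments and pruning; (7) tension-induced migration. Fields therefore
reflect the structure at the start of the day, and structural changes take
hemodynamic effect the following day. The trajectory is a pure function of
(config, seed): a single seed sequence spawns named substreams (sprouting,
growth direction, k_s noise, fixture generation) so that toggling one
mechanism does not shift another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from . import adaptation as adapt
from . import hemodynamics as hd
from . import metrics as met
from . import migration as mig
from . import sprouting as spr
from .fixtures import generate_skeleton
from .network import Network, SPROUT, Sprout, prune_segment
from .oxygen import OxygenState, solve_oxygen
from .params import SimulationConfig, demand_at
from .tissue import TissueDomain
from .vegf import VegfState, solve_vegf


@dataclass
class StepRecord:
    time: float
    total_length_mm: float
    flowing_length_mm: float
    sprout_length_mm: float
    total_inflow_nl_min: float
    arteriolar_inflow_nl_min: float
    mean_tissue_po2_mmHg: float
    hypoxic_fraction_pct: float
    mean_vessel_distance_um: float
    demand: float
    sprouts_formed: int = 0
    sprouts_connected: int = 0
    sprouts_suppressed: int = 0
    segments_pruned: int = 0
    n_segments: int = 0
    n_active_sprouts: int = 0


class SimulationError(Exception):
    pass


class Simulation:
    """Stateful driver for one simulated angiogenesis run."""

    def __init__(
        self,
        config: Optional[SimulationConfig] = None,
        network: Optional[Network] = None,
        domain: Optional[TissueDomain] = None,
    ) -> None:
        self.config = config or SimulationConfig()
        ss = np.random.SeedSequence(self.config.seed)
        kids = ss.spawn(4)
        self.rng_fixture = np.random.default_rng(kids[0])
        self.rng_sprout = np.random.default_rng(kids[1])
        self.rng_direction = np.random.default_rng(kids[2])
        self.rng_ks = np.random.default_rng(kids[3])

        if network is None or domain is None:
            gen_net, gen_dom = generate_skeleton(rng=self.rng_fixture)
            network = network if network is not None else gen_net
            domain = domain if domain is not None else gen_dom
        self.network = network
        self.domain = domain
        self.sprouts: List[Sprout] = []
        self.day = 0.0
        self.records: List[StepRecord] = []
        self.flow_state: Optional[hd.HemodynamicState] = None
        self.oxygen_state: Optional[OxygenState] = None
        self.vegf_state: Optional[VegfState] = None

    # ----------------------------------------------------------------- step
    def solve_fields(self) -> None:
        """Flow, oxygen and VEGF on the current structure."""
        cfg = self.config
        demand = demand_at(cfg.demand_schedule, self.day, cfg.oxygen.M0)
        try:
            self.flow_state = hd.solve_flow(self.network, cfg.hemodynamics)
            self.oxygen_state = solve_oxygen(
                self.network, self.flow_state, self.domain, cfg.oxygen, M0=demand,
                warm_state=self.oxygen_state,
            )
        except Exception as exc:  # annotate with step context
            raise SimulationError(f"field solve failed at day {self.day}: {exc}") from exc
        self.vegf_state = solve_vegf(self.oxygen_state.tissue_po2, self.domain, cfg.vegf)

    def step(self) -> StepRecord:
        cfg = self.config
        self.solve_fields()
        flow, oxy, veg = self.flow_state, self.oxygen_state, self.vegf_state

        formed = connected = suppressed = pruned = 0

        # (4) sprout formation: one trial per non-sprout segment
        if cfg.enable_sprouting:
            for sid in sorted(self.network.segments):
                seg = self.network.segments.get(sid)
                if seg is None or seg.type == SPROUT:
                    continue
                sprout, fired = spr.try_form_sprout(
                    self.network, sid, veg, self.domain, cfg.angiogenesis, self.rng_sprout
                )
                if fired:
                    if sprout is None:
                        suppressed += 1
                    else:
                        formed += 1
                        self.sprouts.append(sprout)

            # (5) elongation / connection
            for sprout in list(self.sprouts):
                if not sprout.active:
                    continue
                event = spr.advance_sprout(
                    self.network, sprout, self.domain, cfg.angiogenesis, self.rng_direction
                )
                if event.outcome == "connected":
                    connected += 1
                elif event.outcome == "suppressed":
                    suppressed += 1
            self.sprouts = [s for s in self.sprouts if s.active]

        # (6) adaptation of flowing segments + pruning
        if cfg.enable_adaptation:
            stimuli = adapt.compute_stimuli(
                self.network, flow, oxy.vessel_po2, cfg.adaptation, self.rng_ks,
                dt=cfg.angiogenesis.dt,
            )
            to_prune = adapt.update_diameters(self.network, stimuli, cfg.adaptation)
            for sid in to_prune:
                if sid in self.network.segments:
                    pruned += len(prune_segment(self.network, sid))
            if pruned:
                tips = {s.tip_node for s in self.sprouts}
                self.sprouts = [
                    s for s in self.sprouts if s.tip_node in self.network.nodes
                ]

        # (7) tension-induced migration (sprout tips advance by growth only)
        if cfg.enable_migration:
            tips = {s.tip_node for s in self.sprouts if s.active}
            mig.migrate_nodes(
                self.network, cfg.migration, dt=cfg.angiogenesis.dt,
                domain=self.domain, fixed_nodes=tips,
            )

        self.day += cfg.angiogenesis.dt
        rec = self._record(formed, connected, suppressed, pruned)
        self.records.append(rec)
        return rec

    def _record(self, formed: int, connected: int, suppressed: int, pruned: int) -> StepRecord:
        net = self.network
        oxy = self.oxygen_state
        dists = (
            net.distance_to_nearest_vessel(self.domain.points)
            if net.segments and self.domain.n_points
            else np.array([np.nan])
        )
        inflows = met.boundary_inflows(net, self.flow_state)
        sprout_len = sum(
            net.length(s.id) for s in net.segments.values() if s.type == SPROUT and not s.flowing
        )
        return StepRecord(
            time=self.day,
            total_length_mm=net.total_length() / 1000.0,
            flowing_length_mm=net.total_length(flowing_only=True) / 1000.0,
            sprout_length_mm=sprout_len / 1000.0,
            total_inflow_nl_min=sum(q for q in inflows.values() if q > 0),
            arteriolar_inflow_nl_min=sum(
                q
                for nid, q in inflows.items()
                if q > 0
                and any(net.segments[s].type == "arteriole" for s in net.segments_at(nid))
            ),
            mean_tissue_po2_mmHg=oxy.mean_tissue_po2,
            hypoxic_fraction_pct=100.0 * oxy.hypoxic_fraction,
            mean_vessel_distance_um=float(np.mean(dists)),
            demand=demand_at(self.config.demand_schedule, self.day - self.config.angiogenesis.dt,
                             self.config.oxygen.M0),
            sprouts_formed=formed,
            sprouts_connected=connected,
            sprouts_suppressed=suppressed,
            segments_pruned=pruned,
            n_segments=len(net.segments),
            n_active_sprouts=len([s for s in self.sprouts if s.active]),
        )

    # ------------------------------------------------------------------ run
    def run(self, days: Optional[int] = None) -> pd.DataFrame:
        horizon = days if days is not None else self.config.days
        for _ in range(int(horizon / self.config.angiogenesis.dt)):
            self.step()
        if not self.records:  # zero-day run: report the initial state
            self.solve_fields()
            self.records.append(self._record(0, 0, 0, 0))
        return self.trajectory()

    def trajectory(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def final_summary(self) -> met.NetworkSummary:
        if self.flow_state is None or self.oxygen_state is None:
            self.solve_fields()
        else:
            # refresh fields for the final structure
            self.solve_fields()
        return met.summarize(self.network, self.oxygen_state, self.flow_state, self.domain)
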