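"""Parameter containers for the angiogenesis/adaptation simulator.

All defaults are the published reference values for rat mesentery. Units are
stated per field; lengths are micrometres, time is days unless noted. The
number of printed decimals does not imply estimation precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


@dataclass
class HemodynamicsParameters:
    """Blood rheology and flow-solver controls.

    The apparent-viscosity and red-cell phase-separation relations are the
    standard published empirical laws; their constants live in the code,
    the choice of law and the solver tolerances live here.
    """

    plasma_viscosity: float = 1.0      # cP; multiplies the relative viscosity
    viscosity_law: str = "invivo"      # "invivo" (ESL-corrected) or "invitro"
    flow_tolerance: float = 1e-4       # relative change in Q and H_D
    max_outer_iterations: int = 100
    hematocrit_damping: float = 0.5    # under-relaxation on H_D updates
    min_flow: float = 1e-9             # nl/min; below this a segment is "no flow"


@dataclass
class OxygenParameters:
    """Blood and tissue oxygen transport parameters."""

    C0: float = 0.5                    # cm3 O2 / cm3 RBC at full saturation
    alpha_eff: float = 3.1e-5          # cm3 O2 cm-3 mmHg-1, effective blood solubility
    P50: float = 38.0                  # mmHg, half-saturation of hemoglobin
    hill_n: float = 3.0                # Hill exponent
    krogh_DOalpha: float = 6e-10       # cm3 O2 cm-1 s-1 mmHg-1 (tissue D*alpha)
    M0: float = 2.0                    # demand, cm3 O2 (100 cm3)-1 min-1
    P_half: float = 1.0                # mmHg, PO2 at half-maximal consumption
    hypoxia_threshold: float = 1.0     # mmHg; tissue below this counts as hypoxic
    arteriole_inflow_po2: float = 75.0  # mmHg
    venule_inflow_po2: float = 38.0    # mmHg
    element_length: float = 10.0       # µm, vessel discretization for sources
    nusselt: float = 3.0               # intravascular transport: constant-Nu model
    blood_DOalpha: float = 6e-10       # cm3 O2 cm-1 s-1 mmHg-1, for the Nu model
    tolerance: float = 0.1             # mmHg, max PO2 change at convergence
    fallback_tolerance: float = 10.0   # mmHg, window-mean drift beyond which the solve fails
    relaxation: float = 0.5
    max_iterations: int = 120
    min_transport_flow: float = 0.05   # nl/min; slower segments carry no convective O2


@dataclass
class VegfParameters:
    """Growth-factor field: hypoxia-dependent release, diffusion, degradation."""

    D_G: float = 1.13e-6               # cm2/s diffusivity
    M_G0: float = 1.97e-3              # pM/s basal release rate
    K_G: float = 2.82e-3               # 1/s degradation rate constant
    C_th: float = 0.8                  # pM sprouting threshold
    C_th50: float = 0.5                # pM half-saturation increment above threshold
    release_po2_scale: float = 20.0    # mmHg; release is basal above this PO2
    release_max_factor: float = 6.0    # anoxic release = factor * basal

    @property
    def L_diff(self) -> float:
        """Diffusion length scale sqrt(D_G/K_G) in µm."""
        import math

        return math.sqrt(self.D_G / self.K_G) * 1e4


@dataclass
class AngiogenesisParameters:
    """Sprout formation, elongation and homing."""

    dt: float = 1.0                    # day, time step
    D_s: float = 10.0                  # µm, diameter of new sprouts
    C_th: float = 0.8                  # pM, threshold VEGF concentration
    C_th50: float = 0.5                # pM, half-saturation increment
    k_sprout: float = 0.002            # µm-1 day-1, maximal sprout formation rate
    V_g: float = 50.0                  # µm/day, elongation rate
    k_V: float = 10.0                  # µm-1, attraction sensitivity toward vessels
    R_max: float = 100.0               # µm, filopodia sensing radius
    theta_max: float = 1.0471975511965976  # rad (π/3), sensing half-angle
    sigma_s: float = 0.1               # rad^2, variance of direction randomization
    substep: float = 5.0               # µm, elongation increment
    connect_distance: float = 5.0      # µm, tip-to-segment connection distance
    node_snap_distance: float = 10.0   # µm, snap new sprout base to nearby node


@dataclass
class AdaptationParameters:
    """Structural diameter adaptation and pruning."""

    tau_ref: float = 0.103             # dyn/cm2, shear-term logarithmic offset
    PO2_ref: float = 93.2              # mmHg, reference for the metabolic signal
    L_c: float = 17300.0               # µm, conducted-response length constant
    Q_ref: float = 0.198               # nl/min, flow reference for metabolic signal
    J_01: float = 1000.0               # µm, conducted-response half-saturation
    k_pressure: float = 0.68           # pressure sensitivity
    k_metabolic: float = 0.70          # metabolic sensitivity (k_m)
    k_conducted: float = 2.45          # conducted sensitivity (k_c)
    k_shrink: float = 2.549            # shrinking tendency (k_s)
    ran_ks: float = 0.1                # s.d. of per-step random component in k_s
    T: float = 4.5                     # day, adaptation time scale
    N_oxy: int = 2                     # oxygen-sensitivity exponent in the metabolic signal
    D_min: float = 3.0                 # µm, pruning threshold (red-cell passage minimum)


@dataclass
class MigrationParameters:
    """Tension-induced lateral migration of nodes."""

    lambda_t: float = 0.05             # normalized-force threshold
    v_max: float = 1.0                 # µm/day, maximum migration speed


@dataclass
class SimulationConfig:
    """Full run configuration: mechanism parameters plus run controls."""

    hemodynamics: HemodynamicsParameters = field(default_factory=HemodynamicsParameters)
    oxygen: OxygenParameters = field(default_factory=OxygenParameters)
    vegf: VegfParameters = field(default_factory=VegfParameters)
    angiogenesis: AngiogenesisParameters = field(default_factory=AngiogenesisParameters)
    adaptation: AdaptationParameters = field(default_factory=AdaptationParameters)
    migration: MigrationParameters = field(default_factory=MigrationParameters)

    days: int = 200                    # run horizon
    seed: int = 0
    demand_schedule: Optional[dict] = None  # {day: M0}; None = constant oxygen.M0
    enable_adaptation: bool = True
    enable_migration: bool = True
    enable_sprouting: bool = True
    output_every: int = 0              # snapshot cadence in days; 0 = never

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        for name, sub in [
            ("hemodynamics", HemodynamicsParameters),
            ("oxygen", OxygenParameters),
            ("vegf", VegfParameters),
            ("angiogenesis", AngiogenesisParameters),
            ("adaptation", AdaptationParameters),
            ("migration", MigrationParameters),
        ]:
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)


def parse_demand_schedule(text: str) -> dict:
    """Parse a demand schedule like ``"0:0.5,50:1.5"`` into {day: M0}."""
    out = {}
    for part in text.split(","):
        day, value = part.split(":")
        out[int(day)] = float(value)
    if 0 not in out:
        raise ValueError("demand schedule must define demand at day 0")
    return out


def demand_at(schedule: Optional[dict], day: float, default: float) -> float:
    """Demand in effect at a given day under a step schedule."""
    if not schedule:
        return default
    applicable = [d for d in schedule if d <= day]
    if not applicable:
        return default
    return schedule[max(applicable)]
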