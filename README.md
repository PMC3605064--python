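# angioadapt

Simulation of adaptive sprouting angiogenesis in thin vascularized tissues
(the rat mesentery is the reference system): how a sparse seed network of
arterioles and venules grows, by stochastic VEGF-driven sprouting, into a
dense disordered mesh, and how structural diameter adaptation, conducted
metabolic signaling, tension-induced vessel migration and pruning then
refine that mesh into a stable, hierarchical, space-filling microvascular
network.

## The model

The tissue is a thin sheet (default 4.23 mm², 20 µm thick) carrying a square
grid of tissue points (50 µm spacing). Each simulated day the model solves,
on the current vessel network:

1. **Network hemodynamics.** Poiseuille segment resistances
   R = 128 η_app L / (π D⁴) with the empirical diameter/hematocrit-dependent
   apparent blood viscosity, nodal-pressure mass balance, and non-uniform
   red-cell partition at diverging bifurcations (phase separation), iterated
   to a self-consistent (P, Q, H_D) state. Wall shear stress τ_w = ΔP·D/(4L).
2. **Oxygen transport.** The steady intravascular/tissue PO₂ field by a
   two-dimensional Green's-function method: vessel elements act as
   distributed sources and tissue points as Michaelis–Menten sinks
   (M = M₀·P/(P₀+P)); blood PO₂ advances along each flow path by
   conservation of the convective flux Q·(H_D·C₀·S(P) + α_eff·P) with Hill
   saturation S(P) = Pⁿ/(Pⁿ+P₅₀ⁿ); an intravascular transport resistance
   separates blood from wall PO₂.
3. **Growth factor.** The VEGF concentration field from hypoxia-dependent
   release (basal when well oxygenated, six-fold basal at anoxia), diffusion
   and first-order degradation: D_G ∇²C − K_G C + M_G(PO₂) = 0, zero-flux
   boundaries. The diffusion length (D_G/K_G)^½ ≈ 200 µm.
4. **Sprouting.** On each vessel a point is sampled uniformly; a sprout
   forms with probability per length and day that is zero below the VEGF
   threshold C_th = 0.8 pM and saturates at k_p = 0.002 µm⁻¹day⁻¹. Sprouts
   start perpendicular to the parent, elongate 50 µm/day in 5 µm steps with
   Gaussian direction noise, are attracted to vessels within a sector
   (radius 100 µm, half-angle π/3) as filopodia would sense them, connect
   to any vessel passed within 5 µm, and are suppressed at the tissue
   boundary. Growth is deliberately not biased up the VEGF gradient.
5. **Structural adaptation.** Each flowing segment integrates
   ΔD/D = S_tot·Δt/T with
   S_tot = log₁₀(τ_w+τ_ref) − k_p·log₁₀(τ_e(P)) + k_m·(S_m + k_c·S_c) − k_s,
   where τ_e(P) is the shear set-point rising with pressure, S_m a
   saturating metabolic signal accumulated downstream with the blood, and
   S_c the conducted response propagated upstream along vessel walls with
   length constant 17.3 mm. Segments below 3 µm (red-cell passage minimum)
   are pruned together with everything whose flow ceases.
6. **Migration.** Vessel tension (∝ diameter) pulls each node with
   normalized force f_t = Σ D_i e_i / Σ D_i; above a threshold the node
   migrates at up to 1 µm/day, remodeling fresh 90°/90°/180° bifurcations
   toward the observed ~120° branching angles.

All parameter defaults are the published reference values for rat mesentery
(see `angioadapt.params`).

## Worked example

```python
from angioadapt import Simulation, SimulationConfig
from angioadapt.fixtures import toy_network
from angioadapt.tissue import rectangle_domain

cfg = SimulationConfig(days=50, seed=3)
cfg.oxygen.M0 = 2.0                       # cm3 O2 / 100 cm3 / min
sim = Simulation(cfg, network=toy_network("shunt_pair"),
                 domain=rectangle_domain(1250, 800))
df = sim.run()
print(df[["time", "total_length_mm", "mean_tissue_po2_mmHg",
          "hypoxic_fraction_pct"]].iloc[[0, 24, 49]])
```

prints (seed 3):

```
    time  total_length_mm  mean_tissue_po2_mmHg  hypoxic_fraction_pct
0    1.0         2.984023             20.543578             26.923077
24  25.0         6.232952             14.272923             36.425339
49  50.0         7.852308             18.475107             29.864253
```

Total vessel length more than doubles as sprouts form and connect; mean
tissue PO₂ first dips while the half-formed mesh steals flow from the
exchange pathways, then recovers as adaptation consolidates functional
routes and prunes redundant ones. With the conducted response weakened
(`cfg.adaptation.k_conducted = 0.5`) the long exchange pathway is lost
instead, only the short arteriovenous shunt survives, and most of the
tissue turns hypoxic.

The full-scale study (the 4.23 mm² five-boundary-node skeleton, 200 days)
runs from the command line:

```bash
angioadapt run --seed 1 --days 200 --demand 2.0 --out run1/
angioadapt run --seed 1 --days 200 --demand 2.0 --no-adaptation --out run_mesh/
```

Expect tens of minutes to a few hours per full run; trajectory CSV, network
exchange tables and VTK snapshots are written to the output directory.

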