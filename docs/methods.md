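# Methods

## Scope and representation

The simulator couples a discrete vessel network to continuum oxygen and
growth-factor fields in a thin (20 µm) two-dimensional tissue sheet. The
network is a planar graph: nodes carry 2-D positions (µm), segments carry a
diameter, a vessel type and a flow-eligibility flag. Tortuosity is
represented by chains of straight segments; every structural edit preserves
a hard minimum segment length of 10 µm, because very short elements
destabilize the convection–diffusion solver. Boundary nodes carry the
hemodynamic boundary conditions (pressure in mmHg or inflow in nl/min, with
inflow hematocrit and inflow PO₂).

The daily step executes: flow/hematocrit solve → oxygen field → VEGF field
→ stochastic sprout formation → sprout elongation and connection →
diameter adaptation and pruning → tension-induced node migration. Fields
therefore describe the structure at the start of the day; structural
changes become hemodynamically active the next day. Adaptation and
migration are applied synchronously from frozen evaluations, so the result
does not depend on iteration order. A single seed sequence spawns four
named substreams (fixture geometry, sprout formation, growth direction,
diameter noise); toggling one mechanism does not shift another's draws, and
a trajectory is a pure function of (configuration, seed).

## Hemodynamics

Segment resistance is Poiseuille, R = 128 η_app L/(π D⁴), converted to
mmHg/(nl·min⁻¹). The apparent viscosity follows the published empirical
diameter/hematocrit laws; both the glass-tube ("invitro") and the
endothelial-surface-layer-corrected ("invivo", default) forms are
implemented, with plasma viscosity 1 cP. Red cells partition at diverging
bifurcations by the empirical logit law (cutoff X₀ = 0.4/D_f, diameter
asymmetry term −6.96·ln(D₁/D₂)/D_f, slope 1 + 6.98(1−H_D)/D_f); red-cell
flux is conserved exactly, with clamping to [0, 1] redistributing any
excess. Junctions with more than two outflows are resolved pairwise in
descending-flow order against the flow-weighted remainder.

Pressures solve the nodal mass balance (sparse reduced system; pressure
boundary nodes eliminated, flow boundary nodes as injections). Because
resistance depends on hematocrit, flows and hematocrits are iterated with
damping 0.5 (progressively 0.75/0.9 after 30/60 sweeps — phase separation
is discontinuous and marginal bifurcations can flip their red-cell
allocation indefinitely) until relative changes fall below 10⁻⁴, at most
100 sweeps. A residual flip (dH ≤ 0.05 in one marginal segment) is accepted
at exhaustion; anything larger raises. Components without a pressure
reference carry no flow and are excluded from the solve.

## Oxygen transport

The steady PO₂ field is a superposition of free-space logarithmic kernels
(per unit sheet thickness): vessel elements (≤ 10 µm) are line sources,
tissue points are square-footprint sinks (50 µm cells, with the exact
uniform-square self-potential on the diagonal), plus one uniform field
whose strength enforces exact net source/sink balance — the closure that a
log kernel requires and the model's approximation of the insulated sheet.
Wall PO₂ is collocated as the average over 8 points of the element's
circumference, matched to blood PO₂ through an intravascular transport
resistance (constant-Nusselt model, Nu = 3, configurable — the effect is
included but no coefficients are published for it).

Consumption is Michaelis–Menten, half-maximal at 1 mmHg. Per outer
iteration the sinks are linearized about the current tissue field and the
coupled linear system (source strengths, tissue PO₂, balance constant)
solved; blood PO₂ is then re-marched along all flow paths. Within an
element the blood relaxes exponentially toward the local wall PO₂ with rate
g_ex/(Q·dc/dP) evaluated at the blood PO₂ — an integrated exchange step
that can never overshoot the wall value, however flat the Hill curve. The
wall-matching rows use the resistance implied by that same integrated
exchange, so solved source strengths equal delivered convective fluxes (the
global balance then closes to well under 1%). Mixed-node PO₂ is recovered
by inverting the flux–content relation (safeguarded Newton). Segments
carrying less than 0.05 nl/min are treated as non-transporting: their blood
equilibrates with the surrounding tissue and they contribute no convective
supply.

Convergence: the joint (blood, tissue) fixed point is accelerated by
Anderson mixing (memory 5, mixing 0.5); strict convergence is a maximum
change below 0.1 mmHg. In marginal, strongly hypoxic networks the discrete
depletion front is genuinely non-contractive (the flux floor at zero flips
whole elements) and the iteration enters a limit cycle; the solver then
accepts the mean over a 24-iterate window once two successive window means
of the tissue field agree (≤ 1 mmHg on average, ≤ 10 mmHg at isolated flip
points), flags the state `converged=False`, and otherwise performs one cold
restart with a doubled budget before failing. Daily remodeling is
insensitive to this residual chatter, which is far smaller than the
day-to-day changes produced by growth itself. At scale the linear systems
are solved by GMRES preconditioned with a stale LU refactored on demand,
and each day warm-starts from the previous day's fields.

## VEGF

The modified-Helmholtz balance D_G ∇²C − K_G C + M_G(PO₂) = 0 is
discretized with the 5-point Laplacian on the 50 µm tissue lattice
(zero-flux boundaries; for a 2-D sheet the cell size cancels) and solved
sparsely — at this grid size a kernel superposition buys nothing. Release
is basal above 20 mmHg tissue PO₂ and rises linearly to six-fold basal at
anoxia, so steady uniform concentrations span M_G0/K_G ≈ 0.7 pM to
6·M_G0/K_G ≈ 4.2 pM; the threshold parameters are in pM (the attainable
range makes any other unit unusable). Sprout-site concentrations are
bilinear interpolations of the grid field.

## Sprouting, adaptation, migration: adopted functional forms

Several response functions are only constrained by their qualitative
properties (threshold, saturation, monotonicity, endpoint values); the
forms adopted here are:

- sprout formation rate: k_p·(C−C_th)/((C−C_th)+C_th50) above C_th, zero
  below; one uniform-point trial per segment per day, probability
  rate·L·Δt capped at 1;
- filopodia attraction weights: f(r) = 1 − r/R_max, g(θ) = 1 − |θ|/θ_max
  (the specific shapes are immaterial provided they vanish at the sector
  edge); line integrals by midpoint quadrature on ≤ 5 µm sub-elements; the
  direction update is d' ∝ d + k_V·V after a Gaussian rotation of variance
  σ_s = 0.1 rad²;
- local metabolic signal: J_m = max(0, 1 − PO₂/PO₂_ref)^N with N = 2 — the
  quadratic exponent is more sensitive at low PO₂ than N = 1, which is what
  protects poorly oxygenated vessels from pruning;
- downstream metabolic signal: each segment adds J_m·l_seg to a running
  flux carried with the blood (split ∝ outflow at diverging nodes, summed
  at converging ones); S_m = log₁₀(1 + Ĵ/(Q + Q_ref)) with Ĵ in µm and Q,
  Q_ref in nl/min. With this normalization the printed sensitivities
  (k_m = 0.70, k_c = 2.45, k_s = 2.549) produce stable vessel diameters; a
  fully non-dimensionalized variant (Ĵ/(Q/Q_ref+1)) weakens the metabolic
  drive by two orders of magnitude and every vessel collapses;
- conducted response: each segment injects ∫S_m e^(−x/L_c)dx, signals
  travel upstream decaying as exp(−s/L_c), summing where conducted streams
  merge and dividing equally among multiple upstream vessels;
  S_c = J_c/(J_c + J_01);
- total stimulus: S_tot = log₁₀(τ_w + τ_ref) − k_p·log₁₀(τ_e(P)) +
  k_m·(S_m + k_c·S_c) − (k_s + ξ), ξ ~ N(0, 0.1²) redrawn per segment per
  day; τ_e(P) = 100 − 86·exp(−5000·(log₁₀log₁₀P)^5.4) clipped to P > 10
  mmHg. The τ_ref offset keeps zero-flow segments strongly shrinking
  instead of singular.

Sprout connections relocate the tip onto the intercept point (moved along
the target, or snapped to an endpoint node, so no segment drops below
10 µm; connection onto a boundary node suppresses the sprout); the chain
then becomes flow-eligible capillary. The parent segment is excluded as a
connection target only within 20 µm of the attachment, so a sprout curving
back can anastomose rather than run coincident with its parent; structural
edits deduplicate same-endpoint parallel segments, which otherwise
degenerate the transport kernels. Pruning removes the sub-threshold segment
(D < 3 µm, strictly), then everything not on a path between two distinct
boundary nodes through the flow-eligible subgraph — this operationalizes
"flow ceases" without a flow solve; the rare zero-flow loop this misses
shrinks and is pruned within a few days anyway. Node migration speed is
v_max·(|f_t|−λ_t)/(1−λ_t), the proportionality fixed by requiring v_max at
the maximal imbalance |f_t| = 1; displacements are capped by the minimum
segment length and domain containment. Sprout tips move by growth only;
all other interior nodes, including non-branching ones, migrate.

## Seed networks and the synthetic skeleton

The observed mesenteric geometry is not numerically published, so the
skeleton generator reproduces its topology class and boundary data, not
coordinates: a rectangular sheet of area 4.23 mm² bounded by a
fixed-diameter venular loop converging on one outflow (15 mmHg), two
feeding arterioles (one at 59.09 mmHg with inflow hematocrit 0.3742, one at
15 nl/min; both 75 mmHg PO₂), two venular inflows (28.1 nl/min, hematocrit
0.40, 38 mmHg PO₂) — five boundary nodes in total — and minimal capillary
connections so the seed is perfused. Interior path nodes receive seeded
lateral jitter; generation is bit-reproducible per seed. Initial interior
calibers (arterioles 25→12 µm, venules 20→35 µm, capillaries 8 µm) are
plausible mesenteric values and configurable; the unstated second
arteriole's inflow hematocrit is set to 0.3742 like the first.

The `shunt_pair` test fixture is one short and one long arteriole→venule
pathway in a ~1 mm² sheet, with fixed-diameter feed and drain segments
standing for the off-domain supply. Its size matters: the downstream
metabolic flux Ĵ scales with vessel mass, and far below ~1 mm² no vessel
can accumulate enough signal to survive, so the weak-conduction comparison
degenerates to total collapse instead of shunt persistence.

## Problem sizes used in the test suite

Unit and oracle tests run on toy networks and ≤ 1 mm² domains. The
mechanism-contrast simulations (conducted-response knockout, migration
on/off, sprout-rate halving, adaptation knockout) use the ~1 mm²
`shunt_pair` fixture over 40–60 days — large and long enough for the
contrasts to express while a complete run takes minutes. Full-scale studies
(4.23 mm², 200 days, replicate seeds) are performed through the CLI; they
take tens of minutes to hours each, comparable to the reference
implementation's reported cost, and are not part of the automated suite.

## What the synthetic conditions do and do not show

The generator emulates the boundary data, domain size and parameter set of
the reference preparation, but not its exact seed geometry; quantitative
network statistics (total length, mean nearest-vessel distance, total flow)
therefore carry the geometry's imprint and are reproduced as orders and
contrasts rather than point values. Passing tests demonstrate the coupled
mechanisms — over-abundant growth with later refinement, shunt suppression
by conducted signaling, branch-angle remodeling by migration, and the
sprout-rate dependence of the density overshoot — not agreement with any
particular animal's vasculature. Real tissues are three-dimensional, have
heterogeneous demand and multiple growth factors; none of that is modeled.

## Known limitations

- Oxygen fields in marginal networks are accepted as limit-cycle means (see
  above); the residual per-point uncertainty is a few mmHg at depletion
  fronts.
- The free-space-plus-constant boundary closure underestimates PO₂ near
  sheet corners relative to a strictly insulated sheet by up to a few mmHg.
- Hematocrit at junctions of more than three vessels uses a pairwise
  reduction of the two-daughter partition law.
- Non-flowing sprouts persist indefinitely until they connect or are
  orphaned by pruning; no retirement rule is applied.
- Conducted signals are attributed at a segment's upstream end; within a
  segment the decay of its own injection uses the exact integral.
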