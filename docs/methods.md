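# Methods

## Scope and model structure

`strokeflow` couples three components:

1. **Network assembly** — a fixed large-vessel anatomy (heart to the circle
   of Willis, plus cerebellar/brainstem branches) described by a packaged
   parameter table of 55 named segments, extended at the six major cerebral
   arteries (left/right ACA, MCA, PCA) by donor cerebral trees.  Donor trees
   may come from a tabulated centreline dataset (id, parent, length, mean
   radius, major-artery label) or from the packaged synthetic generator.
2. **1D pulsatile blood flow** — cross-sectionally averaged mass and
   momentum balance on every segment, closed by an elastic tube law, with
   characteristic junction coupling, a prescribed periodic inflow at the
   ascending aorta, and a calibrated three-element windkessel at every
   outlet.  A clot is a reflective internal face.
3. **Perfusion-territory mapping** — each cerebral outlet claims a
   connected, Murray-sized set of triangles on a labelled pial-surface mesh;
   the outlet's cycle-averaged flow is spread uniformly over its territory.

## Governing equations

With cross-sectional area `A(x,t)`, mean axial velocity `v(x,t)` and static
pressure `p(x,t)`:

    dA/dt + d(Av)/dx = 0
    dv/dt + (2α−1) v dv/dx + (α−1)(v²/A) dA/dx + (1/ρ) dp/dx
          = − 2απμ v / ((α−1) ρ A)

where `ρ = 1050 kg/m³`, `μ = 3.5 mPa·s` and the momentum correction factor
`α = 1.1` reflect a blunted velocity profile.  Note the drag coefficient
implied by this form is `2α/(α−1)·π μ = 22π μ` at `α = 1.1`, considerably
stronger than the `8π μ` of a parabolic (Poiseuille) profile; we keep the
form as written because the steady network resistances and the windkessel
calibration were built around it.  Lumped (Poiseuille) resistances used in
calibration deliberately use `8 μ L/(π r⁴)`: they describe the *appended*
resistance of small vessels in the classical sense and their absolute scale
is immediately compensated by the outlet calibration.

The tube law is the thin-walled elastic membrane relation

    p = p_ref + (β/A₀)(√A − √A₀),     β = √π E h / (1 − ν²)

per segment, with `p_ref` the diastolic pressure (so `A = A₀` at rest),
`ν = 0.5`, and the wall thickness from the empirical two-exponential fit
`h = r₀ [a e^{b r₀} + c e^{d r₀}]` (`a = 0.2802`, `b = −0.5053 /mm`,
`c = 0.1324`, `d = −0.01114 /mm`).  The local wave speed is
`c = √(β √A / (2 ρ A₀))`.

## Numerics

* **Scheme.**  Explicit MacCormack predictor–corrector (second order in
  space and time) on uniform per-segment grids: node count
  `max(3, ceil(L/10 mm) + 1)`.  The viscous drag is integrated explicitly
  inside both stages; the stiffest case in the default anatomy (pontine
  branches, `r = 0.2 mm`) has a drag time constant ≈ 9 time steps, well
  inside the explicit stability region.
* **Time step.**  Global CFL step `dt = 0.8 · min(Δx / (|v| + c))`,
  re-evaluated every step and clipped to land exactly on the snapshot
  phases (default 100 per cycle).
* **Junctions.**  At every junction the unknown end states `(A_e, v_e)`
  satisfy: one extrapolated Riemann invariant `v ± 4c` per end (first-order
  foot-point interpolation along the characteristic, including the drag
  source), zero net mass flux, and continuity of total pressure
  `p + ρv²/2`.  The 2E×2E system is solved by Newton–Raphson (analytic
  Jacobian, unknowns scaled by `A₀`, tolerance 1e−11 on the scaled
  residual, warm-started from the previous step; typically 2–3 iterations).
  Junction arity is arbitrary; the basilar junctions carry up to 7 ends.
* **Inlet.**  A prescribed volumetric waveform `Q(t)`, combined with the
  incoming characteristic, fixes `(A, v)` at the first node.  The default
  template is a half-sine systolic ejection over the first third of the
  cycle, tabulated and normalized so one beat integrates exactly to one
  stroke volume; any sampled waveform can be substituted.  Cycle-averaged
  flows are insensitive to this shape; pulsatility indices are not, and PI
  results are therefore reported as template-dependent.
* **Outlets.**  Three-element windkessel per outlet, `p = p_c + Q R₁` with
  `C dp_c/dt = Q − (p_c − p_ven)/R₂`, integrated implicitly (implicit
  Euler) at the PDE time step for unconditional stability, and coupled to
  the tube through the outgoing characteristic (scalar Newton in `A`).
* **Initial state and convergence.**  Zero velocity and diastolic pressure
  everywhere (exactly the tube-law reference state).  Whole cycles are
  repeated until the Euclidean norm of the cycle-to-cycle pressure change,
  over all nodes at 100 stored phases, drops below 1e−3 (relative); the
  default run needs 8 cycles, with a hard cap of 20 (warning + partial
  result beyond it).
* **Audits.**  Area positivity is asserted on every accepted step;
  junction failures and numerical blow-ups abort with the segment/junction
  named.

## Windkessel calibration

Total peripheral resistance and compliance follow from the cardiac
parameters: `R_tot = ((1/3)P_sys + (2/3)P_dia)/(SV·HR)` (mean arterial
pressure over cardiac output) and `C_tot = τ/R_tot` with `τ = 1.34 s` the
aortic pressure decay time.  The volume compliance already resolved by the
1D network, `C_1D = Σ 2 A₀^{3/2} L/β` (the tube-law `dV/dp` at rest), is
subtracted before distribution.

Cardiac output fractions per body part: 65% thoracic aorta, 5% per
brachial artery, and the remaining 25% shared by all head and neck outlets.
Within a body part, outlet resistances follow Murray's law,
`R_T = (R_tot/CO_f) · (Σ_j r_j³)/r_i³`, which makes the group's parallel
conductance exactly `CO_f/R_tot` regardless of how many outlets it has.
For cerebral outlets the serial Poiseuille resistance of the appended donor
path is subtracted (the 1D solver resolves those vessels explicitly),
floored at `0.1 R_T` with a warning.  Compliance is distributed as
`C = (C_tot − C_1D) R_tot/R_T`, so the outlet compliances sum to the free
compliance.  `R₁` is the characteristic impedance `ρc₀/A₀` of the terminal
vessel — the reflectionless choice — and `R₂ = R_T − R₁` (clamped to
`0.05 R_T` with a warning for degenerate small outlets); venous pressure
(2500 Pa) is the distal pressure of every windkessel.

Default cardiac/blood parameters: HR 60 min⁻¹, SV 70 ml, P_sys 17300 Pa,
P_dia 10100 Pa, τ 1.34 s, venous 2500 Pa, ρ 1050 kg/m³, μ 0.0035 Pa·s,
α 1.1, ν 0.5.

## Synthetic cerebral trees

The generator emulates the *scale* and *scaling law* of real cerebral
centreline datasets without their geometry: recursive bifurcation with
`r_p^γ = r₁^γ + r₂^γ` (γ = 3, Murray), child ratio `r₁/r₂` drawn uniformly
from `[asymmetry, 1]` per bifurcation (default `asymmetry = 0.8`, a mild
realistic bifurcation asymmetry; `asymmetry = 1` gives the symmetric,
fully deterministic tree), segment length `20·r` (a mid-range
length-to-radius ratio for distal cerebral branches), terminating when the
radius falls below 0.4 mm.  With the default trunk radii this yields
roughly 260 pial outlets (≈ 65 per MCA, ≈ 33 per ACA/PCA tree, varying
with the seed) of radius 0.32–0.40 mm — the right order of magnitude for a
centreline dataset.  Radii at
attachment are rescaled by a single per-subtree factor
`r_patient/r_donor-trunk`, preserving intra-tree ratios.

What the generator does *not* emulate: 3D vessel positions (the 1D model
only consumes length and radius), side branches off a trunk
(bifurcations only), vessel tortuosity, and inter-subject topological
variability beyond the radius-split randomness.  Passing tests therefore
demonstrate correctness of the solver and the scaling machinery under a
realistic size distribution, not anatomical fidelity of any single tree.

## Clot model

A clot at fractional position `s` of a segment enforces `v = 0` and
`∂p/∂x = 0` (a reflective wall) at the nearest grid face, and severs every
segment unreachable from the inlet without crossing it.  Severed outlets
report zero mean flow at venous pressure.  Because the communicating
arteries of the CoW form loops, a clot there severs nothing and simply
removes one path; the junction bookkeeping handles both cases.  The distal
stub of a mid-segment clot is dropped from the integration (its volume is a
few μl and it exchanges no flow); partial or permeable clots are out of
scope.

## Perfusion territories

The pial surface is a near-uniform triangulated mesh with one major-region
label per triangle (L/R ACA, MCA, PCA, cerebellum, brainstem).  Triangle
adjacency (shared vertex) with Euclidean centre-to-centre weights defines
the surface graph; distances are Dijkstra geodesics (a Euclidean option
exists for flat patches).  Within each region:

1. fractions `f_i = r_i³/Σr_j³` and triangle budgets `n_i` (largest-
   remainder rounding, every outlet ≥ 1, deterministic low-index
   tie-break);
2. outlets are projected to initial root triangles — by nearest triangle
   when 3D coordinates exist, otherwise by a deterministic hash of the
   outlet id (the network data model carries no centreline positions: this
   is the package's largest deliberate departure from image-based inputs);
3. all clusters grow simultaneously from their roots, each claim being the
   globally cheapest root-distance among frontier triangles, so claims
   interleave by distance and territories stay connected by construction;
   walled-in deficits are then repaired by connectivity-preserving boundary
   moves that restore the exact budgets;
4. each root moves to its cluster's 1-centre (minimax geodesic distance);
5. steps 2–4 iterate until the assignment repeats (stable point or limit
   cycle), capped at 50 rounds.

The synthetic pial mesh is a subdivided icosphere (subdivision 4 → 5120
triangles, radius 70 mm) partitioned into eight contiguous regions (lower
caps for brainstem/cerebellum; anterior/middle/posterior sectors per
hemisphere, MCA largest), with a small seed-controlled rotation of the
labelling frame and a cleanup pass that keeps every region connected.  It
reproduces the area proportions and uniform triangulation that the
clustering relies on, not cortical folding — mismatches caused by real
folded surfaces are outside what these tests can show.

Flow mapping: triangle flow = outlet flow × (triangle area / territory
area); flux (flow per area) is uniform within each territory.

## Design choices where the design was open

* Communicating-artery loops are represented as an undirected multigraph;
  no acyclicity is assumed, and signs follow each segment's
  heart-to-periphery orientation (so basilar/P1 flows print positive here
  where an opposite orientation convention would print them negative).
* The basilar chain hosts the twelve pontine branches three at a time at
  its four internal junctions; AICA branches at the proximal basilar
  junction, SCA at the top together with the P1 segments.
* The Euclidean norm is used in the cycle-convergence metric (the max norm
  converges at the same cycle count in trials).
* Velocity PI is evaluated at the segment mid-node from running extrema
  over the last cycle (≥ 100 effective phases); the sampling location is a
  documented knob because transcranial measurements do not fix it.
* Taper is supported (linear radius interpolation per node) but disabled
  in the default table.

## Problem sizes and runtimes

The default study network has ≈ 570 segments (55 large vessels plus the
synthetic cerebral trees), ≈ 2000 grid nodes and ≈ 285 outlets; a cardiac
cycle takes ≈ 15000 CFL steps (the 1.5 mm ACoA grid with ≈ 18 m/s wave
speed sets the step) and the run converges in 8 cycles, well under a
minute on one core with the compiled kernels.  The five-seed robustness
study repeats this run with independent tree realizations.  Territory
estimation on the 5120-triangle mesh takes a few seconds per run.

## Known limitations

* First-order characteristic treatment at boundaries against a
  second-order interior: junction transparency holds to ≈ 0.1%, not to
  round-off.
* The printed drag form (22πμ) is kept as-is; absolute pressure drops in
  small resolved vessels are correspondingly larger than a Poiseuille
  profile would give.
* No autoregulation or any feedback from perfusion to boundary conditions;
  the cardiac-output distribution is constant.
* Occluded subtrees are severed rather than simulated as stagnant columns;
  intracranial pressure coupling and collateral leptomeningeal flow are
  not modelled.
* Pulsatility indices depend on the inlet template; only their magnitude
  at the MCA and their monotone spatial decay are treated as robust.
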