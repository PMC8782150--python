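# Methods

## Models

**Cell-based (EMI) model.** The tissue is a collection of explicitly
represented cardiomyocytes Ω_i embedded in an extracellular bath Ω_e.  In
each subdomain the potential is quasi-static, ∇·(σ∇u) = 0, with σ_i = 4
mS/cm intracellularly and σ_e = 20 mS/cm extracellularly.  At the membrane
Γ the normal current is continuous and equals the membrane current,
C_m ∂v/∂t + I_ion with v = u_i − u_e and C_m = 1 μF/cm².  At intercalated
discs Γ_g between neighbouring cells the analogous closure uses the disc
capacitance C_g = 0.5 μF/cm², the jump w = u_i,1 − u_i,2 and the passive
gap-junction current I_gap = w/R_g with R_g = 0.0015 kΩcm².  The outer
extracellular boundary is grounded (u_e = 0) on Dirichlet-tagged sides and
sealed on Neumann sides.

**Homogenized (bidomain) model.** Both potentials coexist everywhere:

    ∇·(M_i ∇V) + ∇·(M_i ∇U_e) = χ (C_m ∂V/∂t + I_ion)
    ∇·(M_i ∇V) + ∇·((M_i + M_e) ∇U_e) = 0,      U_i = V + U_e,

with U_e = 0 on Dirichlet sides, ∂U_e/∂n = 0 on Neumann sides, and zero
normal intracellular flux on every side (the standard closure; only the
extracellular conditions are determined by the cell-based problem).

**Parameter bridge.** The homogenized parameters are computed from the same
voxel mesh the cell-based solver uses:

* χ = A_Γ/V_Ω (membrane area per tissue volume),
* area fractions Ā_i = V_Ω_i/V_Ω, Ā_e = 1 − Ā_i (identical for all axes),
* σ̄_i^d = σ_i / (1 + σ_i R_g V_Ω_i / (δ_d² A_j^d)) with δ_d = L_d/(N_d−1),
  defined so that the total intracellular resistance along axis d equals
  the series cytoplasm + gap-junction resistor network exactly — this
  identity is enforced to 1e−12 relative in the tests,
* tensors M_i = diag(Ā_i σ̄_i^d), M_e = Ā_e σ_e I.

With a single cell along an axis there are no discs and σ̄_i = σ_i (the
exact limit).  δ_d uses the full domain extent including the extracellular
padding; with 2 μm padding on cells ≥ 40 μm the induced bias is well below
a percent.

## Discretization

**Geometry.** Structured voxels (default 2 μm).  A voxel is intracellular
iff its center lies inside the cell's radius profile (linear taper
6 → 7 → 6 μm over a 120 μm length, revolved about the cell axis); cells
abut along each axis, and every face between voxels of different cells is a
disc face.  All homogenization integrals are evaluated on this same
staircase mesh, so the two models always describe the same tissue.
Staircase voxelization overestimates smooth surface areas (χ is a
mesh-consistent, not a smooth-geometry, quantity) and resolves the taper to
one voxel; halving the voxel size changes the voxelized cell volume by less
than 5%.  A box-cell family (square cross-section, exactly
integer-countable measures) is provided for hand-checkable fixtures.

**Cell-based solver.** Cell-centered finite volumes with two-point flux.
Membrane and disc faces are internal faces with a double-valued potential;
their flux closure uses the voxel-center jump.  Operator splitting per step
Δt: (1) forward Euler for gating, ionic + stimulus current on v, and the
gap current on w; (2) one linear solve for all voxel potentials with the
capacitive coupling implicit, after which v and w are reset to the new
jumps.  The matrix is symmetric positive definite and constant in time; it
is factorized once per run — banded Cholesky in natural voxel order when
the cross-section is small (strand meshes, bandwidth ny·nz), sparse LU
otherwise.  The solve is formulated for the deviation from the resting
profile so that a resting tissue produces an exactly zero right-hand side:
rest is then a machine-exact fixed point with no per-step roundoff drift.

**Homogenized solver.** Vertex-centered finite volumes (3-point stencil in
1D, 5-point in 2D, half control volumes at boundaries).  Same splitting:
nodewise forward-Euler membrane step, then a fully coupled implicit solve
for (V, U_e) with Dirichlet rows replaced by U_e = 0; one sparse LU per
run.  The fully coupled solve (rather than iterating between the two
equations) keeps the linear step unconditionally stable.

**Units.** mV, ms, μA/cm², mS/cm, μF/cm², kΩcm², lengths internally in cm.
The set is closed: μF/cm²·mV/ms = μA/cm² and mS/cm·mV/cm = μA/cm².

**Time step.** Reference Δt = 0.001 ms.  The explicit disc update
w ← w(1 − Δt/(C_g R_g)) is the stiffest explicit piece: it requires
Δt < 2 C_g R_g (0.0015 ms at the default R_g — the reference step operates
inside, though near, this bound).  When R_g is scaled up the drivers use
Δt = min(0.01, max(0.001, C_g R_g)) ms, which respects the bound with a
2x margin while staying well below the 5 ms membrane time constant.
Halving Δt changes a passive strand profile by < 0.5 mV and the
homogenized-model conduction velocity by < 2% (self-convergence tests).

**Initial conditions.** v at the membrane model's resting potential, w = 0,
u_e = 0, u_i = v; gating at its rest point.

## Membrane models

* **Passive:** I_ion = (v − v0)/R_m with R_m = 5 kΩcm², v0 = −80 mV.
* **Bundled excitable surrogate:** a reduced three-current model (leak +
  fast sigmoidal inward current with slow inactivation h + slow linear
  recovery current s).  Full ionic models plug in through the same
  contract (resting potential, gating dimension, I_ion, gating
  right-hand side).  Design constraints, in order:
  1. rest must be an *exact* equilibrium (all current terms carry a
     (v − v_rest) factor or are rest-corrected constants);
  2. the resting input resistance equals the passive membrane's 5 kΩcm²
     (a leakier subthreshold membrane would load the gap junctions and
     block conduction far below physiological resistance factors);
  3. no equilibrium other than rest on the quasi-static nullclines
     (checked by sign-scanning I_ion(v, h_inf(v), s_inf(v)); an
     undersized recovery current leaves a stable depolarized fixed point
     and the tissue never repolarizes);
  4. an upstroke of several hundred mV/ms, so that a strand propagates a
     genuine traveling wave rather than firing electrotonically as one
     unit;
  5. a plateau of ~10 ms (τ_h), long enough to drive a postjunctional
     cell through threshold across a strongly uncoupled disc, whose
     charging time constant R_junction·C_cell reaches several ms at
     100x the default gap-junction resistance.
  The defaults (g_leak 0.2, g_act 12 mS/cm², activation −45/3 mV,
  inactivation −55/5 mV, τ_h 10 ms, g_rec 500 μA/cm², ε 0.07/ms) satisfy
  all five; they produce conduction at ~100 cm/s at default coupling and
  conduction block between 100x and 300x gap-junction resistance in the
  cell-based model, later in the homogenized model.  The surrogate is a
  generic excitable membrane — its action potential is much shorter and
  its conduction-velocity scale somewhat higher than an atrial ionic
  model's, so absolute velocities are not comparable to tissue data; the
  cross-model *orderings* (homogenized ≥ cell-based, both decreasing in
  R_g, earlier block in the cell-based model) are the meaningful outputs.

**Stimuli** are additive membrane currents on a box region: on the
cell-based side applied to membrane faces whose position lies in the
region, on the homogenized side to grid nodes in the region (the χ factor
in the bidomain equations makes the total injected current per tissue
volume consistent between the two).

## Experiment drivers and their measures

* **Passive strand:** 2 mm strand (1 mm in the bundled checks, to bound
  runtime), sustained −10 μA/cm² on the leftmost fifth of the membrane,
  centerline u_i vs U_i = V + U_e at t = 20 ms; max-norm and relative L2
  after interpolating the cell-based centerline onto the homogenized grid,
  restricted to the cell region.
* **Conduction velocity:** probes at the domain center and at 4/5 of the
  domain length; CV = distance / (difference of first times strictly above
  −20 mV).  Probe positions snap to the nearest membrane face / grid node;
  the snapped distance is used.  A distal probe that never crosses within
  the run (or a wave that dies before the proximal probe after a
  successful stimulus) is conduction block.
* **2D grid:** corner-block stimulus (a fifth of the cells per axis,
  scaled from the 5-of-25 protocol); wavefront position = farthest point
  above −20 mV projected on the domain diagonal.

All drivers are deterministic given their configuration; the package uses
no randomness.

## Problem sizes used in the bundled checks

Strand meshes at 2 μm voxels are 9x9 voxels in cross-section (~40-50k
unknowns for 1-1.2 mm strands); the passive comparison runs 20 ms and the
CV sweeps use early stopping at the distal-probe crossing.  The homogenized
runs use Δx = 10 μm (2 μm for the cable-constant check).  These sizes keep
the full check suite in the minutes range on one core while preserving
every qualitative comparison; the drivers accept the full-scale settings
(2 mm strands, 20-cell strands, 25x25 grids) unchanged.

## Known limitations

* Staircase geometry: no curved-boundary recovery; membrane area (and
  hence χ) is mesh-dependent.
* First-order splitting and two-point flux: errors are O(Δt) + O(Δx);
  no higher-order or adaptive stepping.
* The explicit disc update bounds Δt at the default R_g; a fully implicit
  disc treatment would lift this but change the splitting structure.
* Tapered cylinders connect across y/z through the tangent strip at their
  widest cross-section; transverse disc areas are therefore thin and
  voxel-parity dependent (box cells provide full-face transverse discs).
* The 3D cell-based vs 1D/2D homogenized comparison inherits the
  dimension-reduction assumption that transverse extracellular gradients
  within the strand cross-section are negligible.
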