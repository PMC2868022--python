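# Model and methods

`streaksim` simulates the onset of gastrulation in the early chick embryo
— the remodeling of the sickle-shaped mesendoderm into the primitive
streak, and the accompanying large-scale vortical cell flows — with a
two-dimensional multicell Potts (Glazier–Graner–Hogeweg) model.  This note
documents the model, its parameters and units, the numerical choices, what
the synthetic study conditions do and do not capture, and the design
decisions made where the problem was genuinely open.

## The cell-level model

Each cell is a contiguous set of voxels on a square lattice; voxel `(i, j)`
stores the id of the cell occupying it (0 = medium/substrate).  The tissue
evolves by voxel copies: a random source voxel proposes to copy its owner
onto a random 4-connected neighbor, and the proposal is accepted with the
Metropolis rule

    P(accept) = 1            if ΔE ≤ 0,
    P(accept) = e^(−ΔE/T)    if ΔE > 0,

where `T = 6` models intrinsic, cytoskeletally driven motility.  One Monte
Carlo step (MCS) makes as many attempts as there are lattice sites.  ΔE
sums the active effective-energy terms:

* **Adhesion.**  Each Moore-neighborhood bond between voxels of different
  cells costs `J(type_a, type_b)`; bonds inside one cell cost nothing.
  Smaller J = stronger adhesion.  The default hierarchy is
  `J(same type) = 3 < J(different types) = 7 < J(cell, medium) = 9`, which
  keeps the tissue cohesive (the compactness condition
  `J(cell, medium) > 2 J(cell, cell)` holds) and keeps types sorted.  The
  streak hierarchy overrides `J(S,S) = J(ST,ST) = 2` and `J(S,ST) = 4`;
  the chemorepulsion/S-attraction mechanisms additionally weaken tip–ring
  contact, `J(ST,AO) = 9`.
* **Volume constraint.**  `α (V_k − T_k)²` with compressibility `α = 0.6`
  and target volume `T_k = 50` voxels (time-varying under growth).  Note
  that the *stationary* volume of a cell sits a few voxels below `T_k`:
  the surface-energy derivative shifts the minimum of the total energy,
  by roughly `J·(dP/dV)/(2α)` ≈ 8–12 % here.  This is intrinsic Potts-model
  physics, not a bookkeeping error, and the tests assert stationarity and
  a band around the stationary mean rather than around `T_k` itself.
* **Chemotaxis.**  For a copy moving the responding cell's boundary from
  voxel `s` to voxel `t` in the concentration field `u`:
  `ΔE_chem = −β (u(t) − u(s))`.  Positive β is attraction.  (The sign
  convention follows the mechanism definitions: attractants carry β = +80
  or +40, repellents β = −60, −40, −15.)  The term is applied for the cell
  gaining the voxel, i.e. motion is driven by biased boundary extension.
* **Polarization.**  The chemotactic energy can be rewritten through a
  per-cell polarization vector `P`:  `ΔE_pol = −λ_P (P · x̂)` with `x̂` the
  unit boundary displacement.  With `P` slaved to the local gradient the
  two formulations are equivalent (exactly so on a linear ramp; a unit
  test asserts this).  The polarization form supports *induced
  polarization*, the co-alignment rule below.

## Induced polarization (co-alignment)

Once per MCS every cell's polarization updates synchronously:

    P ← (1 − ρ) P + γ ⟨P⟩_neighbors + χ Σ_f β_f ∇u_f(centroid)

* `ρ` (memory, default 0.1): fraction of P forgotten per step.
* `γ` (neighbor coupling, default 0.095): gain on the contact-length-
  weighted mean polarization of touching cells.  The collective
  (tissue-uniform) mode decays at rate `ρ − γ`; at `γ = ρ` it is conserved
  and would integrate the chemotactic input without bound.
* `χ` (chemotactic gain, default 0.1): couples the cell's own
  β-weighted gradient into P.  The stationary single-cell drive is
  `(χ/ρ) β ∇u`, equal to the plain-chemotaxis scale at the defaults.
* `λ_P` (strength, default 1) weights the alignment energy.
* `|P|` can be saturated at `max_magnitude` (motility is physically
  bounded); the bound is off by default — the local-chemotaxis leash
  below already prevents tip runaway at the default drive.
* After the update the tissue-mean polarization is projected out
  (`zero_net`).  Co-alignment forces are internal to an embryo anchored by
  the vitelline membrane, so they cannot impart net momentum; without the
  projection the near-conserved uniform mode accumulates the chemotactic
  input and the whole embryo drifts off the lattice.  The vortical flows
  of interest carry no net momentum and are unaffected.

The unprinted coefficients (ρ, γ, χ, λ_P) are this package's own
calibration, chosen once so that (i) streak extension completes within
~7000 MCS, (ii) the co-alignment length spans a substantial fraction of
the embryo (the collective decay length grows like `1/√(ρ − γ)`), and
(iii) the collective mode stays bounded.  They are exposed in
`PolarizationParams` and varied in the tests.

When induced polarization is enabled, the chemotactic drive enters twice
by design: locally through the per-voxel chemotaxis term and smoothly
through χ in the P update.  The local term is self-limiting for streak
extension — if the tip outruns its repellent source the local gradient at
its boundary collapses — and acts as a leash that keeps the tip attached,
while the polarization term propagates the drive to neighbors.

## Morphogen fields

Concentration fields live on lattices congruent with the cell lattice.

* **Chemotactic agents** obey `∂u/∂t = D ∇²u + k1·[producer] − k2 u` with
  `D = 1 voxel²/step`, `k1 = 1.5×10⁻³`, `k2 = 10⁻³` (decay time
  `1/k2 = 1000` steps, diffusion length `√(D/k2) ≈ 31.6` voxels).  The
  solver is explicit Euler with internal substeps at half the stability
  bound (`dt_sub = 0.125` for D = 1), eight substeps per MCS so that field
  time keeps pace with Monte Carlo time; non-negativity is guaranteed by
  the stability bound, with no clipping.  Default boundary condition is
  no-flux; absorbing is available.  Fields are initialized quasi-statically
  (sparse direct solve of the steady state) at the start of the streak
  phase.
* **Amplitude calibration.**  A producing region much narrower than the
  diffusion length cannot reach the saturation level `k1/k2 = 1.5`; with
  the printed rates the mesoderm-produced agents would plateau around
  0.2–0.3 and the induction morphogen around 0.4, too weak to reproduce
  the documented behaviors (fields displayed up to 1.5; differentiation
  threshold 0.7).  The package therefore treats the *kinetics* (D, k2,
  hence time scale and gradient length) as fixed and calibrates the
  *amplitude* once per run, per mechanism: for mechanisms whose small
  mesoderm source drives a small responder group (M3; M4 at half
  strength) the agent's production rate is scaled so the pre-equilibrated
  field peaks at `agent_peak` (default 1.0 on the 0→1.5 display scale);
  M1's AP-wide source saturates on its own, and the bulk-responder
  repellents M2/M2b keep the printed rate (an amplified M2 field tears
  the epiblast apart).  The induction field is normalized so its maximum
  is `induction_peak` (default 1.3).  All knobs are exposed; the defaults
  were chosen so the induced sickle is a posterior crescent of ~30–40
  cells and streak extension completes in ~7000 MCS.
* **Induction morphogen**: produced by AO voxels at a rate weighted by the
  anterior–posterior factor `(1 − j/j0)²` (j measured anteriorly from the
  posterior-most epiblast row; production is maximal at the posterior pole
  and vanishes at the anterior pole), solved to steady state once
  (quasi-static).  AP cells whose centroid concentration exceeds 0.7
  differentiate into mesoderm (S); the central angular window of the
  sickle (default 25 %, inner/anterior edge) becomes the streak tip (ST).
* **ECM anchor**: an AO-deposited field with `D = 0.01`,
  `k2 = 10⁻⁴` (profile length `√(D/k2) = 10` voxels) used as a haptotaxis
  target for AO cells — an alternative positional anchor to recentering.

## Positional stability

By default the embryo is rigidly recentered every 50 MCS: the owner grid
and all fields are translated so the tissue's center of mass returns to
the lattice center, and volumes/centroid sums are recomputed exactly
(this also bounds incremental-bookkeeping drift).  Recorded tracks are
therefore in the embryo frame.  The alternative is ECM haptotaxis
anchoring (above).

## Mechanisms

The four streak-extension hypotheses, with the figure-caption response
coefficients:

| name | secretes | responds | β |
|------|----------|----------|----|
| M1 | AP | ST | +80 |
| M2 | ST | AP | −60 |
| M2b | ST | AP, AO | −60, −15 |
| M3 | S | ST | −40 |
| M4 | ST | S | +40 |

All presets use the streak adhesion hierarchy; M3 and M4 add
`J(ST,AO) = 9`.  M3 is self-sustaining: the repellent source travels in
the column directly behind the tip, so the tip never stalls; it is also
the only mechanism whose twin streaks repel each other.

## Proliferation

With growth on, initial target volumes are uniform on [30, 70]; each
target grows by one voxel on a fixed period; a cell whose volume reaches
100 voxels divides along a uniformly random line through its centroid,
both daughters getting fresh ids, `T_k = 50`, and the parent's
polarization.  Lineage events are logged.  Division is deliberately
unoriented and spatially uniform.

The growth-op default period is 20 MCS, but the *scenario* default is
`growth_period = 200` MCS: a 20-MCS period implies a ~1100-MCS cell
cycle — six population doublings over a 7000-MCS run, which no fixed
lattice can hold and which contradicts the low division rate of the
epiblast (cell cycle 8–13 h against the 6 h simulated window).  At the
200-MCS period the population grows by roughly a third over the run,
the regime the proliferation results refer to.

## Units

One simulated cell ≈ 16 real cells; a voxel is 10 µm × 10 µm and one MCS
≈ 3 s (7000 MCS ≈ 6 h of streak extension).  `convert_units` maps
lengths (µm), times (s), velocities (µm/min; 1 voxel/step = 200 µm/min),
vorticities (min⁻¹) and diffusivities (cm²/s; D = 1 voxel²/step =
3.33×10⁻⁷ cm²/s) and round-trips exactly.

## Readouts

* **Tracks**: (step, id, type, x, y, Px, Py) per live cell on a fixed
  cadence, in the embryo frame.
* **Velocity fields**: per-cell displacement over a window, bin-averaged
  (default bin 10 voxels ≈ one cell diameter); empty bins are NaN.  Each
  bin also stores the mean position of its contributing cells.
* **Vorticity**: `ω = ∂v_y/∂x − ∂v_x/∂y` by central differences on the
  binned field; negative clockwise.  The transect profile is taken along
  the horizontal line through the embryo center, perpendicular to the
  streak.
* **Streak geometry**: the aspect ratio is the ratio of principal-axis
  lengths of the S∪ST voxel region computed from second moments (the
  regionprops convention; exactly length/width for a solid rectangle).
  The full-extent ratio is also reported.  Tip attachment = any ST voxel
  Moore-adjacent to an S voxel; tip split = more than one connected ST
  component.
* **Vortex strength**: fraction of AP-area bins with |ω| above 20 % of
  the profile maximum (the 20 % level is this package's choice; the
  grades None < 10 % ≤ Weak ≤ 25 % < Strong follow the qualitative
  banding used to summarize such flows).  Because that fraction is
  scale-free it cannot separate weak fluctuation noise from coordinated
  flow; `vortex_strength` therefore also reports the mean |ω| over the
  AP (used for magnitude comparisons between runs) and accepts an
  absolute vorticity floor.
* **Two-streak classifier**: tip–tip distance trajectory compared with a
  straight-extension null in which each tip advances from its initial
  position toward the embryo center at its observed path speed.
  Sustained excess separation → repel; closing distinctly faster than
  the null and merging → attract/fuse; merging while tracking the null →
  none-until-contact.

## Study conditions and reduced scales

The standard embryo is 625 cells of ~50 voxels (disk radius ≈ 100
voxels, AP radius 77, AO ring ~3 cells wide) on a 250×250 lattice, run
7000 MCS.  The test suite runs the simulation-heavy checks at reduced
scale to stay fast: geometry scales with √(n_cells), field kinetic rates
with 1/area (preserving concentration maxima and the ratio of diffusion
length to embryo radius), and run length with the embryo diameter
(`scaled_scenario`).  Streak runs use 240 cells, the mechanism-grid and
two-streak checks 150 cells.  At these sizes the mesoderm holds only
~10–15 cells, which caps the achievable aspect ratio well below the
full-scale 5–10 band; the reduced-scale tests therefore assert the
qualitative signatures (elongation above the scale-adjusted floor,
midline position, tip attachment, outcome ordering between mechanisms)
while `scripts/acceptance.py` runs the full-scale protocol.

## What the synthetic conditions do not capture

The model is 2-D and ignores hypoblast dynamics, ingression, the third
dimension of cell stacking in the streak, and any specific molecular
identity for the signals; induced polarization is a deliberately abstract
stand-in for whichever co-alignment mechanism (junctional mechanics,
PCP signaling, ECM strain...) operates in vivo.  Passing tests show the
mechanisms are *sufficient* to generate the documented morphologies and
flows in silico, not that they are the mechanisms the embryo uses.

## Qualitative outcome grid: what reproduces and what does not

Sweeping the four mechanisms against polarization and growth at the
standard size reproduces the decisive contrasts: no streak ever forms
without chemotactic signaling; chemotactically active mesoderm disperses
without differential adhesion; M3 with induced polarization gives the
best streak (aspect ratio in the 5–10 band, tip attached); M1 with
polarization forms a streak that stalls near the embryo center where its
attractant plateaus; M4 forms a streak with a split-prone tip;
coordinated rotation (mean |ω| over the AP) rises distinctly only with
induced polarization; only M3 makes twin streaks repel.  Two behaviors
do not reproduce: M2's mesoderm translates as a compact blob rather than
drawing out into a thin streak (the repellent clears a channel as wide
as the blob, so the tail keeps up — at the printed amplitude the blob
is slow, at a calibrated amplitude the epiblast tears), and the weakening
of vortices by proliferation is not resolvable at the mild proliferation
rate the fixed lattice admits (see above).

## Known limitations

* Cell connectivity is not enforced; fragmentation is monitored
  (`fragmentation_report`) and stays at the level of transient 1–2-voxel
  strays under default parameters.
* Very strong drive (large β·∇u, large χ/ρ, or γ → ρ) can detach the tip
  or, without the zero-net projection, translate the embryo into the
  lattice margin; the defaults sit inside the stable regime mapped in the
  tests.
* The Boltzmann acceptance uses a single temperature for all types;
  type-dependent motility is not modeled.
* The aspect-ratio statistic is sensitive to the un-drained sickle base
  early in extension; runs shorter than ~5000 MCS read low.
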