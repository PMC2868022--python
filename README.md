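# streaksim

A multicell Potts (Glazier–Graner–Hogeweg) simulator of primitive-streak
formation in the early chick embryo.

At the onset of gastrulation the chick epiblast — a flat disk of a few
tens of thousands of cells — transforms a sickle-shaped domain of
mesendoderm at its posterior margin into the *primitive streak*, a narrow
midline structure through which mesoderm and endoderm later ingress.
Streak extension is accompanied by embryo-scale counter-rotating vortical
cell flows.  `streaksim` implements an in-silico test bed for the
cell-level mechanisms that could drive this: differential adhesion,
chemotactic attraction/repulsion between mesoderm subpopulations
(mechanisms M1–M4), flock-like induced polarization of neighboring cells,
and diffuse cell proliferation.  The quantitative readouts — cell tracks,
binned velocity fields, vorticity transects, streak aspect ratio, vortex
grades, and a two-streak interaction classifier — are the observables
that discriminate the mechanisms.

## The model in brief

Cells are contiguous voxel patches on a 2-D lattice evolving by
Metropolis-accepted boundary copies that minimize an effective energy

    E = Σ_bonds J(τ, τ′) + α Σ_k (V_k − T_k)²  +  directed-motility terms

with Boltzmann acceptance `min(1, e^(−ΔE/T))`, `T = 6`, `α = 0.6`,
`T_k = 50` voxels, and the adhesion hierarchy `J(same) = 3 <
J(different) = 7 < J(cell, medium) = 9` (streak overrides
`J(S,S) = J(ST,ST) = 2`, `J(S,ST) = 4`).  Chemotaxis adds
`ΔE = −β (u(target) − u(source))` on a reaction–diffusion agent field
`∂u/∂t = ∇²u + k₁·[producer] − k₂u`; induced polarization adds
`ΔE = −λ_P (P·x̂)` with the per-cell vector P relaxing toward the
contact-weighted mean of its neighbors' P plus the cell's own chemotactic
drive.  One Monte Carlo step ≈ 3 s, one voxel ≈ 10 µm.  See
`docs/methods.md` for the full account.

## Worked example

Run the reference scenario — 625-cell disk embryo, posterior sickle
induction at threshold 0.7, streak-tip selection, mechanism M3 (S cells
secrete a repellent sensed by streak-tip cells, β = −40) with induced
polarization, 7000 MCS:

```python
import streaksim as ss

cfg = ss.ScenarioConfig(mechanism="M3", seed=1)
sim = ss.Simulation(cfg)          # builds embryo, induces sickle, tips
sim.advance(7000)

geom = ss.streak_geometry(sim.state)
print(geom)
```

which prints (seed 1):

```
{'aspect_ratio': 5.79, 'aspect_ratio_extent': 3.73,
 'tip_attached': True, 'tip_split': False}
```

i.e. the sickle has remodeled into a connected midline streak about six
times longer than wide, with the tip group still attached at its anterior
end — the morphology scored "Good" (aspect ratio 1:5–1:10) in the
qualitative outcome grading.  The same run's tracks give the flow field
and its vorticity transect:

```python
vf = ss.velocity_field(sim.tracks, 2000, 7000)
profile = ss.vorticity_profile(vf, y=sim.state.center_of_mass()[0])
```

The profile is odd about the midline — near-zero on the streak axis,
one clockwise and one counter-clockwise lobe — the signature of the
paired vortex flows.  `ss.convert_units(v, "velocity")` converts
voxel/step to µm/min (1 voxel/step = 200 µm/min).

The same machinery runs from the shell:

```bash
streaksim run --mechanism M3 --seed 1 --mcs 7000 --out out/
```

writing `tracks.csv`, type/field snapshots and a JSON report.

## Layout

| module | contents |
|--------|----------|
| `streaksim.core` | lattice state, adhesion/volume energies, Metropolis kernel, recentering |
| `streaksim.fields` | reaction–diffusion agents, induction morphogen, ECM anchor |
| `streaksim.guidance` | chemotaxis/haptotaxis/polarization energies, induced-polarization update |
| `streaksim.embryo` | disk embryo, sickle induction, tip selection, mechanism presets, two-streak setup |
| `streaksim.proliferation` | target-volume growth, cell division, lineage log |
| `streaksim.metrics` | tracks, velocity/vorticity fields, streak geometry, outcome classifiers, unit conversion |
| `streaksim.simulation` | scenario config + driver |
| `streaksim.io`, `streaksim.cli` | snapshots, checkpoints, command line |
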