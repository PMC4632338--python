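# Methods

## Model

`crowdlbm` simulates diffusion of hard molecules on a square, periodic 2-D
domain split into well-mixed voxels of side `Δx`.  Two engines share one
code path:

* **LBM** — classical D2Q5 BGK diffusion for point-like solutes in a fluid
  at rest.  Populations `F_d` (molecules/voxel, real-valued mesoscopic
  averages) relax toward `F_eq_d = (ρ/m)·w_d` at rate `ω` and then stream to
  the neighbour voxel of direction `d` with periodic wrap.
* **cLBM** — identical, except that between collision and streaming every
  mover population is multiplied by the insertion probability
  `P ∈ [0, 1]` of its *target* voxel, evaluated from the densities at the
  current time, and the blocked remainder is returned to the rest
  population by the exact per-voxel mass balance `F_0 = ρ/m − Σ_{d=1..4} F_d`.

`P = 1/γ` comes from Scaled Particle Theory.  Two crowding models are
supported and never mixed within a run: the **hard-disk** model
(`ln γ` quadratic in the tracer radius with voxel moments
`S_x = (π/Δx²)·Σ ρ_i r_iˣ`) and the **lattice-packing** model for equal-size
squares (`ln γ = −ln(1−S₂)`, species-independent).  The moments include the
moving species' own density in the target voxel — self-crowding is physical.
Voxels at or above full coverage (`S₂ ≥ 1`) give `P = 0`: a full voxel
admits no entrant, which also forbids position exchange between two full
adjacent voxels.

Key assumptions inherited from the scheme: voxels are internally well mixed;
the fluid is at rest (no advection); the correction is explicit (`P` is
computed once per step from pre-streaming densities, never iterated to
self-consistency); boundaries are periodic and non-configurable.

## Parameters

| parameter | units | default / constraint | notes |
|---|---|---|---|
| `L` | nm | 1000 (catalogue) | domain side |
| `Δx` | nm | 50 or 100 | must divide `L` exactly |
| `Δt` | ms | `Δx²/(4·D⁰)` preferred | pins `ω = 1` |
| `D⁰` | nm²/ms | per species | dilute diffusion coefficient |
| `r`, `A` | nm, nm² | per species | disk radius / square area |
| `m` | g/molecule | 1 | densities equal molecule counts |
| `ω` | — | `(0, 1]` enforced | `ω > 1` can drive populations negative under BGK, which would break the `P`-correction's non-negativity contract; over-relaxation up to `< 2` only by explicit override |

The rest population is closed by mass balance in **both** engines.  For the
classical engine this is algebraically identical to the BGK update of the
rest channel (collision conserves the per-voxel sum), and it makes the two
engines bitwise identical whenever `P` is exactly 1 — in particular, a
crowded run in which every molecule has zero size reproduces the classical
trajectory bit for bit, which the suite asserts over 10³ steps.

Degenerate inputs: negative populations beyond 1e−9 (relative) raise;
smaller rounding negatives are clipped to zero.  `P` outside `[0, 1]` by
more than 1e−9 raises (SPT gives `γ ≥ 1` analytically); drift within that
band is clamped.  Voxels that overfill transiently (several donors feeding
one nearly-full voxel in the same explicit step) are counted, logged once,
and their `P` clamps to zero on the next step; small `Δt` keeps the effect
bounded.  Immobile species contribute to the moments but have their
populations pinned to rest every step.

## kMC reference

The "computational experiment" is an on-lattice kinetic Monte Carlo: one
molecule of side `a = 10 nm` per site on the `L/a` site lattice, hops only
into empty von Neumann neighbours, rate `D⁰/a²` per direction (the choice
that gives a free walker MSD exactly `4D⁰t`), exponential waiting times
`Δt = −ln(u)/R` at total rate `R`.  The production kernel (numba) uses
null events at the constant attempt rate `Σ_sp 4·N_sp·D_sp/a²`, drawing the
attempt count of each recording window from the corresponding Poisson law
(uniformization); this is distribution-identical to rejection-free event
selection and is A/B-tested against the pure-Python rejection-free sampler
that re-enumerates the event list at every step.  Snapshots use the state at
the last event time ≤ t_k; occupancies are coarse-grained to `Δx` voxels.
The initial placement is drawn once from the scenario seed, so the kMC
ensemble and the engines start from the *identical* voxel counts;
repetitions vary only the dynamics seed.  Reactions are not implemented;
the event catalogue contains hops only.  The kMC supports the single-size
square (lattice) model only — the hard-disk scenarios are engine-only.

## MSD estimators

A mesoscopic field has no per-molecule trajectories.  The engine-side tracer
MSD therefore labels each initially occupied tracer voxel as a distinct
species with identical physics (exact, because the crowding coupling sees
only summed densities) and takes the density-weighted mean of squared
voxel-centre distances from each origin, minimum-image on the periodic box.
Displacement is resolved at voxel granularity only, and the estimate is
flagged invalid once the spread reaches half the box; in practice the
minimum-image folding already truncates the estimate by ~1 % when the rms
spread reaches a quarter of the box (measured on the free case against the
`4D⁰t` closed form), so MSD comparisons here use a 10 ms horizon
(rms ≈ 200 nm on the 1000 nm box, truncation < 0.1 %).

The kMC records two per-species MSD estimators:

* **tagged** — exact unwrapped per-molecule displacement.  In a crowded
  exclusion gas this includes the vacancy back-correlation (a molecule's
  consecutive hops are anti-correlated because it preferentially re-enters
  the vacancy it just left); at 20 % coverage this depresses the tagged MSD
  by ~12 % relative to the mean-field slope.
* **jump** — `a²·⟨number of executed hops⟩`, the displacement accumulated as
  if successive hops were independent; its slope is `4D⁰(1−φ)t` at site
  occupancy `φ`.

Engine-vs-kMC MSD comparisons use the **jump** estimator: the mesoscopic
engines only resolve effective voxel-to-voxel transfers and carry no
inter-hop memory, so the matching microscopic quantity is the uncorrelated
hop count — the tagged estimator measures genuine single-particle physics
(the correlation factor) that is outside what a density method can
represent, and the two should not be conflated.  For a free walker the two
estimators coincide, which the free-walker oracle asserts.  In the 0–40 %
coverage scenario the tracer and crowder species are physically identical,
so the kMC MSD is pooled over *all* molecules (same expectation, ~40× the
samples at the highest coverage).

## Synthetic scenarios

The scenario catalogue defines the study conditions: (1) a capacity-filled
voxel column of two 10-nm square species (`Δx = 100 nm`, `Δt = 5 ms`,
`D⁰ = 500`), 100 tracers + 900 blockers; (2) three adjacent two-column bands
of species A/B/C (`D⁰ = 1000/1050/1100`) at 25 molecules/voxel,
`Δx = 50 nm`, `Δt = 0.625 ms`; (3) 100 square tracers among 0–4000 square
crowders (0–40 % coverage), uniform random placement; (4) a hard-disk
tracer of radius 2/1.5/1/0 nm (796 copies) in a four-species disk mixture
covering 30 %; (5) a 1.5 nm tracer (1414 copies) among one crowder species
of radius 2/1.5/1 nm at fixed 30 % coverage (23 873/42 441/95 493 copies).
Free parameters the catalogue leaves open are fixed as documented defaults:
the tracer voxel of scenario 1 sits in the middle row (physics is
translation invariant under the periodic boundaries), and the three bands of
scenario 2 are bands 3–5 of ten, counted left to right.  Random placement
is uniform without replacement over free sites, seeded; regenerating a
scenario from the same seed is bit-identical, and configurations round-trip
through YAML unchanged.

What the generator does *not* emulate: molecule shape beyond disks/squares,
rotational degrees of freedom, hydrodynamic interactions, binding, spatially
correlated (clustered) crowder placements, and sub-voxel density structure.
Passing tests therefore demonstrate fidelity to the idealised
excluded-volume lattice/disk model, not to any particular experimental
membrane.

## Numerical and statistical choices

* Recording and error evaluation use 30 ms for the distribution-error
  scenarios (the point where the error has settled to its quasi-stable
  level) and 10 ms with 2.5 ms recording spacing for MSD comparisons.
* kMC repetition counts are set from the sampling-error budget, not from
  runtime: a mean over `M` squared displacements has relative standard error
  ≈ `1/√M` (the squared displacement of a 2-D walker is approximately
  `χ²₂`-distributed), so pooling ≥ 2.5·10⁵ samples per coverage keeps MSD
  noise near 0.2 %, small against the 0.7 % agreement bound being tested.
  Distribution-error ensembles use 150 (tests) to 400–500 (acceptance
  script) repetitions; the error floor of a finite ensemble scales as
  `1/√reps`, which the 50-repetition quantity deliberately exhibits.
* Mass conservation is exact per step by construction (the rest-population
  closure); the suite checks ≤ 1e−9 relative drift over 10⁴ steps.
* Tie-breaks/conventions: direction indexing follows the streaming
  equations (d = 1 east, 2 north, 3 west, 4 south in matrix coordinates);
  any consistent assignment is equivalent by symmetry.

## Known limitations

* SPT is accurate at low-to-moderate coverage; at high coverage or with
  immobile obstacles, free-space "pockets" inflate `P` and the scheme
  over-predicts diffusion.
* The explicit correction admits transient overfill under simultaneous
  multi-donor influx; there is no rationing rule (none is well defined at
  this level), only the audit-and-clamp described above.
* Tagged-particle correlation physics (vacancy back-flow, anomalous
  exponents) is outside the model class: the engines predict effective
  transfer rates, not single-molecule trajectories.
* 2-D only; D2Q5 only; periodic boundaries only; no reactions or
  advection.
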