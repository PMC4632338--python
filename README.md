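# crowdlbm

Crowding-corrected lattice-Boltzmann (cLBM) simulation of 2-D diffusion in
crowded media, with an on-lattice kinetic Monte Carlo (kMC) reference
simulator.

## The problem

Intracellular compartments and cell membranes are crowded: a large fraction
of the available area/volume is taken up by macromolecules, which slows
diffusion and raises thermodynamic activities.  Microscopic Monte Carlo
methods capture excluded volume exactly but track every molecule and become
expensive for realistic copy numbers.  The classical lattice-Boltzmann
method (LBM) evolves mesoscopic molecule *densities* cheaply, but treats
molecules as point-like — it over-predicts mixing whenever more than one
finite-size species is present.

`crowdlbm` implements a corrected scheme: Scaled Particle Theory (SPT)
supplies, for every voxel and species, the probability `P` that a molecule
trying to enter finds free space, and the LBM populations headed for that
voxel are scaled by it.  The package targets quantitative studies of
obstructed lateral diffusion (e.g. proteins in membranes) where both speed
and excluded-volume fidelity matter.

## The method

The domain is a square periodic lattice of `(1000 nm)²` split into voxels of
side `Δx`, with the five-direction D2Q5 stencil (rest + 4 neighbours).  Per
species `sp` and direction `d`, populations `F_d` (molecules/voxel) evolve
in three stages per time step `Δt`:

1. **BGK collision** toward the rest-fluid equilibrium
   `F_eq_d = (ρ/m)·w_d`, `w = (0, ¼, ¼, ¼, ¼)`, at rate
   `ω = 2 / (1 + 4·D⁰·Δt/Δx²)`; `ω = 1` (i.e. `Δt = Δx²/(4D⁰)`) reproduces
   the finite-difference diffusion stencil exactly and is the recommended
   operating point.
2. **Crowding correction** — the package's core:
   `F_d(i,j) = F_LB_d(i,j) · P(i_next, j_next)` for `d = 1..4`, with the rest
   population closed by mass balance `F_0 = ρ/m − Σ_d F_d`.
   `P = 1/γ = exp(−ln γ)` comes from 2-D SPT for hard-disk mixtures,
   `ln γ = −ln(1−S₂) + [2S₁/(1−S₂)]·r + [S₀/(1−S₂) + S₁²/(1−S₂)²]·r²`
   with moments `S_x = (π/Δx²)·Σ_i ρ_i·r_iˣ`; for square molecules on a
   uniform packing grid this reduces to the free-area law
   `ln γ = −ln(1−S₂)`, `S₂ = (1/Δx²)·Σ_i ρ_i·A_i`.
3. **Streaming** of each mover population to its neighbour voxel, with
   periodic wraparound.

The kMC reference places one 10-nm molecule per lattice site, executes hops
into empty neighbour sites at rate `D⁰/a²` per direction with exponential
waiting times, and is ensemble-averaged and coarse-grained to the voxel grid
for comparison.  Agreement is quantified by the relative distribution error
`error = 100·‖ρ_kMC − ρ_cLBM‖_F / Σρ_kMC` and by the relative error of the
tracer mean squared displacement (MSD).

## Worked example

Two 10-nm square species on a 10×10 voxel grid (`Δx = 100 nm`,
`Δt = 5 ms`, `D⁰ = 500 nm²/ms`); the first voxel column starts filled to
capacity — 100 tracer molecules "A" in the middle voxel, 900 blockers "B"
in the rest.  A diffuses freely along the empty horizontal rows but must
displace B vertically:

```python
from crowdlbm import Simulation, distribution_error, kmc
from crowdlbm.scenarios import example1

scenario = example1(t_end=30.0)
clbm = Simulation(scenario, engine="clbm").run()
lbm = Simulation(scenario, engine="lbm").run()
ens = kmc.run_ensemble(scenario, n_reps=200, seed=7)

for t in (10.0, 20.0, 30.0):
    e_c = distribution_error(ens.density("A", t), clbm.density("A", t))
    e_l = distribution_error(ens.density("A", t), lbm.density("A", t))
    print(f"t = {t:4.0f} ms   error_A(kMC-cLBM) = {e_c:5.2f} %   "
          f"error_A(kMC-LBM) = {e_l:5.2f} %")
```

```
t =   10 ms   error_A(kMC-cLBM) =  9.80 %   error_A(kMC-LBM) = 27.28 %
t =   20 ms   error_A(kMC-cLBM) =  1.96 %   error_A(kMC-LBM) = 19.97 %
t =   30 ms   error_A(kMC-cLBM) =  1.12 %   error_A(kMC-LBM) = 16.62 %
```

An error of 1.12 % means the two methods disagree about the voxel placement
of roughly one molecule out of the 100 simulated; the uncorrected LBM
misplaces ~16.  (Both errors start high while only a handful of coarse
voxels hold any tracer, then settle after a few steps.)

The same machinery is scriptable from the shell:

```bash
crowdlbm scenario example1 --out ex1.yaml
crowdlbm run  --config ex1.yaml --engine clbm --out out_clbm/
crowdlbm kmc  --config ex1.yaml --reps 200 --seed 7 --out out_kmc/
crowdlbm compare --ref out_kmc/ --test out_clbm/ --metric error
```

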