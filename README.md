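# crowdsim

Event-driven hard-sphere simulation of reversible protein dimerization
under macromolecular crowding, with a scaled-particle-theory (SPT)
comparator and polynomial metamodels of the equilibrium constant.

Cells are crowded: 10–40% of cytoplasmic volume is occupied by
macromolecules, and that excluded volume alone shifts binding
equilibria toward compact states. `crowdsim` quantifies the effect for
the simplest test reaction,

    M + M  ⇌  D,        K_eq = [D] / [M]²    (molecules·m⁻³ densities),

by explicitly simulating hard-sphere monomers, dimers and inert
crowders diffusing in a closed box. Diffusion is propagated with an
asynchronous discrete-event scheme (Green's-function-reaction-dynamics
style): each particle's position is sampled only at events, and two
particles can first interact when their *diffusion limit spheres* —
radius `r + 3√(2·D·Δt)`, containing 97.07% of the Brownian probability
mass — touch, a time obtained in closed form. Binding happens with
probability `B` when two monomers come within the threshold distance
`d_th`; dimers dissociate with exponential waiting time of mean `M`.
The apparent `K_eq` then emerges from the particle dynamics, crowding
included. The analytical comparator multiplies the ideal-state constant
`K°` (measured from dilute 1% runs) by the SPT excluded-volume factor
`Γ_exc = γ_M²/γ_D`. Polynomial surrogates with LOOCV-selected degree
summarize `K_eq` over concentration and shape-parameter space. Model
details, assumptions and the calibration of the one free discretization
constant are documented in [docs/methods.md](docs/methods.md).

For users who study crowding effects on reaction equilibria —
computational biophysicists and quantitative cell biologists — and for
anyone needing a compact, fully seeded, pure-Python (numba-accelerated)
reference implementation of this simulator family.

## Worked example

Replicate runs with 10% reactant and 20% inert crowder volume
fraction in a 40 nm box, then the crowding-free comparison:

```python
from crowdsim import (ParameterSet, run_replicates,
                      quasi_equilibrium_summary, idealized_dimer_count)

params = ParameterSet(c_r=0.10, c_i=0.20, box_nm=(40.0, 40.0, 40.0),
                      duration_us=2.0, n_runs=3, seed=1)
runs = run_replicates(params)
est = quasi_equilibrium_summary(runs)
print(f"mean dimers      {est.mean_dimers:.1f} ± {est.std_dimers:.1f}")
print(f"K_eq             {est.k_eq_m3:.3g} m^3/molecule")
ideal = idealized_dimer_count(9.5e-25, est.n_monomer0, est.volume_m3)
print(f"idealized dimers {ideal:.1f} (no crowding, dilute K°)")
```

prints (seed 1, ~4 minutes including JIT compilation):

```
mean dimers      32.5 ± 2.6
K_eq             1.92e-24 m^3/molecule
idealized dimers 27.5 (no crowding, dilute K°)
```

The 98 initial monomers settle at ~33 dimers instead of the ~27 that
dilute-limit mass action predicts: 30% total occupancy roughly doubles
the apparent `K_eq` (1.92e-24 vs the dilute 9.5e-25 m³) — the
excluded-volume enhancement the simulator exists to measure.

The same kind of study from the shell:

```bash
crowdsim simulate --c-r 0.1 --c-i 0.2 --duration-us 2 --runs 3 --out out/
crowdsim spt --k0 9.5e-25 --c-i-grid 0,0.1,0.2,0.3 --out spt.csv
crowdsim campaign --sweep c_i=0,0.1,0.2,0.3 --out campaign/   # resumable
crowdsim fixture --seed 3 --out init.xyz                      # HCP snapshot
```

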