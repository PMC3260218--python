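# Model and methods

## The system

`crowdsim` simulates a reversible homodimerization

    M + M  <->  D

among hard spheres diffusing in a closed rectangular box, optionally in
the presence of chemically inert crowding spheres. The only interaction
is steric: no attractive or soft potentials, no nonspecific
association. The question the simulator addresses is how macromolecular
crowding — occupancy of 10–45% of the volume by impenetrable particles —
shifts the apparent equilibrium constant

    K_eq = [D] / [M]^2        ([X] = number density, molecules m^-3)

away from its dilute (ideal-state) value K°, purely through excluded
volume.

Seven parameters define a condition: reactant and inert volume
fractions `c_r`, `c_i`; the binding probability per collision `B`; the
mean dissociation waiting time `M` (ns), the inverse of the
dissociation rate constant; the monomer diffusion coefficient `D`
(m²/s); the dimer/monomer and inert/monomer volume ratios `alpha`,
`beta`; and the threshold distance `d_th` (nm), the maximum
surface-to-surface gap at which two reactants can interact. Defaults:
`B=0.7`, `M=1 ns`, `D=4.63e-11 m²/s`, `alpha=2`, `beta=1`,
`d_th=0.125 nm`, monomer radius 2.5 nm, a 50 nm cube, 25 µs runs
recorded every 0.15625 µs. Radii follow from the volume ratios
(`r_D = alpha^(1/3) r_M`) and diffusivities from Stokes–Einstein
scaling (`D_X ∝ 1/r_X`). Internally everything runs in nm/ns; public
configuration takes SI-flavoured units.

## Event-driven diffusion

Fixed-timestep Brownian dynamics would waste nearly all its effort on
far-apart particles. Instead the simulator is asynchronous, in the
spirit of Green's-function reaction dynamics: each particle keeps the
position and time at which it was last sampled, and between events its
true position is only known to lie (with probability
`P(chi²_3 <= 9) = 97.07%`) inside its *diffusion limit sphere* of radius

    R_diff(dt) = r + 3 sqrt(2 D dt).

Two particles can first interact when their diffusion limit spheres
touch; the touching time solves

    r_A + 3 sqrt(2 D_A (t - t_A)) + r_B + 3 sqrt(2 D_B (t - t_B)) = d_AB

analytically (isolate one square root, square twice, reject the
spurious root of the resulting quadratic against the original equation,
polish with Newton; a bisection fallback guards the ill-conditioned
near-equal-diffusivity corner). `collision.contact_delay` is verified
against an independent bisection oracle to 1e-9 relative tolerance on
10⁴ randomized inputs.

At an event, the participants' positions are drawn as isotropic
Gaussian displacements (per-coordinate sigma `sqrt(2 D dt)`), rejected
until they fall inside the 3-sigma sphere, mirror-reflected at box
faces (redrawn if the reflection is still outside — possible only in
thin boxes), and rejected against hard-sphere overlap with every other
particle's last-sampled position. On retry exhaustion (dense cages) the
particle keeps its position and advances its clock, which guarantees
progress.

Scheduling is min-event-per-particle: each live particle owns one
pending event — its earliest sphere-contact against any other particle,
or a horizon "refresh" (default 5 ns) when nothing can happen sooner.
Stale events are discarded through per-particle generation counters.
Because every pending event fires or is superseded within one horizon
of its owner's last sample, position staleness is bounded, which makes
cell-grid neighbour search exact: shells are scanned outward until no
unscanned particle — even one maximally stale — could make contact
before the best delay found. Cell edges are sized so that one shell
almost always suffices.

Three event-rate regularizers keep the discrete-event cadence finite
without touching the physics that matters:

* a pair of freshly co-sampled particles is never rescheduled against
  each other sooner than 1e-6 ns (prevents same-float-timestamp
  livelocks; diffusion over it is ~1e-4 nm);
* pairs with no chemistry (anything but monomer–monomer) have their
  contact events floored at 0.01 ns spacing — such events only refresh
  positions under the hard-core constraint, which the sampling step
  already enforces, and without the floor they ping at vanishing
  intervals near contact (a Zeno cascade measured at >1e8 events/µs at
  10% occupancy);
* after a failed dimer placement the colliding pair backs off 0.02 ns,
  roughly a cage-relaxation time, instead of re-attempting the blocked
  binding at contact resolution.

## Reaction rules

At a sphere-contact event between two monomers, both positions are
sampled; the pair *collides* if the sampled gap is below `d_th` (a
sampled hard-core overlap also counts — the spheres must have met
during the interval). A collision binds with probability `B`:

* **bound** — the two monomers are replaced by a dimer of radius
  `alpha^(1/3) r_M` at their centre of mass (jittered retries if the
  centre of mass is blocked; if no placement fits, the collision is
  treated as unbound);
* **unbound** — the pair's diffusion step is *re-sampled* until the
  configuration ends outside interaction range, honouring the rule
  that particles end reaction and collision events separated beyond
  `d_th`.

A dimer dissociates after an exponential waiting time of mean `M`,
splitting into two monomers placed symmetrically about its centre
along a uniformly random axis at separation `2 r_M + d_th` — exactly at
the edge of interaction range. If no axis fits (dense cage), the
dissociation is postponed by a fresh exponential draw.

The distinction between the two re-placement rules matters. A
dissociation deposits the pair exactly at the interaction boundary, so
its next sampled configuration is back in range about half the time; a
rejected collision deposits the pair *conditioned outward*, with
strictly lower re-contact probability. This asymmetry makes the
equilibrium constant superlinear in `B` — the measured K°(B) follows
`K ∝ B/(1 - γB)` with `γ ≈ 0.55` — whereas symmetric deterministic
push-apart of rejected pairs (available as `collision_rule="shell"` or
`"overlap"`) yields K ∝ B. The sensitivity variants are retained
because the re-placement rule is the single most consequential
modelling choice in this class of simulator.

### The contact-resolution constant

Reversible binding in this model has no detailed-balance equilibrium;
the stationary dimer fraction emerges from the kinetics of the
geminate-recombination cascade near the interaction shell, and is
therefore sensitive to how finely that cascade is resolved in time. The
forward rate is within ~30% of the Smoluchowski diffusion limit, so the
absolute K° is governed almost entirely by the escape probability per
dissociation, a pure discretization property.

The resolution is set by `contact_offset_nm`: reactive (monomer–
monomer) pair events fire when the diffusion limit spheres reach this
surface gap, rather than hard contact, so near-shell steps scale with
the distance to the offset surface instead of the distance to the hard
core. The offset must lie below `d_th` (re-placements deposit pairs
outside `d_th`, hence strictly outside the firing surface, keeping the
scheme non-degenerate). It is the one constant of the model that
cannot be derived from first principles; it was fixed **once** at
0.085 nm by matching the single baseline ideal-state constant
K°(B=0.7, M=1 ns) = 9.39e-25 m³ measured from dilute 1% pure-reactant
simulations, and then validated without further adjustment against the
independent operating points B=0.1, B=0.9, M=1.2 ns and D=1.3e-11 m²/s,
which agree within ~4–11% (Monte-Carlo error of the validation runs is
~5%). The M- and D-linearity of K° are structural properties of the
model (the cascade geometry is invariant under both) and hold for any
offset.

## Initial configurations

Reactants always start as monomers. Centres are drawn from a hexagonal
close-packed lattice of spheres of radius `r_sel + d_th/2`, where
`r_sel` is the radius of whichever species occupies the larger total
volume; the half-threshold inflation keeps every pair out of
interaction range at t = 0, and HCP packing (74%) leaves headroom at
the densest condition studied (45% + threshold inflation). Lattice
layers stack along the shortest box axis, which maximizes usable sites
in thin boxes; particles are assigned to uniformly random distinct
sites. Integer particle counts round `C V / v_particle` to nearest.

The reflective boundary confines only particle centres, so bodies may
protrude one radius beyond each wall; the effective volume is larger
than the nominal box. `corrected_concentration` reports occupancy
against the inflated volume `prod(L_i + 2 r_M)` — for the single-layer
50×50×5.125 nm box this maps nominal C = 0.1–0.45 to corrected
C = 0.043–0.188. The correction uses the monomer diameter because all
particles share that radius at the default `beta = 1`; it matters most
for quasi-2D geometries.

## Observables

Runs start far from equilibrium (all monomers) and relax within a
couple of microseconds into a fluctuating quasi-equilibrium.
`quasi_equilibrium_summary` pools dimer counts over five evenly spaced
late time points per run (5, 10, 15, 20, 25 µs for the standard
duration; the same 1/5-spacing for scaled-down runs) across replicate
runs, and computes K_eq from the pooled mean count (the mean of
per-sample K_eq values, which differs by Jensen's inequality, is also
reported). `equilibration_time` measures when the run-averaged curve
enters and stays within a ±5% band (configurable) of its late-window
mean — the band and the enters-and-stays criterion are this package's
own operationalization of an informal visual judgement.
`idealized_dimer_count` inverts the mass-action relation through the
numerically stable root of `K (N0 - 2 N_D)² = N_D V`, exact in both the
K→0 and K→∞ limits.

## Scaled particle theory

For comparison with the explicit simulations, the apparent constant is
also predicted analytically: `K_app = Γ_exc K°` with
`Γ_exc = γ_M²/γ_D`, where the activity coefficients come from the
standard SPT excess chemical potential of inserting a hard sphere of
radius r into a hard-sphere mixture with moments
`ξ_k = (π/6) Σ_j ρ_j (2R_j)^k`:

    ln γ = -ln(1-ξ₃) + [6ξ₂/(1-ξ₃)] r
           + [12ξ₁/(1-ξ₃) + 18ξ₂²/(1-ξ₃)²] r²
           + [8ξ₀/(1-ξ₃) + 24ξ₁ξ₂/(1-ξ₃)² + 24ξ₂³/(1-ξ₃)³] r³

The implementation is validated against the dilute one-component limit
(`ln γ → 8φ`, the hard-sphere second virial) and the mixed-species
pairwise excluded-volume sum `Σ_j ρ_j (4π/3)(r+R_j)³`. Compositions at
a condition are the mass-action equilibrium split of the reactants
(from K°) plus the unchanged inert density. At the 1% reference
composition Γ_exc ≈ 1.04 — small enough to justify treating the dilute
simulations as the ideal state. SPT sees only bulk pairwise exclusion:
it cannot distinguish box geometries (no wall effects) and
progressively understates crowding above ~30–40% occupancy, where
collective packing constraints exceed the pairwise estimate.

## Polynomial metamodels

K_eq surfaces over the condition grid (total concentration C, or
jointly (alpha, C)) are summarized by ordinary least-squares polynomial
fits. Predictors are standardized internally (raw powers of
C ∈ [0.1, 0.45] are ill-conditioned at degree 5) and coefficients
back-transformed to the raw graded-lexicographic monomial basis for
reporting. The degree is chosen by leave-one-observation-out
cross-validation (each run × time point is one observation), computed
through the exact OLS hat-matrix identity and verified against
explicit refits; near-ties at floating-point noise resolve to the
lowest degree. `linear_scaling_r2` quantifies the complementary
finding that the B, M and D families of K_eq(C) curves are scalar
multiples of a reference curve, while the (alpha, C) surface is not.

## What the tests do and do not show

The synthetic conditions exercised by the test-suite are scaled down:
dilute K° checks use several runs of a few microseconds (Monte-Carlo
tolerances of ~10–20%) instead of 100 runs of 25 µs, and the crowding
trend check runs a reduced 40 nm box for 1 µs. The dense-regime
production numbers — fold-changes of dimer counts and K_eq across the
full 8-condition, 10-replicate, 25 µs campaigns — require hours of
compute through the `campaign` runner and are not asserted by tests.
Passing tests therefore demonstrate the correctness of the machinery
(collision times, hard-sphere invariants, conservation, determinism,
estimators, SPT, regression) and the calibrated dilute operating
points, not the full production phenomenology. All randomness flows
from named seeds; identical configuration and seed reproduce a
trajectory bit-for-bit.

## Known limitations

* Spheres only; `beta ≠ 1` inert diffusivity follows Stokes–Einstein
  scaling by assumption (the default `beta = 1` never exercises it).
* The collision cadence near the interaction shell is a model constant
  (`contact_offset_nm`), not a convergent discretization: refining it
  indefinitely would drive K° upward without bound, because continuum
  Brownian motion revisits an absorbing shell almost surely. The value
  shipped is calibrated as described above.
* The kernel's re-placement and regularization rules are exact hard-
  sphere moves but not microscopically reversible; equilibrium
  properties are defined by the kinetics, as in any simulator of this
  family.
* Reported K_eq uses the nominal box volume; the boundary correction
  is applied to concentrations where stated.
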