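# Methods

This note documents the models implemented in `triblock`, the choices made
where the design was genuinely open, and what the desk-scale tests do and
do not establish.

## Coarse-grained model

BAB triblock chains (hydrophobic PVLA-like B end blocks, hydrophilic
PEG-like A middle block) are bead-spring polymers in reduced Lennard-Jones
units: bead diameter sigma = 1, B-B well depth eps_BB = 1, bead mass = 1,
time unit tau = sigma sqrt(m/eps).  Solvent is implicit:

* **B-B**: Lennard-Jones, truncated and energy-shifted at `rcut = 2.5
  sigma` (the effective hydrophobic attraction).  The shift convention is
  `U(r) - U(rcut)`, so the pair energy vanishes continuously at the cutoff.
* **A-A and A-B**: Weeks-Chandler-Andersen (purely repulsive LJ truncated
  at `2^(1/6) sigma`).
* **Bonds**: FENE (`k = 30 eps/sigma^2`, `R0 = 1.5 sigma`) plus a
  unit-strength WCA term on the bonded pair — the standard Kremer-Grest
  construction.

PEG dehydration on heating is the only temperature dependence beyond the
thermostat: across the scanned window of reduced temperature `T* in
[0.5, 1.2]` the A-A strength interpolates linearly from 1.0 down to 0.25
(the hydration shell collapses) and the A-B strength from 0.5 up to 2.0
(block segregation strengthens).  eps_BB is temperature-independent; the
thermal map carries the whole transition-driving asymmetry.  Both endpoint
sets are configuration fields, not constants.

## Dynamics

BAOAB-split Langevin dynamics with `dt = 0.005 tau` and friction
`gamma = 1/tau`, cubic periodic box, minimum-image convention with the
half-open interval `[-L/2, L/2)`.  With `gamma = 0` the scheme reduces
exactly to velocity Verlet; NVE energy drift and momentum conservation are
tested in that limit.  Neighbor search uses a periodic k-d tree with a
0.4-sigma Verlet skin rebuilt every 20 steps; the jitted pair kernel is
validated against an all-pairs reference implementation to 1e-10.

Initial states place chains as random walks (bond length 0.97 sigma) at
the target bead volume fraction, relax overlaps with a bounded soft-cosine
push-off until no pair is closer than 0.8 sigma, then run a short warmup at
a reduced timestep (`dt = 0.002`) before full-speed equilibration.  A
warmup with force capping was tried first and rejected: capping clips the
FENE restoring force and destabilizes bonds.  All randomness derives from
one master seed with documented per-run derivation.

## Study conditions (desk scale)

The experimental system is 22 w/v% polymer; a first-principles mapping of
w/v% to bead volume fraction is out of scope, and bead volume fractions
near 0.22 make the hydrophobe cores percolate into a single cluster at
these box sizes.  The default conditions are therefore:

* bead volume fraction **0.15**,
* chains with `n_A = 8` PEG beads and `n_B_per_end = 1, 2, 3, 4` realizing
  the plotted ratios `2 N_B/N_A = 0.25, 0.5, 0.75, 1.0` (total chain
  length 10-16 beads, so concentration stays comparable across the
  series),
* 100 chains per run (1000-1600 beads), 1k warmup + 40k equilibration +
  16k production steps, frames every 1.6k steps.

These sizes are the package's own desk-scale choice: they resolve discrete
spherical micelles at low temperature and wormlike aggregates at high
temperature in minutes per run.  What they do **not** deliver is full
coarsening: wormlike structures at these sizes are finite, often curved,
and fluctuate; a curved or branched worm has a much less anisotropic
gyration tensor than a straight cylinder of the same contour length.  The
worm mass fraction of a single run is therefore noisy near the boundary,
and the library default sweep uses 3 replicates per grid point.

## Morphology pipeline

Micelle cores are single-linkage clusters of B beads within 1.3 sigma
(just above the LJ minimum; the corona is excluded by construction, so all
diameters are core-only).  Clusters are unwrapped across periodic
boundaries by breadth-first traversal before the gyration tensor is
formed.  Shape classification uses the elongation
`e = lambda_1 / ((lambda_2 + lambda_3)/2)`: spherical below `e_lo = 2`,
wormlike above `e_hi = 5`, intermediate between.  Both thresholds are
config fields; ideal balls give e ~ 1 and cylinders of aspect >= 2 give
e > 5, which the 1000-cloud classifier test verifies at 99% accuracy under
5% positional noise.

Core diameters invert uniform-solid moments: `D = 2 sqrt(5/3 Rg^2)` for
spheres (a uniform ball of radius R has Rg^2 = 3R^2/5) and
`D = 4 sqrt((lambda_2 + lambda_3)/2)` for worms (transverse moment R^2/4).
Intermediate clusters report both with an ambiguity flag.

The **worm mass fraction** that drives phase calls is worm mass over
decisively classified (worm + sphere) mass; intermediate clusters abstain.
Including them would make the call hostage to exactly the objects the
classifier declares ambiguous — at desk scale these are large fused
transients whose elongation straddles `e_hi`.  A `decisive_fraction`
diagnostic records how much clustered mass voted.  Phase calls: spherical
below worm fraction 0.2, wormlike above 0.8, coexistence between.

Aggregates below 10 beads are treated as free chains/oligomers and carry
no weight in phase calls or diameter statistics.

## Scaling theory

The theory treats a micelle as a dense B core of radius `R_B` decorated by
a grafted corona of A blocks of extent `R_A`, with unit prefactors on all
scaling relations (one multiplicative prefactor per relation is exposed in
the configuration):

* `R_A = f^(1/5) v_A^(1/5) b_A N_A^(3/5)` — grafted chains in good solvent;
* `R_B = N_B^(1/3) b_B u^(-1/3)`, with `u = v_B phi_B^(5/2)/b_B^3` — the
  concentration-dependent theta-to-poor-solvent form of the collapsed core;
* `f = N_B^(5/3) N_A^(-3) (b_B/b_A)^5 u^(-5/3) v_A^s` — the aggregation
  number from closing the corona and core sizes against each other.

The closure exponent `s` defaults to +1, the value required for internal
consistency of the free-energy chain below; substituting `f` back gives
`R_A(f) = R_B v_A^(2/5)`, i.e. the closure equates corona and core extents
up to a power of the corona excluded volume (exactly `R_A = R_B` at
`v_A = 1`, the default; `s = -1` selects the strictly geometric closure).
A surface-coverage closure would suggest a squared relation instead; the
switch exists so the alternative can be explored.

Flory energies per block follow `F ~ R^2/(N b^2) + v f N^2/R^3` with the
equilibrium corona and the collapsed core substituted:

* `F_B = N_B^(-1/3) |u|^(-2/3) [1 + (N_B/N_A)^3 (b_B/b_A)^5 v~_B v_A]`
* `F_A = N_B^(-1/3) |u|^(-2/3) (N_B/N_A) (b_B/b_A)^2 v_A^(4/5)`

where `v~_B` is the dimensionless core excluded volume.  In the collapsed
regime `v~_B < 0`, so the common prefactor uses `|u|`; the crossover locus
`F_A = F_B` is unaffected because the prefactor is positive and common.
Setting `F_A = F_B` with `b_A = b_B` and the empirical Flory-Huggins law
`chi = G + H/T`, `v~_B = v~_o (1 - 2 chi)`, gives the closed-form boundary

    v~_o (C - D/T*) = (r v_A^(4/5) - 1) / (r^3 v_A),   r = N_B/N_A,

with lumped coefficients `C = 1 - 2G` and `D = 2H`.  T* is found by
bracketed root finding (brentq, 1e-10 tolerance) on a documented interval;
a property test confirms on a 20x20 coefficient grid that the closed form
and the numerically located `F_A = F_B` crossing agree to relative 1e-6.
Where the right-hand side never meets the left for positive T the ratio is
"spherical at all temperatures"; the infimum ratio with a solution is the
phase-diagram asymptote, refined by bisection on the ratio axis.  Points
exactly on the boundary classify wormlike (closed-boundary convention,
applied with a 1e-9 relative tolerance).

`C` and `D` (equivalently `chi_G = 60.5`, `chi_H = -43`) are lumped fit
parameters, not microscopic constants: the defaults place the boundary
inside the simulation window with the asymptote near plotted ratio 0.38,
and `fit_theory_overlay` recalibrates them to simulated transition
midpoints by linear least squares (the condition is linear in C and D).
Parameter-recovery tests confirm the fit returns planted coefficients to
1% from a theory-labeled grid.

phi_B defaults to 1 (melt-like core above the transition) and is exposed
in the configuration.

## Temperature calibration

The phase diagram's experimental ordinate is Celsius, but the appendix
mapping reduced temperature to Celsius is not available, so the affine
calibration is anchored to the two experimental observations: liquid
(spherical micelles) at 25 C and gel (wormlike) at 37 C.  The map sends
the reduced boundary temperature at the synthesized polymer's block ratio
(~1.07 from the 1570-1500-1570 block masses with PEG repeat 44.05 and an
equimolar valerolactone/lactyl repeat of 86.09 g/mol) to the 31 C
midpoint, with slope fixed by the flanking grid temperatures.  By
construction 25 C lands on the spherical side and 37 C on the wormlike
side; the calibration is a presentation device, not a prediction.

## Packing-argument diameter ratio

The package also computes the geometric sphere/worm diameter ratio from
assumed core packing fractions: random close packing (0.64) for spheres
and densest packing (pi/sqrt(18)) for worms.  The construction behind the
published ratio of 1.18 is not spelled out anywhere we could follow, so
the rule is explicit and configurable: the transverse core size is taken
to scale as `eta^(-p)` with the packing fraction `eta`, with `p = 5/6` by
default — the exponent of the theory's own core-size law `R_B ~
phi^(-5/6)`.  This yields 1.129; the pure volume-conservation exponent
`p = 1/3` yields 1.050.  Neither reproduces 1.18 exactly, and the package
reports the computed value rather than asserting the published one.

## Dose-response statistics

Inhibition is `1 - viability/control`, in [0, 1].  The Bliss independence
expectation is `E = fa + fb - fa fb`; the delta-Bliss reported is
`observed - E`, so positive values mean synergy (the convention is written
into output metadata).  The Hill model
`inhibition = bottom + (top - bottom)/(1 + (IC50/dose)^h)` is fit on the
log-dose scale by bounded trust-region least squares with plateaus
constrained to [0, 1] and deterministic initialization from the data
midpoint; data that do not straddle the response midpoint are refused
rather than extrapolated.  The noise-robustness study simulates a
realistic assay — 12 half-log doses spanning +/- 1.5 decades around the
IC50, triplicate wells, 5% coefficient-of-variation (multiplicative)
noise — and requires median relative IC50 error below 5% over 100
simulated experiments.  With free plateaus and single wells under 5%
additive noise the IC50 is genuinely less determined (~10% median error);
the triplicate CV design reflects how such assays are actually run.

## Synthetic data

Micelle point clouds sample uniform balls and cylinders (Haar-random
orientation) with isotropic Gaussian jitter; planted-micelle trajectories
place non-overlapping cores (optionally with an A corona shell that the
core statistics exclude by construction) in a periodic box; dose-response
grids combine Hill monotherapy curves through the Bliss formula with an
optional localized synergy bump and clipped additive (default) or
multiplicative noise.  Every generator is bit-reproducible from its seed.
What the generators do not emulate: polydispersity, corona-mediated
cluster bridging, instrument drift, or plate edge effects — so passing the
synthetic tests demonstrates correctness of the estimators, not their
field performance on real assays or cryo-TEM measurements.

## Known limitations

* Desk-scale self-assembly does not reach the coarsening endpoint; worm
  fractions near the boundary are replicate-noisy and the simulated
  diameter ratio carries sampling error absorbed by a widened acceptance
  band (twice the reference standard deviation).
* The elongation classifier under-calls long curved or branched worms
  (their gyration tensors are less anisotropic); network/percolation
  analysis is out of scope.
* The reduced-to-Celsius map is anchored, not derived.
* No electrostatics, explicit solvent, hydrodynamics, or pressure
  coupling; concentration enters only through the bead volume fraction.
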