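# Methods

## Normalized binding models

All models describe closed systems at thermodynamic equilibrium in a
dimensionless convention suited to ratiometric pull-down assays: the bait
(GL3) total is 1, ligand amounts are prey:bait molar ratios, and
dissociation constants are relative (K̄_D = K_D / [GL3]_total).  This is
forced by the assay: absolute concentrations in cell extracts are not
measurable, but relative amounts are (quantitative Western blot), so only
ratios and relative affinities are identifiable.

*Single site.*  The bound complex solves a quadratic in the complex
concentration; the physical branch is the smaller root (the larger one
exceeds the totals), and we additionally clamp to `0 ≤ c ≤ min(1, y0)`.
Curves are normalized by the model value at a prey:bait ratio of 100
(`SATURATION_RATIO`), where the bound fraction is within 1% of its
asymptote for every K̄_D ≤ 3 occurring here; the ratio is configurable.

*Competitive binding.*  Two ligands competing for one site give a cubic in
the free bait; we use the exact trigonometric solution.  The arccos
argument can drift past ±1 by rounding at boundary cases (e.g. zero
competitor); drift up to 1e-12 is clamped, larger excursions raise.

*Cooperative trimer.*  Both ligands can bind simultaneously; the second
binding event on an occupied bait sees its K̄_D divided by the
cooperativity parameter α (α < 1 negative, α = 1 independent, α > 1
positive cooperativity).  Equivalently, the ternary complex carries the
thermodynamic weight α·y·z/(K̄₁K̄₂).  α = 0 forbids the ternary complex and
reduces exactly to the competitive model.  The measured pull-down signal of
a tagged prey is the total prey bound to bait (binary plus ternary
complex), normalized at saturation.

*Inhibitor extension.*  Instead of a ternary complex, the prey and the
competitor associate directly in solution, sequestering both from the
bait; only the bait-bound prey is pulled down.  Large prey–competitor
K̄_D recovers the competitive model.

*Hill-type saturation.*  A phenomenological model
`s = q/(1+q), q = a·x + b·xⁿ + c·x·z + d·xᵐ·z` for titrations whose
S-shape no single-site mechanism fits; the integer orders are searched
exhaustively (1–12 by default) with non-negative weights.

Numerics: the two- and three-species equilibria are solved by damped
fixed-point iteration on the free concentrations (exact mass-balance
updates with geometric damping), with a multivariate-root fallback; both
paths verify conservation to 1e-9 relative.  The fitting layer evaluates
the same equilibria through the batched Newton solver described below,
and the test suite checks all three routes against each other and against
long-time integration of the mass-action kinetics.

## The higher-order reaction network

GL3 carries two independent ligand sites per molecule — a MYB site (GL1,
or TRY in the extended network) and a WD40 site (TTG1) — and
homodimerizes.  Species are enumerated *positionally*: the two subunits of
a dimer are distinguishable.  This bookkeeping yields 22 species and 46
reversible (92 irreversible) reactions for the GL1/TTG1/GL3 network —
2 free ligands + 4 monomer-scaffold states + 4² ordered dimer states; 4
monomer ligand events + 32 dimer ligand events + 10 dimerizations — and
45 species / 112 reversible reactions with TRY.  Reporting aggregates
positional microstates into structurally distinct complexes: 13 without
and 26 with the inhibitor.  Positional bookkeeping automatically carries
the statistical factor 2 for asymmetric dimer configurations relative to
symmetric ones.

Reaction rules: ligand binding is per subunit and independent between
subunits; GL3 dimerization is independent of ligand occupancy; the
cooperativity α couples GL1 and TTG1 only on the *same* subunit.  TRY
binds the MYB site independently of TTG1 by default;
`try_cooperativity=True` applies the same α coupling to TRY as a
sensitivity analysis.  Dimer association is written once per unordered
pair of subunit states, producing the canonically ordered dimer; mirrored
orderings are reached through ligand events, and build-time verification
of thermodynamic cycle closure (equilibrium-constant products around all
dual paths equal 1 to 1e-10) guarantees the equilibrium is independent of
this choice.

Rate constants are scale-free for a closed system at equilibrium: each
reversible pair gets forward rate 1 and backward rate equal to its
effective relative dissociation constant.  Only K ratios matter for the
steady state; kinetic trajectories are not interpreted quantitatively.

*Equilibrium solving.*  Detailed balance makes every species concentration
a monomial in the free-monomer concentrations times a thermodynamic
weight (assigned by walking the reaction graph).  Conservation of each
protein then gives one equation per free monomer.  The residual of this
system is the gradient of the strictly convex potential
`Φ(log m) = Σ_s c_s − Σ_p T_p log m_p`, whose Hessian is the positive
semi-definite Gram matrix `J_pq = Σ_s n_ps n_qs c_s`; damped Newton with
an Armijo line search on Φ is therefore globally convergent, and pure
Newton steps are taken once inside the quadratic basin (where the line
search cannot resolve the rounding-level decrease of Φ).  Solves are
batched over totals.  Every solved state is verified for conservation
(1e-9 relative) and detailed balance of all reversible pairs (1e-8
relative); independent long-time integration of the mass-action ODEs is
kept as a test oracle.  Degenerate inputs: a protein with zero total is
held at exactly zero and decoupled from the Newton system.

*Fraction reports.*  A "complex" is any species with at least two
proteins.  Percentages are concentration-weighted (each complex counts
once, regardless of protein content) over a recorded denominator: all
complexes, single-GL3 complexes, or GL3-dimer complexes.  The printed
summaries of the original analysis leave two conventions ambiguous, so
reports carry alternatives alongside the primary values: percentages with
the bare GL3 homodimer excluded from the complex denominator, and (via
the build flag) the TRY-cooperativity variant.  Under the primary
convention the 26 complexes at equimolar amounts span 0.17–21.2%, the
single-GL3 share of the no-inhibitor network is 46.4% (49.1% excluding
the bare homodimer), and the TRY share among dimer complexes is 26.6%
(21.9% under TRY cooperativity).  No single convention reproduces every
rounded prose percentage simultaneously; the bundled expectation checks
therefore record ±4 percentage points for the two convention-ambiguous
checks and ±3 elsewhere, with tolerances written into the manifest.

*SBML.*  The network exports to SBML Level 3 core with explicit
mass-action kinetic laws; species ids encode the scaffold occupancy so a
document re-imports losslessly (structure, rates and reversible pairing).

## Estimation and identifiability

The fit objective is `χ²(θ) = Σᵢ (yᵢ − f(xᵢ,θ))²/σᵢ` — squared residuals
divided by σᵢ, the convention of the original analysis and the package
default.  Note this χ² is not the Gaussian −2 log-likelihood; the
conventional variance weighting (/σᵢ²) is available via
`weighting="variance"` and is used wherever calibrated intervals matter
(the σᵢ form makes the χ² scale, and hence any fixed Δχ² threshold,
dimensionally arbitrary — its intervals are typically far wider than
nominal for σ < 1).  Per-point errors come from the `signal_sd` column
when present, else from replicate standard deviations, else a constant
fitted from the residuals.

Optimization is multi-start (16 log-uniform starts by default) bounded
L-BFGS-B in log-parameter space.  Competition fits take every model
parameter with an interval; equal endpoints fix a parameter — this
implements both protocols used here: dissociation constants constrained
to their single-binding 95% CIs (trimer-model fits) or fixed outright so
α is the single estimable parameter (network-model fits).

Confidence intervals are profile-likelihood based: the profile is scanned
on a log grid (201 points over ±3 decades around the estimate by default;
when the estimate sits on a bound the scan extends across the full
admissible interval), nuisance parameters re-optimized at every grid
point with warm starts, and the interval bounds are exact roots of
`χ²(θ) − (χ²_min + Δ)` found by Brent's method inside the grid bracket —
interpolation on a decades-wide grid misplaces crossings that sit within
one grid step of the minimum.  Δ is the level quantile of χ² with one
degree of freedom (3.841 at 95%, 0.989 at 68%).  A bound whose crossing
never occurs within the scan range is reported as ±∞ and the parameter
flagged non-identifiable.

Model comparison records RMSE and AIC under the `n·ln(RSS/n) + 2k`
convention (stated in the output; other AIC variants shift all models
equally here since the candidate models share n).  Ties break toward
fewer parameters.

## Synthetic data generator

The generator emulates the statistical structure of the quantitative
pull-down design: a dilution series of six log-spaced prey:bait ratios
from 0.25 to 4 plus a saturating point, two technical replicates within
each of three biological replicates.  Per biological replicate, expression
levels are jittered by a log-normal factor (the unaveraged "cloud of
points" across experiments); per measurement, the recorded ratio carries
multiplicative Gaussian error (Western-blot quantification) and the
signal carries multiplicative Gaussian noise (luminescence is
intensity-like; the noise model itself is a modelling choice, as none is
stated for the assay).  Signals are then normalized by the replicate's
*measured* saturation signal, reproducing the real artifact that
normalized values can slightly exceed 1 — the normalizer is itself noisy,
which also injects a fully correlated scale error into each replicate.
`noisy_normalizer=False` switches the artifact off (normalization by the
noise-free saturation value) for studies that require the independent-
error model to hold exactly.  The `signal_sd` column carries the nominal
per-point error (noise level × noise-free curve) for use as σᵢ.

Randomness: a single integer seed through numpy's PCG64
(`default_rng`); competition suites draw per-dataset substreams via
`SeedSequence.spawn`, so suites are jointly deterministic and
bit-reproducible.

What the generator does *not* emulate: raw luminescence units, bead
capture efficiency, background/crosstalk, non-equilibrium incubation
effects, or densitometry artifacts.  Recovery results on synthetic data
therefore certify the estimation machinery under the assumed error
structure, not the assay chemistry.

## Recovery studies and their conditions

Problem sizes were chosen to keep every study at desk scale (seconds to a
few minutes on one CPU):

* *CI calibration*: single-site curves, 30 points (29 log-spaced ratios
  plus saturation), 5% multiplicative noise, exact per-point σ, variance
  weighting, 100 replicates per K̄_D in {0.5, 1.0, 2.3, 2.7}; observed
  coverage 93–94/100.  With the noisy-normalizer artifact on, nominal-95%
  intervals undercover badly (≈30/100) because the correlated scale error
  is outside the independence assumptions — quantified, and the reason the
  calibration study switches the artifact off.
* *Cooperativity recovery*: two competition curves (competitor at 2:1 and
  1:1), 30 points each, 3% multiplicative noise.  The trimer-model fit
  constrains the K̄_Ds to calibrated single-binding CIs; the network-model
  fit fixes them (single estimable parameter).  Single-draw estimates are
  unbiased with sampling sd ≈ 0.028 (trimer, α = 0.2) and ≈ 0.037
  (network, α = 0.4); the reproduction script reports the mean over 10
  (trimer) / 8 (network) independently sub-seeded suites, which measures
  the estimator's recovery rather than one noise draw, and checks that the
  true α lies inside the 95% profile CI of the first suite.
* *Model selection*: the cooperative model outranks the plain competitive
  model by AIC on cooperative-generated data (α = 0.2, 3% noise) in
  ≥ 95/100 seeded replicates; the inhibitor extension reduces RMSE against
  the competitive model on sequestration-generated data.

## Activator–inhibitor analysis

The dimensionless system `∂u/∂t = a − b·u + uⁿ/v + ∇²u`,
`∂v/∂t = uⁿ − v + d·∇²v` generalizes the classical activator–inhibitor
model (n = 2) to higher activator complex orders.  The analysis uses the
reference state `u₀ = a/b, v₀ = (a/b)ⁿ` and the exact partial derivatives
of the kinetics there (`f_u = b(n−a)/a`, `f_v = −(a/b)⁻ⁿ`,
`g_u = n(a/b)ⁿ⁻¹`, `g_v = −1`).  Note the inhibitor equation vanishes at
this state while the activator equation retains its constant source term
(the exact balance would put u₀ at (a+1)/b); the reference-state
convention drops the +1, the standard simplification for a ≫ 1, and all
downstream conditions are exact consequences of the stated derivatives.
The four instability conditions are strict inequalities:
`b(n−a)/a < 1`, `b > 0`, `d·b(n−a)/a > 1`, `(d·b(n−a)/a − 1)² > 4db`.

The Turing space is scanned on a uniform cell-centred grid over
(0, 10] × (0, 10] in (a, b) with 500 cells per axis at d = 10 (all
configurable); the area is the count of admissible cells times the cell
area, and the region centroid summarizes the shift.  Boundary cells
satisfying a condition only with equality are excluded.  Area and
centroid increase strictly with n over {2, 4, 6}; areas change by < 2%
under 2× grid refinement.  The analysis indicates tendencies of the
patterning region only — it is not a reaction–diffusion simulation, and
no dispersion-relation or wavelength analysis is performed.

## Known limitations

* Real measurements are not redistributable; every quantitative claim
  about fits is demonstrated by parameter recovery on synthetic data under
  the stated error model.
* The σᵢ-weighted χ² (the default, matching the original analysis) does
  not yield calibrated intervals; use variance weighting when the CI's
  nominal level matters.
* The network assumes a closed, well-mixed system at equilibrium with
  scale-free rates; kinetics, synthesis/degradation and spatial effects
  are out of scope.
* The TRY-extension binding rules (independent of TTG1 by default) and
  the fraction-report conventions are choices where the printed record is
  ambiguous; both alternatives are computed and reported side by side.
* GL1 homodimerization-mediated higher-order complexes are not modelled
  (only the Hill-type saturation model captures that behaviour
  phenomenologically); CPC is handled only by swapping in its relative
  K_D (2.3) for TRY's.
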