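# Methods

## Model

### Genome and life cycle

The genome model is haploid-equivalent: the state of a deme is a frequency
vector over all `2**L` haplotypes of `L` ordered loci, and selection acts
multiplicatively on haplotypes.  This is the natural state space for the
gamete-flow recursions the package implements; no source we rely on
specifies dominance, and a diploid with multiplicative selection and random
union of gametes reduces to exactly this recursion.  Where a quantity is
defined at the individual level (the mean-fitness profile W̄(x) entering
the analytic barrier formula), the individual value is the product of two
independent gamete fitnesses, i.e. the squared mean haplotype fitness; this
bookkeeping matters — using gamete fitness directly would halve the
exponent of the barrier integral, and the simulator's measured barriers
numerically confirm the squared form.

The life cycle is **migration → selection → random mating with
recombination**, in that fixed order.  δp is defined as the net change in
the recipient deme's neutral-marker frequency over one full cycle, and Δp
as the between-deme difference at the start of the cycle.  Recombination
uses independent crossover indicators on each adjacent inter-locus interval
(probability `adjacent_r[i]`, no interference); compound recombination
fractions follow by convolution and therefore never exceed 1/2.  Exact
enumeration is capped at L = 10 loci; every analysis shipped here uses 2–4.

Selection is parameterized per locus and environment: in environment *e*
the locally disfavoured allele at a selected locus carries a fitness factor
`1 − s_e`.  Negative `s` (a locally favoured foreign allele) is allowed,
subject to all haplotype fitnesses remaining nonnegative.  Three fitness
modes exist:

- **multiplicative** — product of single-locus factors;
- **pairwise_epistasis** — designated pairs carrying both disfavoured
  alleles contribute a joint factor `1 − s12` in place of their two
  single-locus factors; `s12 = s1 + s2` is the no-epistasis (additive)
  reference, matching the convention of the two-flanking-loci formula.
  Negative coefficients express hybrid advantage;
- **dmi** — an incompatibility factor `1 − penalty` whenever the derived
  alleles of a designated pair co-occur on a haplotype, regardless of
  environment.  Because incompatibilities are expressed in recombinants,
  a secondary-contact barrier of this kind takes one generation to appear,
  peaks early, and then dissolves monotonically as the ancestral alleles
  fix.

### Two demes

`simulate_two_deme` iterates the recursion with either a fixed source deme
(unidirectional, the default: an infinite source) or two coupled demes
(bidirectional).  The run stops when the selected loci have equilibrated
(per-generation change < `convergence_tol`, default 1e-12) *and* the
instantaneous `m_e = δp/Δp` has stabilised; non-convergence within
`max_generations` is flagged on the trajectory, not raised, because
non-equilibrium scenarios (incompatibility dissolution, transient
heterosis) are legitimate uses.  `effective_migration_rate` returns the
slope of δp against Δp through the origin over the post-equilibration
window (or a user-supplied generation window out of equilibrium), and
raises once |Δp| falls below 1e-12 — at that point the demes are
homogenized and the ratio is numerically meaningless.

The closed-form results used as oracles are exact in the low-migration
diffusion limit; the deterministic discrete-generation simulator converges
instead to the discrete lineage value (for one locus,
`m_e/m = r(1−s)/(r + s − rs)`), which differs from `r/(s+r)` by at most
~0.03 in RI over the whole parameter range exercised here.  Comparisons use
m = 1e-4 (1e-5 for the fitness-product chain), small enough that O(m)
corrections are negligible.

`expected_class_fitnesses` computes migrant/F1/backcross mean fitnesses by
propagating the class genotype distribution through selection and then a
backcross to the resident haplotype — not the naive Mendelian dilution,
which ignores the purging of deleterious alleles by selection (the naive
sequence is returned alongside for comparison).  The product
`W̄0·W̄1·W̄2·…` reproduces the simulated `m_e/m` at low migration to ~1e-5;
the truncated shortcut `W̄0·W̄1·W̄2²` (class-2 fitness squared, standing in
for the whole tail because fitness deficits halve per backcross) is
accurate to < 0.01 in RI for the multiplicative architectures tested.

### Pool-matrix effective migration (multiple demes)

For a set of demes with arbitrary migration matrix, individuals are split
into pools (deme × genotype at the selected loci).  Once the selected
backgrounds are at migration–selection equilibrium, the per-generation
dynamics of a neutral marker's frequency within each pool is exactly
linear; the pool transition matrix is built by propagating basis vectors
through one generation of the full recursion (no separate approximation is
introduced).  Pairwise effective migration rates are then extracted by
aggregating this matrix onto its n slowest modes expressed in deme-mean
coordinates, which yields the reduced n×n one-generation matrix governing
the slow between-deme dynamics.  Its off-diagonal entries include
multi-generation flow through intermediate demes — which is precisely how
an interposed deme under selection filters gene flow between non-adjacent
demes.  A reducible/absorbing pool structure or a poor slow/fast timescale
separation triggers a warning.  For two demes the construction agrees with
the simulator's `m_e` to ~1e-11 relative.

### Hybrid zone

`simulate_zone` runs a 1D stepped-stone lattice (default 200 demes) from
secondary contact: left half fixed for one haplotype, right half for the
other.  Interior demes exchange a fraction m/2 with each neighbour per
generation (m is the total emigration fraction; the default m = 0.5), so
the lattice maps to the diffusion limit with σ² = m·spacing².  Boundaries
are reflecting, implemented as symmetric interface exchange, which
conserves summed allele frequency exactly in the absence of selection.
Divergent selection flips sign at the environment step (default: the
central interface).  A physical barrier is an interface transmitting
`k·m/2` (permeability k); it restricts gene flow without being part of RI,
and co-located with a genetic barrier it acts synergistically — the
combined B exceeds the sum of the separate Bs at every marker tested.

### Measuring B

`measure_barrier` fits straight lines to the profile on each side of the
focal interface over demes 2..window (window default 8, the deme adjacent
to the interface excluded), extrapolates both to the interface, and reports
Δp (intercept difference), p′ (mean absolute slope), B = Δp/p′ in deme
spacings and in σ units, plus per-side estimates for asymmetry.  Degenerate
profiles are handled explicitly: flat → B = 0; a step with flat flanks →
B = +inf.

Two practical caveats, both consequences of the estimator rather than the
model, are handled by explicit tools:

1. **Tightly linked markers.**  The neutral marker's effective diffusivity
   is reduced over the region where linkage disequilibrium with the
   selected locus persists, of width ~σ/√r demes.  A fitting window inside
   that region measures a near-field (smaller) B; capturing the full
   barrier of an r = 0.01 marker requires `skip`/`window` set beyond
   ~σ/√r.  Window choice is therefore part of the operational definition
   for tight linkage; the bounded-habitat m_e check below uses
   skip = 10, window = 25 for r = 0.01.

2. **Weak, spatially extended barriers** (B below one deme spacing).  The
   extrapolated step then drowns in the curvature of the still-diffusing
   neutral profile.  `measure_barrier_difference` measures the same
   quantity against a matched no-barrier reference run of the same age:
   the difference field plateaus at ±(B/2)·p′ just outside the
   selection-affected zone, and the plateau is read off directly (offset
   15 demes, averaged over 5).  With this estimator the simulated B for
   s = 0.02 agrees with the analytic integral within 8% at r ∈
   {0.1, 0.25, 0.5} (tolerance used in tests: 20%, as the integral itself
   is a weak-selection approximation).

The analytic barrier `barrier_analytic` evaluates
∫[(W̄(x)/W̄0)^(−1/r) − 1]dx by trapezoidal quadrature on the simulated
(individual-level) mean-fitness profile; `me_from_barrier` applies
m_e = σ²/(2BX); `ecogeographic_barrier` evaluates
B = σ²·n1*·n2*/(m·∫2n1n2dx) for range-displacement isolation, returning
+inf for non-overlapping ranges.

The bounded-habitat check of m_e = σ²/(2BX) requires the two sides to act
as internally well-mixed demes, i.e. the internal mixing time X²/σ² must be
shorter than the exchange time 1/m_e (B ≫ X).  The shipped scenarios — a
1%-permeability physical barrier in a 60-deme habitat, and an s = 0.2,
r = 0.01 genetic barrier in a 100-deme habitat — satisfy this and reproduce
the predicted rate within 5%; weaker barriers visibly violate the premise
and drift toward the internal-diffusion limit, which is why the relation is
quoted only as accurate "within a factor of 2".

## Empirical estimators

The organismal indices and the F_ST inversion are direct formula
implementations with domain checks; the F_ST conversion documents that,
applied to data, it estimates `N_e·m_e` (the migration the loci actually
experienced), not the raw migration rate.  Barrier components combine
sequentially: stage i removes a fraction RI_i of the flow remaining after
stages < i, so per-stage absolute contributions are order-dependent while
the total `1 − Π(1−RI_i)` is order-invariant; the sequential-residual rule
is this package's choice of convention.

### Stepped-cline fitting

The three-part model is a central step with exponential tails:
`p(x) = q·exp(θ_L(x−c))` left of the center and
`1 − q·exp(−θ_R(x−c))` right of it.  A shift of the center within an
inter-site gap can be absorbed exactly into the tail amplitudes, so the
center is pinned by the symmetric-step convention p(c⁻) = 1 − p(c⁺) = q;
this constrained family spans the same functions and makes all parameters
identifiable.  Δp = 1 − 2q, the central gradients are θ·q, and B = Δp/p′
per side and for the side-average.

Fitting minimises Pearson-weighted residuals `(model − freq)/√(p(1−p)/n)`
— asymptotically the binomial maximum-likelihood fit — with a bounded
trust-region least-squares solver, multi-started from the steepest observed
steps plus the transect midpoint (ties toward the midpoint).  Decreasing
transects are flipped internally.  Flat transects (range < 0.1), fits with
a negligible step (Δp < 0.05) or explaining < 50% of the variance raise a
fit-failure diagnostic instead of returning a spurious estimate.  Optional
confidence intervals come from a seeded parametric bootstrap (binomial
resampling of counts under the fitted model).

**Recovery properties.**  Noiseless transects are recovered to machine
precision.  Under binomial noise the information content of the transect
bounds any estimator: a Fisher-information (Cramér–Rao) calculation for the
default truth (Δp = 0.3, B = 40 per side) shows that a 41-site transect at
n = 100/site cannot deliver a median relative error in B below ~18%, with
more than half of the error contributed by the central-gradient estimate.
The default synthetic transect therefore uses dense spatial coverage — 201
sites across 200 distance units — for which the information floor is ~8%
and the fitted median error over 200 seeded replicates is 8–9%.  This
mirrors the field situation: resolving the flanking gradients of a stepped
cline requires dense sampling around the zone, and sparse transects
genuinely cannot estimate B precisely.  Estimator bias decreases with
per-site sample size (checked at n = 20/100/500).

Cross-method consistency (cline fit versus lattice-level `measure_barrier`)
holds once the profile is quasi-steady and the transect resolves the zone
core: a strong-selection zone at generation 2000 sampled at 25 sites
spanning ±25 demes gives agreement within 7%.  A coarse transect (25 sites
across the whole 200-deme habitat) does not resolve the near field and the
two methods then measure different things; this is a sampling-design
statement, not an estimator defect.

## Synthetic data

`riflow.fixtures` generates every input the estimators consume, with the
generating truth returned alongside: stepped-cline transects (binomial
counts or exact expected counts), hybrid-class fitness tables, mating-count
tables, and (δp, Δp) trajectories.  All randomness flows through explicit
integer seeds; identical specs produce byte-identical TSV output.  What the
generator emulates — and what it does not — bounds what the tests show:
transect noise is pure binomial sampling around the true model, with no
spatial autocorrelation of sampling error, no misassigned positions and no
population structure beyond the cline itself, so the recovery study
measures estimator behaviour under the model, not robustness to field
pathologies.  Similarly, the deterministic simulators have no genetic
drift: agreement with closed forms demonstrates the migration–selection–
recombination logic, not finite-population behaviour.

## Numerical choices and problem sizes

- Haplotype frequencies are renormalised only through the selection step;
  migration and recombination conserve them to float precision.
- "Low migration" for analytic comparisons: m = 1e-4 (1e-5 for the
  fitness-product chain); equilibrium at per-generation change < 1e-12.
- Default zone lattice 200 demes; the weak-selection analysis uses 600
  demes and 12 000 generations so the reference profile's diffusion scale
  (√(σ²t) ≈ 77 demes) comfortably exceeds the measurement offset while
  staying clear of the boundaries; the bounded-habitat analyses use 60–100
  demes and 60 000–120 000 generations to resolve the slow equalization.
  All zone states are small arrays (n_demes × 2^L, L ≤ 2 here), so these
  runs take seconds.
- The infinite fitness-class product is truncated once a class fitness is
  within 1e-9 of 1 (after class 3); deficits halve per backcross, so the
  dropped tail is bounded by the last factor squared.
- Trust-region least squares runs at xtol = ftol = gtol = 1e-15 so that
  noiseless recovery is limited by float arithmetic, not the stopping rule.

## Known limitations

- Haploid-equivalent genetics: no dominance, no heterozygote-specific
  fitness, no sex-specific recombination or interference.
- One spatial dimension; no 2D mosaics or non-coincident multi-cline
  geometries.
- Deterministic dynamics: no drift, so F_ST here is only the textbook
  island-model conversion, not a simulated quantity.
- `measure_barrier`'s window-8 default is an operational near-field measure
  for markers with σ/√r larger than the window (see above); comparisons
  across studies must hold the window fixed or work in the far field.
- The pool-matrix reduction assumes the deme-level modes are the slowest;
  with very strong migration relative to selection the timescales blur and
  the construction warns.
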