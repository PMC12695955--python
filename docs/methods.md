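# Methods

This note documents the statistical procedures, their assumptions, the
parameters that matter, and the design decisions taken where more than one
reasonable construction exists. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Beach registry and distances

A colony is a set of named beach segments with centroids in a projected
coordinate system (UTM zone 10N for the shipped study registry). Distances
are Euclidean between centroids — at sub-2-km colony extent the geodesic
correction is far below the beach-level measurement resolution, so none is
applied. Because animals are located only to the beach, every downstream
distance is discrete: two seals on the same 80 m beach are 0 m apart.

Legacy names accumulated over decades of resighting are handled by explicit
alias rules rather than string munging, one of six kinds: `same_as`
(typo/renaming), `midpoint_of_pair` and `centroid_of_cluster` (ambiguous
names covering several candidate sites; coordinates are the arithmetic mean
of the targets), `subdivision_of` (over-specific sub-area names inherit the
parent centroid — no sub-area coordinates exist to do better),
`legacy_coordinates` (renamed gullies with historically mapped positions),
and `omit` (uninterpretable names whose records are excluded with a reason
code). Rules may reference other aliases (a renamed gully can itself have a
typo variant), so resolution iterates to a fixed point. Region membership
is an explicit table, not a geometric predicate: boundaries like "all
beaches north of X" are conventions of the field program, not derivable
from centroids.

The study registry in `philopatry.studymap` carries the real 52-code
structure (40 mapped + 12 aliased, 1 omitted) with *synthetic* stand-in
coordinates laid along a ~3.2 km coastline; real analyses must substitute
the program's own coordinate table.

## Pair definitions

* **Natal beach**: the first beach at which a female was observed in her
  age-0 season (earliest date; same-day ties broken by input row order,
  which is documented rather than hidden because the field convention
  specifies only "first beach").
* **Pupping beach**: the first beach at which her pup of a season was
  observed, by the same rule.
* **Season year**: December observations belong to the following January's
  breeding season (configurable boundary month), matching the
  December-February haul-out.
* **Qualification**: the mother's natal beach must be known and inside the
  colony (immigrants excluded), the pupping beach inside the colony, and
  neither an omitted name. Exclusions carry reason codes
  (`unknown_natal`, `immigrant`, `omitted_beach`, `unknown_beach`) so the
  sample-size accounting of every analysis is reconstructible.
* **Fidelity pairs**: for mothers with k ≥ 2 pupping events,
  first-versus-later pairs (k−1 per mother) feed the fidelity permutation
  test; all unordered event pairs (k(k−1)/2, with their year lags) feed the
  lag regression. A consecutive-pairs-only variant is available behind a
  flag.

## Permutation test

Null: a female's pupping beach is unrelated to her natal (or first-pupping)
beach. Alternative (one-sided): observed pair distances are *shorter* than
chance. Each of `n_perm` replicates (default 10,000) permutes the second
beach column uniformly against the first and recomputes the statistic (mean
or median pair distance); permuting one column is equivalent to shuffling
the pair alignment, which is the exchangeability the null asserts.

`p = #{T_perm ≤ T_obs}/n_perm`, with ties counted (a degenerate all-zero
configuration correctly yields p = 1). No +1 continuity correction is
applied; when the count is zero the result is reported as
`p < 1/n_perm` rather than as exact zero evidence. p-values are exact
conditional on the observed beach multiset when pairs are exchangeable;
repeat mothers induce within-mother dependence in real data, which this
test (like the field's standard practice) does not model — the synthetic
null scenario therefore draws events independently when measuring type-I
error.

## Median quantile regression

Displacement is regressed on maternal age (natal analysis) or lag years
(fidelity analysis) at τ = 0.5 by minimizing the total check loss
Σ ρ_τ(y − a − bx). For a two-parameter line the minimum is attained at a
line through two observations with distinct x, so the solver scores every
such candidate line and returns the exact global minimizer (no iterative
tolerance). With heavily tied predictors the optimum can be non-unique;
the first minimal candidate in pair order is returned deterministically.

Predictor levels observed fewer than `min_level_count = 2` times are
dropped and logged: a lag year represented by a single pair is not
representative of that lag.

Inference is a paired (x, y) bootstrap (default B = 2000, seeded): the
one-sided p for slope > 0 is the fraction of bootstrap slopes ≤ 0, and the
percentile interval of the bootstrap slopes gives the CI. The bootstrap
reuses the candidate-line loss matrix across replicates (any optimal line
for a resample passes through two original points), which keeps the exact
solver inside the loop. The rank-score test is out of scope.

## Multinomial region model

Pup region (Northern/Central/Southern) is modelled on mother natal region
by softmax regression on the aggregated 3×3 table, maximized by Newton
iteration (gradient norm < 1e-8 or 200 iterations, with step-halving).
With one parameter per predictor level the model is saturated: fitted
probabilities equal empirical row proportions and exponentiated
coefficients (relative-risk ratios) equal empirical odds ratios against the
baseline cells — a closed form the tests verify. Wald p-values come from
the observed information matrix. Complete separation (an empty cell) sends
the MLE to infinity; it is detected and handled with a ridge penalty of
1e-6, which is reported in the fit object. Baseline outcome and reference
predictor both default to Southern so that printed contrasts read
"... versus Southern pups"; RRR < 1 is rendered as "1/RRR times less
likely". Mothers contributing several pairs are not given random effects —
the model matches the field's standard single-level analysis.

## Shape diagnostics

**Dip statistic.** The dip of a sample is the smallest sup-norm distance
between its empirical CDF and any unimodal CDF (convex up to a mode,
concave after, possibly with an atom at the mode). It is computed exactly
by bisection on the distance d: feasibility of a given d reduces to
finding a mode placement — entirely convex, entirely concave, or an atom at
one of the (tie-collapsed) sample sites — such that each side admits a
shape-constrained fit inside the band the empirical CDF defines. Each side
is checked with a support-line envelope: the smallest exit slope a convex
fit can have at a site is forced by earlier band edges, and the upper
envelope of those support lines is both a feasibility certificate and the
pointwise-minimal feasible fit. The junction at the mode enforces
monotonicity (convex end ≤ concave start) and the slope chains *through*
the mode — without the latter a concave branch could illegally pause flat
across a between-cluster valley and rise again, understating the dip of
bimodal samples. Ties collapse to sites, so atoms (including constant
samples, dip 0) are exact. Bisection runs 50 iterations on unit-scaled
data (resolution ~1e-13); the statistic is affinely invariant and lies in
[1/(2n), 1/4] for samples with at least two distinct values. The test
suite validates it against an independent LP minimizer over explicitly
parametrized piecewise-linear unimodal CDFs.

The dip test's null distribution is Monte-Carlo from uniform(0,1) samples
of the same size (the standard convention of the test; default
n_boot = 2000, seeded), with p the fraction of null dips ≥ observed.
Beach-snapped distances are heavily tied, which inflates the dip relative
to continuous data of the same shape; the uniform null is the conventional
reference and is reported as such.

**Bimodality coefficient.** bc = (g₁² + 1)/(g₂ + 3(n−1)²/((n−2)(n−3)))
with bias-corrected sample skewness g₁ and excess kurtosis g₂ (the
convention of the common R implementation); a naive-moment variant sits
behind a flag. Values above 5/9 are flagged, not enforced. Undefined for
n < 4 or zero variance. The pipeline computes the dip on the natal
distance distribution and bc on the first-versus-later distribution (the
conventional pairing), and both are available for either.

## Synthetic colony generator

The generator's defaults describe a study-like colony: 40 beaches in three
regions (14/5/21) at 82.5 m spacing (~3.2 km of coastline), 70 females
observed 2001-2023, first pupping at age 3+ (geometric, mean ≈ 3.7),
~1.8 pupping events per female with a 20% annual skip rate, 10% immigrant
mothers, 5% of records written with legacy beach names, and a philopatry
kernel scale λ = 400 m chosen so the simulated mean natal-to-pupping
displacement (~300-400 m against a ~1 km uniform-null mean) resembles a
strongly philopatric mainland colony.

Mechanics, and what they do and do not emulate:

* Beaches lie on a 1-D line; real colonies bend and branch, but distances
  remain matrix lookups either way, so pipeline behaviour is unaffected.
* A female's first pupping beach is drawn with probability ∝ exp(−d/λ)
  around her natal beach (Gaussian kernel behind a flag). Later events
  move from the *first* event's beach by a persistent direction times
  `drift_per_lag_m × lag`, rounded to the lattice, plus a symmetric ±1-step
  noise with P(no step) = 0.7 > 1/2. Consequently the median distance
  between two events L years apart is exactly `drift_per_lag_m × L`
  whenever that is a lattice multiple — the drift recovery scenario uses
  25 m spacing with 50 m/yr drift so the generative parameter is literally
  the regression's target. A per-event-independent displacement scheme was
  rejected because magnitude folding biases small-lag medians once kernel
  spread exceeds the drift.
* `independent_events=True` draws every event fresh from the kernel; the
  no-philopatry preset uses it (with the Gaussian kernel at 10× colony
  length, flat to 1% across the colony) so that the type-I calibration
  scenario actually encodes independence — anchored events induce
  within-mother correlation that a pair-permutation test is not built for,
  and the exponential kernel at that scale still carries a detectable
  tilt toward the natal site.
* Pup records are emitted so the chronologically first sighting is at the
  true pupping beach (including occasional late-December first sightings
  that must roll into the next season); later sightings may wander to
  neighbouring beaches. Alias corruption rewrites only names that resolve
  back to the same site, so truth comparisons stay exact.
* Not modelled: survival, harem structure, founder effects, pup mortality,
  density dependence, 2-D topography. Passing recovery tests therefore
  demonstrates estimator correctness under the stated generative model,
  not robustness to every feature of real colony data.

## Problem sizes and numerical choices

Test-suite operating-characteristic runs use 200 null datasets (type-I),
100 strong-philopatry datasets (power), and 100 datasets per drift level
(CI recovery), each capped at 124 pairs; permutation replicates are 999
(calibration) and 2000 (power) per dataset, and the recovery bootstrap uses
B = 200 — sizes chosen to estimate each rate well inside its acceptance
band. The acceptance script uses 100/50/30 datasets for the same three
sweeps. Analysis defaults remain n_perm = 10,000, B = 2000,
dip n_boot = 2000. All random streams are `numpy.random.default_rng`
children of a single user seed; identical seeds reproduce every output
byte for byte. Quantile conventions are type-7 (linear interpolation)
throughout. Degenerate inputs fail loudly with named errors (constant
predictor, zero-variance bc, empty pair sets naming the exclusion
reasons), never silently.

## Known limitations

* Repeat mothers violate pair independence in the real analyses (natal
  n includes one pair per mother-year); the permutation p is reported in
  the field's standard form without a clustered correction.
* Beach-level resolution floors every distance at the beach spacing;
  quartiles and dip values inherit the lattice.
* The dip's uniform null ignores the discreteness of snapped distances.
* The multinomial model reports sampling-theory Wald p-values from a
  saturated 3×3 table; with small cells the ridge fallback stabilizes the
  numbers but wide intervals should be expected.
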