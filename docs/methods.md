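# Methods

## Model and procedure

Items are i.i.d. pairs (X, Y) with Y one of m class labels and conditional
class probabilities p(a_k | x). The Bayes classifier assigns each x to the
class maximizing p(a_k | x) (ties to the lowest class index, so the induced
sets partition the feature space) and attains the minimal full-coverage
error, the Bayes risk.

An ε-refusal triage rule may instead emit a "no classification" token on at
most a fraction ε of items. Its loss is the joint probability of labeling
*and* mislabeling, L(T) = P[Y ≠ T(X), X ∈ D], under the coverage constraint
P[X ∈ D] ≥ 1 − ε. The optimal rule thresholds the winning-class
probability: D = {x : max_k p(a_k | x) > b}, with the Bayes label on D. The
decision sets are nested in b, so the optimal loss is monotone decreasing in
ε, and the rule factorizes as (decision-set indicator) × (Bayes label),
which the `TriageResult` container asserts structurally.

**Threshold direction.** Coverage decreases as b grows, so "b feasible"
means coverage(b) ≥ 1 − ε and the loss-minimizing choice is the *largest*
feasible b (refuse as much as the budget allows). We adopt that convention
throughout and always report the realized b.

**Finite samples.** On n weighted rows (weights default to uniform 1/n, a
Monte-Carlo stand-in for the feature density), the rule refuses rows in
increasing order of their maximum probability while the refused mass stays
within ε — for uniform weights, exactly ⌊εn⌋ rows when the cut value is
untied. Rows tying exactly at the cut are refused in original-row order
only as far as the one-sided budget allows, so a pure threshold may label
some tied rows; on continuous scores the distinction never materializes.
The budget comparison uses a relative guard of 1e-9 plus 1e-12 absolute so
that cumulative sums of 1/n do not spuriously overshoot ε = k/n.

**Two-class band.** For m = 2 the winning probability is ≥ 1/2 and the
threshold rule is pointwise identical to refusing when the class ratio
p(1|x)/p(0|x) lies in [1/b', b'] with b' = b/(1−b). The domain is
b ∈ [1/2, 1): at b = 1/2 the band is the measure-zero tie set, and b = 1
would refuse everything.

**Empirical rule.** The same machinery applies to the row maxima of any
row-stochastic score matrix (soft-max output). If the scores are a monotone
increasing transform of the true conditionals, the ordering of row maxima is
preserved, hence the refused set at any budget is identical to the oracle's
— the finite-sample shadow of the asymptotic consistency statement, and
exactly what the property tests assert. Fitting a threshold on one score
set and applying it to another is supported (honest out-of-sample
evaluation); applying in-sample is the default in the examples because the
precision–coverage curve of interest is the in-sample one.

**Curve and inversion.** The precision–coverage curve sweeps thresholds over
the sorted distinct row maxima plus a zero endpoint, so it is exact for the
sample: coverage is strictly decreasing and the joint loss non-increasing
along the sweep (raising the threshold can only remove potential errors).
`threshold_for_precision` returns the maximal-coverage point whose precision
meets the target — the operating point that minimizes human workload — and
signals unattainability explicitly via `PrecisionTarget.attainable` rather
than raising or returning a degenerate rule.

**Class-count filter.** Classes that are rare in training tend to carry the
highest per-class error, so `min_count_filter` masks any class with fewer
than `min_count` training examples (typical operating cutoffs: 100, 500,
1000) and `apply_triage` refuses items whose winning class is masked.
Masking lowers realized coverage below 1 − ε; the realized coverage is
always reported as-is, never silently re-normalized into the budget.

## Synthetic models

The generators are 1-D finite Gaussian mixtures: class priors π_k, means
μ_k, scales σ_k. One dimension is a deliberate choice, not a simplification
of convenience only: the posterior is available in closed form, decision
regions {max-posterior > b} are finite unions of intervals whose probability
is an exact difference of normal CDFs, and adaptive quadrature of the
remaining smooth integrands is fast and tight. The shipped defaults are the
symmetric two-class model (equal priors, means ±1, σ = 1; Bayes risk
Φ(−1) ≈ 0.1587) and a mildly unbalanced three-class model.

- `exact_bayes_risk`: 1 − ∫ max_k π_k φ_k(x) dx by `scipy.integrate.quad`
  (absolute tolerance 1e-12), split at the argmax-crossing points located by
  a 4001-point grid scan refined with `brentq`; integration bounds at ±10
  standard deviations beyond the extreme means.
- `exact_triage_risk`: bisection on b ∈ [0, 1] (tolerance 1e-10) for the
  largest b whose decision region keeps mass ≥ 1 − ε — the coverage is
  non-increasing in b with possible flat stretches, and bisection against a
  one-sided feasibility predicate lands on the largest feasible value — then
  integration of density-minus-winning-joint over the region.
- `sample`: labels from the priors, features from the class conditionals,
  and the *exact* posterior attached to every sampled feature, all driven by
  `numpy.random.default_rng(seed)`.
- `corrupt_scores`: applies a monotone transform φ entrywise to the exact
  posteriors and renormalizes rows, emulating an M-consistent upstream
  classifier; optional Gaussian noise on the log scale (seeded). Shipped
  transforms: identity, power γ > 0, and temperature-T scaling
  (p ↦ p^{1/T}, the soft-max of scaled logits). For m = 2 every power /
  temperature transform preserves the across-row ordering of row maxima
  after renormalization; for m > 2 it can break, which the generator
  detects (rank scan at noise 0) and reports with a warning — per-row
  winners are preserved regardless.

What the synthetic data does *not* emulate: high class counts (hundreds of
labels), label noise, covariate shift between fit and apply sets, and
miscalibrated scores that are **not** monotone in the truth. Passing tests
therefore certify the triage machinery — optimality, monotonicity,
consistency under monotone transforms — not the quality of any real
upstream classifier's scores.

## Numerical choices and conventions

- Row-stochasticity tolerances: 1e-9 for exact conditionals, 1e-6 for
  soft-max scores in memory, and 1e-4 *per score cell* on disk (rounded
  exports), where off rows are renormalized with a logged warning.
- Refused items carry the reserved token `REFUSE`; a score table or rule
  whose class labels collide with it is rejected at load time.
- Undefined precision at coverage 0 is NaN, never 0 or 1.
- File outputs format floats with `%.10g`, so identical inputs yield
  byte-identical outputs across runs and platforms; curve round-trips are
  exact to that precision.
- Diagnostics go to the logger / standard error; results only to standard
  output and output files.

## Problem sizes used in the checks

Exhaustive-search optimality is verified on randomized instances with
n ≤ 12 (all 2^n refusal subsets enumerated, 1,000 instances); band
equivalence on 10,000 random two-class rows at five thresholds; the
monotone-transform shadow on 5,000 synthetic items; Monte-Carlo convergence
at n = 10^4 against the quadrature-exact population risk, with agreement
required within three binomial standard errors. These sizes make every
guarantee either exact (enumeration, pointwise set equality) or
statistically sharp at desk scale.

## Known limitations

- The generators are one-dimensional; the triage machinery itself is
  dimension-free (it only consumes probability rows), but quadrature-exact
  risks for multivariate mixtures are not provided.
- Nonuniform weights make budget-constrained refusal a knapsack problem;
  the implementation keeps the thresholding (population-optimal) rule,
  which for pathological weight configurations may not attain the exhaustive
  finite-sample optimum. With the default uniform weights the two coincide,
  which is what the enumeration oracle certifies.
- `exact_triage_risk` refuses ε = 1 (no decision region to characterize)
  and `fit_threshold` refuses empty matrices, both with explicit errors.
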