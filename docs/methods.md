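# Methods

## Problem setting

A diagnostic accuracy trial scores a new test against a comparator
(reference standard) that is itself imperfect. `refnoise` models the
comparator as the ground-truth labels corrupted by *non-systematic*
classification noise — random flips independent of the test result — and
quantifies the resulting distortion of AUC, PPA, NPA, PPV and NPV. Noise
that is *correlated* with the test (reference bias, e.g. the comparator and
the test sharing a failure mode) is explicitly out of scope; it inflates
rather than deflates apparent performance and requires a different model.

## Cohort models

* **Perfect test**: negative scores uniform on [0, 0.4], positive on
  [0.6, 1]. Any disjoint pair of bands satisfies the contract (sample
  AUC exactly 1 for every seed); uniform bands keep plots legible. The
  threshold 0.5 sits between the bands.
* **Binormal**: negatives ~ N(0, 1), positives ~ N(Δ, 1) with
  Δ = √2·Φ⁻¹(AUC), the standard equal-variance binormal ROC model; the
  population AUC equals the target, the sample AUC fluctuates around it
  (SE ≈ 0.01 at 100/100 for AUC 0.98). Threshold = Δ/2.
* **Fixed counts**: binary calls with exactly `round(se·n⁺)` true positives
  and `round(sp·n⁻)` true negatives called correctly; which patients is
  random, so worked 2×2 examples are bit-stable across seeds. Rounding is
  half-away-from-zero everywhere a count is derived from a proportion,
  chosen over banker's rounding for platform stability.

Call convention: `score ≥ threshold` ⇒ positive call; ties at the threshold
are positive.

## Noise injection

All three schemes flip an exact count `round(rate·N)` rather than running
per-patient Bernoulli trials. Exact counts make the x-axis of a sweep the
*realized* noise level, so the spread of the apparent metrics reflects only
which patients were flipped. (A Bernoulli variant would add flip-count
variance; its omission is why the simulated empirical intervals here are
slightly narrower than ones generated by per-patient coin flips at the same
rate.) Uniform mode draws from the pooled cohort, so the realized FP/FN
split is hypergeometric — a deliberate source of the interval width.
Weighted mode draws sequentially with renormalization after each draw
(without replacement: a patient has one label); a zero-weight patient is
never flipped. Injections are never chained: applying ε twice is not 2ε,
because flips can cancel.

## Metrics and intervals

AUC is the Mann–Whitney rank statistic with 0.5 credit for ties, computed
from midranks in O(n log n); an O(n²) pairwise loop is kept in the test
suite as an oracle and the two agree exactly. Metrics with an empty
denominator (e.g. NPV when no test-negative calls exist) are reported as
missing with a count of occurrences, never as zero.

Two kinds of interval appear and should not be confused:

* **bootstrap CI** — patient-level resampling with replacement, percentile
  interval (default 2000 resamples, 95%); quantifies sampling uncertainty
  of a metric on one fixed label set. Percentile rather than BCa, as the
  intervals of interest here are wide and the refinement is immaterial.
* **empirical CI** — 2.5th–97.5th percentile of a metric across Monte-Carlo
  iterations; quantifies the spread induced by *which* patients the
  comparator misclassifies. At zero noise it is degenerate (width 0) by
  construction.

Aggregation across iterations uses medians and percentile intervals, not
means and standard deviations. Default 100 iterations per noise level;
analytic/simulation cross-checks in the tests use 10,000.

Sub-seeding is counter-based: iteration *j* at level *i* uses
`SeedSequence(master, spawn_key=(i, j))`, so a sweep is bit-reproducible
and extending it never perturbs existing cells.

## Closed-form expectations

Because flips are independent of scores and calls, each comparator class is
a mixture of truly-positive and truly-negative patients, giving exact
expectations for the agreement metrics under class-rate injection (the
denominators are deterministic there) and a three-term pair mixture for
AUC; see the README for the formulas. Within-class score exchangeability
(mixed pairs contribute ½) is the key assumption; it fails only if flip
weights depend on the test score. Under pooled uniform injection the
denominators are random and the identities hold approximately (the
discrepancy at 200 patients is < 0.001 in our checks).

The rejection probability of a perfect test under an agreement requirement
(e.g. "PPA ≥ 0.99") treats the observed agreement count as
Binomial(n, per-label accuracy) and evaluates the exact tail; thresholding
is applied to the point estimate, not a CI bound, and the trial size is a
parameter rather than a constant. The relative error (1−AUC)/(1−AUC₀)
normalizes apparent degradation by the noise-free error; it is undefined at
AUC₀ = 1 and the package raises rather than returning infinity.

## Expert-panel comparator

Panelist calls map to probabilities (positive 1, negative 0, indeterminate
½); the patient's confidence is their simple average, so with three
panelists it lies on the lattice {0, 1/6, 1/3, 1/2, 2/3, 5/6, 1}. Labels
follow the confidence (> ½ positive, < ½ negative, = ½ indeterminate);
strata are nested by agreement (super-unanimous requires a matching site
diagnosis on top of unanimity). Two conventions are deliberate package
choices, isolated behind single predicates:

* **Forced-label tie rule**: confidence exactly ½ forces a *positive*
  label ("err on the side of caution" for a treatable condition).
* **Residual uncertainty**: p_wrong = 1 − max(c, 1−c), a probability-scaled
  measure (entropy-like alternatives are not probabilities and would not
  feed the weighted injector directly). Misclassification rates are means
  of p_wrong within each forced-label class, so indeterminate patients
  contribute ½ through their forced label.

The synthetic generator gives each panelist an independent indeterminate
rate and error rate, and the site diagnosis the same error model (binary,
separately configurable). Note that the simple-average confidence is *not*
a calibrated posterior: with accurate panelists at 50% prevalence the mean
residual uncertainty overstates the true wrong-assignment probability
(e.g. 0.146 vs 0.067 at 10% error and 10% indeterminate rate). The test
suite therefore validates the pipeline against the exact expectation of its
own statistic, enumerated over all 27 call triples — the package estimates
comparator uncertainty as adjudication panels report it, not the latent
truth. Panelist non-independence (shared case-report information) is not
modelled.

## What the synthetic data does and does not show

The generators emulate the *structure* of diagnostic trials — class sizes,
score overlap, exact call counts, panel adjudication — with scores that are
exchangeable within class and noise independent of everything else.
Passing tests therefore demonstrate the arithmetic and distributional
behaviour of the estimator under stated noise models; they do not
demonstrate robustness to correlated reference error, covariate-dependent
scores, drifting thresholds or non-independent panelists, none of which the
generators produce.

## Problem sizes and numerical choices

Monte-Carlo checks in the test suite use 100–1,000 iterations for medians
and empirical intervals, 10,000 where simulation means are compared with
closed forms (agreement required within 3 Monte-Carlo standard errors), and
5,000-patient panels for rate recovery — sizes at which Monte-Carlo error
is far below the tolerances being asserted. Grid strings `start:stop:step`
include both endpoints within 1e−9. CSV output is comma-separated UTF-8
with `.` decimals; manifests are sorted-key JSON so reruns diff cleanly.

## Known limitations

* Noise is non-systematic by assumption; reference bias is out of scope.
* Binary states only: no multiclass, time-to-event or covariate models.
* The panel model fixes three panelists (stored as a sequence, so a
  k-panelist extension changes no data model) and assumes independence.
* No deconvolution: the package quantifies the distortion of apparent
  performance; it does not estimate true performance from noisy data.
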