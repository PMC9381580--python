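# Methods

This note documents the statistical procedures the package implements, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## The classification problem and its objective

The clinical setting is pretreatment prediction of pathological complete
response (pCR) to chemoradiotherapy in rectal cancer from biopsy expression
profiles. Because a false pCR call could deny a patient needed surgery, the
primary objective is **sensitivity at zero false-positive rate** (sens₀):
the largest true-positive rate achievable by any score threshold admitting
no negatives. The implementation uses *strict* threshold semantics — a
positive tied with the best-scoring negative does **not** count — so the
"no false positives" guarantee survives ties. AUC (Mann–Whitney form, ties
counted ½) is the secondary measure. Both are checked exactly against an
exhaustive brute-force threshold sweep in the tests.

Labels derive from the tumour regression grade in percent: positive iff
TRG = 100, negative iff TRG < 45, intermediate otherwise; missing TRG can
fall back to a user-declared ordinal mapping (e.g. Dworak 4 → positive),
and otherwise yields *unknown*, which is excluded from training and
evaluation, never imputed.

## Signature discovery

Each of `n_repetitions` (default 500; the test suite and acceptance script
use 100, which is where the selection statistics stabilise at the simulated
effect sizes while keeping a full run in seconds) repetitions:

1. stratified random split of the 32+32 extreme responders, 3/4 training,
   1/4 test (stratification guarantees the objective is defined on the
   8+8 test set);
2. Welch two-sample *t* on the training half (Welch rather than pooled
   variance: the safest default when class variances differ); the top
   `pool_size` = 100 genes by *p*-value form the candidate pool —
   hill-climbing over the whole array would add cost without benefit,
   since genes outside the top 100 essentially never improve the
   objective;
3. greedy forward hill climbing: starting from the empty set, add the
   candidate whose linear SVM (trained on the training half) most improves
   sens₀ on the test half; stop when no addition strictly improves. Ties
   prefer the better differential-expression rank; equal-objective moves
   are rejected, which both guarantees termination (the objective is a
   strictly increasing sequence on a finite grid) and prefers smaller
   feature sets. An optional swap move (`allow_swap`) replaces one selected
   gene by a candidate; forward-only is the default.

Selection counts across repetitions are tested against an exact binomial
upper tail with null rate = (mean selected-set size across repetitions) /
pool size — i.e. the chance a particular pool gene would be picked if
selection were blind within the pool. This binomial formalisation is a
documented design choice; genes with *p* < α (default 0.05) form the
signature, ordered by selection count. The whole procedure is a pure
function of (data, configuration, master seed): per-repetition seeds are
spawned by counter, so results do not depend on execution order.

## The frozen SVM

The final classifier is a linear soft-margin SVM (C = 1, features
standardized to zero mean / unit variance on the training data; the source
study does not state these settings, so they are declared defaults and
configurable). The operating threshold is the largest training-negative
decision value plus one float step: `decision > threshold` therefore cannot
fire on any training negative — a structural, leakage-free reading of
"no false positives" as a deployable rule. Thresholding from test data is
never done.

Frozen with the model are the feature list, weights, bias, standardization
parameters, the operating threshold and the training cohort's reference
quantiles; the JSON artifact round-trips to identical decision values.
Application to an external cohort is: per-sample quantile alignment to the
frozen reference, then the frozen decision function — no retraining. Note
that zero *training* false positives does not bound the false-positive rate
on new negatives; a fresh negative exceeds the maximum of the 32 training
negatives with probability ≈ 1/33 (and slightly more in practice, since
the SVM biases its own training negatives downward), so occasional
validation false positives are expected behaviour, not a defect.

Two SVM engines back the same interface: libsvm via scikit-learn (default
for final models, cross-validation, and the leave-one-out signature
benchmark) and an internal dual coordinate-descent solver (L1-loss,
liblinear-style with an L2-regularized bias term, numba-compiled) used
inside the hill-climb inner loop, where a discovery run needs on the order
of 10⁵ fits of 48-sample problems and per-fit library overhead dominates.
The two agree on the analytic two-point problem exactly and produce
near-identical decision orderings on simulated cohorts (tested); the
regularized bias makes coefficients differ slightly on asymmetric data,
which is immaterial to a ranking objective.

Quantile normalization follows the standard convention: target distribution
= across-sample mean of sorted columns; ties receive the mean of the
reference values over the tied positions. Reference-anchored alignment is
per sample (rank replacement against the frozen vector), the only variant
that supports a single-patient workflow. Normalization acts on the full
matrix before signature subsetting.

## The ratio score

The second classifier avoids normalization entirely:
score = Σ_{g∈numerator} Exp_g / Σ_{g∈denominator} Exp_g on positive
linear-scale intensities, exactly invariant under global rescaling (bitwise
for power-of-two factors, to rounding otherwise). When the input matrix is
log2, values are exponentiated first (`unlog=True`, the trainer's default);
the scale choice is recorded because the original formulation does not
state it. The published 21-gene instance is shipped verbatim — 14 numerator
and 12 denominator symbols with 7 shared, in legacy nomenclature
(KIAA1598/C19orf51/C20orf26/CASC5) resolved through the package alias table
(→ SHTN1/DNAAF3/CFAP61/KNL1); two signature genes (MCM5, STARD3) appear in
neither sum, which is a legal training outcome, so the training universe is
still all 21 genes.

Training: one stratified 50/50 split of the extremes; 100 random restarts
of greedy best-improvement local search over per-gene membership toggles
(4 independent memberships per gene, minus moves emptying the denominator;
the random start is drawn with both sets non-empty, since an empty
numerator scores every sample 0 and strands the search), maximizing
training sens₀; the restart with the highest test-half sens₀ wins (ties:
higher training sens₀, then fewer genes, then restart order). The original
description calls the search "simulated annealing" but specifies a
strictly-improving acceptance rule with no temperature schedule, which is
greedy local search with restarts; that is what is implemented.

## Survival analysis

Kaplan–Meier product-limit estimates and the two-group log-rank test are
implemented directly from the hypergeometric O−E / variance formula (they
are part of this package's evaluation contract) and verified against
lifelines. Score-based prognosis: top/bottom 50% median split (strictly
above the median = high; at-median = low, a declared tie rule), log-rank
per endpoint (OS, DFS), and Spearman correlation between score and TRG.

## The synthetic-data generator

Log2 intensities are Normal(μ_g, σ) with per-gene baselines
μ_g ~ Uniform(6, 14) — a typical two-colour array dynamic range, safely
positive so linear-scale ratios are defined — and σ = `noise_sd` (default
1.0). The first `n_informative` (default 10) genes are shifted by
`effect_size` (default 2.0, i.e. Cohen's d = 2) in positives; with
`graded_effect` the shift instead scales linearly from 0 at TRG = 10 to the
full effect at TRG = 100, which gives Spearman-style analyses signal across
the response range. TRG is 100 for positives, Uniform(10, 44.9) for
negatives, Uniform(45, 99.9) for intermediates. The study-design defaults
(32+32 extremes, 161-case full range) mirror the discovery design; the
effect size and noise level are conventions — the source cohort publishes
no estimates of either — chosen so that the planted signal is strong but
not trivially separable at n = 64.

Validation cohorts reuse the reference cohort's gene universe with
per-gene baselines estimated from the reference *negatives* (whose
informative genes are unshifted; using all samples would leak a fraction of
the class effect into the baseline) plus an additive batch shift, which is
exactly what reference-anchored alignment removes. Survival cohorts draw
exponential event times with hazard ∝ exp(−β·z), z the standardized mean of
the informative-gene residuals, and censor an expected `censor_rate`
fraction uniformly before the event.

What the generator does **not** emulate: probe-level dye or spatial
artifacts, heavy-tailed or correlated noise, batch effects beyond an
additive shift, informative-gene correlation structure, or realistic
censoring patterns. Passing tests therefore demonstrate that the procedures
recover the structure they assume, at the stated effect sizes — not that
the published signature or its printed performance would re-derive from the
real cohorts, which would require the deposited data.

## Numerical choices and degenerate inputs

* Duplicate probes per symbol collapse by per-probe mean after
  normalization (deterministic and symmetric).
* Welch test with zero variance in both groups: t = 0, p = 1, flagged.
* Zero-FPR threshold uses `nextafter` on the max negative decision value.
* Binomial selection test is the exact tail, not a normal approximation.
* Single-column quantile normalization is the identity; single-class
  evaluation inputs raise.
* Missing signature genes: hard error by default; `drop` (with warning,
  for partially measured panels) and `impute-reference-mean` are opt-in.
* All stochastic procedures consume a single integer seed through
  `numpy.random.SeedSequence` substreams.

## Problem sizes used in the checks

The test suite and acceptance script run discovery at 64 samples ×
500 genes × 100 repetitions × pool 100 (about 1.5 s per run), ratio-score
training at 100 restarts over 21 genes, survival calibration on 500–1,000
simulated cohorts of n = 60 and power runs at n = 400. These sizes are
where the Monte-Carlo estimates in the tests stabilise; all scale linearly
if increased.

## Known limitations

* The binomial null for selection frequency treats repetitions as
  independent and pool membership as exchangeable; both are approximations
  (splits overlap, pools vary).
* Per-sample rank alignment assumes the external platform measures the
  same transcript universe; missing-feature handling is the caller's
  responsibility before alignment.
* The dual coordinate-descent engine regularizes the bias; for strongly
  unbalanced or unscaled data the libsvm engine is the reference.
* `sens₀` is a coarse statistic at small n (steps of 1/n₊); confidence
  intervals are out of scope.
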