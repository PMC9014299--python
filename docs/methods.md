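# Methods

## Model and assumptions

`triangulate` fits a two-class latent class model to the joint binary
outcomes of K methods tested against the same n hypotheses.  The latent
status A_i ~ Bernoulli(ρ) is never observed; conditional on A_i the K
calls are independent Bernoulli draws with success probability φ_k
(A=1) or ψ_k (A=0).  The observable data distribution is a mixture over
the 2^K call patterns, and the pattern counts are a sufficient
statistic: all fitting, bootstrapping and simulation-fitting work on the
2^K-vector of counts, so one likelihood evaluation costs O(2^K)
regardless of n.

The identifying assumption is **conditional independence**: given the
truth, one method's call carries no information about another's.  This
is plausible when the methods use genuinely different data and modelling
logic (e.g. heritability enrichment vs. eQTL overlap vs. variance
components) and fails when methods share inputs or errors; correlated
errors bias the estimated specificities upward.  The model also assumes
a **single global prevalence** ρ across all hypothesis pairs rather
than, say, per-trait prevalences — pooling maximizes the information
available to the 2K+1 parameters.

Identifiability requires 2^K − 1 ≥ 2K + 1, i.e. K ≥ 3; fitting with
fewer methods raises `IdentifiabilityError`.  The likelihood is exactly
invariant under (ρ, φ, ψ) → (1−ρ, ψ, φ); fits are reported under the
convention Σ_k (φ_k − ψ_k) ≥ 0 (nonnegative average Youden index),
i.e. the methods are assumed jointly better than anti-informative.

## Estimation

* **Quasi-Newton MLE** (`fit_mle`): all 2K+1 parameters are mapped to
  the logit scale and optimized unconstrained with L-BFGS-B using an
  analytic gradient (gradient tolerance 1e-8, ftol 1e-13).  Multi-start:
  one moment-style start (ρ=0.5; φ_k, ψ_k bracketing each method's
  observed positive rate at ±0.15) plus uniform-random starts, 20 starts
  total by default; the best optimum is kept.  Pattern probabilities and
  parameters are clipped to [1e-10, 1−1e-10] inside the likelihood so
  degenerate data (e.g. a single repeated pattern) yield boundary
  estimates and a `DegenerateDataWarning` instead of log(0) failures.
* **EM** (`fit_em`): an independent implementation of the same
  likelihood used as a cross-check.  The E-step computes each pattern's
  posterior responsibility for the associated class; the M-step updates
  (ρ, φ, ψ) as responsibility-weighted frequencies.  Iteration stops
  when the per-step log-likelihood gain falls below 1e-10 (max 10,000
  iterations); the same multi-start and label convention apply.  The two
  routes agree to ~1e-6 per parameter on well-behaved data; the test
  suite requires 1e-4.
* **Bootstrap** (`bootstrap_operating_characteristics`): rows are
  resampled with replacement, implemented as one multinomial draw over
  the empirical pattern distribution per replicate (exactly equivalent,
  since only pattern counts matter).  B = 99 replicates by default; each
  replicate refits with a reduced start budget (moment + 4 random).  The
  resampling stream of replicate r derives from SeedSequence([seed, r]);
  the fit-start seed is shared across replicates so identical resamples
  give identical fits (this makes the SE exactly 0 for constant data).
  SE is the across-replicate standard deviation; failed replicates are
  dropped with a logged warning and the effective B reported.

## Scoring and FDR

For a fitted (ρ, φ, ψ) the package reports, per pair, the
specificity-weighted score S_i and the posterior
FDR_i = P(A_i = 0 | pattern), computed with single ρ and (1−ρ) mixture
factors — the form consistent with the per-method FDR
ψ_k(1−ρ)/(ψ_k(1−ρ)+φ_kρ).  The overall FDR over the n₊ pairs with
S_i > 0 uses rank-based inverse-normal weights
ω_i = Φ⁻¹((r_i − 0.5)/n₊) + 1 with average ranks for ties.  Two
numerical conventions matter here:

* the quantile points (r − 0.5)/n₊ are symmetric, so untied weights sum
  to n₊ exactly — the count of combined discoveries; ties (common, since
  S takes at most 2^K values) can move the sum slightly, which is logged
  but not an error;
* for n₊ > 3 the lowest-ranked weights are negative; they are clipped
  at 0 inside the overall-FDR average (only there, so the Σω_i = n₊
  identity for the weight vector itself is preserved) to keep the result
  a convex combination of pair-level FDRs — an overall "FDR" outside
  [min, max] would be uninterpretable.

`fdr_at_discovery_count` compares the combined call set with a single
method at a matched number of discoveries m: pairs are ranked by
descending S (ties broken by ascending pair FDR) and the weighted
overall FDR of the top m is returned.

## Threshold sweeps

P-value matrices are binarized at p ≤ t (inclusive — a p-value exactly
at the cutoff counts as significant).  Rows with any missing p-value are
removed first (complete-case filter, count logged).  The default grid is
0.01–0.09 by 0.01 then 0.1–0.9 by 0.1 (18 points).  Each threshold is
fitted independently (no warm starts — reproducibility over speed at
this scale) with its own bootstrap, seeded from SeedSequence([seed,
grid-index]).  Fits with boundary prevalence (ρ̂ < 0.01 or > 0.99) or
any φ̂_k < ψ̂_k are flagged `unstable` in the output rather than
suppressed; an all-null input typically produces exactly such flags.

## Synthetic data

`simulate_binary` draws the latent labels first and the calls
conditionally, which is distribution-identical to drawing pattern counts
from a multinomial over the 2^K theoretical probabilities (the test
suite asserts the pattern frequencies match within binomial bounds) but
additionally yields ground-truth labels for FDR-calibration checks.
`simulate_pvalue_matrix` emulates a multi-method study at the p-value
level: null p-values Uniform(0,1), alternative p-values Beta(a_k, 1)
with 0 < a_k ≤ 1, independent across methods given the label.
Thresholding at t then gives false-positive rate exactly t and
sensitivity t^{a_k}, so the entire ROC curve has a closed form to test
against.  All randomness descends from a single root seed through
`numpy.random.SeedSequence` spawning in fixed order (labels first, then
one stream per method), making every generator bit-reproducible.

What the simulator does *not* emulate: correlated errors between
methods, per-trait heterogeneity in prevalence or power, p-value
inflation/miscalibration under the null, and missingness mechanisms
other than completely-at-random.  Passing tests therefore demonstrate
correctness of the estimator under its own assumptions, not robustness
to their violation on real multi-method data.

## Default study conditions

The validation study built into the tests and the acceptance script uses
three methods with sensitivities (0.35, 0.85, 0.8) and specificities
(0.85, 0.35, 0.8) — one specific-but-insensitive method, one
sensitive-but-unspecific, one good at both — with prevalence ρ = 0.3,
100 simulation repeats, and n ∈ {1,000; 10,000; 100,000}.  The package's
own choices where the design was open: ρ = 0.3 as a realistic interior
prevalence for the recovery study; oracle-equivalence checks at n =
2,000 over 50 seeds; boundary-degradation comparison at ρ = 0.05 vs 0.3
with n = 10,000.

## Known limitations

* Conditional dependence between methods is not modelled; estimates are
  biased when it is present and K is small.
* With K = 3 the model is just-identified; standard errors can be large
  for weakly informative methods (visible in the bootstrap SEs at small
  Youden indices), and estimation efficiency degrades as ρ approaches 0
  or 1.
* The bootstrap reports standard errors only — no percentile or BCa
  intervals.
* The score S takes at most 2^K distinct values, so ranking within the
  combined discovery list is coarse and tie-handling materially affects
  the rank weights.
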