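# triangulate

**Gold-standard-free evaluation of multiple binary testing methods, with
specificity-weighted evidence combination.**

Many discovery problems in genomics ask the same yes/no question of the
same hypotheses with several very different methods — for example, "is
this tissue relevant to this complex trait?" answered by heritability
enrichment, eQTL-based, and variance-component approaches.  The methods
often disagree, and no gold standard exists to say which is right.
`triangulate` is for researchers in that position: it estimates each
method's sensitivity, specificity, and the underlying prevalence of true
associations *without any reference truth*, then combines the methods'
calls into a single score with calibrated false discovery rates.

## The model

Let A_i ∈ {0, 1} be the unobserved truth for hypothesis pair i
(i = 1…n) with prevalence ρ = P(A=1), and let Y_ik be method k's binary
call.  Each method has sensitivity φ_k = P(Y_ik=1 | A=1) and
false-positive rate ψ_k = P(Y_ik=1 | A=0), with specificity
ψ′_k = 1 − ψ_k.  Assuming the K methods are conditionally independent
given A, the likelihood is

    L(θ, ρ) = ∏_i [ ρ ∏_k P(Y_ik | A=1) + (1−ρ) ∏_k P(Y_ik | A=0) ]

With K ≥ 3 methods the 2^K − 1 observable degrees of freedom exceed the
2K + 1 parameters, so (ρ, φ, ψ) is identifiable from the agreement
structure of the calls alone — the classic latent-class (Hui–Walter-type)
idea.  The fit is by quasi-Newton maximum likelihood on the logit scale,
cross-checked by an independent EM implementation, with nonparametric
bootstrap standard errors (99 replicates by default).

On top of the fitted characteristics the package computes:

* **association score** S_i = Σ_k Y_ik ψ′_k / Σ_k ψ′_k — the
  specificity-weighted fraction of methods calling pair i positive;
* **pair FDR** — the posterior P(A_i=0 | Y_i1…Y_iK);
* **method FDR** — ψ_k(1−ρ) / (ψ_k(1−ρ) + φ_k ρ);
* **overall FDR** — a rank-based inverse-normal-weighted mean of pair
  FDRs over the n₊ pairs with S_i > 0, where ω_i = Φ⁻¹((r_i−½)/n₊) + 1
  and Σω_i = n₊ for untied scores.

P-value matrices (wide or long TSV) can be binarized at a threshold t
(positive iff p ≤ t) and swept over a grid — 0.01…0.09 then 0.1…0.9 by
default — to trace each method's estimated ROC curve with bootstrap
whiskers, plus FDR versus the number of discoveries.

## Worked example

`examples/recover_operating_characteristics.py` simulates three methods
of very different quality applied to 20,000 hypothesis pairs (30% truly
associated) and recovers their operating characteristics blind:

```
estimated prevalence rho = 0.326  (truth 0.3)
method  sensitivity (SE)   specificity (SE)   truth phi/spec
  1     0.330 (0.017)      0.852 (0.012)      0.35 / 0.85
  2     0.835 (0.018)      0.355 (0.013)      0.85 / 0.35
  3     0.791 (0.071)      0.814 (0.030)      0.80 / 0.80
```

Each estimate sits within about one bootstrap standard error of the
value used to generate the data, even though no row's true status was
ever revealed to the fit.  The other examples sweep a threshold grid
over synthetic p-value matrices (`threshold_sweep_roc.py`) and build a
scored association table with per-pair and overall FDR
(`score_associations.py`).

A thin CLI wraps the same functions:

```bash
triangulate simulate-pvalues --rho 0.3 --shapes 0.2,0.4,0.6 -n 5000 \
    --seed 1 --out pvals.tsv
triangulate score pvals.tsv -t 0.05 --out atlas.tsv
triangulate sweep pvals.tsv -B 99 --out roc.tsv
```

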