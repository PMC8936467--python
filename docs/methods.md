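# Methods

`basepro` implements an integrative prognosis framework for ER+ breast
cancer built on tumour-intrinsic genomic-aberration signature scores and
tumour-extrinsic immune infiltration scores. This note records the models,
the numerical choices, and what the synthetic benchmarks do and do not
demonstrate.

## Aberration calling

Recurrent events are binary per-sample indicators `X_j`:

* **Mutations** — a gene qualifies when at least one nonsynonymous variant
  is present in at least 10% of the cohort (the denominator is the full
  sample list, including samples absent from the MAF). The default
  qualifying classes are the nonsynonymous point-mutation classes
  (Missense, Nonsense, Nonstop, Splice_Site, Translation_Start_Site) plus
  frameshift/in-frame indels; `include_indels=False` restricts to point
  mutations only. Both readings are supported because the two natural
  descriptions of the event set ("point mutations" vs "mutations and
  indels") differ; indels are included by default.
* **Copy number** — SEG segments (1-based inclusive on disk) are converted
  to 0-based half-open internally and reduced to gene-level values as the
  overlap-length-weighted mean of overlapping segment log2 ratios; genes
  with no overlapping segment are copy-neutral (0). Amplification calls use
  value > log2(2.82) ≈ 1.496 and deletions value < −log2(1.32) ≈ −0.401,
  interpreted literally as bounds on the gene-level log2 copy ratio; both
  thresholds are plain parameters because the phrase "fold increase greater
  than log2(2.82)" also admits a ratio > 2.82 reading. The same 10%
  recurrence rule is applied to CNV events for consistency.

Event columns are ordered mut, amp, del, alphabetically within kind, so the
matrix layout is reproducible.

## Signature weights

For each gene *i* (expression on the log2(x+1) scale), ordinary least
squares regresses expression on all event indicators jointly
(`Y_i = β_{i,0} + Σ_j β_{i,j} X_j`, the multivariate model) or on one
indicator at a time (univariate). The implementation solves the shared
normal equations once and vectorises across genes; p-values are two-sided
coefficient t-tests with n − k − 1 residual degrees of freedom. Genes with
zero expression variance get β = 0, p = 1. A rank-deficient event design
raises an error naming the collinear columns (or drops them when
`drop_collinear=True`).

Weights split by coefficient sign: raw weight −log₁₀ p goes to w⁺ when
β > 0 and to w⁻ when β < 0, is capped at 10 (so p ≤ 1e−10 saturates) and
divided by the range over the union of the two capped vectors, giving
weights in [0, 1] with the most significant gene at exactly 1. Base-10
logarithms are the default (making the cap of 10 correspond to p = 1e−10);
the base and cap are parameters. p-values are floored at 1e−300 before
logging, which the cap makes inconsequential. A β of exactly 0 yields zero
weight on both sides.

## BASE scoring

For sample scoring we use the rank-based BASE statistic ("Binding
Association with Sorted Expression"):

1. **Profile** — each gene is centred by its cohort median; the sample's
   genes are ordered by signed centred value, decreasing (a gene at +2
   ranks before one at −3), and the magnitudes g_k = |centred value| form
   the profile. Median centring makes the ranking reflect sample-specific
   deregulation rather than baseline transcript abundance, and the
   magnitudes are nonnegative so the cumulative curves are monotone.
2. **Statistic** — with weights w aligned to the ranking,
   `f(i) = Σ_{k≤i} g_k w_k / Σ_k g_k w_k` and
   `b(i) = Σ_{k≤i} g_k (1−w_k) / Σ_k g_k (1−w_k)`; the raw score is the
   signed value of f − b at its largest absolute excursion (positive wins
   exact ties). Internally f − b is evaluated as a single cumulative sum of
   `g·(w(1/F + 1/B) − 1/B)`, which is algebraically identical and costs one
   pass per side. Constant weight vectors give exactly zero (f ≡ b is an
   algebraic identity and is special-cased so floating-point residue cannot
   leak through the normalisation).
3. **Null** — the profile order is permuted (gene/weight pairs move
   together) 1000 times; the same permutations serve the w⁺ and w⁻ sides.
   Each raw score is divided by the mean |null deviation| (default) or
   z-scored against the null (`null_norm="zscore"`). If a side's null is
   degenerate the normalised score is 0.
4. **Score** — normalised Score⁺ minus normalised Score⁻. High scores mean
   the sample's deregulation pattern resembles event carriers.

Permutation substreams are keyed on (sample position, weight-set content
fingerprint): independent across distinct signatures, and bit-identical for
duplicated weight sets regardless of label. `share_permutations=True`
reuses one substream per sample across all weight sets — the pipeline's
`run-all` uses this for throughput; it changes scores only at the
Monte-Carlo level of the 1000-permutation null.

**Negative control.** `permutation_control_scores` destroys the gene-weight
correspondence independently for every sample (and control replicate)
before scoring. A single shuffle shared across the cohort is deliberately
not used as the control: one fixed mis-pairing still defines an arbitrary
signature whose chance discrimination on strongly structured profiles
varies widely between draws (we measured a per-draw AUC spread of roughly
±0.15 under the benchmark conditions), whereas the per-sample shuffle has
expected AUC exactly 0.5.

## Immune infiltration scores

Reference profiles for six cell types (naive B, memory B, CD4+ T, CD8+ T,
NK, monocytes) yield per-type weights: a gene's specificity is its
reference expression minus the maximum across the other types (log scale);
the top 100 genes with positive specificity receive w⁺ = s/max(s), all
other weights zero, and w⁻ ≡ 0 (infiltration only adds transcripts).
Samples are then scored with the same BASE machinery. The scores are
relative infiltration levels, not cell fractions; no constrained-regression
deconvolution is attempted.

## Prognosis classification

Ten-year labels: an event at t ≤ 10 years is poor prognosis, follow-up to
or beyond 10 years without an event within them is good, censoring before
10 years excludes the sample. Random forests (500 trees, √p features per
split, unlimited depth, Gini importance; permutation importance available)
are evaluated with stratified 10-fold cross-validation over a canonical
lexicographic sample ordering; out-of-fold probabilities are pooled and
scored once with the Mann–Whitney AUC (ties ½), which equals brute-force
pair counting. Stratification is a variance-reduction choice. Backward
elimination removes exactly one least-important feature per step (ties
broken alphabetically), records the pooled CV AUC at every size, and
returns the highest-AUC set at the fewest features (AUC compared at 1e−4
resolution). Correlated ROC curves are compared with DeLong's test using
the structural-components covariance estimate; identical predictors return
p = 1 with a warning.

## Survival analysis

Cox proportional-hazards fits (Efron ties, via lifelines) serve univariate
score models and clinically adjusted models (age, stage, lymph-node count,
grade, size; ordinal integer coding for grade/stage). Non-convergence is
retried with a small ridge penalty and reported. Kaplan–Meier curves
compare median-dichotomised groups (ties at the median go to the low
group) with the log-rank test. The concordance index counts pairs that are
comparable (both events, or one event strictly before the other's time)
and concordant (higher risk, shorter survival), with risk ties and tied
event times counting ½ — implemented in-package so the pair conventions
are exact, and verified against O(n²) enumeration. Stepwise Cox selection
is forward with backward checks at Wald thresholds 0.15/0.15 (the
conventional defaults of the stepwise Cox routines this mirrors); forced
clinical covariates are never dropped. Trained models assign validation
samples to tertile risk groups by the linear predictor; remainders go to
the lower-risk groups (n = 10 → 4/3/3), and "removing clinical features"
zeroes those coefficients of the fitted model by default
(`drop_covariates`), with refitting available as the alternative.
Cross-validated concordance pools out-of-fold linear predictors over k
folds and scores them once; folds are re-randomised (up to 10 times) if a
training fold lacks events.

## Synthetic cohorts

The generator produces the structure the analysis assumes:

* Expression `= μ_i + Σ_j δ_{i,j} X_{j,s} + Σ_c f_{c,s}·ref_{i,c} + ε`,
  with μ_i ~ N(7, 2) on the log2 scale, noise sd 0.5, and each event's
  planted 150-gene set split half up- half down-regulated by the effect
  size (default 1.0 log2 units). Carrier sets have exact counts
  (round(fraction·n), sampled without replacement) so calling round trips
  are exact. Events are independent by default; an optional Gaussian-copula
  correlation exercises the multivariate-vs-univariate distinction.
* Immune admixture: disjoint marker sets per cell type (default 60 genes at
  reference level ~6 vs ~1 background), Dirichlet fractions (concentration
  30, mean 5% per type) with a non-immune remainder, added
  fraction-weighted to the expression.
* Clinical covariates: age ~ N(60, 10); size ~ LogNormal(ln 2, 0.5) cm;
  grade {1,2,3} at (0.2, 0.45, 0.35); stage {1..4} at (0.3, 0.4, 0.2,
  0.1); node count ~ Poisson(1.5).
* Survival: exponential times with hazard h₀·exp(linear risk), h₀ = 0.05
  events/year, risk linear in event status (0.7 per event) and
  standardised clinical covariates; constant baseline hazard keeps
  proportional hazards exact so Cox recovery is unbiased. Censoring is
  independent uniform C ~ U(0, c_max) with c_max solved by bisection from
  the analytic expected censoring fraction (default 30%).
* Genomic files: one nonsynonymous MAF row per mutation carrier; SEG
  segments exactly covering each CNV event gene at log2 ratio +2.0
  (amplification) or −1.0 (deletion) for carriers and 0 otherwise, on a
  synthetic 1-kb-gene annotation.

All randomness flows from one master seed through named substreams, so
cohorts regenerate bit-identically.

**What the benchmarks show.** Synthetic cohorts have independent genes
(beyond the planted structure), additive effects, exponential survival and
no batch effects, missingness or probe-level noise. Passing tests
demonstrate that the statistics are implemented correctly and recover
planted structure at realistic sizes — not that the framework attains any
particular accuracy on real tumours, where correlated expression programs
and violated proportional hazards will lower all performance numbers.

## Benchmark problem sizes

The self-checks use cohorts of 400–600 samples with 1200–2000 genes and
6–10 events, 1000-permutation nulls, 10-fold cross-validation, and a full
pipeline run at n = 600 × 2000 genes; these sizes were chosen as the
smallest at which the planted-recovery margins are stable.

## Known limitations

* The exact normalisation inside the original BASE statistic and the
  reference immune-score construction are not fully specified upstream;
  both are reconstructed here with the documented, configurable choices
  (`null_norm`, specificity-based immune weights).
* No GISTIC-style significance model for CNV regions, no germline
  filtering, no probe-to-gene mapping (gene-level input assumed), no
  time-varying covariates or competing risks, no probability calibration
  of the forests.
* The Oncotype DX comparator score is an input column (0–100, classes
  0–17/18–30/31–100); the package never computes it.
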