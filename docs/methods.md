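# Methods

`evicalib` calibrates in silico missense predictor scores into two-sided,
ACMG/AMP-style benign/deleterious evidence thresholds and evaluates
competing evidence-assignment schemes. This note documents the models, the
numerical choices, and what the synthetic cohort does and does not
emulate.

## Consensus classification

Each variant carries per-submitter calls in {B, LB, VUS, LP, P}. B/LB and
P/LP are pooled into counts N_B/LB and N_P/LP alongside N_VUS. A variant
is P/LP by consensus iff N_P/LP ≥ max(N_VUS, 1) and N_B/LB = 0 (B/LB
symmetrically); variants with both a B/LB and a P/LP call are excluded as
conflicting, and variants where VUS calls strictly outnumber both sides
are excluded as uncertain. Conflict is checked before the VUS rule; with
these formulas the rules are mutually exclusive and exhaustive (verified
by enumeration), so the ordering only affects which exclusion *code* a
doubly-excludable vector would get, and no such vector exists. A
VUS-vs-called tie goes to the called side because the VUS rule requires a
strict majority. Variants with no calls at all get a distinct
`EXCLUDED_EMPTY` code for debuggability.

## Firth logistic regression

Per-gene variant sets are small and often separable (a score value that
perfectly splits the classes), where ordinary logistic maximum likelihood
diverges. We therefore fit class (P/LP = 1) on a single score by
maximizing the Jeffreys-penalized likelihood
ℓ*(β) = ℓ(β) + ½ ln det I(β), I(β) = XᵀWX, W = diag(π(1−π)),
which always has a finite maximizer. The solver is a Newton iteration on
the modified score U*ⱼ = Σᵢ (yᵢ − πᵢ + hᵢ(½ − πᵢ)) xᵢⱼ (hᵢ the weighted
hat-matrix diagonal), with step-halving (≤20 per iteration) to keep ℓ*
non-decreasing. Convergence is declared at max |Δβ| < 1e−8 or
max |U*| < 1e−6, capped at 100 iterations. Scores are centered and scaled
internally — CADD-scale covariates otherwise ill-condition the Hessian —
and coefficients are back-transformed exactly: the penalty changes only by
a β-independent constant under affine rescaling of the covariate, so
standardization does not move the optimum (the reported ℓ* is adjusted by
ln s to refer to the raw scale). Standard errors come from the inverse
penalized Fisher information at the optimum and are diagnostics only; no
Wald or likelihood-ratio inference on β is offered. Only the
intercept-plus-one-score model is fit, one predictor at a time, on the raw
score scale (no transformation).

The suite cross-checks the solver against an independently coded
dense-grid maximizer of ℓ* on small datasets including complete
separation, and against the closed form logit((s+½)/(n+1)) for the
intercept-only model.

## Two-sided thresholds

A fitted model is inverted at predicted probabilities p_lower = 0.2 and
p_upper = 0.8: T_BE = (logit(0.2) − β0)/β1 and T_DE likewise, so
expit(β0 + β1 T) reproduces the probabilities to machine precision. Scores
at or below T_BE give benign evidence, at or above T_DE deleterious
evidence, and the band in between no evidence; boundary scores qualify
(probability exactly 0.2/0.8 counts as evidence). A missing score always
gives no evidence. Fits with β1 < 0 (a SIFT-like, negatively oriented
predictor) keep their probability-side solutions and are flagged
`orientation="negative"` rather than silently swapped; evidence
comparisons then run in the reversed direction. A slope within 1e−10 of
zero is a degenerate fit and thresholds are refused.

Gene-level thresholds are fit per gene for genes with at least 10 B/LB and
10 P/LP consensus variants; eligibility is counted before missing-score
removal (missing scores are dropped only from the fit). Generalized
thresholds come from one pooled fit with no gene terms.

Confidence intervals use a bootstrap stratified by classification status
(resampling with replacement within the B/LB and P/LP strata separately,
within gene for gene scope — for the pooled scope stratification is by
class only), refitting and re-inverting each replicate, and taking the
percentile interval (5th/95th for the default 90% level). Stratum sizes
are preserved exactly in every replicate. Replicates that fail to converge
or have β1 ≤ 0 are excluded and counted; a CI with more than half its
replicates excluded is flagged unreliable. Percentile was chosen as the
minimal-assumption default; in our coverage study (fixed 150/150 strata,
n = 300, unit-interval score law) basic, normal-with-bootstrap-SE and
studentized variants all landed within a point of percentile, so nothing
better was available. Known limitation: at 200 replicates the 90%
percentile interval covers the true T_DE about 85% of the time, rising
toward ~87% at large replicate counts — a small-sample property of the
threshold functional, which is why the pipeline default is 10,000
replicates. Note the stratified bootstrap targets inference conditional on
the observed class split; coverage statements are with respect to
repeated sampling with the strata held fixed.

## Evaluation

Evidence is assigned by leave-one-out cross-validation: for each variant
the relevant model (its gene's variants for GENE mode, the pooled set for
GENERALIZED, gene-if-eligible-else-pooled for COMBINED) is refit without
that variant, inverted, and applied to its score. Variants with missing
scores get no evidence without fitting; a held-out fit that degenerates
(single class or flat slope) logs a diagnostic and yields no evidence.
GENERALIZED mode refits per held-out variant by default; `refit=False`
uses fixed full-data thresholds instead. The SIFT/PolyPhen2 agreement
comparator — deleterious iff SIFT < 0.05 and PolyPhen2 possibly/probably
damaging, benign iff SIFT ≥ 0.05 and PolyPhen2 benign, otherwise no
evidence — needs no fitting and is evaluated directly.

Calls are tallied against consensus classes with deleterious evidence as
the positive call: TP is deleterious evidence on a P/LP variant, TN benign
evidence on B/LB, FP/FN the corresponding errors, NE no evidence on
either. The summary statistics are PPV = TP/(TP+FP), NPV = TN/(TN+FN),
yield rate YR = (TP+TN+FP+FN)/total and the overall prediction performance
OPP = √((PPV² + NPV² + YR²)/3), computed at full precision and rounded to
3 decimals only when reported. PPV (resp. NPV) is refused, not defaulted,
when no deleterious (benign) evidence was assigned.

Metric differences between two methods are tested by two-sided Fisher
exact tests on the minimal 2×2 tables whose proportions are the metrics:
[[TP_a, FP_a], [TP_b, FP_b]] for PPV, the TN/FN analogue for NPV, and
[[assigned_a, NE_a], [assigned_b, NE_b]] for YR; the comparisons are
unpaired. OPP differences use a Monte Carlo permutation test: the observed
statistic is |OPP_a − OPP_b|, each permutation independently swaps the two
methods' calls per variant with probability ½, and
p = (#{permuted ≥ observed} + 1)/(n_perm + 1). The scheme is pairwise (two
comparators at a time, noted in output metadata). A permuted replicate
with an undefined PPV/NPV contributes a zero difference and is logged —
negligible at realistic sizes. The swap null assumes the two calls of a
pair are exchangeable and pairs independent across variants; calibration
checks must simulate a null satisfying that (two coupled shuffles of one
fixed call vector are negatively dependent across variants and make the
test look spuriously conservative). Under an i.i.d. null the measured
type-I error at α = 0.05 is 5.4%.

Ranks are descending (1 = best) with competition ranking; ties share the
smaller rank and are flagged.

## Synthetic cohort

The generator emulates the structure of a curated ClinVar/dbNSFP
evaluation set: 20 clinically actionable genes totalling 2,153 variants
(gene sizes 40–280), per-gene pathogenic prevalence 0.35–0.65, six numeric
predictors on realistic supports (REVEL [0,1], BayesDel [−1.3, 0.8], CADD
[0, 60], MetaSVM/Eigen unbounded, SIFT [0,1] negatively oriented) plus a
categorical PolyPhen2 call, and per-predictor missingness at observed
dbNSFP-extract rates (5.1% SIFT, 0.6% PolyPhen2, 0.1% MetaSVM, 2.1%
Eigen, none for CADD/REVEL/BayesDel) applied independently of class.

Within a gene, each predictor's scores are class-conditional equal-variance
Gaussians. For such a mixture the posterior log-odds of pathogenicity is
*linear* in the score, so every predictor follows an exactly logistic law
logit P(path | x) = β0 + β1 x with β1 = (μ1−μ0)/σ² — giving closed-form
true thresholds for any probability cutoff, which is what the calibration
and recovery tests check against. Default discriminability is Δ/σ ≈ 2.1 to
2.4 for the meta-predictors (weaker, 1.5, for SIFT), and the per-gene
probability-0.5 midpoints are spread over roughly ±0.15 on unit-scale
predictors to reproduce the wide between-gene threshold variation curated
sets exhibit. Submitter calls (3 per variant) are truth-consistent with
probability 1 − noise (noise 0.1 by default), otherwise VUS or an opposing
label with equal probability. One master seed is split into named
substreams (classes, scores, missingness, submissions, polyphen) so
changing one component never perturbs another.

What the generator does **not** emulate: correlated errors between
predictors (real meta-predictors share training data and features),
skewed or multimodal real score distributions, submitter-specific biases,
gene-size/ascertainment correlations, and any sequence-level structure.
Passing tests therefore demonstrate the *procedure* is correct and
calibrated under its stated model, not that any particular predictor wins
on real data. Distributional choices are simulation conveniences, not
claims about any real cohort. Score clipping to the supports slightly
perturbs the logistic law in the extreme tails; the laws are parameterized
so the affected mass is ≲0.2%, and exactness-sensitive tests use unbounded
supports.

## Problem sizes and defaults

Full-scale defaults follow the analysis constants: probabilities 0.2/0.8,
eligibility floor 10 per class, 10,000 bootstrap replicates for 90% CIs,
10,000 permutations. The test suite scales simulations to desk size —
grid-oracle fits at n ≤ 8, parameter recovery over 200 simulations at
n = 500, coverage over 500 datasets at n = 300 with 200 replicates,
permutation calibration over 500 datasets at 500 permutations — and the
bundled analysis scripts default to 1,000 bootstrap replicates
(`--n-boot 10000` restores the full setting).

## Known limitations

- Thresholds are a global linear-logit calibration per gene; no local
  (per-score-bin) calibration, shrinkage across genes, or non-linear
  models.
- Percentile bootstrap CIs modestly undercover at small replicate counts
  (see above).
- The Fisher comparisons are unpaired even though both methods score the
  same variants; the paired information is only exploited by the OPP
  permutation test.
- No ACMG/AMP evidence-strength tiers and no combination of evidence
  across predictors; one predictor at a time.
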