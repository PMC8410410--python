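# Methods

## Scope and data model

`metamarker` evaluates one continuous expression biomarker across many
independent case/control datasets.  Each dataset is reduced to a
`StudyRecord`: a case arm and a control arm, each summarized as
(n, mean, sample SD), optionally with a 2×2 confusion table
(TP/FP/FN/TN) obtained by dichotomizing the marker.  The packaged
reference tables cover miR-1-3p in head-and-neck squamous cell carcinoma:
18 public microarray datasets plus the TCGA-HNSC miRNA-seq cohort
(484 tumors vs 44 normals).

All readers use TSV with a header (comma-separated via a flag); missing
value tokens ("NA", empty) are dropped with a logged count exposed in the
returned table's `attrs`, never silently.  An optional per-study `log2`
manifest flag applies the transform at load time, since public chips are
reported on mixed scales.

## Group comparisons

Arms are compared with Welch's unequal-variance t-test
(t = |m₁ − m₂| / √(s₁²/n₁ + s₂²/n₂), Welch–Satterthwaite df, two-sided p);
the statistic is reported as a magnitude plus a direction flag, matching
how clinical tables print positive T values.  Multi-level clinical
parameters are compared through declared two-level splits
(e.g. stage III–IV vs I–II).  Strata with fewer than two usable samples
yield a summary row with the test omitted and flagged.

One inconsistency in the packaged reference table is worth knowing:
recomputing the clinical comparisons from its own summary rows matches the
printed T values exactly for tissue (6.048), tumor status (1.967) and
T stage (2.762) under Welch's test, but the pathologic-stage row (2.771)
matches the pooled-variance Student t (2.769; Welch gives 2.737).  The
source evidently mixed the two t-test conventions across rows.  The
package uses Welch throughout.

## Continuous (SMD) meta-analysis

Per-study effects are standardized mean differences
d = (m_case − m_control)/s_p with the pooled SD
s_p² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2).

* `measure="cohen"` (default): variance (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)).
  This is the convention of the classic Stata `metan` command, whose
  output the packaged reference summaries were produced with; it
  reproduces the reference pooled estimates and confidence intervals to
  print precision (fixed −0.58 (−0.74, −0.42) vs reported
  −0.59 (−0.75, −0.43); random −0.42 (−0.79, −0.04) vs reported
  −0.41 (−0.80, −0.03)).
* `measure="hedges"`: multiplies d by the small-sample correction
  J = 1 − 3/(4(n₁+n₂−2)−1).  Preferable on first principles for very
  small arms, and available everywhere, but it matches the reference
  intervals slightly less well, so it is not the default.

Pooling is inverse-variance: fixed-effect weights w = 1/v; the
DerSimonian–Laird random-effects model estimates
τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) and re-weights by 1/(v + τ²).
Q and I² = max(0, (Q − df)/Q)·100 are always reported from the
fixed-effect weights.  Confidence intervals are Wald intervals with
z = 1.96.  Following the usual decision rule, I² > 50% indicates that the
random-effects summary should be preferred.

Sensitivity analysis re-pools (random model) with each study left out in
turn.  Subgroup pooling applies the random model within user-supplied
labels (subgroup membership is configuration, not inference).  Begg's
test rank-correlates the standardized deviates
t_i = (g_i − ĝ_fixed)/√(v_i − 1/Σw) with the variances v_i: for k ≤ 8 the
p-value is the exact permutation tail of the Kendall score; otherwise the
tie-corrected normal approximation with continuity correction.  Tied
variances throughout make the statistic undefined; p = 1 is returned with
a tie flag.

### Known discrepancies against the reference values

* Removing the four named heterogeneity-source datasets (GSE32906,
  GSE32960, GSE34496, GSE45238) and re-pooling the remaining 15 effects
  gives I² ≈ 39% here, against a reported residual I² of 47.0%.  No
  standard SMD variant (Cohen/Hedges, either variance form, with or
  without the TCGA cohort) reproduces 47.0% for this removal set from the
  packaged per-arm summaries; nearby removal sets do produce ≈47%, so the
  reported value likely corresponds to a slightly different computation
  than the one described.
* Begg's test on the 19 effects gives p ≈ 0.89–0.94 depending on the SMD
  measure (reported: 0.961); the conclusion (no evidence of small-study
  bias) is unchanged.

## Diagnostic-accuracy meta-analysis

Per dataset, the empirical ROC uses every observed value as a candidate
cutoff; the AUC is the Mann–Whitney pair-count estimator with ties
counted 0.5.  Because a panel of datasets can contain effects in both
directions, the positive direction (low marker = case, or high = case) is
chosen automatically so AUC ≥ 0.5, unless forced.  The operating cutoff
maximizes the Youden index J = Se + Sp − 1, ties broken toward higher
specificity and then deterministically by cutoff value.

The 2×2 tables are pooled with the bivariate random-effects model:
y_i = (logit Se_i, logit Sp_i) with within-study variances
1/tp + 1/fn and 1/tn + 1/fp (0.5 added to every cell of any table
containing a zero), y_i ~ N(μ, S_i + Ψ) with unstructured Ψ.  Ψ is
estimated by restricted maximum likelihood (Nelder–Mead over log-SDs and
atanh-correlation, three starts); μ and its covariance follow by
generalized least squares.  The fit was verified during development to
agree with an independent REML implementation to six decimals on the
packaged tables.  If the optimizer fails, an independent univariate
DerSimonian–Laird pooling of each logit axis is used and flagged in the
result's `method` field.

Likelihood ratios and the diagnostic odds ratio are derived from the
summary point (PLR = Se/(1−Sp), NLR = (1−Se)/Sp, DOR = PLR/NLR) with
delta-method CIs on the log scale; the log-DOR gradient with respect to μ
is exactly (1, 1).  The summary ROC curve is the Rutter–Gatsonis HSROC
implied by the bivariate fit: with σ₁² = Ψ₁₁, σ₂² = Ψ₂₂,
β = ln(σ₂/σ₁) and Λ = (σ₂/σ₁)^½ μ₁ + (σ₁/σ₂)^½ μ₂, the curve is
logit Se = Λe^(−β/2) + e^(−β) · logit FPR, integrated numerically over
FPR ∈ [0, 1] for the AUC.  When the between-study variances vanish the
shape degenerates to the symmetric β = 0 curve through the summary point.

### Known discrepancies against the reference values

The bivariate fit of the 18 packaged 2×2 tables gives summary sensitivity
0.75, specificity 0.66, PLR 2.19, NLR 0.38, DOR 5.7 and sROC AUC 0.755.
The previously reported set (sensitivity 0.41, specificity 0.77,
PLR 2.31, NLR 0.40, DOR 7.87, AUC 0.83) is internally inconsistent: at
specificity 0.77, the reported PLR of 2.31 implies sensitivity ≈ 0.53 and
the reported NLR of 0.40 implies sensitivity ≈ 0.69, while
PLR/NLR = 2.31/0.40 = 5.8, not the reported DOR of 7.87.  The likelihood
ratios recomputed here (2.19 and 0.38) match the reported ones closely,
and our DOR matches their ratio; the reported sensitivity of 0.41 is
unreachable from the printed tables, whose study-level sensitivities are
mostly above 0.55.  Univariate DerSimonian–Laird and Moses–Littenberg
variants were also checked and do not reproduce the reported set either.
The originally reported pooling covered 19 datasets but only 18 confusion
tables were ever published (the TCGA one was not), which may account for
part of the difference.

## Vote-count DEG screening

Per-dataset tables of (gene, log₂FC, P) are thresholded with strict
inequalities (|log₂FC| > 1 and P < 0.05 by default); a gene counts once
per dataset regardless of direction, and genes appearing in at least
`min_appearances` datasets (default 9) survive.  Survivors are combined
with external evidence lists (transfection-response DEGs, predicted
targets, sequencing DEGs) under a configurable policy — `intersect_any`
(default: supported by at least one non-empty evidence set),
`intersect_all`, or `union` — and split into up/down sets by majority
direction across datasets; ties are excluded with a warning.

## Downstream verification

Over-representation uses the upper hypergeometric tail P(X ≥ overlap)
with every gene set intersected with the user-supplied universe first,
plus Benjamini–Hochberg adjustment.  This is a plain ORA: engine-specific
scores of annotation servers (e.g. EASE-adjusted statistics and curated
backgrounds) are deliberately not replicated, so p-values are comparable
across runs but not with such servers' output.  Hub genes are ranked by
how many of the enriched pathways contain them.  Correlation is the
Pearson product-moment r with the two-sided t-based p.  Survival uses the
Kaplan–Meier product-limit estimator and the two-group log-rank test
(via lifelines); the default high/low grouping is a median split (ties to
"low"), and with zero events the curves are identically 1 and the test is
reported as uninformative (χ² = 0, p = 1).

## Synthetic data

`gen_multistudy_expression` draws study-level true effects
δ_i ~ N(δ, τ²) and normal within-arm values with randomized per-study
location and scale; defaults (k = 19, δ = −0.6, τ² = 0.3, case arms
3–60, control arms 3–40, SD 0.5–3) emulate the size and heterogeneity of
the packaged 19-dataset collection, including its very small arms.  A
log-normal option mimics linear-scale chips.  `gen_deg_tables` plants
signal genes that exceed both DEG thresholds in exactly a chosen number
of datasets against a uniform-p, sub-threshold background — so recovery
tests have an exact expected answer.  `gen_survival_cohort` draws
exponential event times with a group hazard ratio and independent
exponential censoring calibrated to a target censoring fraction.

Generators are pure functions of (config, seed); the seed fans out to
per-study substreams so earlier studies are unchanged when k grows.  The
generators emulate summary-level structure only: no probe-level artifacts,
batch effects, correlated genes, or non-normal expression distributions —
passing recovery tests demonstrates estimator correctness under the
assumed model, not robustness to real-chip pathologies.

Under the default conditions, the DerSimonian–Laird Wald interval's
empirical 95% coverage is about 0.92 (the well-known mild undercoverage
of the DL interval with moderate k and small arms); the recovery test
runs 1000 replicates so the Monte-Carlo error of the coverage estimate
(~0.009) is small against the acceptance band.

## Numerical choices and degenerate inputs

* Welch df denominator underflow (near-constant arms) falls back to the
  pooled-df limit; two constant equal arms give t = 0, p = 1.
* I² is defined as 0 when k = 1 or Q ≤ df, keeping it in [0, 100).
* τ² is truncated at 0; with homogeneous inputs the random model
  reproduces the fixed model exactly.
* Begg deviates guard v_i ≤ 1/Σw with a small epsilon.
* ROC tie-breaks and vote-count thresholds use strict inequalities as
  documented, so boundary rows (|log₂FC| = 1, P = 0.05) are excluded.
* REML uses three fixed starting points; convergence failure triggers the
  flagged univariate fallback rather than an exception.

## Problem sizes

The packaged analyses (19 effects; 18 2×2 tables) run in well under a
second apiece except the bivariate REML fit (~0.3 s).  The simulation
studies used by the test suite — 1000 meta-analysis replicates for
coverage, 100 bivariate-model replicates for accuracy recovery, 200
null-survival replicates — were sized so each completes in seconds to
about half a minute while keeping Monte-Carlo error well inside the
asserted tolerances.
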