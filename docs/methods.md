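# Methods

## Normalization and percentile ranking

Raw counts from a targeted immune RNA panel are not comparable across
sequencing runs; the package normalizes them in two steps.  Per batch, a
no-template control (NTC) estimates reagent/background signal and its
per-gene counts are subtracted from every sample in the batch, floored at
zero (negative adjusted counts are never propagated).  Adjusted counts are
scaled to reads per million (RPM) and the sample's ten housekeeping-gene
RPMs are compared with a locked housekeeping RPM profile; the median of the
ten ratios is the sample's Normalization Ratio, and nRPM = RPM / ratio.
The median makes the ratio robust to a single housekeeping dropout; a
sample whose housekeeping signal is entirely zero is a QC failure and is
excluded and reported, never imputed.

Design choices where the procedure is under-determined:

* **Numerator of nRPM.**  The ratio is defined on RPM, so the default
  divides RPM (not raw adjusted reads) by the ratio; this makes nRPM
  exactly invariant to uniform depth changes.  A `numerator="reads"`
  switch provides the reads-based variant for sensitivity analysis.
* **Percentile convention.**  Ranks are continuous mid-ranks,
  100·(#{r < v} + ½·#{r = v})/N, which is monotone and symmetric under
  ties.  Vendors may use a strictly-less or integer convention; the
  mid-rank choice is documented rather than asserted as anyone's standard.
* **Category boundaries.**  The verbal definitions ("25th–74th") map to
  half-open intervals on continuous ranks: low [0, 25), moderate [25, 75),
  high [75, 100].

Ranking every reference sample against its own reference model yields, by
construction of the mid-rank, a 25/50/25 % low/moderate/high split (checked
at N = 735 within ±3 %).

## Association statistics

The high category of the gene of interest (CD40 by default) is the outcome
throughout.  The univariable screen forms 2×2 tables for age ≥ 61, male
sex, eligible cancer types (n ≥ 15 **or** a high fraction above the cohort
average — the inclusive reading of an ambiguous "and/or" rule; the chosen
list is emitted), MSI, TMB ≥ 10/Mb, PD-L1 IHC, and each other tracked
immune gene.  The odds ratio is the cross product (identical to the
one-covariate logistic MLE), with Wald CI and two-sided Wald p; a zero cell
triggers the Haldane–Anscombe +0.5 correction and flags the result.  The
Wald choice matters only in extreme tables; Fisher's exact test is used for
the cross-tab tables.

Variables with p ≤ 0.05 enter a multivariable logistic model.  MSI/TMB
missingness is handled by chained-equation multiple imputation under MAR:
binary logistic imputation models (each missing variable given all other
covariates plus the outcome) with posterior-draw coefficients, m = 20
imputations and 10 burn-in cycles by default (the source procedure states
none of these constants; these follow common MICE practice), pooled by
Rubin's rules with Barnard–Rubin degrees of freedom.  With no missing data
the pooled estimate collapses exactly to the complete-data MLE.  Perfectly
separated fits fall back to a lightly ridge-stabilized IRLS step and are
flagged.

The combined CD4/8 signature is "high CD4 **or** high CD8" (consistent
with the published margins, where the combined count is at least the larger
and at most the sum of the individual counts); the rule is configurable.

## Differential expression

Expression is log2(nRPM + 1); the pseudo-count tames the zero-heavy low
end of a targeted panel and is configurable.  For each gene a two-group
comparison gives the pooled variance on n₁+n₂−2 df; an inverse-chi-square
prior (d0, s0²) is moment-matched on the log variances (the standard
empirical-Bayes recipe, with a trigamma-inverse Newton solve), and the
moderated t uses the posterior variance with d0 + d degrees of freedom.
If the observed log-variance spread is no larger than sampling predicts,
d0 = ∞ and all genes share s0².  Benjamini–Hochberg adjustment runs over
all genes with non-zero pooled variance; a gene is a DEG when adjusted
p < 0.05 and |log2 FC| ≥ 0.5.

## Mutation enrichment

Gene-level tests compare alteration counts between the high and
low/moderate groups with two-sided Fisher exact tests (point-probability
summation, the convention of mainstream implementations); genes altered in
fewer than 3 samples (default) are untestable and filtered.  Pathway-level
tests first collapse the binary matrix over hallmark-style gene sets with
an any-member-altered rule (threshold configurable; the source analysis
does not state its collapse rule).  q-values are BH within each analysis
level; a feature is significant at q < 0.05 and |log2 OR| > 1.  The
separate top-k comparison takes the union of each group's k most
frequently altered genes (frequency descending, then name ascending on
ties) and applies a Bonferroni threshold of 0.05 / union size.

## Survival

Three endpoint cohorts are built from the clinical table: OS from advanced
disease for immunotherapy-naive patients, and OS / PFS from therapy start
for the treated subset (PFS event = progression or death, whichever first;
alive/progression-free patients are censored at last contact).
Kaplan–Meier curves, Greenwood variances, log-log CIs and the log-rank
test come from lifelines; medians undefined when the curve never reaches
0.5 are reported as missing.  The Cox model maximizes the partial
likelihood by Newton–Raphson (tolerance 1e-9, ≤ 50 iterations, step
halving, covariates internally standardized) with Efron tie handling by
default and Breslow available; monotone likelihoods are detected and
flagged rather than reported as converged.  The gene of interest enters
either as the binary high category or as the continuous 0–100 rank
(per-unit hazard ratio).  The multivariable covariate list is
configuration, not a hard-coded set.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes: a
735-sample locked reference and a 514-sample study cohort across ~30
cancer types with a colorectal-dominant composition (140 colorectal, 55
pancreatic, 49 breast, 43 ovarian, ...).  Counts are Poisson with
log2-mean = gene baseline + loading × latent immune factor (SD 0.8) +
cancer-type shift + N(0, 0.75) residual noise, scaled to a uniform
200k–1M read depth, plus a Poisson(5) background that the per-batch NTC
rows estimate.  Housekeeping genes dominate the library, load zero on the
latent factor, and carry only SD 0.15 residual noise; the CD40 ligand sits
at a low baseline so its distribution peaks at the bottom of the scale.
Baselines and residual noise were chosen so the induced CD40–CD28 rank
correlation lands near the mid-0.4s before compositional attenuation
(observed ≈ 0.35 at n = 514) and CD40–GITR somewhat lower — the ordering
the analysis expects.  Cancer-type shifts elevate CD40 in pancreatic,
liver/bile-duct and ovarian tumors and depress it in colorectal and
head-and-neck tumors.

Clinical covariates: age ~ N(61, 11); 60 % female; MSI ~ Bernoulli(0.03);
TMB lognormal (inflated when MSI-unstable) dichotomized at ≥ 10/Mb;
PD-L1 positivity logistic in the immune factor.  MSI/TMB missingness is
missing-at-random: the probability depends only on the observed cancer
type (alternating type multipliers around target rates of 34/514 and
64/514).  Mutations are Bernoulli with gene-specific baseline log-odds
echoing the pan-cancer landscape and a logistic link to the immune factor
(APC −1.0, CTNNB1 −0.5, CCND1 +0.35, others 0).  Survival times follow
exponential-baseline proportional hazards (baseline medians ≈ 42 / 18 / 5
months for naive OS, ICI OS, ICI PFS) with an immune-factor coefficient of
−0.2 and independent exponential censoring calibrated to a 35 % censor
fraction; 489/514 samples carry curated clinical data and 217/489 of those
are immunotherapy-treated.

What the generator does **not** emulate: overdispersion beyond Poisson,
batch effects other than additive background, gene–gene structure beyond
the single latent factor, informative censoring, and correlated missing
data.  Passing tests therefore demonstrate correctness of the statistical
machinery under a clean generative model, not robustness to real-data
pathologies such as FFPE degradation or panel dropout.

## Numerical conventions and problem sizes

All randomness flows from a single seed through named per-stage
substreams, so identical configurations produce byte-identical outputs.
Parameter-recovery checks use 100 replicates at n = 2000 (m = 10
imputations with 5 burn-in cycles for the MI check), the moderated-t
operating characteristics use 20 replicates of 2000-gene matrices at 50
samples per group, and the Fisher oracle comparison enumerates every 2×2
table with positive margins and total ≤ 40.  The end-to-end pipeline runs
the full 735 + 514 study in a few seconds.

## Known limitations

* The moderated-t implementation covers the plain two-group eBayes fit;
  no variance trend, robust estimation, or precision weights.
* The Cox fitter supports time-fixed covariates only.
* The imputation engine handles binary missing covariates (the MSI/TMB
  case); continuous missingness would need an extra imputation model.
* Reported survival medians on small strata are noisy; their log-log CIs
  are frequently one-sided open, which is expected behavior.
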