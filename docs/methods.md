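# Methods

## Problem and model

`tira` implements a transcriptome-wide association (TWAS) approach to
predicting non-durable response (NDR) versus durable response (DR) to
anti-TNF therapy in Crohn's disease. Rather than training on millions of
genotype markers directly — hopeless at a few hundred samples — the
genotype matrix is first collapsed into per-gene imputed expression values
using pre-trained cis-eQTL weight models (PredictDB layout): for gene *g*
with model weights *w_gk* over cis-SNPs *k*,

    T_g(i) = Σ_k  w_gk · d_k(i)

where *d_k(i)* is the harmonized alternative-allele dosage of sample *i*.
These few thousand derived features, optionally joined with eight clinical
covariates, feed a consensus feature-selection and evaluation engine built
on L1-penalized logistic regression.

The emulated study geometry is 234 patients with 14 NDR cases (~6%
prevalence), the cohort size at which the whole procedure is designed to
remain stable despite extreme class imbalance.

## Genotype quality control

Samples: call rate > 0.95, then heterozygosity rate within ±3 SD of the
cohort mean. The mean/SD are computed once over the samples passing the
call-rate filter (single pass, no iterative re-flagging); population SD; a
sample exactly on the bound passes. Variants: minor allele frequency
≥ 0.05 (MAF = min(f, 1−f), f = mean dosage / 2 over non-missing calls) and
an exact Hardy–Weinberg test p ≥ 0.001.

The HWE test is the Levene–Haldane conditional (exact) test — the default
of standard GWAS QC tooling — not the chi-square approximation. It is
computed in exact integer arithmetic: conditional on the allele counts, the
weight of heterozygote count *h* is the integer
2^h · n! / (n_AA! h! n_aa!), and the two-sided p is the ratio of the summed
weights not exceeding the observed one. Exact integers make the "≤
observed probability" comparison unambiguous (no floating-point tie
hazards); mid-p is off. Continuous dosages are rounded to hard calls for
the genotype counts, since the exact test is defined on counts.

## Expression imputation

Harmonization reconciles each weight record's effect/non-effect alleles
with the genotype file's ref/alt: matching orientation keeps *d*, swapped
orientation maps *d → 2 − d*, any other pair is skipped with a recorded
reason. Strand-ambiguous A/T and C/G sites are accepted on an exact
id+allele match by default (`ambiguous="drop"` skips them). Missing
dosages are mean-imputed per variant with means frozen at fit time, which
preserves the scalar-product form and makes imputation linear across
concatenated cohorts; a skip mode drops the term instead. Genes with no
usable model variant are omitted and listed; per-gene coverage (fraction of
model variants used) is reported.

## Feature assembly

Dichotomous clinical variables are encoded 0/1 with a recorded level map
(male = 1); disease location and behavior are one-hot over their declared
level orders with no reference level dropped (the L1 penalty absorbs the
collinearity); age and all gene features are standardized (x − mean)/SD
with population SD. By default the scaler is fitted on each trial's
training split only and applied to its test split — no leakage; a global
mode standardizes once on the full cohort for fidelity with protocols that
describe a single preprocessing pass. Zero-variance features on the fit
subset are dropped with a warning.

## Consensus selection engine

Each of `n_trials` (default 100) trials:

1. **Constrained split.** An 8:2 train/test split with the case count
   fixed at `case_split` (default 10 train / 4 test); controls fill the
   test set to round(n·0.2), half away from zero (234 → 47: 4 cases + 43
   controls). Deterministic per trial seed (`base_seed + trial index`).
2. **L1 scan.** For each C in 10, 20, …, 100 (C = inverse regularization
   strength), an L1-penalized logistic regression (liblinear coordinate
   descent, tol 1e-6, ≤ 10⁴ iterations) is fitted on the training split
   and scored by stratified 5-fold cross-validated AUC-ROC (folds fixed
   across the C grid within a trial; scaler fitted once on the full
   training split, not per fold). Best C maximizes CV AUC; ties go to the
   smallest C. Survivors are the features with nonzero coefficient in the
   full-training-split fit at the best C.
3. **RFE.** Recursive feature elimination refits a near-unpenalized
   logistic model (L2, C = 10⁶ — chosen so the importance ranking is an
   effectively maximum-likelihood |coefficient| on standardized features)
   and drops the least important feature each round (tie: drop the
   lexicographically last name) until k remain. If fewer than k survive,
   all survivors are returned with a warning.
4. **Evaluation.** A logistic model of the selected features (same
   near-unpenalized convention) is fitted on train and scored on test:
   AUC-ROC with midrank tie handling, AUC-PRC by stepwise
   (average-precision) interpolation. The classification cutoff maximizes
   Youden's J = sensitivity + specificity over the unique score thresholds
   of the test curve (ties: the lower cutoff, i.e. higher sensitivity);
   a train-derived-cutoff mode is provided as the methodologically
   conservative option. No class reweighting anywhere: plain maximum
   likelihood on the raw imbalance.

Selected combinations (sorted name tuples) are tallied across trials; the
modal combination is the reported signature. Metric means/SDs use
population SD. The representative trial minimizes the Euclidean distance
between its (AUC-ROC, AUC-PRC, sensitivity, specificity, precision) vector
and the mean vector, each coordinate divided by its across-trial SD
(zero-SD coordinates omitted); its ROC/PRC points are emitted by the
pipeline. Trial-set comparisons (e.g. between tissue models) use the
two-sided pooled-variance t-test on the AUC lists.

`ConsensusLassoRFE` wraps the engine as a scikit-learn-style estimator
(get_params/set_params, fit, predict_proba); after fit it refits the modal
combination on the full, globally standardized data for prediction.

## Univariate association

Per gene, maximum-likelihood logistic regression of case status on imputed
expression, two-sided Wald p (the PrediXcan association convention; no
multiple-testing adjustment by default). Expression is standardized first
so β is log-odds per SD and comparable across genes; a raw-scale mode
exists because published coefficient tables do not always state the scale.
Perfect separation is detected (disjoint class supports) and reported as a
flagged result with non-finite β rather than a spuriously finite estimate.

## Cohort table and eQTL concordance

Continuous baseline characteristics use the pooled-variance Student t-test
(computable from printed group summaries); categorical ones use Pearson
chi-square without continuity correction, falling back to the two-sided
Fisher exact test when any observed cell of a 2×2 is zero or any expected
count is below 1. Published baseline tables often mix these conventions
row by row, so per-row overrides can force either test; the test used is
always recorded. The two-sided Fisher p uses the point-probability
convention (tables with probability ≤ observed × (1 + 1e-7)).

Direction concordance: with case/control alternative-allele frequencies
(Σ dosage / 2·non-missing per group), an external eQTL slope sign, and the
model's β sign, the record is concordant iff
sign(freq_case − freq_control) × slope_sign = β_sign — e.g. cases carrying
fewer copies of an expression-lowering allele have higher imputed
expression, so a positive β agrees. Equal frequencies are "indeterminate",
not an error. The allele-frequency difference is tested with a Fisher
exact test on the allele-count 2×2 (allele-based, matching how such
frequencies are printed; a genotypic test is deliberately not the
default). External eQTL effect sizes are inputs from a small TSV, never
recomputed: public eQTL-browser values drift across releases and only the
sign enters the analysis.

## Synthetic cohort generator

The generator produces the statistical structure the pipeline assumes,
with full ground truth for recovery tests:

* **Genotypes** — hard-call dosages {0,1,2} drawn from Hardy–Weinberg
  proportions at MAFs uniform on (0.05, 0.5] (the post-QC spectrum);
  continuous-dosage dialects are supported by the readers but the default
  emulates genotyping-array data. No linkage disequilibrium or
  stratification (out of scope).
* **Weight models** — each gene owns a disjoint block of 2–6 SNPs (the
  simplest structure satisfying the cis-model assumption and keeping
  recovery tests unambiguous); a `weight_sparsity` fraction (default 0.7)
  of block SNPs get nonzero weights ~ Normal(0, 0.3) truncated at
  |w| > 0.05, mimicking elastic-net-selected eQTL effect scales. Genes
  drawing no nonzero weight are unimputable: flagged, not emitted — except
  planted effect genes, which are forced imputable so the planted signal
  exists.
* **Expression** — latent expression = weighted dosage sum + Gaussian
  noise (default SD 0.15 against a genetic SD of roughly 0.3–0.4). The
  noise stands for the cis-model's unexplained variance; the default keeps
  the genetic fraction high because the planted-recovery checks probe the
  selection machinery, and the genes such a pipeline reports are precisely
  the well-imputed ones. Real imputed transcriptomes have many genes with
  far lower cis-heritability; passing recovery tests here say nothing
  about signals carried by poorly imputed genes.
* **Phenotype** — logistic model on standardized latent expression of the
  planted genes (default: one gene at log-OR 2.0 per SD) plus weak clinical
  effects (age 0.2, smoking 0.3 log-odds); the intercept is solved (Brent)
  so the expected case fraction equals 14/234, and a rejection mode redraws
  until exactly `n_cases` cases are realized.
* **Clinical covariates** — frequencies typical of a Korean Crohn's cohort
  at first anti-TNF exposure (73% male, 22% smoking, 3% family history,
  location 25/14/61%, behavior 73/11/16%, 5% upper-GI, 39% perianal,
  age ~ N(28, 9) years).

All draws come from purpose-tagged streams derived from (seed, tag), so
adding a generator step never shifts the draws of an existing one and
seeded runs are bit-reproducible.

## Numerical and design choices

* Exact integer arithmetic for the HWE test; Fraction-based enumeration
  oracles in the tests agree to < 1e-12.
* liblinear for all logistic fits (deterministic under a fixed
  random_state); L1 stage tol 1e-6, max 10⁴ iterations.
* Test-size rounding: half away from zero.
* All tie-breaks (C grid, RFE importance, Youden threshold) are
  deterministic and logged per trial.
* Population-SD convention everywhere a SD is used (scalers, trial metric
  summaries); recorded in the scaler record.
* Errors are typed: configuration (exit 2), data (exit 3), stage
  failure (exit 4) — partial pipeline outputs are preserved on failure.

## Problem sizes used in validation

The planted-signal validation runs 100 trials on a 234-sample cohort with
one effect gene among ≥ 500 null genes; the all-null validation uses
60-gene cohorts over several generator seeds; oracle suites cover all
2×2 tables to total 40, sampled genotype triples to n = 200, and
score/label sets to size 30; parameter recovery uses 100 replicates at
n = 5000 and 1000 null replicates at n = 1000. These sizes were chosen as
the smallest at which each property is statistically unambiguous.

## Known limitations

* Relatedness (IBD), ancestry PCA filtering, and reference-panel genotype
  imputation are out of scope; inputs are assumed post-imputation.
* Weight-model training (elastic net on reference transcriptomes) is out
  of scope; the package consumes weight sets.
* The generator plants effects through latent expression only; real
  datasets have LD between gene blocks, pleiotropic SNPs, and
  population structure the generator deliberately omits, so consensus
  frequencies on real data will be less clean than on synthetic data.
* With 14 cases, per-trial test metrics rest on 4 cases; AUC-PRC and
  precision are accordingly noisy, which is exactly why the consensus
  tally, not any single trial, is the reported result.
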