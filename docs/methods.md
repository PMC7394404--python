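# Methods

This note documents the models, procedures and numerical conventions
implemented in `misvote`, the choices made where the design was genuinely
open, and what the synthetic-data experiments do and do not demonstrate.

## Classifier

The classifier is a two-member soft-voting ensemble: a random forest and
an L2-regularized logistic regression, each producing a positive-class
probability, combined as a normalized weighted average

    s(x) = (w_T p_T(x) + w_L p_L(x)) / (w_T + w_L),   w_T, w_L ≥ 0.

The two learner classes are deliberately different in kind: the forest
captures non-linear feature interactions and is insensitive to feature
scale; the regression extrapolates smoothly and degrades more gracefully
when a dominant feature (such as allele frequency) is uninformative for a
given variant. The ensemble assumes its inputs are fully annotated
numeric features; it performs no internal imputation.

**Decision threshold.** A variant is called deleterious iff
`s(x) > 0.5` strictly. A score exactly at the threshold is classified
benign. The boundary had to be assigned to one side; benign is the
conservative choice for clinical shortlists, and the behaviour is pinned
by a boundary test. The threshold is a model attribute and configurable.

**Standardization.** The linear learner receives features standardized to
zero mean and unit variance; the forest receives raw values. During
cross-validated search the standardizer is fit on training folds only; the
persisted model carries the standardizer fit on the full training set.
Standardization is required for the coefficient-based feature ranking to
be meaningful.

**Hyper-parameter search.** Randomized search over a discrete space
(forest: number of trees, depth, feature subsampling, leaf size;
regression: inverse regularization C; voting weights: each from
{0.25, 0.5, 0.75, 1.0}), default 20 candidates evaluated by stratified
k-fold (default 5) cross-validation. The selection objective is mean
held-out AUC; the best configuration is refit on the full training data.
All sampling flows from a single integer seed, and the search history is
stored in the model's training metadata. Class imbalance beyond 10:1
triggers a recorded warning rather than an error.

**Feature selection.** Recursive feature elimination is run per learner:
fit on the surviving features, rank (impurity importance for the forest,
absolute standardized coefficient for the regression), remove the
lowest-ranked, and record the cross-validated AUC at the current feature
count. The elimination step defaults to 7 features per round while more
than 150 remain and 1 thereafter — coarse early steps keep large feature
spaces tractable while preserving single-feature resolution near the
cutoff — and is configurable. Both learners must keep the same number of
features (a requirement of the voting design); each keeps its own set by
default, with a shared set available by passing identical lists.

## Feature taxonomy

The default manifest has 113 features: 6 population allele frequencies
(global, AFR, AMR, EAS, NFE, SAS), 8 conservation scores, 92 functional
measures (CCRS, MPC, and 90 amino-acid substitution features), and 7
upstream predictor scores. Manifest order defines feature-matrix column
order. Amino-acid substitution features are lookups
`M[ref_aa, alt_aa]` in 20×20 AAindex-style property matrices, with
residues in fixed alphabetical one-letter order (ACDEFGHIKLMNPQRSTVWY).
The 90 matrix slots ship with placeholder identifiers and are rebound to
real accessions by loading an AAindex-format flat file (full 20×20 blocks
or lower triangles, which are mirrored); only standard residues are
accepted, and nonstandard letters raise an explicit error rather than
being imputed. Upstream predictor and conservation scores are consumed as
annotation columns only and are never recomputed.

## Dataset construction

Positives are admitted at the highest curation confidence only: a
`Pathogenic` clinical-significance assertion (not `Likely_pathogenic`)
whose review status contains a multi-submitter, expert-panel or
practice-guideline term and no conflicting-interpretation flag; or, from
curated disease-mutation archives, a `DM` status tag exactly (`DM?`
excluded). Negatives come from population records with global MAF
strictly below 1 % and depth strictly above 30X, excluding anything in
the positive sources. All inequalities are taken literally from their
">30X" / "<1 %" definitions and are strict; boundary tests pin depth 30,
depth 10 and MAF exactly 1 % as non-passing. Whether the depth column is
mean site depth or per-sample depth is left to the data supplier; the
filter consumes whatever single depth column is present.

A circularity filter subtracts, from both classes, any variant present in
the training sets of the component predictors (supplied as text exclusion
lists), because evaluating on a component's training variants inflates
performance (type 1 circularity). Negatives are then subsampled without
replacement to match the positive count, and each class is split into
train/test with `floor(n · train_fraction)` training variants (default
0.9). Every sampled artifact is a pure function of its seed.

Training keeps only fully covered variants; for scoring user exomes an
explicit median-imputation mode exists that fills uncovered cells with
per-feature training-free medians and reports the number of imputed cells
per variant, so degraded predictions are visible.

Variant identity is `(chrom, pos, ref, alt)` with `chr` prefixes
stripped for comparison; alleles are matched exactly, with no
normalization or left-alignment, since the pipeline operates on annotated
VCFs whose keys already agree. Multi-allelic records are split per ALT
allele. When a record carries several transcript annotations, the reader
takes the first by default or an entry flagged canonical on request; no
claim is made about which convention upstream pipelines used.

## Metric panel

Twelve metrics derive from the confusion matrix with deleterious as the
positive class: sensitivity, specificity, precision, NPV, accuracy, F1,
MCC, AUC, Log Loss, DOR, FPR, FNR. The panel implements the eight metrics
with explicit definitions in its source material plus accuracy, NPV, FPR
and FNR to complete the twelve.

Conventions:

* **AUC** is the rank (Mann-Whitney) statistic; tied scores receive
  averaged ranks. It is checked against an all-pairs brute-force oracle
  in the tests.
* **DOR** = (TP·TN)/(FP·FN); with a zero denominator and positive
  numerator it is reported as `+inf` (matching how a perfectly specific
  tool is conventionally reported). An optional Haldane–Anscombe +0.5
  correction is available, off by default.
* **Log Loss** has two modes. `probability` (default) is the
  cross-entropy of the continuous scores with each term's probability
  clipped to [1e-15, 1]; clipping is applied per term (to `p` and to
  `1-p` separately) so the loss is class-symmetric to full float
  precision. `hard` evaluates the same divergence on the 0/1 predicted
  classes, which reduces to `misclassification_rate × (-ln 1e-15)` —
  loss values of order 3–5 for ~90 %-accurate classifiers arise under
  this convention, and the report always names the mode used.
* Any other metric with a zero denominator is reported as NaN — an
  explicit undefined marker — never silently as 0.
* Repeated balanced evaluation draws `n_rep` (default 10) balanced benign
  samples per rarity bin without replacement and reports per-metric mean
  and sample standard deviation (ddof = 1; 0 when `n_rep` = 1). The
  rarity bins are MAF < 0.01, 0.005, 0.001, 0.0001 (strict) and
  "singleton", defined as allele count exactly 1.
* Cross-tool comparisons first drop variants missing any tool's score and
  report per-tool missingness percentages.

## Spike-in exome simulation

A simulated disease exome is a benign background plus exactly one spiked
causative variant. Clinical filters are depth strictly above 10X and MAF
strictly below 1 %, with variants lacking a MAF annotation passing (a
novel variant cannot be excluded by frequency); exclusion lists are
subtracted. The causative rank is 1 plus the number of variants scoring
strictly higher — optimistic competition ranking, so ties share the best
rank; a pessimistic mode (ties share the worst rank) is available, and
sorted outputs break score ties deterministically by (chrom, pos). Ranks
are computed within all filtered variants, not only those classified
deleterious. Rank distributions of two tools are compared by a two-sided
Mann-Whitney test: the permutation distribution of U is enumerated
exhaustively for combined n ≤ 12 (exact under ties), and the normal
approximation with tie correction is used above that.

## Synthetic data generator

The generator emulates the class-conditional statistical structure the
pipeline assumes, not any real cohort:

* **Global MAF**: benign variants draw a latent frequency from
  0.01 × Beta(0.5, 20) (rare but observed); deleterious variants are
  absent from the population (frequency 0) with probability
  0.8 × min(1, effect_size/3) and otherwise draw a tenfold rarer Beta.
  Tying the frequency separation to `effect_size` makes the null control
  exact: at `effect_size = 0` both classes share one distribution.
  Frequencies are rounded to allele counts at a fixed allele number
  (250,000) and recomputed as AC/AN, so MAF, AC and AN are mutually
  consistent and "singleton" (AC = 1) is well defined.
* **Population columns** multiply the shared latent frequency by
  lognormal(0, 0.5) noise, clipped to [0, 1] — informative but mutually
  redundant, which is why feature selection can prune some of them.
* **Conservation, functional and predictor features** are Gaussian with
  the deleterious class shifted by `effect_size` standard deviations
  (default 3, a deliberately strong separation for control experiments);
  a `noise_fraction` of them (default 0.1) is label-independent.
* **Substitution features** are matrix lookups on random missense
  substitutions using synthetic symmetric standard-normal matrices —
  label-independent, serving as realistic correlated nuisance structure.
* **Background exomes** use the benign profile with depth
  Normal(45, 12) truncated at 0 and small fractions of MAF-absent (3 %)
  and common, MAF > 1 % (4 %) variants, so roughly 90 % of a generated
  exome survives the clinical filters and a 460-variant draw yields a
  post-filter exome of the ~420-variant scale typical of filtered
  missense lists.

What passing tests on this generator show: the pipeline's plumbing,
filter semantics, seeding and ranking are correct, and the ensemble
recovers class structure when it exists (held-out AUC > 0.95 at 3 sd
separation) and finds none when it does not (AUC ≈ 0.5 on permuted
labels). What they do not show: performance on real variants, whose
feature correlations, annotation gaps and label noise are far richer than
the Gaussian/Beta families used here. Real-data headline numbers depend
on licensed archives and are out of scope.

## Problem sizes and runtime choices

The test suite and the acceptance script size their experiments for a
single CPU: the separable-control ensemble is trained on 2,000 + 2,000
variants × 113 features with 3 search candidates and 3 folds; the
permuted-label control runs 10 seeds at 250 variants per class; the
spike-in study uses 50 exomes of 460 pre-filter variants with a
200-variant causative pool. Fits inside unit tests use reduced manifests
(11 features) and 1–3 search candidates. These sizes are documented as
the package's own experiment design; all of them are parameters.

## Known limitations

* The 90 AAindex matrix slots are placeholders until a real AAindex flat
  file is supplied; shipped synthetic matrices are labelled as such.
* Probabilities are not calibrated (no Platt/isotonic step); scores are
  ranking devices and threshold calls, not calibrated risks.
* The VCF reader handles SNVs only (missense by definition); indels and
  consequence prediction from transcripts are out of scope.
* The exact-permutation rank test enumerates C(n, n1) assignments and is
  limited to combined n ≤ 12 by design; larger samples use the
  asymptotic test.
* `evaluate` reports NaN for undefined metrics; downstream consumers must
  handle NaN and `+inf` (DOR) explicitly.
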