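# Methods

This note documents the statistical model behind each stage, the
synthetic-study generator that the tests run against, the numerical
choices, and the known limits of what the test suite demonstrates.

## Differential screen

Each omics layer is screened independently.  Per feature:

* **Homogeneity gate.**  Levene's test in its original mean-centred form
  (the Brown–Forsythe median variant is available via
  `levene_center="median"`): W is the one-way ANOVA F statistic on
  absolute deviations from the group centre, referred to F(1, N−2).  A
  feature proceeds only if p ≥ α (default 0.05).  Two constant groups
  have trivially equal dispersion and return p = 1.
* **Location test.**  Pooled equal-variance two-sided Student *t* with
  df = n₁ + n₂ − 2.  The pooled variant (rather than Welch) is
  deliberate: the gate has already screened out variance-heterogeneous
  features.  A zero-pooled-variance feature with unequal means is flagged
  degenerate (NaN) rather than assigned an infinite statistic.
* **FDR.**  Benjamini–Hochberg step-up within the layer (features tested
  in that layer only; joint adjustment across layers is a caller choice).
  The screen's significance flag is conjunctive: `levene_p ≥ α and
  q < 0.05`.
* Fold-change is case mean / control mean of the matrix values, with the
  plain difference emitted alongside (`diff`); for a log2-scale
  expression matrix `diff` *is* the log2 fold-change.  Features with any
  missing value are dropped and logged; no imputation.

Cohort description tables use a two-sided Fisher exact test under the
point-probability-sum convention (sum of hypergeometric point
probabilities ≤ the observed one, with 1e-7 relative slack on the
comparison — this convention, not tail doubling, yields the cohort
table's reference p-values 0.03 and 0.003) and the Wilcoxon rank-sum
test (exact null for combined n ≤ 20 without ties, tie-corrected normal
approximation otherwise, no continuity correction).

Gene-level integration: a gene qualifies when it has ≥ 1 significant
feature in both layers; direction labels are the majority sign of the
significant features' `diff`.  The methylation–expression correlation is
Pearson's r between the across-sample means of the gene's significant
CpGs and of its significant transcripts.  Sample clustering z-scores each
feature row and applies complete-linkage agglomeration on Euclidean
distances between samples; a two-cluster cut is reported.  Concordance
between two screens (full cohort vs the gestational-age ≥ 37 restricted
subset) is Kendall's τ-b on the per-feature t statistics (an option:
p-values would serve as well; τ on t was chosen because it preserves
sign information).

## Text mining

Preprocessing follows the order: lowercase → split on non-alphanumerics
→ drop tokens shorter than 4 characters → drop stop words (default:
scikit-learn's English list; any iterable can be passed) → Porter stem.
The Porter stemmer is implemented in `placmine._porter` (the classic
five-step algorithm) and validated against the canonical example pairs.
N-grams (default orders 1–3) are built on the post-filter token stream.

The term matrix is terms × genes with M[i,j] = tf × idf, idf in base-2
log, and tf normalized by one shared denominator — the total number of
terms of all n-gram orders in the gene summary.  Terms appearing in fewer
than 2 gene documents are pruned before weighting (configurable).  Gene
columns are L2-normalized by default ({none, l1, l2} exposed).  A term
occurring in every document has idf = 0 and therefore never appears in
any cluster summary.

LSA is a truncated SVD (ARPACK with a fixed deterministic start vector;
dense LAPACK when k reaches the rank bound, where retained variance is
1 by construction).  Retained variance is Σ retained σ² / ‖M‖²_F.
K-means uses k-means++ with 10 restarts and a fixed seed; cluster
summaries rank terms by the back-projection U·c of the cluster's mean
latent coordinate, flooring negative weights at zero.  Defaults mirror
array-scale practice (k = 1000 components capped at rank, 24 clusters);
synthetic corpora are far smaller, so tests pass k explicitly.

## Phenotype models

Traits: group (classification, accuracy), premature birth = 39 −
gestational age (weeks; > 2 pre-term, ≤ −3 post-term), birth-weight Z
and head-circumference Z (regression, Pearson r with its two-sided p).
Z-scores are either supplied directly or derived from raw measurements
against a user-provided growth reference table (GA × sex → mean, SD,
linear interpolation in GA); no reference values are embedded.

One shared stratified 2/3 : 1/3 split serves all four traits (per-group
allocation ⌊n·ratio + 0.5⌋, seed-controlled).  Feature columns are
standardized with training-set statistics before any distance-based step
— necessary when beta-scale and expression-scale features mix.  SMOTE
runs on the training side only: synthetic minority samples are
x + λ(x_nn − x), λ ~ U(0,1), x_nn among the k = 5 nearest minority
neighbours, until 1:1 balance; for continuous traits the minority
*group* (controls) is oversampled and the target interpolated with the
same λ (a SMOTER-style interpretation, flagged to users).  Grid-search
CV (5-fold, stratified for classification; Pearson r as the regression
selection score) runs over linear/RBF kernels, C ∈ {0.1, 1, 10, 100}
and ε ∈ {0.1, 0.5}; the winner is refit on the full training set, for
classification inside a sigmoid probability calibrator.  Permutation
importance on the untouched test set averages the metric drop over 20
column shuffles (configurable), floors negatives at zero and rescales to
percent of maximum.  The network includes features at ≥ 10% for any
trait, labels those at ≥ 80%, and a supplementary table lists ≥ 50%.

## The synthetic-study generator

The generator emulates the study design: 8 controls vs 28 cases;
gestational age 38.7 ± 0.7 vs 34.0 ± 3.9 weeks; birth-weight Z
−0.07 ± 0.89 vs −2.02 ± 0.75; head-circumference Z 0.22 ± 0.49 vs
−1.30 ± 0.86; 2000 features per layer with 50 planted each
(hypomethylation fraction 0.8; Δβ = 0.4; log2 fold-change 1.5); 200
genes, 10 of them planted in both layers with transcripts negatively
coupled to their CpGs; a 4-topic corpus with 146–167 abstracts per gene
(a realistic per-gene retrieval interval) of 12 pseudo-word tokens
each — abstract length is scaled down from real abstracts since only the
bag-of-stems statistics matter downstream.

Numerical choices worth knowing:

* Betas are logit-normal (per-CpG baseline + logit-scale noise,
  SD 0.35), so they respect [0,1] without clipping and effects compose
  additively on the logit scale.  Planted baselines are drawn
  direction-compatibly so the shifted case mean stays in mid-range
  (≈ 0.15–0.85): array-scale differential CpGs move 0.7 → 0.3, and a
  target near the boundary would crush the beta-scale variance and be
  (correctly) removed by the homogeneity gate.
* Planted features emulate *homoscedastic* differential signals — the
  kind that survive a Levene gate.  The case-group logit noise is
  rescaled by quadrature + bisection so the case mixture's beta-scale
  mean absolute deviation (the dispersion functional Levene compares)
  equals the control group's.  Residual gate losses are then the test's
  own α, which also caps attainable recall at about 1 − α.
* The gestational-age confound: case GA is an equal-weight two-component
  mixture (components placed to match the 34.0 ± 3.9 moments given a
  1.5-week within-component SD), and planted effect sizes are scaled
  1.05×/0.95× by component.  This reproduces two GA-separated IUGR
  sub-clusters under hierarchical clustering.  Stronger scaling makes
  planted features bimodal within cases and the gate rejects them, so
  the confound strength trades off directly against screen recall.
* Traits are group mean + group SD × (√R² · u + √(1−R²) ε), where u is
  the standardized mean of the trait features' latent noise; R² defaults
  to 0.6.  Trait features are planted CpGs plus planted *uncoupled*
  transcripts (coupled transcripts carry their CpG's noise, not their
  own, and cannot act as independent drivers).
* Expression is stored on the log2 scale (positive, variance-stable),
  matching normalized bead-array practice; planted effects are additive
  there.

**The strong-signal cohort** (`strong_signal_config()`) used to
characterize the prediction stage is a deliberately easier, explicitly
named condition: a three-fold cohort (24/84, same ratio and group
moments), trait R² = 0.85 spread over all uncoupled planted features,
and GA coupled to the severity score (ρ = 0.6 — more severe restriction
delivers earlier).  The reason is statistical, not cosmetic: with 36
samples the held-out third contains 12 samples, so a Pearson test at
p < 0.01 demands r > 0.71, and even an oracle predictor of the planted
signal at R² = 0.6 clears that in barely nine test draws out of ten;
the fitted SVM plateaus near r ≈ 0.75 with ~100 features and 24 training
samples per fold regardless of kernel and regularization.  The enlarged
test split (36 samples, r > 0.43 needed) measures the stage's operating
characteristics instead of split lottery.  Trait-feature importance
separation is likewise assessed on importances pooled across seeds,
because a single 12–36-sample test set gives the rank-sum test little
power.

## What passing tests do and do not show

The generator produces Gaussian/logit-normal noise, independent features
(outside the planted couplings), no batch effects, no probe chemistry or
detection-p artefacts, no cell-composition heterogeneity, and a
vocabulary of synthetic stems with uniform topic structure.  Passing
recall/FDR, ARI and prediction checks therefore demonstrates the
*implementation* is correct and well-calibrated under the declared
model — not that real placental arrays would yield comparable error
rates, nor that the published gene lists would be recovered; those
depend on controlled-access data this package deliberately does not
require.

## Degenerate inputs and tie-breaking

Identical groups: t = 0, p = 1; both groups constant: Levene p = 1.
Empty BH input returns empty.  k exceeding the LSA rank bound is capped
with a warning and reports retained variance 1.  K-means ties are
resolved by the seeded k-means++ restarts; grid-search CV ties go to the
earlier grid point.  SMOTE lowers k with a warning when the minority is
small and refuses a singleton minority.  Constant test predictions make
Pearson r undefined and are reported as a failure flag rather than a
number.  All pipeline randomness derives from one master seed through a
seed sequence; the run report records each stage's sub-seed.

## Problem sizes used in the checks

Screen characteristics: 200 null replicate cohorts (2000 features, 8 vs
28) and 10–20 planted replicates; text mining: the 200-gene default
corpus; prediction: 50 strong-signal cohorts; determinism: two complete
runs of a reduced configuration (500 features/layer, 60 genes, 6–10
abstracts/gene).  These sizes keep a full verification run within a few
minutes on one CPU while leaving every stage's statistics measurable.
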