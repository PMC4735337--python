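# Methods

This note documents the models, algorithms and numerical choices behind
`subtypecurves`, in the spirit of a statistical software appendix: enough
detail to reimplement every stage, plus an honest account of what the
synthetic benchmarks do and do not demonstrate.

## 1. The synthetic cohort generator

The generator (`subtypecurves.simulate`) emulates a bulk RNA-seq cohort of
breast tumours with known ground truth. Its defaults describe the
reference study conditions; everything is overridable per experiment.

**Subtype labels.** `n_samples` (default 885) samples are apportioned over
the five intrinsic subtypes (Basal, Her2, LumA, LumB, Normal) by
deterministic largest-remainder allocation of `class_proportions`
(default 132/65/393/190/105 ÷ 885, a luminal-heavy clinical mix), then
shuffled by seed. Largest-remainder allocation rather than multinomial
sampling keeps class counts exact, so stratified-sampling arithmetic is
testable without Monte-Carlo slack.

**Expression model.** Each gene has a baseline log2 mean drawn once from
N(`baseline_log2_mean`=3, `baseline_log2_sd`=2). A random subset of
`n_informative` (default 600 of 20477) genes is subtype-informative: each
class shifts each informative gene by ±`effect_size` with probability
`informative_activation`=0.5 (sign random). LumB does not draw its own
shifts independently — with probability `lumAB_correlation` (default 0.8)
it copies LumA's shift for that gene. This single parameter is what makes
the two luminal classes molecularly similar and produces the
LumA↔LumB-dominated confusion structure downstream.

**Counts.** Per-sample library sizes are log-normal with mean
`library_size_mean`=5×10⁶ and CV 0.3. Gene means are the softmax of the
latent log2 profile times the library size; counts are gamma-Poisson
(negative binomial) with a single global `dispersion` (default 0.35;
var = μ + φμ²). A global dispersion is a simplification — real data show
gene-dependent dispersion — but it is the minimal overdispersion model
that breaks Poisson-based reasoning in the right way.

**Receptor status.** The biological truth is deterministic in the
subtype: ER⁺ ⇔ luminal, Her2⁺ ⇔ Her2-enriched; PR is Bernoulli
conditional on ER (0.85 / 0.05). Truth raises the latent mean of the
matching marker gene (ESR1, PGR, ERBB2) by `marker_shift`=3 log2 units
*before* counts are drawn. The clinical labels the models train on are
the truth passed through independent label flips with
`receptor_noise_rate`=0.05 — the emulation of assay/chart noise that puts
a ceiling of ≈1−r on any classifier's achievable accuracy.

**Calibration of the defaults.** The reference analysis gives no
generative model, only the shape of its results. `effect_size` and
`dispersion` were therefore calibrated once, jointly, so that default
cohorts yield a supervised learning curve that rises through N≈100–350
and flattens in the high-0.80s on a 50-gene informative panel —
qualitatively the published shape — and were then frozen at 0.7 and 0.35.
No other default was tuned against downstream results.

**What the generator does not model:** batch effects, gene–gene
correlation beyond class structure and library size, isoforms, gene
length bias, contamination, and any raw-read phenomena. Consequently,
passing benchmarks here demonstrates the *pipeline logic and statistical
machinery*, and the qualitative orderings (more samples → better; deeper
→ better up to a plateau; unsupervised ≤ supervised; luminal confusion
dominates); they do not certify the absolute accuracies one would obtain
on clinical data.

## 2. Preprocessing

- **Normalization:** median-of-ratios size factors (the "DESeq" method):
  for genes with all-positive counts, the per-sample median of
  count/geometric-mean ratios. The median is taken on the ratio scale
  (interpolation on the log scale differs at even reference counts, a
  subtle bug the brute-force oracle test caught). Expression is
  log2(count/sf + 1); the pseudo-count keeps zeros finite and centroids
  interpretable in log2 units. The transform itself is a design choice —
  the field standard — since only the normalization method is dictated.
- **Feature selection:** the top-`fraction` genes by variance with
  ceiling retention (20477 × 0.25 → 5120) and ties at the boundary broken
  by input order; or an explicit gene panel, in panel order, with missing
  genes reported.
- **Read thinning:** per sample with total T > target, every gene count is
  replaced by Binomial(count, target/T). This is expectation-equivalent
  to read-level subsampling given that the artifact starts from count
  matrices; zeros are preserved and counts never increase. Depth
  experiments recompute size factors after thinning.
- **Outlier flagging:** an automatic surrogate for visual PCA inspection:
  samples are flagged when their Hotelling score distance on the first
  k components or their reconstruction residual exceeds an empirical
  quantile (default 0.99 on both).

## 3. Classifiers

All three families sit behind one train/tune/predict contract on
samples × genes matrices.

- **Nearest shrunken centroids** is implemented from the published
  formulas. Standardized class-vs-overall contrasts
  d_ik = (x̄_ik − x̄_i)/(m_k(s_i+s0)) with m_k = √(1/n_k − 1/n) (the
  variance factor when the class mean is part of the overall mean) are
  soft-thresholded by Δ; centroids are rebuilt and samples assigned by
  min_k Σ_i (x_i−x̄'_ik)²/(s_i+s0)² − 2 log π_k. s0 is the median of the
  pooled within-class SDs; priors are empirical. Ties in the argmin
  resolve to the first class in label order.
- **Elastic net** delegates to scikit-learn's saga multinomial logistic
  regression (true multinomial loss, not one-vs-rest); the grid is
  parameterized by mixing weight α (l1_ratio) and penalty strength λ
  (C = 1/λ); features are standardized on the training fold.
- **Random forest** delegates to scikit-learn with `n_trees` and
  `max_features` tunable.

**Tuning** is stratified inner k-fold CV (default 5 folds) over the
`ClassifierSpec` grid in product order, maximizing mean fold accuracy with
first-occurrence tie-breaking; a single-point grid short-circuits without
fitting. Default grids are desk-scale: α ∈ {0.1,…,1.0} × 20-point λ path,
500 trees × {√p, p/4} features, 15-point NSC threshold path.

## 4. Learning-curve engine

A round draws a stratified outer test set of round(0.10·N) samples
(largest-remainder over classes, so test composition matches the cohort),
then for each training size a stratified subset of the remaining pool.
"100-fold cross-validation" is interpreted as 100 independent repetitions
of this holdout procedure (`n_rounds`), not a 100-fold partition. Within
a round all conditions (classifier, feature set, depth) share the same
outer split, so comparisons are paired. All seeds derive from a single
master seed through named SeedSequence streams; identical configs are
byte-identical on disk. Per-class accuracy is recall (the diagonal of the
row-normalized confusion matrix); balanced accuracy is the unweighted mean
of recalls over classes present; SEM is SD/√rounds, reported as 0 for a
single round. Infeasible sizes are skipped with a warning.

## 5. Receptor-status curves

Univariate logistic regression (unpenalized MLE) of clinical status on
marker expression. The ROC is exhaustive: cutpoints are midpoints between
adjacent distinct scores plus ∓∞ sentinels; "positive" means
score ≥ cutpoint. The operating point maximizes Youden's J with ties
broken toward higher specificity, then toward the larger cutpoint —
fully deterministic. The cutoff is chosen on training scores only.
Note that maximizing J guarantees accuracy ≥ majority-class accuracy only
for balanced prevalence (where accuracy = (J+1)/2); under imbalance the
J-optimal point can trade accuracy for sensitivity — an inherent property
of the criterion, not an implementation artifact.

## 6. Unsupervised arm

Samples are clustered by UPGMA on 1 − Pearson correlation of expression
profiles (constant profiles are rejected by name). The tree is pruned
top-down by a SigClust-style test: at each node, the observed statistic
is the **2-means cluster index** (within-split SS over total SS about the
grand mean) of the node's samples; the null is a diagonal Gaussian whose
spectrum is the empirical covariance spectrum floored at the background
noise variance (squared normal-consistent MAD of all entries) with a
soft-threshold shift preserving total variance when flooring would
inflate it; p is the fraction of `n_sim` (default 100) simulated null
datasets whose 2-means cluster index is ≤ the observed one. A node with
p < α (default 0.05) splits along its two subtrees; otherwise it is a
final cluster.

Scoring the node's best 2-means partition rather than the tree's own
children split is deliberate: average linkage routinely peels single
outliers off near the root, and a lopsided tree split scored against a
2-means-calibrated null has essentially no power (observed index ≈0.995
vs null ≈0.975 even for strongly clustered data). With 2-means scoring
the test is calibrated — on data drawn from the fitted null the rejection
rate is ≈α — and the well-separated five-class benchmark is pruned to
exactly five clusters. Clusters smaller than `min_cluster_size` (default
5) are merged into their best-correlated cluster: a "significantly
reproducible" cluster of one outlying sample is a contradiction, and the
floor stabilizes the recovered cluster count across seeds.

Label transfer walks the priority order Basal, Normal, Her2, LumA, LumB;
each label claims the unassigned cluster with maximal Spearman
correlation to its reference centroid (ties: lowest cluster index);
surplus clusters take their own best-correlated label. In synthetic runs
the reference centroids are the generator's latent class means — the
documented substitution point where a real deployment would plug in
published subtype centroids. Held-out samples are classified by the
nearest-centroid rule (the NSC discriminant at threshold 0, pooled
within-cluster SDs, cluster-size priors) against the labelled cluster
centroids; when pruning leaves a single cluster the whole test set
inherits its label, recorded with a warning — the honest small-sample
failure mode visible at N=100.

## 7. Problem sizes and numerical conventions

The shipped tests and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which each property is statistically
decidable: full-scale cohorts (885 × 20477) wherever the arithmetic is
exact or cheap; 20 rounds × sizes {100, 200, 350} for curve-shape
properties; 200 replicates for null-calibration rates (bands of ±3
binomial SE); 100 null simulations per SigClust test; 1000 replicate
thinnings for the binomial expectation. Monte-Carlo assertions use
3-SE bands plus a small fixed epsilon against discreteness. Output
tables are written with `%.10g` float formatting so reruns are
byte-comparable. Matrices are dense pandas DataFrames (genes × samples);
an 885 × 20477 count matrix is ~145 MB as float64, well within desktop
memory.

## 8. Known limitations

- Absolute accuracies depend on the synthetic effect-size calibration and
  transfer to real cohorts only qualitatively.
- The SigClust null is diagonal (soft-thresholded spectrum); heavy-tailed
  or zero-inflated expression at low counts makes deep, small nodes
  test-happy, which the minimum-cluster-size floor tames but does not
  model away.
- PR status in real cohorts underperforms its marker gene for reasons
  (biology vs label noise) the generator can emulate via
  `receptor_noise_rate` but not explain.
- No batch effects or cross-cohort transfer; learning curves here answer
  the within-protocol design question only.
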