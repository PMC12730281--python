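# Methods

## Scope

`omicnet` predicts categorical or quantitative phenotypes from up to three
omics modalities at a time and ranks input features by how strongly they
drive the fitted model. Six modality types are supported: gene expression,
miRNA expression, DNA methylation, and protein expression (continuous);
SNP genotypes and gene-level copy-number states (categorical). The package
is headless: every step of the workflow — ingestion and validation,
encoding, training, evaluation, saliency ranking, gene mapping, pathway
over-representation — is a library call, with a thin CLI chaining them.

## Encoding and preprocessing

Continuous matrices are z-scored **per sample** across features using the
population standard deviation of the observed entries of that row;
missing entries are then set to 0, which is the row mean in z-space, so a
missing cell is neutral to any downstream linear score. Zero-variance rows
become all zeros rather than NaN. A per-feature mode exists behind the
`axis="feature"` flag for workflows that prefer column standardization.

SNP genotypes are one-hot encoded over the five-symbol alphabet
A, C, G, T, missing — missingness is a first-class state with its own
channel, and no imputation is attempted. Gene-level CNV uses the five
GISTIC-style states −2 (homozygous deletion), −1 (single-copy deletion),
0 (diploid), +1 (low-level amplification), +2 (high-level amplification).
The CNV alphabet has no missing symbol; to preserve the invariant that
every one-hot vector sums to exactly 1, a missing CNV cell maps to the
neutral diploid channel. CpG features can be filtered to those inside a
gene or within a promoter window (default 2000 bp upstream of the
strand-aware gene start) before modeling.

Bundles merge 1–3 encoded modalities by inner join on sample IDs; the
sample order of the first modality (restricted to the intersection) is
canonical. Long-term-survival labels derive from survival records with a
3-year threshold: observed deaths are LTS (> 3 y) or non-LTS (≤ 3 y);
records censored at ≤ 3 years are excluded because their class is
unknowable; records censored beyond 3 years are LTS, since survival past
the threshold is established regardless of later follow-up.

## The multi-branch CNN

Each modality enters its own branch of 1-D convolutions along the feature
axis (channels = the one-hot alphabet, or a singleton for continuous
data), with Leaky-ReLU activations. Branch outputs are pooled and
concatenated, batch-normalized, and passed to a fully connected head with
dropout in every layer; the output is a 2-unit softmax for binary
classification (cross-entropy loss) or a single linear unit for
regression (mean-squared-error loss). Optimization is Adam with optional
decoupled (AdamW-style) weight decay applied to weight matrices only.

The network, its backpropagation, and the optimizer are implemented
directly in NumPy. Layers are seeded through `numpy.random.Generator`;
rebuilding a spec with the same seed reproduces the initial weights bit
for bit, and with dropout 0 and batch norm off the untrained network is a
deterministic function of its input.

Three pooling modes are provided. `local` (default) applies a
non-overlapping windowed max (default window 4) and flattens, which keeps
position information — essential when the signal lives at specific
feature positions rather than in translation-invariant motifs. `max` and
`mean` are global pools producing one value per filter; they yield much
smaller heads but are position-blind, so they suit data where local
patterns (e.g. haplotype context around a SNP) carry the signal.

Defaults (2 conv layers, 16 filters, kernel 5, dense sizes 64/16, dropout
0.5, Leaky slope 0.01, learning rate 1e-3, batch 32, 50 epochs) are
starting points inside the tunable search space, not fitted constants.
For the synthetic-cohort studies shipped with the package we use a
deliberately compact, interpretability-oriented configuration — one 1×1
convolution layer, no pooling reduction (`pool_size=1`), batch norm off,
dropout 0.1, weight decay 10 — because wide kernels and pooling windows
smear gradient saliency across neighboring features, and strong decoupled
weight decay discourages the network from memorizing samples through
rare one-hot channels.

Baselines: logistic regression with a pure L2 (ridge) penalty, an
RBF-kernel SVM, a decision tree, and a random forest, all from
scikit-learn, consuming the flattened concatenation of the encoded
modalities (feature-major, channels adjacent). Regression tasks swap in
ridge, SVR, and the regression tree/forest.

## Training, evaluation, and hyperparameter search

Splitting is 60/20/20 train/validation/test by default; partition sizes
are floor(n·f) with the remainder assigned to train first, then
validation. Stratification (on by default for classification) allocates
per-class quotas by largest remainder subject to the exact global sizes,
so class shares per partition are preserved to within one sample. K-fold
assignment uses scikit-learn's (stratified) K-fold with shuffling; fold
sizes differ by at most one.

Classification is scored by ROC AUC (threshold sweep + trapezoid rule;
the suite verifies equality with the Mann–Whitney U formulation to
1e-12) and precision-recall curves; the positive-class score is the
softmax probability of the LTS class when present. Regression reports the
Pearson correlation coefficient and R². K-fold evaluation retrains a
fresh clone per fold and reports per-fold metrics and their arithmetic
mean; fold-mean AUC (not pooled predictions) is the headline number.

Hyperparameter search implements a tree-structured-Parzen-style
sequential optimizer: after 10 random startup trials, observations are
split into a good fraction (top 10%) and the rest; each is modeled by an
adaptive Parzen mixture (per-center bandwidth = the larger gap to the
sorted neighbors, clipped below by width / min(100, 1 + n), plus a
domain-wide prior component), and the proposal maximizes the good/bad
density ratio over 24 candidates drawn from the good mixture. Integer
ranges round the continuous machinery; categorical choices use
Laplace-smoothed count ratios. A `random` mode provides the control; the
suite asserts the Bayesian mode beats random search's median on smooth
1-D/2-D objectives at 40 trials. The best-so-far trace is monotone and
the whole trial sequence is reproducible from the seed.

## Saliency and biomarkers

For the multi-CNN, a feature's saliency is the mean over samples of the
maximum over input channels of |∂ score / ∂ input|, where the score is
the pre-softmax logit of the target class (the sample's predicted class
by default, or a fixed class index) — differentiating the logit rather
than the probability avoids softmax saturation. Channel-max preserves the
strongest allele/state signal; sample-mean stabilizes the estimate across
the cohort; both aggregations are swappable arguments. The suite verifies
the gradients against central finite differences (relative error < 1e-3
over 20 random networks). Baseline importances use |coefficients|
(linear models) or impurity importances (trees/forests), aggregated to
feature level by channel max; the RBF SVM exposes neither and is
rejected with a pointer.

Saliencies convert to dense ranks: rank 1 is the highest value, ties
share a rank, ranks are consecutive. Top-k selection is tie-inclusive
(every record at or above the k-th record's rank), so a selection may
exceed k; a threshold mode is the alternative. Markers with genomic
positions map to genes either by interval containment or by nearest gene
within a distance bound; interval arithmetic is 0-based half-open, so the
distance from a position p to a gene [s, e) is s − p upstream and
p − (e − 1) downstream. Per gene the best (minimum) dense rank and the
contributing markers are reported; unmapped markers are recorded, never
fatal. "Significant" throughout means salient to the model, not
statistically significant — no p-values are attached to markers.

## Over-representation analysis

A marker-derived gene list is tested against GMT collections with the
hypergeometric upper tail (one-sided Fisher's exact test): given a
background universe of N genes, a gene set of size K after intersection
with the background, and a query of size n, the p-value is
P(overlap ≥ observed). The background defaults to the genes measured on
the platform rather than the whole genome. Benjamini–Hochberg adjustment
runs across all tested sets and is invariant to record order; both raw
and adjusted p-values are reported. The implementation is checked against
brute-force enumeration over all overlap counts on small universes
(≤ 25 genes) to 1e-12.

## The synthetic cohort generator

The generator defines the study conditions the shipped tests and the
acceptance script run under. Defaults: 200 samples; three modalities
(gene expression, SNP, CNV) with 500 features each; 10 planted driver
features (4 expression, 3 SNP, 3 CNV, mutually distant along the feature
axis and hosted by disjoint genes); effect size 1.5 per driver; one
expression–expression interaction of strength 1.0; noise sd 1.0;
2% missing cells in expression and SNP data.

Continuous features follow per-feature normal laws (means N(0, 1),
scales U(0.5, 1.5)), as in real expression matrices; the planted effect
acts on the standardized residual, i.e. the feature's value in z-space.
SNP features draw a reference/alternative allele pair and a minor-allele
frequency from U(0.1, 0.5); CNV states are multinomial over the five
levels (5/15/60/15/5% by default). Categorical driver signals are
centered, unit-variance state indicators (alternative allele present;
copy-number amplified), so "effect size" means the same contribution
scale in every modality. The linear predictor η sums the weighted
signals, interactions, and Gaussian noise; binary labels are
Bernoulli(logistic(η)); survival times are exponential with rate
(ln 2 / 3) · exp(−η) — median 3 years at η = 0 — under independent
exponential censoring, and the generated survival records reproduce the
cohort labeler's LTS assignments exactly on the non-excluded samples.
A non-uniform mode drops whole modalities for random sample subsets,
mimicking cohorts where not every patient was profiled on every platform.

The matching annotation generator tiles disjoint 1-kb genes (1-kb gaps,
100 genes per synthetic chromosome), positions every feature inside its
host gene, and emits gene sets: one pathway holding exactly the host
genes of the planted drivers plus 49 random background pathways of 20
genes. This makes the full chain — train, rank, map, enrich — testable
against known ground truth without any external download.

What the generator does not emulate: linkage disequilibrium and other
feature-feature correlation, batch effects, heavy-tailed expression
distributions, and platform-specific missingness structure. Passing
tests on these cohorts therefore demonstrates mechanical and statistical
correctness of the pipeline, not expected performance on real tumor or
crop data.

## Known limitations

With 10 equally weighted drivers, each contributes ≤ ~10% of the variance
of η regardless of the common effect size, and the Bernoulli label step
roughly halves the usable signal; at 200 samples against 1,500 candidate
features the resulting per-feature signal sits near the detection floor
for any estimator, univariate or multivariate. The CNN's gradient
saliency typically places only a minority of the planted drivers in the
top 10 on these cohorts (the acceptance script reports the measured
mean): rare one-hot channels give an overparameterized network cheap
sample-memorization routes that weight decay only partially suppresses.
Full top-10 recovery of all planted drivers should not be expected at
these cohort sizes; the end-to-end enrichment chain is more robust,
because even a partially recovered marker list concentrates on planted
host genes. The problem sizes used
by the shipped studies (200 × 1,500 features, 5 seeds, 5-fold) were
chosen so the whole suite trains on a single CPU in minutes.

Other limitations: binary classification only (no multi-class head);
no survival models or concordance metrics — survival enters only through
cohort labeling; no imputation beyond the zero rule; ORA only (no
ranked-list enrichment with permutation nulls); baselines' RBF SVM has
no per-feature importance.
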