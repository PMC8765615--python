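# Methods

## The prediction problem

Bacterial operons place several genes on one polycistronic mRNA. In
short-read RNA-seq coverage this leaves a characteristic signature:
co-transcribed neighbors show read-through — the intergenic region between
them carries depth comparable to the flanking genes — whereas independently
transcribed neighbors show a coverage trough between genes. `operon_voter`
turns that signature into a supervised binary classification of adjacent
gene pairs, with raw coverage deliberately replaced by rank statistics so
that calls are robust to sequencing depth and batch effects.

## Featurization

For each adjacent pair on a replicon, gene A is the 5'-most gene in
transcription order (for a minus-strand pair that is the genomically right
gene; for opposite-strand pairs the left gene). Three windows are cut from
the per-base depth track:

* `covA`: the 50 bp of gene A nearest its 3' end (whole gene if shorter);
* `covI`: the central 50 bp of the intergenic region (whole region if
  shorter; the single base at the left gene's end when the genes abut or
  overlap, so every comparison stays defined);
* `covB`: the 50 bp of gene B nearest its 5' end.

Kruskal-Wallis rank tests are run on (A,I), (B,I), (A,B) and the three-way
(A,I,B), each yielding the tie-corrected H statistic and a chi-square
upper-tail p-value with k−1 degrees of freedom (all-identical windows give
H=0, p=1 by convention). The 12 model features are the four H values, the
four log10 p-values (p floored at 1e−300, so log10 p ∈ [−300, 0]), the two
gene lengths, the signed intergenic length, and a strand-match indicator.
Pairs where neither gene reaches a mean full-span depth of 10 are discarded
before featurization: unexpressed pairs carry no evidence in either
direction.

Window size (50 bp), the expression cutoff (10), and the central-window
left-biased rounding `floor((L−50)/2)` are the package defaults; an integer
`offset` parameter (default 0) can shift the gene windows away from the
intergenic boundary for sensitivity analyses. Depth values are used as-is —
the rank transform inside the KW test is the normalization strategy.

## Classifier suite and voting

Six binary classifiers are trained on the same feature table: logistic
regression (ridge by default), an RBF-kernel SVM, a random forest, gradient
boosted trees (XGBoost), a small ReLU/adam multilayer perceptron, and
Gaussian naive Bayes. Features are min-max scaled for all algorithms except
the two tree ensembles, which are invariant to monotone feature scaling
(verified by test). SVM probabilities come from a Platt-calibrated decision
function. Each algorithm calls a pair positive when its positive-class
probability is ≥ 0.5 (ties go to the positive call, favoring recall).

The ensemble decision is a threshold vote: a pair is an operon pair when at
least k of the six algorithms call it, k ∈ 1..6 with default 3. Low k favors
recall, high k specificity; recall is non-increasing and specificity
non-decreasing in k by construction (property-tested). With replicated
samples, an optional consensus step first drops pairs seen in fewer than
`min_replicates` samples (default 2) and lets an algorithm vote only when
its calls agree across replicates (unanimity by default; a majority mode is
available). A disagreeing algorithm abstains rather than voting negative, so
consensus can only remove votes.

Positive pairs at the chosen threshold are strung into operons: maximal
runs of consecutive same-strand positive pairs merge into multi-gene
chains; a negative, missing, or opposite-strand pair breaks a chain.

## Hyperparameters

With `optimize=False` (the default) documented defaults are used
(`estimators.DEFAULT_HYPERPARAMETERS`). With `optimize=True` each
algorithm's hyperparameters are chosen by sequential Bayesian optimization:
a Matern-5/2 Gaussian-process surrogate with expected-improvement
acquisition over the spaces in `hyperopt.SEARCH_SPACES` (10 evaluations,
objective = mean 10-fold stratified CV accuracy); a random-search fallback
over the same spaces and budget is selectable. Continuous bounds were fixed
once for reproducibility — e.g. C ∈ [1e−3, 1e3] (log), estimators ∈
[50, 500], depth ∈ [2, 20], learning rate ∈ [1e−3, 0.5] (log), variance
smoothing ∈ [1e−12, 1e−6] (log), 1–3 hidden layers of 4–128 neurons,
alpha ∈ [1e−5, 1e−1] (log). The SVM kernel is fixed to RBF by default; a
categorical kernel search is available (`SVM_kernel_search` space). XGBoost
runs with `min_child_weight=0` so the suite fits arbitrarily small training
sets exactly. The package-wide default seed is 1009731.

## Evaluation

Recall = TP/(TP+FN) and specificity = TN/(TN+FP); a zero denominator yields
a missing value, never 0. ROC curves sweep score thresholds and AUC is
trapezoidal; for a single binary call this reduces to (sens+spec)/2.
Confidence intervals use a percentile bootstrap: 100 iterations, each
resampling 10% of the scored pairs with replacement, reporting the mean and
the 2.5/97.5 percentiles. `split_validate` repeats stratified 75/25
train/validation splits (default 50; reducible for desk-scale runs) and
averages per-algorithm recall/specificity. Call tables that retain
per-replicate rows are scored per (pair, sample) row; consensus tables per
pair. Feature diagnostics use midrank Spearman correlation of each feature
against the binary label.

## Synthetic data

The generator emulates the statistical premise of the method, not the
sequencing process. Genes are laid out left to right on one replicon and
grouped into transcription units whose sizes are geometric (stop probability
`p_stop`, default 0.5, i.e. mean unit size 2); each unit gets one strand
(minus fraction 0.5) and one expression level drawn log-normally
(median 50×, log-sd 1). Per-base depth is negative-binomial around
background + unit depth over genes, background + `r`·depth over within-unit
gaps (read-through factor `r`, default 0.9), and background alone (default
1×) between units; the dispersion parameter (default 5; variance
m + m²/dispersion) controls noise, and replicates (default 2) redraw noise
over a shared layout (unit depths can optionally be redrawn per replicate).
Gap lengths are uniform 1–30 bp within units and 50–400 bp between units.
Every adjacent pair is labeled: 1 inside a unit, 0 otherwise.

The default benchmark (4,000 genes, 2 replicates, ~7,700 filtered
(pair, sample) rows) is deliberately a favorable regime: the within/between
gap distributions do not overlap and read-through is strong, so classifiers
can reach ceiling performance. Passing the recovery tests therefore shows
that the pipeline transmits the planted signal faithfully, not that real
genomes — where intergenic-distance distributions overlap heavily, coverage
has positional biases, and annotations are imperfect — will be classified
near-perfectly. The generator also omits read-level artifacts (GC bias,
gene-body trends, strandedness), so no test here speaks to those.

Scale choices: the consensus experiments use 1,500-gene genomes with
dispersion 0.5 (strongly overdispersed, var ≈ m + 2m²) to create genuine
replicate disagreement; the repeated-split and optimization tests use a few
hundred genes. These sizes were chosen as the smallest at which the measured
quantities are stable across seeds.

## Numerical choices and degenerate inputs

* KW on all-identical data returns H=0, p=1 rather than erroring; scipy's
  tie correction can round H to a tiny negative, so H is clamped at 0
  before the chi-square tail (otherwise the tail evaluates to NaN).
* p-values are floored at 1e−300 before log10 — far below any attainable
  chi-square tail at window sizes ≤ 150 — so features never reach −inf.
* Min-max scaling maps a constant training column to 0 and does not clip
  out-of-range values at prediction time.
* Intergenic length is kept signed; overlapping genes contribute negative
  distances the classifiers may exploit.
* Chain merging treats each replicon independently; pair ids accept either
  gene order ("A|B" or "B|A").
* The chi-square p-value is asymptotic: at very small window sizes it can
  differ from the exact permutation p by a few hundredths, which is why the
  permutation cross-checks run at moderate group sizes (n ≈ 30 per group)
  while tiny cases are checked against exact enumeration.

## Known limitations

* Coverage is assumed unstranded; convergent transcription over a shared
  intergenic region can mimic read-through.
* The expression filter is applied per (pair, sample); a pair may enter the
  table in one replicate and not another, which the consensus step then
  drops.
* The voting ensemble has no notion of calibration across algorithms; vote
  counts are ordinal evidence, not probabilities.
* Bounds on the hyperparameter spaces are pragmatic, not exhaustive; the
  10-evaluation budget is small and mainly suited to refreshing defaults on
  new data.
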