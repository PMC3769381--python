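# Methods

This note documents the models and procedures implemented in `toxsig`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic benchmark does and does not establish.

## Unit of analysis and fold changes

The pipeline classifies *treatment groups*, not individual animals: all
replicates sharing compound, dose, sex, and dosing duration are collapsed
into one vector of mean log2 fold-changes,

    fc(g, j) = mean log2 expression of group g at probeset j
             − mean log2 expression of the control samples with the same
               vehicle and duration.

Controls are matched on vehicle and duration (time-matched vehicle
controls); control animals of both sexes are pooled. Both sexes are kept as
separate treatment groups and pooled into one training set per duration, with
sex retained as metadata. The two dosing durations (3 d, 14 d) are modeled
strictly separately and never pooled. A compound dosed at two levels
contributes two independent treatment groups with the same class label.

Rationale: group-level fold changes are the natural unit when the scientific
question is per-compound classification, they cancel probeset-level baseline
effects, and they reduce the n≫p imbalance that per-animal modeling would
worsen. The cost is a small effective sample size (≈22 defined groups per
duration at the emulated design), which drives several numerical policies
below.

## Stage 1: ensemble signature inference

For one binary task (C vs NC, GC vs NGC, GC vs NC, NGC vs NC; "C" pools GC
and NGC; undefined-class groups are always excluded from training):

1. **Subsampling.** n = 25 "bootstraps", each a class-stratified 90 %
   subsample *without replacement* (round(0.9·n) in-bag; the complementary
   10 % is the out-of-bag set). Subsampling without replacement is the only
   reading under which a complementary out-of-bag fraction of 10 % exists.
   Per-class quotas use largest-remainder rounding, so in-bag class
   proportions are within one member of the global proportions. A class may
   end up fully in-bag when the training set is tiny; this is permitted and
   logged, and such bootstraps simply contribute no out-of-bag AUC.
2. **Ranking.** On each bootstrap's z-scored in-bag fold-change matrix, each
   selector of the ensemble produces a total ranking of all probesets:
   - `GOLUB`: |μ₊ − μ₋| / (σ₊ + σ₋) with sample (n−1) SDs. The classical
     signal-to-noise form is used; a zero denominator (both classes constant)
     is replaced by machine-tiny, which only matters on degenerate inputs.
   - `SVM`: |w_j| of a linear soft-margin SVM (C = 1 by default).
   - `SVM_RFE`: recursive elimination driven by linear-SVM weights. The
     schedule keeps ⌈n/2⌉ features per iteration while that is at least 10,
     then drops to 10 and removes one feature at a time (from 100 features:
     100→50→25→13→10→9→…→1). Halving above 10 balances fidelity near the
     decision-relevant sizes against cost; the ranking is the reverse
     elimination order, with same-batch features ordered by |w| at
     elimination time.
   - `PAM`: nearest-shrunken-centroids statistic
     d_kj = (x̄_kj − x̄_j)/(m_k (s_j + s₀)) with m_k = √(1/n_k − 1/n),
     pooled within-class SD s_j, and s₀ = median_j s_j; score =
     max_k |d_kj| after soft-thresholding by Δ (default Δ = 0, i.e. the
     unshrunken statistic; Δ is exposed as a parameter).
   - `PCA` / `PLSDA` (alternative ensemble): |loading| on the first
     principal component (unsupervised, column-centered) and |weight| on the
     first PLS component against a ±1-coded response.
   Ties are always broken by ascending probeset index, making every ranking
   deterministic; all selectors are deterministic given the data, so
   Stage 1 is bit-reproducible from its seed.
3. **Out-of-bag performance.** For each selector, bootstrap, and signature
   size on the grid {2, 5, 10, 15, 20, 30, 40, 60, 80, 100} (10 sizes
   spanning [2, 100]; entries above P−1 are dropped for small feature
   universes), the selector's paired classifier is trained on the in-bag
   top-size features and scored on the out-of-bag groups; the AUC is averaged
   over bootstraps. Pairing: SVM and SVM-RFE rankings are judged with a
   linear SVM, PAM with the shrunken-centroid classifier, and GOLUB / PCA /
   PLS-DA with weighted voting — each ranking by its natural decision rule.
   One-class out-of-bag sets yield no AUC and are excluded (logged).
4. **Optimal size.** A cubic smoothing spline (smoothing parameter by
   generalized cross-validation) is fitted to the (size, mean AUC) points and
   evaluated on every integer size in range; flat stretches resolve to the
   smaller size (parsimony). With exactly 4 points an interpolating cubic is
   used; with fewer, the raw argmax. If *no* point is defined (every
   bootstrap had a one-class out-of-bag set — possible at nested-CV fold
   sizes), the optimum is undefined; if that happens for every selector and
   no explicit consensus size was configured, the consensus size falls back
   to the median of the size grid with a warning.
5. **Stability.** Per selector and size, the mean pairwise Kuncheva index
   KI = (rP − k²)/(k(P − k)) over the 25 bootstrap signatures. This form
   satisfies the three defining anchors: 1 for identical subsets, −1 for
   disjoint half-universe subsets, 0 in expectation for independent draws.
6. **Consensus.** Every feature's 1-based ranks are summed over all n×m full
   rankings; features are ordered by ascending rank sum (ties by probeset
   index). Full rankings, not top-k membership, enter the sums. The consensus
   size defaults to the median of the per-selector spline optima (robust to
   one selector's degenerate curve) and can be fixed in the configuration.

## Stage 2: classification

Fold-changes of the signature probesets are standardized by z-scores with
mean and sample (n−1) SD estimated on the training groups only. A
zero-variance training feature gets SD := 1 (the feature becomes constant 0)
with a logged warning rather than an error, so applying a signature never
aborts on a flat gene.

Six classifiers emit a confidence in [0, 1] for the positive class:

| kind | model | confidence |
|---|---|---|
| SVM | linear SVC | logistic map 1/(1+e^(−d)) of the decision value |
| KNN | k-nearest neighbors (Euclidean) | fraction of positive nearest neighbors |
| PAM | nearest shrunken centroids | posterior ∝ π_k·exp(−δ_k/2), δ_k the standardized distance to the shrunken centroid |
| Naive Bayes | Gaussian per-feature likelihoods | posterior |
| Random forest | 500 trees | vote fraction |
| Weighted voting | Golub-style | strength v = (V_win − V_lose)/(V_win + V_lose) mapped by (v+1)/2; all-zero votes abstain at 0.5 |

The logistic and affine maps are monotone surrogates chosen because they are
the simplest increasing maps from the raw score ranges (SVM decision values
of roughly ±10; voting strength exactly [−1, 1]) onto [0, 1]; all reported
AUCs are invariant to any monotone rescaling. Weighted-voting weights are
the signed signal-to-noise ratios and each feature's decision boundary is the
midpoint of its class means.

Internally every classifier is fitted in a canonical label orientation (the
first training profile's class is coded 0), so refitting with complemented
labels reuses the identical underlying fit and label-swap symmetry
(confidence → 1 − confidence) holds exactly, not just approximately.

**Hyperparameter grids** (tuned by mean inner-fold AUC; ties take the
smaller value): SVM C ∈ {0.01, 0.1, 1, 10, 100}; KNN k ∈ {1, 3, 5} (clipped
to the training size); PAM Δ on 10 evenly spaced values from 0 to the
training set's max |d|; random forest max features ∈ {√P, P/3} with 500
trees; naive Bayes and weighted voting have no tuned parameters.

## Evaluation

- **AUC** is rank-based (Mann–Whitney), ties counting ½ — exactly equal to
  pair enumeration, which the tests verify by brute force.
- **Nested 3×3 CV.** Outer 3-fold evaluation with inner 3-fold tuning. When
  the signature source is Stage 1, the *full* Stage-1 pipeline runs on each
  outer training fold with a seed derived only from the root seed and the
  fold index — the held-out fold cannot influence the signature, and deleting
  its profiles reproduces the fold signature bit-for-bit (enforced by test).
  Fold AUCs are averaged; a one-class outer test fold contributes no AUC
  (logged).
- **Fold grouping.** By default all treatment groups of one compound share a
  fold (`by_compound`), preventing a compound's other sex or dose group from
  leaking into training; `by_group` treats each treatment group
  independently. Fold assignment is stratified by class at the unit level
  (compounds or groups) with a seeded rotation, so small classes spread
  across folds.
- **Fixed signatures** (e.g. published gene lists) skip Stage 1; probesets
  absent from the dataset are dropped with a logged count, and zero overlap
  is an error. Pairwise signature overlaps are reported as intersection-count
  matrices.
- **Undefined compounds** are scored by all classifiers trained on the
  defined compounds; the per-compound call is a majority vote over all
  (classifier, treatment group) confidences, where votes above 0.5 count for
  the positive class, below 0.5 against, and exactly 0.5 abstains; a tied or
  empty vote yields "ambiguous", never a silent resolution.
- **PCA projection** restricts group profiles to a signature, column-centers,
  and returns the top-2 principal-component coordinates with class/sex
  metadata for hull plots.

## Synthetic benchmark

The generator emulates the motivating study design: 14 compounds — 3 GC (one
with two dose groups), 3 NGC, 4 NC, 3 undefined — × 2 sexes × 2 durations,
6 replicates per group, controls for both vehicles at both durations
(2 × 2 × 2 × 6 = 48 control samples; 336 treated samples; 2000 probesets).
Baseline log2 expression is Normal(8, 1) per probeset with Normal(0, 0.5)
replicate noise. Three disjoint planted sets of 20 probesets each carry
class effects: GC compounds shift the GC-specific and shared sets, NGC
compounds the NGC-specific and shared sets, NC compounds nothing; shift
magnitude is 2 within-group SDs (i.e. 1.0 log2 units) with a random fixed
sign per feature, scaled by a per-compound modifier uniform on [0.8, 1.2]
(so compounds are distinguishable and compound-grouped CV is not trivial)
and attenuated by 0.6 at day 3 — encoding the empirical "short dosing is
harder" pattern as a generative knob. A sex effect of 0.5 log2 units on a
random 5 % of probesets in males acts on treated and control samples alike;
because control sexes are pooled when computing fold changes, it survives as
a structured nuisance. Undefined compounds are generated from an explicit
GC-like or NGC-like regime, so their post-hoc classification has a knowable
right answer.

The Gaussian noise model was chosen for analytic transparency; nothing in
the pipeline assumes it. What the generator does **not** emulate: probe-level
microarray physics, batch and array effects, correlated gene modules,
heavy-tailed biological variation, dose–response nonlinearity. Passing the
synthetic benchmarks therefore demonstrates the pipeline's correctness and
its statistical behavior under a controlled regime — not field performance
on real arrays.

**Recovery score.** Signature recovery is measured as
|signature ∩ relevant planted set| / min(|signature|, |relevant set|), where
the relevant set for C vs NC is the union of the shared and both
class-specific sets, and for GC vs NGC the two class-specific sets. The
min-denominator makes the score 1 exactly when a signature smaller than the
planted universe consists entirely of relevant features, which is the
meaningful notion of recovery when, e.g., a size-20 consensus is judged
against 60 planted features.

## Problem sizes and numerical choices

The acceptance-level checks run the full default design (2000 probesets, 25
bootstraps × 4 selectors, nested 3×3 CV on 22 treatment groups); the
permutation-null calibration averages 20 compound-level label permutations
with a reduced selector pair (GOLUB + PAM, 10 bootstraps) and a fixed
consensus size of 20, which leaves the null distribution untouched while
keeping the experiment lean. Unit tests use scaled-down designs (300–500
probesets, 4 replicates). Known limitations: at nested-CV fold sizes
(~15 training groups) the 10 % out-of-bag sets shrink to single groups, so
out-of-bag size-optimization curves are undefined there and a fixed or
fallback consensus size is used; spline-based size optimization needs at
least 4 defined curve points; and with ~10 compounds the outer-fold AUCs are
coarse-grained (few positive–negative pairs), which is why null-band checks
average over many permutations.
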