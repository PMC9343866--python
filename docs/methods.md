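# Methods

`imbalmicro` studies a binary host-trait prediction problem — current
smoker vs. non-current smoker from saliva microbiome relative abundances —
under severe class imbalance (about 1:6), and asks whether training-set
augmentation restores minority-class sensitivity. Everything below is the
package's own account of what it computes and under which assumptions.

## Data model and preprocessing

A cohort is a samples × taxa count matrix plus per-sample metadata
(smoking status never/former/current, sex, age group, ethnicity, cohort
label). Preprocessing follows the standard 16S species-table chain:

1. **Coverage filter** — keep samples with strictly more than 1,000 total
   reads (strict `>`).
2. **Total-sum scaling (TSS)** — divide each sample's counts by its total,
   yielding compositions summing to 1.
3. **Abundance filter** — drop taxa whose mean relative abundance across
   samples is strictly below 1e-4. Surviving rows no longer sum to 1; the
   `normalized` flag drops accordingly.
4. **Cross-cohort intersection** (when two tables are given) — restrict to
   shared taxa in lexicographic order.
5. **Re-normalization** — an explicit second TSS pass so classifiers see
   proper compositions. Whether to re-normalize after dropping taxa is not
   dictated by the data model; it is on by default and switchable
   (`renormalize_after_intersect`), since leaving rows sub-unit keeps the
   discarded mass interpretable but feeds non-compositional vectors to the
   models.

Labels collapse never+former into "non-current" (label 1); "current" is
label 0 and is the positive class throughout — the minority class is the
one the analysis cares about, so sensitivity bookkeeping (confusion matrix,
AUC score orientation) is anchored to it.

## Augmentation schemes

All schemes operate on a training split only and synthesize (or delete)
samples; validation, test and holdout folds are never touched.

* **SMOTE-style over-sampling** — each synthetic sample is
  `x + u·(x_nn − x)` for a minority row `x`, one of its `k = 5` nearest
  minority neighbors (plain Euclidean on the given feature scale, distance
  ties broken by lower row index), and `u ~ U[0,1]`. Generation is spread
  as evenly as possible across source rows; remainder slots are assigned to
  rng-chosen sources. If the minority class has ≤ k members, k is reduced
  to minority−1 with a warning.
* **ADASYN-style over-sampling** — per minority row `i`, a hardness weight
  `r_i` = fraction of majority members among its k nearest neighbors in the
  pooled two-class set (self excluded); synthetic counts are allocated
  proportionally to `r_i` by largest remainder (ties to the lower index),
  and interpolation partners are minority-only, as in SMOTE. If no minority
  row has a majority neighbor (all `r_i = 0`), the scheme falls back to
  SMOTE with a warning.
* **Random under-sampling** — a uniform without-replacement subset of the
  majority class, kept rows unmodified and in input order.
* **Combined over/under schemes** — the target ratio comes from the
  equation `t = |C_min − C_max|`, `over = |t − C_min| / C_max`,
  `under = (C_max − t) / C_min`, with both ratios read as minority:majority
  target fractions (the convention of mainstream imbalanced-learning
  toolkits). The minority class is raised to `round(over · C_max)`
  (half-up) and the majority under-sampled to match; `under` is
  algebraically always 1, i.e. the combined schemes equalize the classes at
  `|C_max − 2·C_min|` samples each (175/1,070 → 720/720). The equation is
  implemented as written; for imbalance milder than 1:2 its target falls
  below `C_min`, in which case no synthesis happens and the majority is
  under-sampled to `C_min`.
* **Tree-based generative augmentation (TADA-style)** — a phylogeny-aware
  generator. A source minority composition is converted to `D = 10,000`
  working pseudo-counts and pushed down the rooted taxon tree: at each
  internal node the node's count is split among its children by a Dirichlet
  draw whose mean is the source row's observed clade proportions and whose
  concentration is `ν = 100` (a binary node reduces to a
  `Beta(ν·p, ν·(1−p))` split), followed by a multinomial assignment of
  integer counts given the draw. Mass is therefore conserved exactly at
  every node, clades absent from the source stay absent, and leaf counts
  are re-normalized into a composition. `ν` controls dispersion around the
  source (`ν → ∞` reproduces it up to multinomial noise of order
  `sqrt(p/D)`); `D ≥ n_taxa` sets the count resolution. Branch lengths are
  accepted but unused by default; `branch_scaled_variance` divides ν by
  the mean child branch length so long branches get noisier splits.

Determinism contract: identical inputs, plan and seed give bitwise-identical
augmented sets; synthetic rows are appended after the originals and carry
their source-row indices.

## Evaluation design

The layout is a 5×2 nested cross-validation with repeats. Per repeat: a
stratified 80/20 split reserves a final holdout; the 80% is split into 5
stratified outer folds; each outer-training fold is split 50/50 into two
inner folds. Hyperparameters are chosen by randomized search (default 30
draws; the desk-scale profile uses 10) maximizing mean inner-validation
MCC, where each inner training half is augmented independently and each
validation half is raw. The winner is refit on the augmented outer-training
fold and scored once on the untouched outer-test fold (MCC and AUC). Each
repeat re-randomizes the whole chain, including the 80/20 split. Ten
repeats × 5 folds give 50 fold values per (data type, classifier) in the
full design.

Seven classifier backends run behind one fit/predict/score contract:
logistic regression, k-nearest neighbors, linear and RBF support vector
machines, decision tree, random forest and gradient-boosted trees
(scikit-learn and XGBoost). Search spaces are editable defaults per backend
(regularization strength, neighbor count, kernel width, depth/leaf sizes,
learning rate/estimators). Seeds derive from one master seed through a
counter-based scheme keyed on (repeat, fold, data type, classifier), so
adding a data type or backend does not perturb the folds or draws of the
others.

Metrics are implemented from their definitions: MCC as
`(TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))` with the conventional 0
when a denominator factor vanishes, and AUC as the rank-based
Mann–Whitney estimator `U/(n_pos·n_neg)` with ties credited ½, oriented so
larger scores mean "more smoker-like".

Leakage control is structural and audited: augmentation sees only training
portions; every fold's membership is recorded in a manifest (synthetic
rows get `syn_*` ids), and tests assert that test manifests contain only
original sample ids disjoint from their training folds.

## Comparison statistics

Per classifier, the six data types' fold-MCC distributions are compared
with a tie-corrected Kruskal–Wallis omnibus and pairwise two-sample
Wilcoxon rank tests, BH-corrected within classifier, at adjusted p < 0.05.
The rank test uses the exact U distribution for tie-free samples up to
n = 50 and the normal approximation with tie/continuity correction
otherwise (the rule R's `wilcox.test` applies). "Wilcoxon" is read as the
unpaired rank-sum form by default because different data types alter the
training sets while sharing fold structure; a `paired` switch provides the
signed-rank alternative, which is also what fold-paired baseline-vs-scheme
contrasts use. Percent change vs. baseline pools the five augmented types;
a baseline whose mean MCC is numerically zero (a random predictor) yields
a "baseline-random" sentinel instead of a meaningless ratio.

## Synthetic cohorts

The generator emulates the statistical shape of a pooled two-cohort saliva
species table rather than any real sample:

* 124 taxa whose base composition is a symmetric Dirichlet draw raised to
  the `dominance = 3` power and renormalized, which concentrates ≥ 75% of
  mass in the top ~20 taxa;
* per-sample compositions `Dirichlet(50 · class mean)` — substantial
  within-class variation;
* read depths LogNormal(ln 20,000, 0.5), counts multinomial;
* zero inflation as post-hoc dropout: taxa below the median base abundance
  are zeroed per (sample, taxon) with probability 0.3;
* class structure: 175 minority ("current") vs 1,070 majority samples, the
  majority split 50/50 into never/former; a multiplicative `effect_size`
  (default 3) on 12 effect taxa in the minority mean, placed by default
  inside one clade of the generated random rooted bifurcating tree
  (sequential random leaf attachment, exponential branch lengths, mean
  0.1) so the phylogeny-aware augmenter has exploitable structure.

What the generator does **not** emulate: sequencing error, chimeras,
taxonomy mis-assignment, cohort batch effects, covariate structure
(age/sex/ethnicity are decorative), or the real data's correlation
structure between taxa beyond compositional closure. Passing tests on this
generator therefore demonstrate the pipeline's mechanics (leakage-freedom,
calibration, effect recovery), not field performance on real cohorts.

## Regimes, and what augmentation can and cannot fix

Two findings from running the pipeline on its own generator matter for
interpreting any result it produces:

1. **Augmentation pays off only where imbalance actually breaks the
   baseline.** With the default planted effect (3-fold on a 12-taxon
   clade) the classes are nearly separable and a baseline linear SVM
   already reaches fold MCC ≈ 0.8; no augmentation scheme improves on it.
   The interesting regime is weak signal: at effect ≈ 1.3–1.5 the baseline
   collapses toward constant majority prediction (MCC ≈ 0.04–0.17) while
   augmented training lifts MCC to ≈ 0.13–0.30 with fold-paired
   significance (see `analysis/04_weak_signal.py`). This mirrors the
   motivating observation that a near-random imbalanced baseline coexists
   with a respectable AUC.
2. **Null-data fold values are correlated, not independent.** With
   `effect_size = 1` the generator is exactly exchangeable between classes
   and mean fold MCC is zero across independent cohorts. Within a single
   cohort, however, outer folds share training samples, so their
   chance-direction estimates correlate and all fold values carry a common
   offset of either sign; a fold-level standard error understates the
   uncertainty of their mean, and a degenerate baseline (constant majority
   prediction, MCC identically 0) can differ "significantly" from the
   augmented types' noise in a rank test. Calibration claims on a single
   dataset should therefore be read at the cohort level, not the fold
   level; the acceptance checks that assert fold-level calibration at a
   fixed seed are known to trip on this and are kept strict deliberately.

## Numerical and design choices

* Rounding of class targets is half-up; largest-remainder allocation
  breaks ties toward lower indices; neighbor ties break toward lower row
  indices — all choices that keep runs bitwise reproducible.
* Dirichlet draws with very small concentrations can underflow to an
  all-zero gamma vector; such rows fall back to the mean split.
* The stratified splitter assigns `floor(fraction · class size)` per class
  (with an epsilon guard against float noise) and gives any leftover
  sample to the larger part; every class must be represented on both
  sides.
* MCC's zero-denominator convention is 0; AUC requires both classes.
* Backend failures during search score that configuration at −∞ and are
  logged; an augmentation failure marks the affected (data type,
  classifier, fold) records as failed and the run continues.
* Problem sizes in the shipped tests and scripts are desk-scale: 2 repeats
  and 5–10 search draws on cohorts of 120–1,245 samples; the full design
  (10 repeats, 30 draws, 7 backends) is configuration away.

## Known limitations

* The generator's effect model is multiplicative-and-renormalize on a
  clade; real smoking-associated shifts span phyla in both directions.
* TADA's internals here are one faithful reduction of "phylogeny-aware
  generative model" (hierarchical Dirichlet-multinomial with a fixed
  concentration); other reductions (e.g. branch-length-calibrated beta
  variances fit to data) are not implemented beyond the
  `branch_scaled_variance` switch.
* The under-sampling ratio of the combined schemes is identically 1 by
  construction of the printed equation; a genuinely tunable under ratio is
  exposed (`under_ratio`) but non-default.
* Single-threaded by design; a `--threads` flag is accepted for interface
  stability but does not parallelize.
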