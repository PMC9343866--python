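# imbalmicro

Class-imbalance-aware prediction of a binary host trait — current smoker
vs. non-current smoker — from saliva microbiome relative-abundance tables.

Public microbiome cohorts are heavily imbalanced (here about 1:6,
minority = current smokers), and accuracy-maximizing classifiers respond by
predicting the majority class, which looks fine on AUC and is useless for
the minority class researchers actually care about. This package implements
the full counter-strategy as an analysis pipeline:

* **Preprocessing** of species count tables: >1,000-read coverage filter,
  total-sum scaling (TSS), mean-relative-abundance < 1e-4 taxon filter,
  cross-cohort taxon intersection, label construction (never + former →
  non-current).
* **Five training-set augmentation schemes**: SMOTE- and ADASYN-style
  minority over-sampling, each alone (minority raised to majority size) or
  combined with random majority under-sampling via the ratio equation

  `t = |C_min − C_max|, over = |t − C_min|/C_max, under = (C_max − t)/C_min`

  (at 175 vs 1,070 this gives over = 720/1070 ≈ 0.673 and under ≡ 1, i.e.
  720 vs 720 after balancing), plus a **phylogeny-aware generative
  augmenter** (TADA-style) that redraws a source composition down a rooted
  taxon tree with Dirichlet-multinomial splits of concentration ν at every
  internal node.
* **Leakage-safe 5×2 nested cross-validation** with repeats: augmentation
  is applied independently to every training portion and never to
  validation/test/holdout folds; randomized hyperparameter search maximizes
  inner-fold MCC over seven classifier backends (LR, KNN, linear and RBF
  SVM, decision tree, random forest, XGBoost).
* **Evaluation and comparison**: Matthews correlation coefficient
  `MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))` (robust to
  imbalance) and rank-based AUC per fold; Kruskal–Wallis omnibus, pairwise
  Wilcoxon tests with Benjamini–Hochberg correction, and percent change vs.
  the non-augmented baseline.
* **Synthetic cohort generator** reproducing the study conditions
  (175/1,070 samples, 124 taxa dominated by a few species, zero-inflated
  multinomial counts, log-normal depths, a planted multiplicative class
  effect localized in one clade of a random rooted tree), so the whole
  pipeline is testable end-to-end without any real data.

## Worked example

The numbered scripts under `analysis/` run the study end-to-end on the
synthetic cohort and write their tables under `results/`:

```bash
python analysis/01_simulate.py --seed 0        # cohort + tree
python analysis/02_preprocess.py               # filters + labels
python analysis/03_nested_cv.py --seed 0       # 6 data types x {LR, SVML}
python analysis/04_weak_signal.py --seed 0     # where augmentation pays off
python analysis/05_compare_and_final.py --seed 0
```

`02` prints the preprocessing outcome:

```
kept 1245/1245 samples and 79/124 taxa; class counts {1: 1070, 0: 175} (0 = current smoker)
```

`04` contrasts the two signal regimes (mean nested-CV MCC for a linear SVM,
10 fold values each; `paired_p` is a fold-paired signed-rank test vs. the
non-augmented baseline):

```
 effect_size  data_type  mean_mcc  paired_p_vs_baseline
         1.3       none    0.0384                   NaN
         1.3 smote_over    0.1329                0.0371
         1.3       tada    0.1341                0.0840
         1.5       none    0.1713                   NaN
         1.5 smote_over    0.2707                0.0137
         1.5       tada    0.2579                0.0195
         3.0       none    0.8161                   NaN
         3.0 smote_over    0.8085                0.6953
         3.0       tada    0.8079                0.5566
```

Reading: with a strong planted effect (3-fold) the classes are nearly
separable, the imbalanced baseline is already excellent and augmentation is
a wash. In the weak-signal regime (1.3–1.5-fold) — the regime real
smoking-microbiome data lives in — the baseline collapses toward constant
majority prediction (MCC ≈ 0.04) while augmented training roughly doubles
the achievable MCC, with fold-paired significance. `05` then trains the
final model (TADA + linear SVM, mirroring the study's choice) on the 80%
split and validates once on the pristine 20% holdout:

```
final model (tada + SVML): holdout MCC 0.760, holdout AUC 0.971
```

A `click` CLI wraps the same library for shell use:
`imbalmicro simulate|preprocess|cv|compare|final|all --config run.yaml
--seed 0 --fast --out results/`.

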