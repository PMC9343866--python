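"""Metrics, stratified splitting, nested CV, search, and the final model."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from imbalmicro.augment import AugmentationPlan
from imbalmicro.classifiers import default_specs
from imbalmicro.evaluate import (
    ConfusionMatrix,
    FoldScheme,
    ModelArtifact,
    auc,
    confusion_from_predictions,
    mcc,
    nested_cv,
    random_search,
    stratified_kfold,
    stratified_split,
    train_final_and_holdout,
)
from imbalmicro.tables import binarize_smoking, tss_normalize


def random_confusions(rng, n):
    return [
        ConfusionMatrix(*map(int, rng.integers(0, 60, size=4))) for _ in range(n)
    ]


def cm_to_vectors(cm):
    """Expand a confusion matrix into label/prediction vectors (positive=0)."""
    y_true = [0] * (cm.tp + cm.fn) + [1] * (cm.tn + cm.fp)
    y_pred = [0] * cm.tp + [1] * cm.fn + [1] * cm.tn + [0] * cm.fp
    return np.array(y_true), np.array(y_pred)


class TestMcc:
    def test_perfect_prediction(self):
        assert mcc(ConfusionMatrix(50, 50, 0, 0)) == 1.0

    def test_random_prediction(self):
        assert mcc(ConfusionMatrix(25, 25, 25, 25)) == 0.0

    def test_printed_formula_example(self):
        value = mcc(ConfusionMatrix(tp=90, tn=1, fp=9, fn=0))
        assert value == pytest.approx(90 / np.sqrt(99 * 90 * 10 * 1), abs=1e-4)
        assert value == pytest.approx(0.3015, abs=1e-4)

    def test_zero_denominator_convention(self):
        # all-one-class predictions: a denominator factor vanishes -> 0
        assert mcc(ConfusionMatrix(0, 90, 0, 10)) == 0.0
        assert mcc(ConfusionMatrix(10, 0, 90, 0)) == 0.0

    def test_matches_sklearn_on_random_matrices(self, rng):
        for cm in random_confusions(rng, 300):
            if cm.n == 0:
                continue
            y_true, y_pred = cm_to_vectors(cm)
            assert mcc(cm) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12
            )

    def test_bounded_and_swap_invariant(self, rng):
        for cm in random_confusions(rng, 500):
            if cm.n == 0:
                continue
            v = mcc(cm)
            assert -1.0 <= v <= 1.0
            swapped = ConfusionMatrix(tp=cm.tn, tn=cm.tp, fp=cm.fn, fn=cm.fp)
            assert mcc(swapped) == pytest.approx(v, abs=1e-12)


class TestAuc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([0.9, 0.8, 0.2, 0.1])  # larger = more smoker-like
        assert auc(y, scores) == 1.0

    def test_constant_scores_are_random(self):
        y = np.array([0, 1, 0, 1, 1])
        assert auc(y, np.ones(5)) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 31))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
            wins = ties = 0
            pos = scores[y == 0]
            neg = scores[y == 1]
            for p in pos:
                for q in neg:
                    wins += p > q
                    ties += p == q
            expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert auc(y, scores) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        scores = rng.uniform(size=50)
        # sklearn scores the label-1 class; our positive class is 0
        assert auc(y, scores) == pytest.approx(
            roc_auc_score(1 - y, scores), abs=1e-12
        )

    def test_single_class_is_error(self):
        with pytest.raises(ValueError, match="both classes"):
            auc(np.zeros(4), np.arange(4.0))


class TestStratifiedSplit:
    def test_study_scale_allocation(self, rng):
        y = np.array([0] * 175 + [1] * 1070)
        a, b = stratified_split(y, 0.8, rng)
        assert (y[a] == 0).sum() == 140 and (y[a] == 1).sum() == 856
        assert len(a) + len(b) == 1245
        assert np.intersect1d(a, b).size == 0

    def test_full_fraction_is_error(self, rng):
        y = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="empty partition"):
            stratified_split(y, 1.0, rng)

    def test_ratio_preserved_within_one_sample(self, rng):
        for _ in range(20):
            n0, n1 = int(rng.integers(5, 50)), int(rng.integers(5, 200))
            y = np.array([0] * n0 + [1] * n1)
            frac = float(rng.uniform(0.3, 0.8))
            a, _ = stratified_split(y, frac, rng)
            got0 = (y[a] == 0).sum()
            assert abs(got0 - frac * n0) <= 1.0

    def test_kfold_partitions_and_stratifies(self, rng):
        y = np.array([0] * 20 + [1] * 80)
        folds = stratified_kfold(y, 5, rng)
        combined = np.sort(np.concatenate(folds))
        assert np.array_equal(combined, np.arange(100))
        for f in folds:
            assert (y[f] == 0).sum() == 4  # 20 minority spread evenly


@pytest.fixture(scope="module")
def prepared_cohort(small_cohort):
    table, meta, tree = small_cohort
    norm = tss_normalize(table)
    labels = binarize_smoking(meta)
    y = labels.labels.loc[norm.sample_ids].to_numpy()
    return norm.values, y, tree, norm.taxon_ids, norm.sample_ids


class TestRandomSearch:
    def _inner_sets(self, X, y, rng):
        half = len(y) // 2
        idx = rng.permutation(len(y))
        a, b = idx[:half], idx[half:]
        return [(X[a], y[a], X[b], y[b]), (X[b], y[b], X[a], y[a])]

    def test_single_configuration_returned(self, rng):
        X = rng.uniform(size=(40, 3))
        y = np.array([0, 1] * 20)
        spec = default_specs(["DT"], n_search_iterations=3)[0]
        spec = type(spec)(spec.name, spec.builder, {"max_depth": [2]}, 3)
        params = random_search(spec, self._inner_sets(X, y, rng), rng)
        assert params == {"max_depth": 2}

    def test_dominant_configuration_wins(self, rng):
        # linearly separable data: a sane regularization beats a crippling one
        X = np.vstack([rng.normal(0, 0.3, (30, 2)), rng.normal(4, 0.3, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        spec = default_specs(["LR"], n_search_iterations=8)[0]
        spec = type(spec)(spec.name, spec.builder, {"C": [1e-6, 10.0]}, 8)
        params = random_search(spec, self._inner_sets(X, y, rng), np.random.default_rng(0))
        assert params["C"] == 10.0

    def test_identical_seeds_identical_choices(self, rng):
        X = rng.uniform(size=(30, 4))
        y = np.array([0, 1] * 15)
        spec = default_specs(["SVMR"], n_search_iterations=5)[0]
        sets = self._inner_sets(X, y, rng)
        p1 = random_search(spec, sets, np.random.default_rng(77))
        p2 = random_search(spec, sets, np.random.default_rng(77))
        assert p1 == p2


class TestNestedCV:
    @pytest.fixture(scope="class")
    def cv_result(self, prepared_cohort):
        X, y, tree, taxa, ids = prepared_cohort
        plans = [AugmentationPlan(scheme="none"), AugmentationPlan(scheme="smote_over")]
        specs = default_specs(["LR"], n_search_iterations=4)
        scheme = FoldScheme(repeats=2, master_seed=5)
        return nested_cv(X, y, plans, specs, scheme, tree=tree,
                         taxon_ids=taxa, sample_ids=ids), scheme

    def test_cardinality(self, cv_result):
        result, scheme = cv_result
        # repeats x outer_k records per (plan, spec)
        assert len(result.records) == 2 * 1 * scheme.repeats * scheme.outer_k
        counts = result.records.groupby(["data_type", "classifier"]).size()
        assert (counts == scheme.repeats * scheme.outer_k).all()

    def test_no_failures_on_clean_data(self, cv_result):
        result, _ = cv_result
        assert not result.records["failed"].any()

    def test_leakage_manifests(self, cv_result):
        result, _ = cv_result
        test_ids = [set(v) for k, v in result.manifests.items() if k[0] == "test"]
        train_ids = [set(v) for k, v in result.manifests.items() if k[0] == "train"]
        for tr_key, tr in result.manifests.items():
            if tr_key[0] != "train":
                continue
            rep, fold = tr_key[1], tr_key[2]
            te = set(result.manifests[("test", rep, fold)])
            synth = {i for i in tr if i.startswith("syn_")}
            originals = set(tr) - synth
            assert not te & originals, "test fold overlaps training originals"
            assert not te & synth, "synthetic ids leaked into a test fold"
            assert all(not t.startswith("syn_") for t in te)

    def test_class_counts_hit_plan_targets(self, cv_result):
        result, _ = cv_result
        for (rep, fold, scheme_name), counts in result.class_counts.items():
            post = counts["post"]
            if scheme_name == "none":
                assert post == counts["pre"]
            else:
                assert post[0] == post[1]

    def test_reproducible_under_master_seed(self, prepared_cohort):
        X, y, tree, taxa, ids = prepared_cohort
        plans = [AugmentationPlan(scheme="smote_combined")]
        specs = default_specs(["DT"], n_search_iterations=3)
        scheme = FoldScheme(repeats=1, master_seed=42)
        r1 = nested_cv(X, y, plans, specs, scheme, sample_ids=ids)
        r2 = nested_cv(X, y, plans, specs, scheme, sample_ids=ids)
        assert r1.records.equals(r2.records)
        assert r1.manifests == r2.manifests

    def test_shuffled_labels_give_null_mcc(self, prepared_cohort):
        X, y, _, _, ids = prepared_cohort
        y_shuf = np.random.default_rng(123).permutation(y)
        plans = [AugmentationPlan(scheme="none")]
        specs = default_specs(["LR"], n_search_iterations=3)
        res = nested_cv(X, y_shuf, plans, specs, FoldScheme(repeats=2, master_seed=8),
                        sample_ids=ids)
        vals = res.metric_values("none", "LR")
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) <= 2 * se + 1e-12


class TestFinalModel:
    def test_artifact_round_trip_and_metrics(self, prepared_cohort, tmp_path):
        X, y, tree, taxa, ids = prepared_cohort
        plan = AugmentationPlan(scheme="smote_over")
        spec = default_specs(["LR"], n_search_iterations=4)[0]
        scheme = FoldScheme(repeats=1, master_seed=3)
        art = train_final_and_holdout(X, y, plan, spec, scheme)
        assert -1 <= art.holdout_mcc <= 1 and 0 <= art.holdout_auc <= 1
        path = tmp_path / "model.pkl"
        art.save(path)
        assert path.with_suffix(".pkl.json").exists()
        back = ModelArtifact.load(path)
        assert np.array_equal(back.backend.predict(X), art.backend.predict(X))
        assert back.holdout_mcc == art.holdout_mcc

    def test_signal_beats_shuffled_baseline(self, prepared_cohort):
        X, y, _, _, _ = prepared_cohort
        plan = AugmentationPlan(scheme="smote_over")
        spec = default_specs(["LR"], n_search_iterations=4)[0]
        scheme = FoldScheme(repeats=1, master_seed=3)
        art = train_final_and_holdout(X, y, plan, spec, scheme)
        y_shuf = np.random.default_rng(5).permutation(y)
        art_null = train_final_and_holdout(X, y_shuf, plan, spec, scheme)
        assert art.holdout_mcc > art_null.holdout_mcc
        assert art.holdout_mcc > 0.2  # planted effect is recoverable


def test_confusion_from_predictions_totals(rng):
    y = rng.integers(0, 2, 40)
    p = rng.integers(0, 2, 40)
    cm = confusion_from_predictions(y, p)
    assert cm.n == 40
    assert cm.tp == int(((y == 0) & (p == 0)).sum())
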