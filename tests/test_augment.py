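"""Augmentation schemes: ratio equation, SMOTE/ADASYN, under-sampling, TADA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from imbalmicro.augment import (
    AugmentationPlan,
    GenerativeParams,
    adasyn_oversample,
    adasyn_weights,
    apply_plan,
    combined_ratio,
    random_undersample,
    smote_oversample,
    tada_augment,
)
from imbalmicro.phylo import PhyloTree


class TestCombinedRatio:
    def test_study_class_sizes(self):
        # 175 smokers vs 1,070 non-smokers: t = 895, over = 720/1070, under = 1
        over, under = combined_ratio(175, 1070)
        assert over == pytest.approx(720 / 1070)
        assert under == 1.0

    def test_balanced_classes_are_noop(self):
        for c in (1, 17, 500):
            assert combined_ratio(c, c) == (1.0, 1.0)

    @given(st.integers(1, 10_000), st.integers(0, 10_000))
    @settings(max_examples=1000, deadline=None)
    def test_under_ratio_identically_one(self, c_min, extra):
        # c_max - t = c_min algebraically, so the under ratio is always 1
        _, under = combined_ratio(c_min, c_min + extra)
        assert under == 1.0

    def test_zero_minority_is_error(self):
        with pytest.raises(ValueError, match="minority"):
            combined_ratio(0, 10)


class TestSmote:
    def test_two_points_collinear(self, rng):
        minority = np.array([[0.0, 0.0], [1.0, 1.0]])
        synth = smote_oversample(minority, 4, k=1, rng=rng)
        assert synth.shape == (4, 2)
        # every point on the segment between the two parents
        assert np.allclose(synth[:, 0], synth[:, 1])
        assert np.all((synth >= 0.0) & (synth <= 1.0))

    def test_zero_new_is_empty(self, rng):
        out = smote_oversample(np.ones((3, 2)), 0, k=1, rng=rng)
        assert out.shape == (0, 2)

    def test_single_row_is_error(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            smote_oversample(np.ones((1, 3)), 2, k=1, rng=rng)

    def test_parents_are_brute_force_nearest_and_bound_children(self, rng):
        minority = rng.uniform(size=(20, 5))
        k = 3
        synth, parents = smote_oversample(minority, 37, k, rng, return_parents=True)
        assert len(parents) == 37
        d2 = ((minority[:, None, :] - minority[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        for row, (src, nn) in zip(synth, parents):
            kth = np.sort(d2[src])[k - 1]
            assert d2[src, nn] <= kth + 1e-12  # nn verified k-nearest by all-pairs scan
            lo = np.minimum(minority[src], minority[nn])
            hi = np.maximum(minority[src], minority[nn])
            assert np.all(row >= lo - 1e-12) and np.all(row <= hi + 1e-12)

    def test_even_spread_across_sources(self, rng):
        minority = rng.uniform(size=(10, 3))
        _, parents = smote_oversample(minority, 25, 2, rng, return_parents=True)
        counts = np.bincount([p[0] for p in parents], minlength=10)
        assert counts.min() == 2 and counts.max() == 3 and counts.sum() == 25

    def test_k_reduced_with_warning(self, rng):
        with pytest.warns(UserWarning, match="reducing"):
            smote_oversample(np.eye(3), 3, k=5, rng=rng)


class TestAdasyn:
    def test_allocations_sum_to_n_new(self, rng):
        for _ in range(50):
            n_min = rng.integers(3, 15)
            minority = rng.uniform(size=(n_min, 4))
            majority = rng.uniform(size=(rng.integers(5, 30), 4))
            n_new = int(rng.integers(1, 40))
            synth = adasyn_oversample(minority, majority, n_new, k=3, rng=rng)
            assert synth.shape == (n_new, 4)

    def test_weights_match_brute_force(self, rng):
        minority = rng.uniform(size=(8, 3))
        majority = rng.uniform(size=(12, 3))
        k = 4
        r = adasyn_weights(minority, majority, k)
        pooled = np.vstack([minority, majority])
        for i in range(8):
            d = np.linalg.norm(pooled - minority[i], axis=1)
            d[i] = np.inf
            nn = np.argsort(d, kind="stable")[:k]
            assert r[i] == pytest.approx((nn >= 8).sum() / k)

    def test_hard_point_gets_more_offspring(self):
        rng = np.random.default_rng(5)
        # one minority point inside majority mass, one far away
        minority = np.array([[0.0, 0.0], [100.0, 100.0], [100.0, 101.0]])
        majority = np.array([[0.1, 0.0], [0.0, 0.1], [0.1, 0.1], [-0.1, 0.0]])
        _, parents = adasyn_oversample(
            minority, majority, 12, k=3, rng=rng, return_parents=True
        )
        counts = np.bincount([p[0] for p in parents], minlength=3)
        assert counts[0] > counts[1] and counts[0] > counts[2]

    def test_fallback_to_smote_when_no_majority_nearby(self, rng):
        minority = np.zeros((4, 2)) + np.eye(4, 2) * 0.01
        majority = np.full((4, 2), 1000.0)
        with pytest.warns(UserWarning, match="falling back"):
            synth = adasyn_oversample(minority, majority, 6, k=2, rng=rng)
        assert synth.shape == (6, 2)


class TestUndersample:
    def test_keep_all_is_identity(self, rng):
        m = np.arange(12.0).reshape(4, 3)
        out, kept = random_undersample(m, 4, rng)
        assert np.array_equal(out, m)
        assert kept.tolist() == [0, 1, 2, 3]

    def test_deterministic_under_seed(self):
        m = np.arange(30.0).reshape(10, 3)
        a, ka = random_undersample(m, 1, np.random.default_rng(9))
        b, kb = random_undersample(m, 1, np.random.default_rng(9))
        assert np.array_equal(a, b) and np.array_equal(ka, kb)

    def test_kept_rows_are_exact_copies(self, rng):
        m = rng.uniform(size=(10, 4))
        out, kept = random_undersample(m, 6, rng)
        assert np.array_equal(out, m[kept])
        assert np.all(np.diff(kept) > 0)  # order preserved

    def test_uniform_selection_frequencies(self):
        rng = np.random.default_rng(2024)
        m = np.arange(10.0).reshape(10, 1)
        hits = np.zeros(10)
        for _ in range(10_000):
            _, kept = random_undersample(m, 1, rng)
            hits[kept[0]] += 1
        assert chisquare(hits).pvalue > 0.01

    def test_too_many_requested_is_error(self, rng):
        with pytest.raises(ValueError, match="n_keep"):
            random_undersample(np.ones((3, 2)), 4, rng)


class TestTada:
    @pytest.fixture
    def composition(self, small_tree, rng):
        taxa = sorted(small_tree.leaf_labels)
        comp = rng.dirichlet(np.ones(len(taxa)), size=3)
        return taxa, comp

    def test_large_nu_reproduces_source(self, small_tree, composition):
        taxa, comp = composition
        params = GenerativeParams(nu=1e9, depth=10_000_000)
        rng = np.random.default_rng(0)
        synth = tada_augment(comp[:1], small_tree, 4, params, rng, taxon_ids=taxa)
        assert np.max(np.abs(synth - comp[0])) < 1e-3

    def test_zero_clade_stays_zero(self, small_tree):
        taxa = sorted(small_tree.leaf_labels)
        nodes = small_tree.indexed_nodes(taxa)
        clade = next(n for n in nodes[1:] if len(n.leaf_set) >= 2)
        comp = np.full((1, len(taxa)), 1.0)
        comp[0, clade.leaf_set] = 0.0
        comp /= comp.sum()
        rng = np.random.default_rng(3)
        synth = tada_augment(comp, small_tree, 10, GenerativeParams(), rng, taxon_ids=taxa)
        assert np.all(synth[:, clade.leaf_set] == 0.0)

    def test_mass_conserved_at_every_node(self, small_tree, composition):
        taxa, comp = composition
        rng = np.random.default_rng(4)
        synth, trace = tada_augment(
            comp, small_tree, 6, GenerativeParams(depth=5000), rng,
            taxon_ids=taxa, return_trace=True,
        )
        assert trace, "expected per-node records"
        for rec in trace:
            assert np.array_equal(rec["children"].sum(axis=1), rec["parent"])
        # compositional output
        assert np.allclose(synth.sum(axis=1), 1.0, atol=1e-9)

    def test_missing_taxon_is_error(self, small_tree, composition):
        taxa, comp = composition
        taxa = taxa[:-1] + ["taxon_9999"]
        with pytest.raises(ValueError, match="taxon_9999"):
            tada_augment(comp, small_tree, 2, GenerativeParams(), np.random.default_rng(0), taxon_ids=taxa)


class TestApplyPlan:
    @pytest.fixture
    def study_scale(self, rng):
        X = rng.uniform(size=(1245, 6))
        y = np.array([0] * 175 + [1] * 1070)
        return X, y

    def test_combined_targets_720_720(self, study_scale):
        X, y = study_scale
        out = apply_plan(X, y, AugmentationPlan(scheme="smote_combined", seed=1))
        assert out.class_counts() == {0: 720, 1: 720}

    def test_over_only_equalizes_to_majority(self, study_scale):
        X, y = study_scale
        out = apply_plan(X, y, AugmentationPlan(scheme="smote_over", seed=1))
        assert out.class_counts() == {0: 1070, 1: 1070}

    def test_none_is_passthrough(self, study_scale):
        X, y = study_scale
        out = apply_plan(X, y, AugmentationPlan(scheme="none", seed=1))
        assert np.array_equal(out.features, X)
        assert np.array_equal(out.labels, y)
        assert np.all(out.origin == "original")

    def test_synthetic_rows_only_in_minority(self, study_scale):
        X, y = study_scale
        out = apply_plan(X, y, AugmentationPlan(scheme="adasyn_combined", seed=2))
        assert set(out.labels[out.origin == "synthetic"]) == {0}
        for flag, par in zip(out.origin, out.parent_ids):
            if flag == "synthetic":
                assert par and all(y[p] == 0 for p in par)
            else:
                assert par is None

    def test_bitwise_determinism(self, study_scale):
        X, y = study_scale
        plan = AugmentationPlan(scheme="adasyn_over", seed=11)
        a = apply_plan(X, y, plan)
        b = apply_plan(X, y, plan)
        assert np.array_equal(a.features, b.features)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.origin, b.origin)

    def test_tada_requires_tree(self, study_scale):
        X, y = study_scale
        with pytest.raises(ValueError, match="tree"):
            apply_plan(X, y, AugmentationPlan(scheme="tada", seed=0))

    def test_tada_plan_balances_compositions(self, small_tree, rng):
        taxa = sorted(small_tree.leaf_labels)
        X = rng.dirichlet(np.ones(8), size=40)
        y = np.array([0] * 8 + [1] * 32)
        out = apply_plan(
            X, y, AugmentationPlan(scheme="tada", seed=3),
            tree=small_tree, taxon_ids=taxa,
        )
        assert out.class_counts() == {0: 32, 1: 32}
        assert np.allclose(out.features.sum(axis=1), 1.0, atol=1e-9)

    def test_balanced_input_is_noop_for_combined(self, rng):
        X = rng.uniform(size=(20, 3))
        y = np.array([0] * 10 + [1] * 10)
        out = apply_plan(X, y, AugmentationPlan(scheme="smote_combined", seed=0))
        assert out.class_counts() == {0: 10, 1: 10}
        assert np.all(out.origin == "original")


def test_plan_json_round_trip():
    plan = AugmentationPlan(
        scheme="tada", k_neighbors=7,
        tada_params=GenerativeParams(nu=50.0, depth=2000), seed=42,
    )
    back = AugmentationPlan.from_json_dict(plan.to_json_dict())
    assert back.scheme == plan.scheme
    assert back.k_neighbors == plan.k_neighbors
    assert back.tada_params.nu == 50.0
    assert back.tada_params.depth == 2000
    assert back.seed == 42


def test_unknown_scheme_rejected():
    with pytest.raises(ValueError, match="unknown scheme"):
        AugmentationPlan(scheme="mixup")
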