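"""Separability criterion, wrapper fitness, and the four selectors."""

import itertools

import numpy as np
import pytest

from plaquemark.caga import CAGAConfig
from plaquemark.features import FeatureMatrix
from plaquemark.selection import (
    ClassifierConfig,
    ConfusionCounts,
    SelectionResult,
    caga_filter_select,
    caga_wrapper_select,
    classify_test,
    make_separability_objective,
    pca_select,
    separability_fitness,
    wrapper_fitness,
)


def brute_force_lambda(class1, class2, eps=1e-12):
    """Independent re-summation of the criterion from raw loops."""
    class1 = np.atleast_2d(class1)
    class2 = np.atleast_2d(class2)
    n1, n2 = class1.shape[0], class2.shape[0]
    p1, p2 = n1 / (n1 + n2), n2 / (n1 + n2)
    c1 = sum(v for row in class1 for v in row) / class1.size
    c2 = sum(v for row in class2 for v in row) / class2.size
    s_b = (c1 - c2) ** 2
    s_w = 0.0
    for i in range(n1):
        for k in range(class1.shape[1]):
            s_w += (p1 / n1) * (class1[i, k] - c1) ** 2
    for j in range(n2):
        for k in range(class2.shape[1]):
            s_w += (p2 / n2) * (class2[j, k] - c2) ** 2
    return s_b / max(s_w, eps)


def _matrix(columns, labels):
    columns = np.asarray(columns, dtype=float)
    return FeatureMatrix(
        matrix=columns,
        template_length=columns.shape[0],
        index_maps=[np.arange(columns.shape[0])] * columns.shape[1],
        labels=np.asarray(labels),
    )


class TestSeparability:
    def test_worked_example_equals_sixteen(self):
        # class1 {0,2}, class2 {4,6}: centers 1 and 5, S_b=16, S_w=1
        lam = separability_fitness(np.array([[0.0], [2.0]]), np.array([[4.0], [6.0]]))
        assert lam == pytest.approx(16.0, abs=1e-9)

    def test_equal_centers_give_zero(self):
        lam = separability_fitness(np.array([[1.0], [3.0]]), np.array([[0.0], [4.0]]))
        assert lam == 0.0

    def test_matches_brute_force_on_random_small_matrices(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(1, 4), rng.integers(1, 4)
            m = rng.integers(1, 5)
            a = rng.normal(0, 3, size=(n1, m))
            b = rng.normal(1, 3, size=(n2, m))
            assert separability_fitness(a, b) == pytest.approx(
                brute_force_lambda(a, b), abs=1e-9, rel=1e-9
            )

    def test_invariant_under_within_class_permutation(self, rng):
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(5, 3))
        lam = separability_fitness(a, b)
        assert separability_fitness(a[rng.permutation(4)], b[rng.permutation(5)]) == (
            pytest.approx(lam)
        )

    def test_strictly_increasing_in_center_gap(self):
        a = np.array([[0.0], [2.0]])
        lams = [separability_fitness(a, a + shift) for shift in (1.0, 2.0, 4.0, 8.0)]
        assert all(x < y for x, y in zip(lams, lams[1:]))

    def test_zero_within_class_variance_guarded(self):
        lam = separability_fitness(np.array([[1.0]]), np.array([[2.0]]))
        assert np.isfinite(lam) and lam > 1e9

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            separability_fitness(np.empty((0, 1)), np.array([[1.0]]))

    def test_fast_objective_matches_direct_evaluation(self, rng):
        cols = rng.normal(100, 10, size=(8, 6))
        labels = ["AD", "CTL", "AD", "CTL", "AD", "CTL"]
        fm = _matrix(cols, labels)
        objective = make_separability_objective(fm, np.arange(6))
        for _ in range(25):
            mask = rng.random(8) < 0.5
            if not mask.any():
                continue
            a = cols[mask][:, np.array(labels) == "AD"].T
            b = cols[mask][:, np.array(labels) == "CTL"].T
            assert objective(mask) == pytest.approx(
                separability_fitness(a, b), rel=1e-9
            )


class TestWrapperFitness:
    def _separable(self):
        # feature 0 encodes the class perfectly; feature 1 is constant
        cols = np.array([[0, 0, 0, 10, 10, 10], [5, 5, 5, 5, 5, 5]], dtype=float)
        labels = ["CTL", "CTL", "CTL", "AD", "AD", "AD"]
        return _matrix(cols, labels)

    def test_separable_validation_reaches_one(self):
        fm = self._separable()
        acc = wrapper_fitness(
            np.array([1, 0], dtype=bool),
            fm,
            np.array([0, 1, 3, 4]),
            np.array([2, 5]),
            ClassifierConfig(kind="svm"),
        )
        assert acc == 1.0

    def test_accuracy_bounded_and_deterministic_for_svm(self, rng):
        cols = rng.normal(size=(5, 10))
        fm = _matrix(cols, ["AD"] * 5 + ["CTL"] * 5)
        mask = np.ones(5, dtype=bool)
        train, val = np.arange(6), np.arange(6, 10)
        a1 = wrapper_fitness(mask, fm, train, val, ClassifierConfig(kind="svm"))
        a2 = wrapper_fitness(mask, fm, train, val, ClassifierConfig(kind="svm"))
        assert 0.0 <= a1 <= 1.0 and a1 == a2

    def test_shuffled_labels_score_near_majority_rate(self, rng):
        """Permutation null: with uninformative labels the expected
        validation accuracy approaches the majority-class rate."""
        accs = []
        for _ in range(30):
            cols = rng.normal(size=(4, 24))
            labels = rng.permutation(["AD"] * 12 + ["CTL"] * 12)
            fm = _matrix(cols, labels)
            accs.append(
                wrapper_fitness(
                    np.ones(4, dtype=bool),
                    fm,
                    np.arange(16),
                    np.arange(16, 24),
                    ClassifierConfig(kind="svm"),
                )
            )
        assert np.mean(accs) == pytest.approx(0.5, abs=0.12)

    def test_rf_fitness_averages_repeated_forests(self, rng):
        fm = self._separable()
        acc = wrapper_fitness(
            np.array([1, 1], dtype=bool),
            fm,
            np.array([0, 1, 3, 4]),
            np.array([2, 5]),
            ClassifierConfig(kind="rf", rf_trees=25, rf_repeats=4),
            rng=rng,
        )
        assert 0.0 <= acc <= 1.0
        assert acc * 4 * 2 == pytest.approx(round(acc * 4 * 2))  # mean of 4 over 2 samples

    def test_empty_mask_rejected(self):
        fm = self._separable()
        with pytest.raises(ValueError):
            wrapper_fitness(
                np.zeros(2, dtype=bool),
                fm,
                np.array([0, 1, 3, 4]),
                np.array([2, 5]),
                ClassifierConfig(),
            )

    def test_overlapping_splits_rejected(self):
        fm = self._separable()
        with pytest.raises(ValueError):
            wrapper_fitness(
                np.array([1, 0], dtype=bool),
                fm,
                np.array([0, 1, 2]),
                np.array([2, 5]),
                ClassifierConfig(),
            )


def _planted_matrix(rng, length=12, informative=(2, 5), n_per_class=4):
    """Features `informative` separate the classes; the rest are noise."""
    cols = rng.normal(100.0, 4.0, size=(length, 2 * n_per_class))
    labels = np.array(["AD"] * n_per_class + ["CTL"] * n_per_class)
    for f in informative:
        cols[f, :n_per_class] -= 40.0
    return _matrix(cols, labels)


class TestCagaFilterSelect:
    def test_attains_exhaustive_optimum_on_planted_problem(self, rng):
        fm = _planted_matrix(rng)
        idx = np.arange(fm.n_samples)
        objective = make_separability_objective(fm, idx)
        exhaustive = max(
            objective(np.array(bits, dtype=bool))
            for bits in itertools.product([0, 1], repeat=fm.template_length)
            if any(bits)
        )
        result = caga_filter_select(
            fm, idx, CAGAConfig(max_iterations=25, seed=11)
        )
        assert result.fitness == pytest.approx(exhaustive, rel=1e-12)

    def test_fitness_invariant_under_sample_duplication(self, rng):
        """Duplicating every sample leaves priors and centers unchanged, so
        the criterion value of any mask is unchanged."""
        fm = _planted_matrix(rng)
        doubled = _matrix(
            np.hstack([fm.matrix, fm.matrix]),
            np.concatenate([fm.labels, fm.labels]),
        )
        obj_a = make_separability_objective(fm, np.arange(fm.n_samples))
        obj_b = make_separability_objective(doubled, np.arange(doubled.n_samples))
        for _ in range(20):
            mask = rng.random(fm.template_length) < 0.5
            if not mask.any():
                continue
            assert obj_a(mask) == pytest.approx(obj_b(mask), rel=1e-9)

    def test_default_search_settings(self):
        cfg = CAGAConfig()
        assert cfg.population_size == 50
        assert cfg.initial_crossover_prob == 0.8
        assert cfg.initial_mutation_prob == 0.05
        assert cfg.max_iterations == 30
        assert cfg.elite_count == 50


class TestCagaWrapperSelect:
    def test_planted_noiseless_problem_reaches_validation_accuracy_one(self):
        rng = np.random.default_rng(0)
        length, n = 10, 6
        cols = np.full((length, 2 * n), 100.0)
        cols += rng.normal(0, 0.01, size=cols.shape)
        cols[3, :n] -= 50.0
        cols[7, :n] -= 50.0
        fm = _matrix(cols, ["AD"] * n + ["CTL"] * n)
        result = caga_wrapper_select(
            fm,
            np.array([0, 1, 2, 6, 7, 8]),
            np.array([3, 4, 5, 9, 10, 11]),
            ClassifierConfig(kind="svm"),
            CAGAConfig(population_size=20, elite_count=20, max_iterations=10, seed=2),
        )
        assert result.fitness == 1.0

    def test_rf_wrapper_runs_and_reports_provenance(self, rng):
        fm = _planted_matrix(rng, length=6)
        result = caga_wrapper_select(
            fm,
            np.array([0, 1, 4, 5]),
            np.array([2, 3, 6, 7]),
            ClassifierConfig(kind="rf", rf_trees=15),
            CAGAConfig(population_size=6, elite_count=6, max_iterations=2, seed=9),
        )
        assert result.algorithm == "caga_rf_wrapper"
        assert 0.0 <= result.fitness <= 1.0
        assert result.n_selected >= 1


class TestPCASelect:
    def test_dominant_class_aligned_feature_ranked_first(self, rng):
        cols = rng.normal(0, 0.1, size=(6, 10))
        cols[2, :5] += 20.0  # dominating variance aligned with the class split
        fm = _matrix(cols, ["AD"] * 5 + ["CTL"] * 5)
        result = pca_select(fm, np.arange(10), n_features=1)
        assert result.mask[2]
        assert result.n_selected == 1

    def test_invariant_to_sample_order(self, rng):
        cols = rng.normal(50, 5, size=(8, 12))
        labels = np.array(["AD"] * 6 + ["CTL"] * 6)
        fm = _matrix(cols, labels)
        perm = rng.permutation(12)
        fm_perm = _matrix(cols[:, perm], labels[perm])
        a = pca_select(fm, np.arange(12), n_features=3)
        b = pca_select(fm_perm, np.arange(12), n_features=3)
        assert np.array_equal(a.mask, b.mask)

    def test_default_feature_budget_is_125(self, rng):
        cols = rng.normal(100, 10, size=(200, 12))
        fm = _matrix(cols, ["AD"] * 6 + ["CTL"] * 6)
        result = pca_select(fm, np.arange(12))
        assert result.n_selected == 125

    def test_constant_matrix_rejected(self):
        fm = _matrix(np.full((4, 6), 7.0), ["AD"] * 3 + ["CTL"] * 3)
        with pytest.raises(ValueError):
            pca_select(fm, np.arange(6), n_features=2)


class TestClassifyTest:
    def test_separable_data_lands_on_the_diagonal(self):
        cols = np.array([[0, 0, 0, 10, 10, 10]], dtype=float)
        labels = ["CTL", "CTL", "CTL", "AD", "AD", "AD"]
        fm = _matrix(cols, labels)
        _, counts = classify_test(
            np.array([True]),
            fm,
            np.array([0, 1, 3, 4]),
            np.array([2, 5]),
            ClassifierConfig(kind="svm"),
        )
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (1, 1, 0, 0)

    def test_all_positive_predictions_count_ctl_as_false_positives(self):
        counts = ConfusionCounts.from_labels(
            ["AD", "CTL", "CTL", "AD"], ["AD", "AD", "AD", "AD"]
        )
        assert counts.fp == 2 and counts.fn == 0
        assert counts.tp == 2 and counts.tn == 0

    def test_overlapping_train_test_rejected(self, rng):
        fm = _planted_matrix(rng)
        with pytest.raises(ValueError):
            classify_test(
                np.ones(fm.template_length, dtype=bool),
                fm,
                np.arange(5),
                np.arange(4, 8),
                ClassifierConfig(),
            )


def test_selection_result_rle_round_trip(rng):
    mask = rng.random(200) < 0.3
    result = SelectionResult(mask=mask, fitness=1.25, algorithm="caga_filter", seed=3)
    restored = SelectionResult.from_dict(result.to_dict())
    assert np.array_equal(restored.mask, mask)
    assert restored.fitness == 1.25 and restored.algorithm == "caga_filter"
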