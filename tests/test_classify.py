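"""Linear classifiers, leave-one-out evaluation, permutation and rank-sum tests."""

import inspect
import itertools

import numpy as np
import pytest

from oracles import rank_sum_exact_p, svc_qp_oracle
from seegconn import (
    ClassifierReport,
    LabeledPoint,
    SeparatingLine,
    SingleClassError,
    SingularCovarianceError,
    fit_lda,
    fit_linear_svc,
    loo_evaluate,
    permutation_test,
    rank_sum_test,
)


def _two_clusters(rng, n_pos=6, n_neg=6, sep=6.0, scale=0.5):
    pos = rng.normal([0.0, 0.0], scale, (n_pos, 2))
    neg = rng.normal([sep, 0.0], scale, (n_neg, 2))
    x = np.vstack([pos, neg])
    y = np.array([True] * n_pos + [False] * n_neg)
    return x, y


class TestLinearSVC:
    def test_symmetric_pair_bisected(self):
        x = np.array([[0.0, 0.0], [2.0, 0.0]])
        y = np.array([False, True])
        line = fit_linear_svc(x, y, C=1e6, tol=1e-10)
        # symmetry forces the perpendicular bisector through (1, 0)
        assert abs(line.decision_values([[1.0, 0.0]])[0]) < 1e-6
        assert line.predict([[1.5, 0.0]])[0]
        assert not line.predict([[0.5, 0.0]])[0]

    def test_separable_data_separated_with_large_c(self, rng):
        x, y = _two_clusters(rng)
        line = fit_linear_svc(x, y, C=1e6)
        assert np.array_equal(line.predict(x), y)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            fit_linear_svc(np.zeros((3, 2)), [True, True, True])

    def test_nonpositive_c_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_svc(np.eye(2), [True, False], C=0.0)

    def test_overlapping_points_match_qp_oracle(self):
        # 4-point configuration with one point inside the other class
        x = np.array([[0.0, 0.0], [0.2, 1.0], [1.0, 0.1], [0.9, 1.0]])
        y = np.array([True, True, False, False])
        for C in (1.0, 10.0):
            line = fit_linear_svc(x, y, C=C, tol=1e-12)
            w, b = svc_qp_oracle(x, y, C)
            assert np.abs(line.decision_values(x) - (x @ w + b)).max() < 1e-6

    def test_matches_public_sklearn_estimator(self, rng):
        # the low-level solver path must coincide with sklearn.svm.SVC
        from sklearn.svm import SVC

        for _ in range(20):
            n_pos = int(rng.integers(2, 9))
            n_neg = int(rng.integers(2, 9))
            x, y = _two_clusters(rng, n_pos, n_neg, sep=2.0, scale=1.0)
            order = rng.permutation(len(x))
            x, y = x[order], y[order]
            for C in (1.0, 50.0):
                line = fit_linear_svc(x, y, C=C, tol=1e-6)
                clf = SVC(kernel="linear", C=C, tol=1e-6).fit(x, y)
                assert np.allclose(line.weights, clf.coef_[0], atol=1e-12)
                assert line.offset == pytest.approx(clf.intercept_[0], abs=1e-12)

    def test_accepts_labeled_points(self):
        pts = [
            LabeledPoint("a", 0.0, 0.0, False),
            LabeledPoint("b", 2.0, 0.0, True),
        ]
        line = fit_linear_svc(pts, [p.label for p in pts], C=1e6)
        assert line.predict([[1.5, 0.0]])[0]


class TestLDA:
    def test_symmetric_clusters_give_bisector(self, rng):
        x, y = _two_clusters(rng, sep=4.0)
        line = fit_lda(x, y)
        mid = (x[y].mean(axis=0) + x[~y].mean(axis=0)) / 2.0
        assert abs(line.decision_values([mid])[0]) < 1e-10
        assert np.array_equal(line.predict(x), y)

    def test_hand_computed_two_plus_two(self):
        x = np.array([[0.0, 0.0], [2.0, 1.0], [4.0, 0.0], [5.0, 3.0]])
        y = np.array([True, True, False, False])
        line = fit_lda(x, y)
        mu_p, mu_n = x[:2].mean(axis=0), x[2:].mean(axis=0)
        # pooled covariance of two 2-point classes, (n-2) denominator
        sp = sum(np.outer(d, d) for d in (x[:2] - mu_p)) + sum(
            np.outer(d, d) for d in (x[2:] - mu_n)
        )
        pooled = sp / 2.0
        w = np.linalg.solve(pooled, mu_p - mu_n)
        assert np.allclose(line.weights, w, atol=1e-10)
        assert line.offset == pytest.approx(-w @ (mu_p + mu_n) / 2.0, abs=1e-10)

    def test_singular_pooled_covariance_rejected(self):
        x = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        y = np.array([True, True, False, False])
        with pytest.raises(SingularCovarianceError):
            fit_lda(x, y)

    def test_small_class_rejected(self):
        with pytest.raises(SingleClassError):
            fit_lda(np.eye(3, 2), [True, False, False])


class TestLooEvaluate:
    def test_well_separated_clusters_are_perfect(self, rng):
        x, y = _two_clusters(rng)
        rep = loo_evaluate(x, y)
        assert rep.sensitivity == 1.0
        assert rep.specificity == 1.0
        assert rep.accuracy == 1.0

    def test_metric_formulas_from_counts(self):
        rep = ClassifierReport.from_counts(tp=9, fp=2, tn=11, fn=1)
        assert rep.sensitivity == pytest.approx(0.900, abs=5e-4)
        assert rep.specificity == pytest.approx(11 / 13, abs=5e-4)
        assert rep.accuracy == pytest.approx(20 / 23, abs=5e-4)
        assert rep.tp + rep.fp + rep.tn + rep.fn == rep.n == 23

    def test_single_outlier_is_the_only_miss(self, rng):
        x, y = _two_clusters(rng, n_pos=7, n_neg=6)
        x[0] = [6.0, 0.0]  # positive point planted inside the negative cluster
        # C=1 suits this unit-scale geometry: the outlier is tolerated by the
        # soft margin instead of warping the boundary around its neighbours
        fitter = lambda a, b: fit_linear_svc(a, b, C=1.0)  # noqa: E731
        rep = loo_evaluate(x, y, fitter)
        # brute-force refits as the oracle
        expected = []
        for i in range(len(x)):
            keep = np.arange(len(x)) != i
            line = fitter(x[keep], y[keep])
            expected.append(bool(line.predict(x[i : i + 1])[0]))
        assert rep.predictions == expected
        misses = [i for i, (p, t) in enumerate(zip(rep.predictions, y)) if p != t]
        assert misses == [0]

    def test_contracts(self, rng):
        x, y = _two_clusters(rng)
        with pytest.raises(ValueError):
            loo_evaluate(x[:2], y[:2])
        with pytest.raises(SingleClassError):
            loo_evaluate(x, np.ones(len(x), dtype=bool))


class TestPermutationTest:
    def test_worst_possible_observation_gives_p_one(self):
        # a fitter stub whose fixed line misclassifies every observed point
        x = np.array([[0.0, -1.0], [0.2, -2.0], [0.1, 1.0], [0.3, 2.0]])
        y = np.array([True, True, False, False])
        fixed = lambda pts, labs: SeparatingLine(np.array([0.0, 1.0]), 0.0)  # noqa: E731
        res = permutation_test(x, y, n_permutations=50, seed=3, fitter=fixed)
        assert res.observed.accuracy == 0.0
        assert res.p_accuracy == 1.0

    def test_monte_carlo_agrees_with_exhaustive_enumeration(self, rng):
        x, y = _two_clusters(rng, n_pos=3, n_neg=3, sep=8.0)
        n_perm = 4000
        res = permutation_test(x, y, n_permutations=n_perm, seed=21, fitter=fit_lda)
        obs = loo_evaluate(x, y, fit_lda).accuracy
        # exact exceedance over all C(6,3)=20 equally likely arrangements
        accs = []
        for pos_idx in itertools.combinations(range(6), 3):
            perm = np.zeros(6, dtype=bool)
            perm[list(pos_idx)] = True
            accs.append(loo_evaluate(x, perm, fit_lda).accuracy)
        p_exact = np.mean([a >= obs - 1e-12 for a in accs])
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(res.p_accuracy - p_exact) <= 3 * se + 1e-12

    def test_seeded_runs_are_identical(self, rng):
        x, y = _two_clusters(rng, n_pos=4, n_neg=4)
        a = permutation_test(x, y, n_permutations=60, seed=9, fitter=fit_lda)
        b = permutation_test(x, y, n_permutations=60, seed=9, fitter=fit_lda)
        assert (a.p_accuracy, a.p_sensitivity, a.p_specificity) == (
            b.p_accuracy,
            b.p_sensitivity,
            b.p_specificity,
        )
        # the cohort-level default matches the study protocol
        sig = inspect.signature(permutation_test)
        assert sig.parameters["n_permutations"].default == 10_000

    def test_add_one_estimator_never_zero(self, rng):
        x, y = _two_clusters(rng, n_pos=4, n_neg=4, sep=10.0)
        res = permutation_test(x, y, n_permutations=40, seed=2, fitter=fit_lda,
                               add_one=True)
        assert res.p_accuracy >= 1.0 / 41.0


class TestRankSum:
    def test_extreme_arrangement_exact_p(self):
        w, p = rank_sum_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert w == 6.0  # rank-sum of the first group
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_interleaved_groups_not_significant(self):
        _, p = rank_sum_test([1.0, 3.0, 5.0], [2.0, 4.0, 6.0])
        assert p > 0.5

    def test_matches_enumeration_oracle(self, rng):
        a = rng.normal(0.0, 1.0, 5)
        b = rng.normal(1.0, 1.0, 6)
        _, p = rank_sum_test(a, b)
        assert p == pytest.approx(rank_sum_exact_p(a, b), abs=1e-12)

    def test_large_or_tied_samples_use_corrected_approximation(self, rng):
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(0.8, 1.0, 20)
        _, p = rank_sum_test(a, b)
        assert 0.0 < p < 1.0
        _, p_tied = rank_sum_test([1.0, 1.0, 2.0], [1.0, 3.0, 4.0])
        assert 0.0 < p_tied <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestReportInvariants:
    def test_counts_partition_the_cohort(self, rng):
        x, y = _two_clusters(rng, n_pos=5, n_neg=7, sep=2.0, scale=1.5)
        rep = loo_evaluate(x, y)
        assert rep.tp + rep.fp + rep.tn + rep.fn == len(x)
        assert rep.sensitivity == rep.tp / (rep.tp + rep.fn)
        assert rep.specificity == rep.tn / (rep.tn + rep.fp)
        assert rep.accuracy == (rep.tp + rep.tn) / len(x)
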