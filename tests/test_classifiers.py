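"""Classifier paradigms, LOOCV evaluation and performance metrics."""

import numpy as np
import pytest
from scipy import optimize

from episelect import (
    IMPROVEMENT_ONLY,
    SEIZURE_FREE,
    ClassifierSpec,
    f_measure,
    fit_naive_bayes,
    fit_ridge_logistic,
    loocv_evaluate,
    make_knn,
    roc_auc,
)
from episelect.classifiers import _one_hot, _penalized_ll

from conftest import make_cohort, random_cohort

ALL_SPECS = [
    ClassifierSpec("naive_bayes"),
    ClassifierSpec("ridge_logistic"),
    ClassifierSpec("knn", k=3),
]


def _toy_4rows():
    # classes 2/2; feature value A appears once in the seizure-free class
    return make_cohort(
        {"f": ["A", "B", "A", "A"]},
        [SEIZURE_FREE, SEIZURE_FREE, IMPROVEMENT_ONLY, IMPROVEMENT_ONLY],
    )


class TestNaiveBayes:
    def test_posterior_matches_count_oracle(self):
        """4-row toy: posterior equals hand-multiplied smoothed ratios."""
        cohort = _toy_4rows()
        model = fit_naive_bayes(cohort, ["f"], alpha=1.0)
        probe = make_cohort({"f": ["A"]}, [SEIZURE_FREE], schema=cohort.schema)
        post = model.predict_proba(probe)[0]
        # oracle: prior 1/2 each; P(A|free) = (1+1)/(2+2) = 1/2,
        # P(A|improv) = (2+1)/(2+2) = 3/4
        p_free = 0.5 * 0.5
        p_improv = 0.5 * 0.75
        expected = p_free / (p_free + p_improv)
        assert post[1] == pytest.approx(expected, abs=1e-10)

    def test_empty_feature_set_returns_prior(self):
        cohort = make_cohort(
            {"f": ["A"] * 19},
            [SEIZURE_FREE] * 14 + [IMPROVEMENT_ONLY] * 5,
        )
        model = fit_naive_bayes(cohort, [])
        post = model.predict_proba(cohort)
        assert np.allclose(post[:, 1], 14 / 19)

    def test_separable_feature_dominates(self):
        cohort = make_cohort(
            {"f": ["A", "A", "B", "B"]},
            [SEIZURE_FREE, SEIZURE_FREE, IMPROVEMENT_ONLY, IMPROVEMENT_ONLY],
        )
        model = fit_naive_bayes(cohort, ["f"])
        post = model.predict_proba(cohort)
        assert (post.argmax(axis=1) == np.array([1, 1, 0, 0])).all()

    def test_exhaustive_joint_count_oracle_random_cohorts(self):
        """NB posterior equals the explicit smoothed-count computation."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            cohort = random_cohort(rng, n=14, p=3)
            model = fit_naive_bayes(cohort, cohort.feature_names, alpha=1.0)
            post = model.predict_proba(cohort)
            enc = cohort.encode()
            y = enc.y
            n1, n0 = int(y.sum()), int((1 - y).sum())
            for i in range(cohort.n):
                terms = {1: n1 / cohort.n, 0: n0 / cohort.n}
                for j, f in enumerate(enc.feature_names):
                    C = enc.n_categories[j]
                    for k, nk in ((1, n1), (0, n0)):
                        cnt = int(((enc.X[:, j] == enc.X[i, j]) & (y == k)).sum())
                        terms[k] *= (cnt + 1.0) / (nk + C)
                expected = terms[1] / (terms[0] + terms[1])
                assert post[i, 1] == pytest.approx(expected, abs=1e-10)


class TestRidgeLogistic:
    def test_huge_penalty_collapses_to_base_rate(self):
        cohort = make_cohort(
            {"f": ["A", "A", "B", "B", "A"]},
            [SEIZURE_FREE] * 3 + [IMPROVEMENT_ONLY] * 2,
        )
        model = fit_ridge_logistic(cohort, ["f"], ridge_lambda=1e8)
        assert np.abs(model.coef[1:]).max() < 1e-6
        post = model.predict_proba(cohort)[:, 1]
        assert np.allclose(post, 3 / 5, atol=1e-6)

    def test_separable_with_tiny_penalty(self):
        cohort = make_cohort(
            {"f": ["A", "A", "A", "B", "B"]},
            [SEIZURE_FREE] * 3 + [IMPROVEMENT_ONLY] * 2,
        )
        model = fit_ridge_logistic(cohort, ["f"], ridge_lambda=1e-8)
        post = model.predict_proba(cohort)[:, 1]
        assert (post[:3] > 0.5).all() and (post[3:] < 0.5).all()

    def test_coefficients_match_generic_optimizer(self):
        """Newton solution agrees with scipy BFGS on the same objective."""
        rng = np.random.default_rng(8)
        cohort = random_cohort(rng, n=16, p=2)
        lam = 0.1
        model = fit_ridge_logistic(cohort, cohort.feature_names, ridge_lambda=lam)
        enc = cohort.encode()
        Z = _one_hot(enc.X, enc.n_categories)
        y = enc.y.astype(float)
        pen = np.full(Z.shape[1], lam)
        pen[0] = 0.0
        res = optimize.minimize(
            lambda w: -_penalized_ll(Z, y, w, pen),
            np.zeros(Z.shape[1]),
            method="BFGS",
            options={"gtol": 1e-12, "maxiter": 2000},
        )
        # the penalized likelihood has a flat one-hot redundancy direction;
        # compare fitted probabilities and the objective value instead of raw
        # coefficients plus the coefficients themselves
        assert _penalized_ll(Z, y, model.coef, pen) == pytest.approx(
            _penalized_ll(Z, y, res.x, pen), abs=1e-6
        )
        assert np.allclose(model.coef, res.x, atol=1e-4)


class TestKNN:
    def test_k1_identity_neighbor(self):
        cohort = make_cohort(
            {"f": ["A", "B", "C"], "g": ["A", "B", "C"]},
            [SEIZURE_FREE, IMPROVEMENT_ONLY, SEIZURE_FREE],
        )
        model = make_knn(cohort, ["f", "g"], k=1)
        post = model.predict_proba(cohort)
        assert np.allclose(post[:, 1], [1.0, 0.0, 1.0])

    def test_all_neighbor_limit(self):
        cohort = make_cohort(
            {"f": ["A", "B", "A", "B", "A"]},
            [SEIZURE_FREE] * 3 + [IMPROVEMENT_ONLY] * 2,
        )
        model = make_knn(cohort, ["f"], k=4)
        probe = make_cohort({"f": ["A"]}, [SEIZURE_FREE], schema=cohort.schema)
        # scores among any 4 of the 5 training rows: close to class frequency
        assert abs(model.predict_proba(probe)[0, 1] - 3 / 5) <= 1 / 4

    def test_matches_exhaustive_distance_sort_oracle(self):
        """5-row toy, k=3: prediction equals full pairwise-distance sort with
        stable row-order tie-breaking."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            cohort = random_cohort(rng, n=5, p=3, n_cats=2)
            model = make_knn(cohort, cohort.feature_names, k=3)
            enc = cohort.encode()
            post = model.predict_proba(cohort)[:, 1]
            for i in range(5):
                d = [(int((enc.X[t] != enc.X[i]).sum()), t) for t in range(5)]
                d.sort()  # stable by (distance, original row order)
                votes = [enc.y[t] for _, t in d[:3]]
                assert post[i] == pytest.approx(sum(votes) / 3)

    def test_k_exceeding_training_size_rejected(self):
        cohort = make_cohort(
            {"f": ["A", "B", "A"]}, [SEIZURE_FREE, IMPROVEMENT_ONLY, SEIZURE_FREE]
        )
        with pytest.raises(ValueError):
            make_knn(cohort, ["f"], k=3)


class TestLOOCV:
    def test_majority_baseline_accuracy(self):
        """Empty feature set: every minority hold-out is wrong, majority right."""
        cohort = make_cohort(
            {"f": ["A"] * 19},
            [SEIZURE_FREE] * 14 + [IMPROVEMENT_ONLY] * 5,
        )
        res = loocv_evaluate(ClassifierSpec("naive_bayes"), cohort, [])
        assert res.accuracy == pytest.approx(14 / 19)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.paradigm)
    def test_perfect_feature_gives_perfect_cv(self, spec):
        cohort = make_cohort(
            {"f": ["A"] * 10 + ["B"] * 6, "noise": ["X", "Y"] * 8},
            [SEIZURE_FREE] * 10 + [IMPROVEMENT_ONLY] * 6,
        )
        res = loocv_evaluate(spec, cohort, ["f"])
        assert res.accuracy == 1.0
        assert res.auc == 1.0

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.paradigm)
    def test_outcome_copy_feature_perfect_accuracy(self, spec):
        rng = np.random.default_rng(21)
        cohort = random_cohort(rng, n=14, p=2)
        copy = ["SF" if o == SEIZURE_FREE else "IO" for o in cohort.outcome]
        cohort.features["copy"] = copy
        from episelect import FeatureSchema

        cohort.schema["copy"] = FeatureSchema(name="copy", categories=("IO", "SF"))
        res = loocv_evaluate(spec, cohort, ["copy"])
        assert res.accuracy == 1.0

    def test_confusion_counts_consistent(self):
        rng = np.random.default_rng(2)
        cohort = random_cohort(rng, n=15, p=3)
        res = loocv_evaluate(ClassifierSpec("naive_bayes"), cohort)
        c = res.confusion
        assert c["TP"] + c["FP"] + c["TN"] + c["FN"] == cohort.n
        assert res.accuracy == pytest.approx((c["TP"] + c["TN"]) / cohort.n)
        assert len(res.fold_scores) == cohort.n

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.paradigm)
    def test_posteriors_sum_to_one(self, spec):
        rng = np.random.default_rng(33)
        cohort = random_cohort(rng, n=12, p=3)
        model_post = {
            "naive_bayes": lambda: fit_naive_bayes(cohort, cohort.feature_names),
            "ridge_logistic": lambda: fit_ridge_logistic(cohort, cohort.feature_names),
            "knn": lambda: make_knn(cohort, cohort.feature_names, k=3),
        }[spec.paradigm]()
        post = model_post.predict_proba(cohort)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_fast_nb_path_equals_explicit_per_fold_fits(self):
        rng = np.random.default_rng(44)
        for _ in range(5):
            cohort = random_cohort(rng, n=11, p=3)
            res = loocv_evaluate(ClassifierSpec("naive_bayes"), cohort)
            for i in range(cohort.n):
                idx = [j for j in range(cohort.n) if j != i]
                model = fit_naive_bayes(cohort.subset(idx), cohort.feature_names)
                probe = cohort.subset([i])
                expected = model.predict_proba(probe)[0, 1]
                assert res.fold_scores[i] == pytest.approx(expected, abs=1e-12)


class TestMetrics:
    def test_auc_examples(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5
        assert roc_auc([0.9, 0.3, 0.5], [1, 1, 0]) == 0.5  # 1 concordant, 1 discordant

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            s = rng.random(15)
            y = (rng.random(15) < 0.5).astype(int)
            y[:2] = [0, 1]
            a = roc_auc(s, y)
            assert roc_auc(np.exp(3 * s) - 1, y) == pytest.approx(a, abs=1e-12)

    def test_auc_matches_trapezoidal_roc_integration(self):
        """Mann-Whitney estimator equals the area under the empirical ROC."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(6, 30))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            y = (rng.random(n) < 0.5).astype(int)
            y[:2] = [0, 1]
            thresholds = np.unique(scores)[::-1]
            tpr = [0.0]
            fpr = [0.0]
            n_pos, n_neg = y.sum(), (1 - y).sum()
            for t in thresholds:
                tpr.append(((scores >= t) & (y == 1)).sum() / n_pos)
                fpr.append(((scores >= t) & (y == 0)).sum() / n_neg)
            area = np.trapezoid(tpr, fpr)
            assert roc_auc(scores, y) == pytest.approx(area, abs=1e-10)

    def test_auc_requires_both_classes(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize(
        "conf,expected",
        [
            ((14, 2, 3, 0), 0.9333333333),
            ((1, 1, 0, 1), 0.5),
            ((0, 0, 5, 2), 0.0),
        ],
    )
    def test_f_measure_values(self, conf, expected):
        assert f_measure(*conf) == pytest.approx(expected, abs=1e-9)

    def test_f_measure_empty_confusion_rejected(self):
        with pytest.raises(ValueError):
            f_measure(0, 0, 0, 0)
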