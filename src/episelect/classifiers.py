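"""Supervised classifiers on categorical clinical features, under LOOCV.

Three paradigms are supported — categorical naive Bayes with Laplace
smoothing, logistic regression with a ridge penalty on one-hot encoded
categories, and k-nearest-neighbour with overlap (Hamming) distance — each
exposing a class posterior for the ``seizure_free`` outcome.  Evaluation is
leave-one-out cross-validation: n models, each trained on n-1 patients and
scored on the held-out one; accuracy is the mean held-out 0/1 correctness,
the AUC is computed from the n pooled held-out scores, and the F-measure
treats ``seizure_free`` as the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .dataset import (
    SEIZURE_FREE,
    CohortTable,
    EncodedCohort,
    impute_class_conditional_mode,
)

__all__ = [
    "ClassifierSpec",
    "CVResult",
    "NaiveBayesModel",
    "RidgeLogisticModel",
    "KNNModel",
    "fit_naive_bayes",
    "fit_ridge_logistic",
    "make_knn",
    "loocv_evaluate",
    "roc_auc",
    "f_measure",
]

PARADIGMS = ("naive_bayes", "ridge_logistic", "knn")


@dataclass(frozen=True)
class ClassifierSpec:
    """A classification paradigm plus its hyperparameters.

    Defaults: Laplace alpha 1 (naive Bayes), ridge lambda 1e-8 (a
    near-unpenalized conventional default), k = 3 neighbours with overlap
    distance.
    """

    paradigm: str
    laplace_alpha: float = 1.0
    ridge_lambda: float = 1e-8
    k: int = 3

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.laplace_alpha < 0 or self.ridge_lambda < 0 or self.k < 1:
            raise ValueError("invalid hyperparameters")


@dataclass
class CVResult:
    accuracy: float
    auc: float
    f_measure: float
    confusion: dict[str, int]  # TP/FP/TN/FN with seizure_free positive
    fold_scores: np.ndarray  # held-out P(seizure_free | x) per patient
    predictions: np.ndarray  # held-out 0/1 predictions (1 = seizure_free)

    @property
    def errors(self) -> np.ndarray:
        """Per-fold 0/1 error vector (1 = misclassified)."""
        return self._errors

    _errors: np.ndarray = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC estimator with midrank tie handling.

    Equals (concordant pairs + half of tied pairs) / (positives x negatives).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind not in "biu":
        y = np.array([1 if v == SEIZURE_FREE else 0 for v in labels])
    pos = y == 1
    n_pos = int(pos.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: one class absent")
    ranks = sps.rankdata(s, method="average")
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def f_measure(tp: int, fp: int, tn: int, fn: int) -> float:
    """F1 with seizure_free as the positive class; 0 when TP = 0."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("negative confusion counts")
    if tp + fp + tn + fn == 0:
        raise ValueError("empty confusion matrix")
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# Naive Bayes
# ---------------------------------------------------------------------------


def _check_query_schema(model, cohort: CohortTable) -> None:
    """Queries must encode with the training vocabulary, not their own."""
    for name, cats in zip(model.feature_names, model.categories):
        if cohort.schema[name].categories != cats:
            raise ValueError(
                f"feature {name!r}: query schema categories "
                f"{cohort.schema[name].categories} differ from the training "
                f"schema {cats}"
            )


@dataclass
class NaiveBayesModel:
    feature_names: list[str]
    categories: list[tuple[str, ...]]
    class_log_prior: np.ndarray  # shape (2,), order [improvement_only, seizure_free]
    cond_log_prob: list[np.ndarray]  # per feature: (n_categories, 2)
    n_categories: np.ndarray

    def predict_proba(self, cohort: CohortTable) -> np.ndarray:
        """Posterior [P(improvement_only), P(seizure_free)] per patient."""
        _check_query_schema(self, cohort)
        enc = cohort.encode(self.feature_names)
        if (enc.X < 0).any():
            raise ValueError("prediction requires fully observed features")
        return self._predict_encoded(enc.X)

    def _predict_encoded(self, X: np.ndarray) -> np.ndarray:
        logp = np.tile(self.class_log_prior, (X.shape[0], 1))
        for j, table in enumerate(self.cond_log_prob):
            logp += table[X[:, j]]
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)


def fit_naive_bayes(
    train: CohortTable,
    features: Sequence[str],
    *,
    alpha: float = 1.0,
) -> NaiveBayesModel:
    """Categorical naive Bayes with Laplace smoothing.

    Class priors are unsmoothed relative class frequencies; each feature's
    class-conditional category probability is ``(count + alpha) /
    (n_class + alpha * n_categories)``, so every category retains mass and
    unseen categories at prediction time are well-defined.
    """
    enc = train.encode(list(features))
    cats = [train.schema[f].categories for f in enc.feature_names]
    return _fit_nb_encoded(enc, alpha, cats)


def _fit_nb_encoded(
    enc: EncodedCohort, alpha: float, categories: list[tuple[str, ...]]
) -> NaiveBayesModel:
    if enc.n == 0:
        raise ValueError("empty training set")
    if (enc.X < 0).any():
        raise ValueError("training requires fully observed features (impute first)")
    n_k = np.array([(enc.y == 0).sum(), (enc.y == 1).sum()], dtype=float)
    if (n_k == 0).any():
        warnings.warn("a class is absent from the training set; smoothing priors")
        prior = (n_k + 1) / (n_k.sum() + 2)
    else:
        prior = n_k / n_k.sum()
    cond = []
    for j in range(enc.X.shape[1]):
        C = int(enc.n_categories[j])
        counts = np.zeros((C, 2))
        np.add.at(counts, (enc.X[:, j], enc.y), 1.0)
        table = (counts + alpha) / (n_k + alpha * C)
        cond.append(np.log(table))
    return NaiveBayesModel(
        feature_names=list(enc.feature_names),
        categories=list(categories),
        class_log_prior=np.log(prior),
        cond_log_prob=cond,
        n_categories=enc.n_categories.copy(),
    )


def _loocv_nb_scores(enc: EncodedCohort, alpha: float) -> np.ndarray:
    """Held-out P(seizure_free|x) per patient, vectorized over folds.

    Exploits the count structure of naive Bayes: full-cohort counts minus the
    held-out row's own contribution give every fold's training counts.
    """
    X, y, n = enc.X, enc.y, enc.n
    n_k_full = np.array([(y == 0).sum(), (y == 1).sum()], dtype=float)
    own = np.eye(2)[y]  # (n, 2): row i removes itself from class y_i
    n_k = n_k_full - own  # per-fold class sizes, (n, 2)
    if (n_k <= 0).any():
        # a fold loses an entire class: smooth priors in those folds
        warnings.warn("LOOCV fold lost an entire class; smoothing fold priors")
        prior = (n_k + 1) / (n_k.sum(axis=1, keepdims=True) + 2)
    else:
        prior = n_k / (n - 1)
    logp = np.log(prior)
    for j in range(X.shape[1]):
        C = int(enc.n_categories[j])
        counts = np.zeros((C, 2))
        np.add.at(counts, (X[:, j], y), 1.0)
        cnt = counts[X[:, j]] - own  # (n, 2): training count of own category
        logp += np.log((cnt + alpha) / (n_k + alpha * C))
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    return p[:, 1]


# ---------------------------------------------------------------------------
# Ridge logistic regression
# ---------------------------------------------------------------------------


@dataclass
class RidgeLogisticModel:
    feature_names: list[str]
    categories: list[tuple[str, ...]]
    coef: np.ndarray  # intercept first, then one coefficient per category
    ridge_lambda: float
    converged: bool
    n_categories: np.ndarray

    def _design(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        D = int(self.n_categories.sum())
        Z = np.zeros((n, 1 + D))
        Z[:, 0] = 1.0
        offset = 1
        for j in range(X.shape[1]):
            Z[np.arange(n), offset + X[:, j]] = 1.0
            offset += int(self.n_categories[j])
        return Z

    def predict_proba(self, cohort: CohortTable) -> np.ndarray:
        _check_query_schema(self, cohort)
        enc = cohort.encode(self.feature_names)
        if (enc.X < 0).any():
            raise ValueError("prediction requires fully observed features")
        eta = self._design(enc.X) @ self.coef
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p1, p1])


def fit_ridge_logistic(
    train: CohortTable,
    features: Sequence[str],
    ridge_lambda: float = 1e-8,
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> RidgeLogisticModel:
    """Logistic regression with ridge-penalized one-hot category coefficients.

    All categories of every feature are one-hot encoded; the intercept is
    unpenalized.  Coefficients maximize the penalized log-likelihood
    ``sum(log p) - lambda/2 * ||w||^2`` by damped Newton iterations to
    gradient norm ``tol`` (max ``max_iter``).  With ``lambda = 0`` on
    separable data the optimum diverges: the fit then returns
    ``converged=False`` with a warning.
    """
    enc = train.encode(list(features))
    if (enc.X < 0).any():
        raise ValueError("training requires fully observed features (impute first)")
    coef, converged = _fit_ridge_encoded(
        enc, ridge_lambda, tol=tol, max_iter=max_iter
    )
    if not converged:
        warnings.warn("ridge logistic fit did not converge")
    return RidgeLogisticModel(
        feature_names=list(enc.feature_names),
        categories=[train.schema[f].categories for f in enc.feature_names],
        coef=coef,
        ridge_lambda=ridge_lambda,
        converged=converged,
        n_categories=enc.n_categories.copy(),
    )


def _one_hot(X: np.ndarray, n_categories: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    D = int(n_categories.sum())
    Z = np.zeros((n, 1 + D))
    Z[:, 0] = 1.0
    offset = 1
    for j in range(X.shape[1]):
        Z[np.arange(n), offset + X[:, j]] = 1.0
        offset += int(n_categories[j])
    return Z


def _fit_ridge_encoded(
    enc: EncodedCohort, lam: float, *, tol: float = 1e-8, max_iter: int = 200
) -> tuple[np.ndarray, bool]:
    Z = _one_hot(enc.X, enc.n_categories)
    y = enc.y.astype(float)
    d = Z.shape[1]
    w = np.zeros(d)
    pen = np.full(d, lam)
    pen[0] = 0.0  # intercept unpenalized
    converged = False
    for _ in range(max_iter):
        eta = Z @ w
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = Z.T @ (y - p) - pen * w
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        W = np.clip(p * (1 - p), 1e-12, None)
        H = (Z * W[:, None]).T @ Z + np.diag(np.maximum(pen, 1e-12))
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # damped update guards against overshoot near separability
        obj0 = _penalized_ll(Z, y, w, pen)
        t = 1.0
        while t > 1e-8:
            w_new = w + t * step
            if _penalized_ll(Z, y, w_new, pen) >= obj0 - 1e-12:
                break
            t /= 2.0
        w = w + t * step
    return w, converged


def _penalized_ll(Z, y, w, pen) -> float:
    eta = Z @ w
    # log-likelihood via stable log(1+exp)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return ll - 0.5 * float(np.sum(pen * w * w))


# ---------------------------------------------------------------------------
# k-nearest neighbour
# ---------------------------------------------------------------------------


@dataclass
class KNNModel:
    feature_names: list[str]
    categories: list[tuple[str, ...]]
    X_train: np.ndarray
    y_train: np.ndarray
    k: int

    def predict_proba(self, cohort: CohortTable) -> np.ndarray:
        _check_query_schema(self, cohort)
        enc = cohort.encode(self.feature_names)
        if (enc.X < 0).any():
            raise ValueError("prediction requires fully observed features")
        p1 = np.array([self._score_one(row) for row in enc.X])
        return np.column_stack([1 - p1, p1])

    def _score_one(self, row: np.ndarray) -> float:
        d = (self.X_train != row).sum(axis=1)
        order = np.argsort(d, kind="stable")  # distance ties: original row order
        votes = self.y_train[order[: self.k]]
        return float(votes.mean())

    def predict(self, cohort: CohortTable) -> np.ndarray:
        """Hard labels; vote ties resolve toward the training majority class."""
        p1 = self.predict_proba(cohort)[:, 1]
        majority = 1 if self.y_train.mean() >= 0.5 else 0
        out = (p1 > 0.5).astype(int)
        out[p1 == 0.5] = majority
        return out


def make_knn(train: CohortTable, features: Sequence[str], k: int = 3) -> KNNModel:
    """Lazy k-NN on overlap (Hamming) distance over the selected features."""
    enc = train.encode(list(features))
    if (enc.X < 0).any():
        raise ValueError("training requires fully observed features (impute first)")
    if k > enc.n - 1:
        raise ValueError(f"k={k} exceeds n-1={enc.n - 1}")
    return KNNModel(
        feature_names=list(enc.feature_names),
        categories=[train.schema[f].categories for f in enc.feature_names],
        X_train=enc.X,
        y_train=enc.y,
        k=k,
    )


def _loocv_knn(enc: EncodedCohort, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Held-out scores and hard predictions for k-NN, one fold per row."""
    X, y, n = enc.X, enc.y, enc.n
    if k > n - 2:
        raise ValueError(f"k={k} exceeds LOOCV training size {n - 2}")
    # pairwise overlap distances
    D = np.zeros((n, n), dtype=np.int64)
    for j in range(X.shape[1]):
        D += X[:, j][:, None] != X[:, j][None, :]
    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        order = idx[np.argsort(D[i, idx], kind="stable")]
        votes = y[order[:k]]
        f = votes.mean()
        scores[i] = f
        if f == 0.5:
            majority = 1 if y[idx].mean() >= 0.5 else 0
            preds[i] = majority
        else:
            preds[i] = int(f > 0.5)
    return scores, preds


# ---------------------------------------------------------------------------
# LOOCV evaluation
# ---------------------------------------------------------------------------


def loocv_evaluate(
    spec: ClassifierSpec,
    cohort: CohortTable,
    features: Sequence[str] | None = None,
    *,
    impute_in_folds: bool = False,
) -> CVResult:
    """Leave-one-out cross-validation of one paradigm on a cohort.

    Fits n models, each on n-1 patients, scoring the held-out one.  With the
    default pipeline the cohort is already imputed; ``impute_in_folds=True``
    instead performs class-conditional mode imputation inside every training
    fold (the held-out case's missing cells take the training fold's overall
    modes, since its class may not be assumed known), avoiding the outcome
    leakage of whole-cohort imputation at the price of deviating from the
    original procedure.
    """
    names = list(features) if features is not None else cohort.feature_names
    if cohort.n < 3:
        raise ValueError("LOOCV needs at least 3 patients")
    y = np.array([1 if o == SEIZURE_FREE else 0 for o in cohort.outcome])
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")

    if impute_in_folds:
        scores, preds = _loocv_strict(spec, cohort, names)
    else:
        enc = cohort.encode(names)
        if (enc.X < 0).any():
            raise ValueError("cohort has missing values; impute first or use impute_in_folds")
        scores, preds = _loocv_encoded(spec, enc)
    return _summarize(scores, preds, y)


def _loocv_encoded(spec: ClassifierSpec, enc: EncodedCohort) -> tuple[np.ndarray, np.ndarray]:
    if enc.X.shape[1] == 0:
        # empty feature set: posterior equals the fold prior
        scores = _loocv_nb_scores(
            EncodedCohort(
                X=np.empty((enc.n, 0), dtype=int),
                y=enc.y,
                feature_names=[],
                n_categories=np.empty(0, dtype=int),
            ),
            alpha=1.0,
        )
        return scores, (scores > 0.5).astype(int)
    if spec.paradigm == "naive_bayes":
        scores = _loocv_nb_scores(enc, spec.laplace_alpha)
        return scores, (scores > 0.5).astype(int)
    if spec.paradigm == "knn":
        return _loocv_knn(enc, spec.k)
    # ridge logistic: explicit per-fold refits
    n = enc.n
    scores = np.empty(n)
    for i in range(n):
        idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        sub = EncodedCohort(
            X=enc.X[idx],
            y=enc.y[idx],
            feature_names=enc.feature_names,
            n_categories=enc.n_categories,
        )
        if sub.y.min() == sub.y.max():
            warnings.warn("LOOCV fold lost an entire class; intercept-only fallback")
            scores[i] = float(sub.y.mean())
            continue
        coef, _ = _fit_ridge_encoded(sub, spec.ridge_lambda)
        Z = _one_hot(enc.X[i : i + 1], enc.n_categories)
        scores[i] = 1.0 / (1.0 + np.exp(-(Z @ coef)[0]))
    return scores, (scores > 0.5).astype(int)


def _loocv_strict(
    spec: ClassifierSpec, cohort: CohortTable, names: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    from .dataset import _mode  # same tie-break convention as full imputation

    n = cohort.n
    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        idx = [j for j in range(n) if j != i]
        train = impute_class_conditional_mode(cohort.subset(idx))
        # held-out row: fill its missing cells from training-fold overall modes
        test_feats: dict[str, list[str | None]] = {}
        for name in names:
            v = cohort.features[name][i]
            if v is None:
                v = _mode(train.features[name], cohort.schema[name])
            test_feats[name] = [v]
        test = CohortTable(
            patient_ids=[cohort.patient_ids[i]],
            features=test_feats,
            outcome=[cohort.outcome[i]],
            schema=cohort.schema,
        )
        model = _fit_model(spec, train, names)
        scores[i] = model.predict_proba(test)[0, 1]
        if isinstance(model, KNNModel):
            preds[i] = model.predict(test)[0]
        else:
            preds[i] = int(scores[i] > 0.5)
    return scores, preds


def _fit_model(spec: ClassifierSpec, train: CohortTable, names: list[str]):
    if spec.paradigm == "naive_bayes":
        return fit_naive_bayes(train, names, alpha=spec.laplace_alpha)
    if spec.paradigm == "ridge_logistic":
        return fit_ridge_logistic(train, names, spec.ridge_lambda)
    return make_knn(train, names, k=spec.k)


def _summarize(scores: np.ndarray, preds: np.ndarray, y: np.ndarray) -> CVResult:
    tp = int(((preds == 1) & (y == 1)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    res = CVResult(
        accuracy=float((preds == y).mean()),
        auc=roc_auc(scores, y),
        f_measure=f_measure(tp, fp, tn, fn),
        confusion={"TP": tp, "FP": fp, "TN": tn, "FN": fn},
        fold_scores=scores,
        predictions=preds,
    )
    res._errors = (preds != y).astype(float)
    return res
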