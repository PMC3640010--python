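"""Multinomial-mixture (latent class) clustering of categorical cohorts.

The model assumes each patient belongs to one of K latent components; given
the component, features are independent categorical draws from per-component
probability tables.  Parameters are estimated by EM with soft
responsibilities, which directly yields the probability that each case
belongs to each cluster rather than a hard assignment.  Agreement scoring
compares the hard argmax assignment, under the best cluster-to-label
mapping, against the known surgical outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .dataset import CohortTable

__all__ = [
    "MixtureModel",
    "AgreementReport",
    "fit_multinomial_mixture",
    "cluster_agreement",
]


@dataclass
class MixtureModel:
    K: int
    weights: np.ndarray  # (K,)
    theta: dict[str, np.ndarray]  # feature -> (K, n_categories)
    responsibilities: np.ndarray  # (n, K)
    loglik_trace: list[float]
    feature_names: list[str]

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def assign(self) -> np.ndarray:
        """Hard component labels by argmax responsibility."""
        return self.responsibilities.argmax(axis=1)


def _em_once(
    X: np.ndarray,
    n_categories: np.ndarray,
    K: int,
    rng: np.random.Generator,
    *,
    smoothing: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray, list[float]]:
    n, p = X.shape
    resp = rng.dirichlet(np.ones(K), size=n)
    trace: list[float] = []
    weights = np.full(K, 1.0 / K)
    thetas: list[np.ndarray] = []
    prev = -np.inf
    for _ in range(max_iter):
        # M-step (with small-count smoothing against zero-probability lock-in)
        nk = resp.sum(axis=0)
        weights = nk / n
        thetas = []
        for j in range(p):
            C = int(n_categories[j])
            counts = np.zeros((K, C))
            for c in range(C):
                counts[:, c] = resp[X[:, j] == c].sum(axis=0)
            thetas.append((counts + smoothing) / (nk[:, None] + smoothing * C))
        # E-step
        log_w = np.log(np.clip(weights, 1e-300, None))
        logp = np.tile(log_w, (n, 1))
        for j in range(p):
            logp += np.log(thetas[j])[:, X[:, j]].T
        norm = logsumexp(logp, axis=1)
        resp = np.exp(logp - norm[:, None])
        ll = float(norm.sum())
        trace.append(ll)
        if np.isfinite(prev) and abs(ll - prev) <= tol * max(1.0, abs(prev)):
            break
        prev = ll
    return weights, thetas, resp, trace


def fit_multinomial_mixture(
    cohort: CohortTable,
    K: int = 2,
    seed: int = 0,
    restarts: int = 10,
    *,
    features: Sequence[str] | None = None,
    smoothing: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureModel:
    """Fit a K-component multinomial mixture by EM.

    Each restart initializes responsibilities from a symmetric Dirichlet and
    iterates EM until the relative log-likelihood change falls below ``tol``
    (or ``max_iter``); the restart with the highest final log-likelihood
    wins.  M-step category counts receive ``smoothing`` pseudo-mass so no
    category probability collapses to exactly zero.  Components whose weight
    degenerates below 1e-6 trigger a warning.
    """
    names = list(features) if features is not None else cohort.feature_names
    enc = cohort.encode(names)
    if (enc.X < 0).any():
        raise ValueError("cohort has missing values; impute first")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > enc.n:
        raise ValueError(f"K={K} exceeds cohort size {enc.n}")
    best = None
    for r in range(max(1, restarts)):
        rng = np.random.default_rng([seed, r])
        fit = _em_once(
            enc.X,
            enc.n_categories,
            K,
            rng,
            smoothing=smoothing,
            tol=tol,
            max_iter=max_iter,
        )
        if best is None or fit[3][-1] > best[3][-1]:
            best = fit
    weights, thetas, resp, trace = best
    if (weights < 1e-6).any():
        warnings.warn("degenerate mixture component (weight < 1e-6)")
    theta = {name: thetas[j] for j, name in enumerate(names)}
    return MixtureModel(
        K=K,
        weights=weights,
        theta=theta,
        responsibilities=resp,
        loglik_trace=trace,
        feature_names=names,
    )


@dataclass
class AgreementReport:
    n_correct: int
    n: int
    mapping: dict[int, str]  # cluster index -> outcome label
    misassigned: list[object]  # case ids of mismatches under the best mapping
    composition: dict[int, dict[str, int]]  # cluster -> outcome -> count
    tied_cases: list[object]  # cases with an exactly 0.5 responsibility


def cluster_agreement(
    responsibilities: np.ndarray,
    labels: Sequence[str],
    case_ids: Sequence[object] | None = None,
) -> AgreementReport:
    """Score 2-cluster soft assignments against binary outcome labels.

    Cases are hard-assigned to their argmax cluster (an exact 0.5 tie goes
    to cluster 0 and is flagged); the cluster-to-label mapping maximizing
    the number of matches is chosen, and the mismatching case ids reported.
    """
    R = np.asarray(responsibilities, dtype=float)
    if R.ndim != 2 or R.shape[1] != 2:
        raise ValueError("responsibilities must be n x 2")
    labels = list(labels)
    if len(labels) != R.shape[0]:
        raise ValueError("labels length mismatch")
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError("labels must be binary")
    ids = list(case_ids) if case_ids is not None else list(range(1, len(labels) + 1))
    ties = [ids[i] for i in range(len(ids)) if R[i, 0] == R[i, 1]]
    assign = np.where(R[:, 0] >= R[:, 1], 0, 1)

    best_map, best_correct = None, -1
    for perm in permutations(uniq):
        mapping = {0: perm[0], 1: perm[1]}
        correct = sum(mapping[a] == lab for a, lab in zip(assign, labels))
        if correct > best_correct:
            best_correct = correct
            best_map = mapping
    mis = [
        ids[i] for i in range(len(ids)) if best_map[assign[i]] != labels[i]
    ]
    composition: dict[int, dict[str, int]] = {0: {}, 1: {}}
    for a, lab in zip(assign, labels):
        composition[int(a)][lab] = composition[int(a)].get(lab, 0) + 1
    return AgreementReport(
        n_correct=int(best_correct),
        n=len(labels),
        mapping=best_map,
        misassigned=mis,
        composition=composition,
        tied_cases=ties,
    )
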