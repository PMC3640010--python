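"""Race-search feature selection with bootstrap stability ranking.

The wrapper search races the current feature subset against all of its
single-deletion candidates: every candidate is scored by the per-fold 0/1
error vector of a leave-one-out cross-validation, candidates significantly
worse than the incumbent (paired t-test on the fold errors) drop out of the
lap, and the best remaining candidate replaces the incumbent when its mean
error is strictly lower.  Backward elimination proceeds until no deletion
improves.  Because a single run on a 19-patient cohort is unstable, the
selection is repeated over stratified bootstrap resamples and features are
ranked by how often they survive; prefixes of that ranking are then
evaluated incrementally to choose the final subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .classifiers import (
    ClassifierSpec,
    CVResult,
    _fit_ridge_encoded,
    _loocv_knn,
    _loocv_nb_scores,
    _one_hot,
    loocv_evaluate,
)
from .dataset import IMPROVEMENT_ONLY, SEIZURE_FREE, CohortTable, EncodedCohort

__all__ = [
    "RaceConfig",
    "FrequencyRanking",
    "SelectionCurve",
    "race_search_backward",
    "bootstrap_selection_frequencies",
    "incremental_subset_evaluation",
]


@dataclass(frozen=True)
class RaceConfig:
    """Racing parameters: backward elimination with t-tests at level alpha."""

    alpha: float = 0.05
    max_laps: int | None = None
    paired: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class FrequencyRanking:
    """Per-feature selection counts over B bootstrap resamples.

    ``order`` sorts features by descending count; ties keep the cohort's
    original feature order (stable).
    """

    counts: dict[str, int]
    B: int
    spec: ClassifierSpec
    order: list[str] = field(init=False)

    def __post_init__(self) -> None:
        names = list(self.counts)
        self.order = sorted(names, key=lambda f: (-self.counts[f], names.index(f)))
        bad = [f for f, c in self.counts.items() if not 0 <= c <= self.B]
        if bad:
            raise ValueError(f"counts outside [0, B] for {bad}")


@dataclass
class SelectionCurve:
    """LOOCV performance of nested ranking prefixes of sizes 1..p."""

    points: list[tuple[tuple[str, ...], CVResult]]
    best: tuple[str, ...]


def _errors_encoded(
    spec: ClassifierSpec, enc: EncodedCohort, cols: Sequence[int]
) -> np.ndarray:
    """Per-fold LOOCV 0/1 errors on a column subset, without metric overhead."""
    sub = EncodedCohort(
        X=enc.X[:, list(cols)],
        y=enc.y,
        feature_names=[enc.feature_names[c] for c in cols],
        n_categories=enc.n_categories[list(cols)],
    )
    if spec.paradigm == "naive_bayes":
        scores = _loocv_nb_scores(sub, spec.laplace_alpha)
        preds = (scores > 0.5).astype(int)
    elif spec.paradigm == "knn":
        _, preds = _loocv_knn(sub, spec.k)
    else:
        n = sub.n
        preds = np.empty(n, dtype=int)
        for i in range(n):
            idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
            fold = EncodedCohort(
                X=sub.X[idx],
                y=sub.y[idx],
                feature_names=sub.feature_names,
                n_categories=sub.n_categories,
            )
            if fold.y.min() == fold.y.max():
                preds[i] = int(fold.y[0])
                continue
            coef, _ = _fit_ridge_encoded(fold, spec.ridge_lambda)
            Z = _one_hot(sub.X[i : i + 1], sub.n_categories)
            preds[i] = int((Z @ coef)[0] > 0.0)
    return (preds != sub.y).astype(float)


def _paired_p(e_cand: np.ndarray, e_inc: np.ndarray, paired: bool) -> float:
    d = e_cand - e_inc
    if paired:
        if np.allclose(d, 0) or d.std(ddof=1) == 0:
            return 1.0
        t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        return float(2 * sps.t.sf(abs(t), d.size - 1))
    res = sps.ttest_ind(e_cand, e_inc, equal_var=False)
    return float(res.pvalue) if np.isfinite(res.pvalue) else 1.0


def race_search_backward(
    cohort: CohortTable,
    spec: ClassifierSpec,
    config: RaceConfig | None = None,
    seed: int | None = None,
) -> tuple[str, ...]:
    """Backward-elimination race over feature subsets.

    Starting from all features, each lap evaluates every single-deletion
    candidate of the incumbent subset by per-fold LOOCV errors.  Candidates
    whose paired t-test against the incumbent shows them significantly worse
    (p < alpha) are eliminated from the lap; among the survivors the one
    with the lowest mean error becomes the lap winner and replaces the
    incumbent when its mean error does not exceed the incumbent's — a tie
    favors the smaller subset, so features whose removal costs nothing are
    pruned.  The race stops when every deletion strictly degrades
    performance or a single feature remains.  Candidates are examined in
    name order and exact ties between equally good deletions are broken
    uniformly by the seeded generator, so the procedure is deterministic
    for a fixed seed and equivariant under reordering of feature columns
    (with no seed, the first candidate in name order wins ties).
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    config = config or RaceConfig()
    if len(set(cohort.outcome)) < 2:
        raise ValueError("outcome is constant; racing undefined")
    names = sorted(cohort.feature_names)
    if not names:
        raise ValueError("cohort has no features")
    enc = cohort.encode(names)
    current = list(range(len(names)))
    e_inc = _errors_encoded(spec, enc, current)
    laps = 0
    while len(current) > 1:
        laps += 1
        if config.max_laps is not None and laps > config.max_laps:
            break
        m_inc = e_inc.mean()
        tied: list[tuple[int, np.ndarray]] = []
        best_mean = np.inf
        for c in current:
            candidate = [g for g in current if g != c]
            e_cand = _errors_encoded(spec, enc, candidate)
            m_cand = e_cand.mean()
            if m_cand > m_inc and _paired_p(e_cand, e_inc, config.paired) < config.alpha:
                continue  # significantly worse: eliminated from this lap
            if m_cand < best_mean - 1e-12:
                best_mean = m_cand
                tied = [(c, e_cand)]
            elif abs(m_cand - best_mean) <= 1e-12:
                tied.append((c, e_cand))
        if not tied or best_mean > m_inc:
            break  # every deletion degrades performance
        pick = 0 if rng is None else int(rng.integers(len(tied)))
        best_col, e_inc = tied[pick]
        current = [g for g in current if g != best_col]
    return tuple(names[c] for c in current)


def _stratified_resample(
    outcome: Sequence[str], rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap row indices preserving the exact original class counts."""
    idx_sf = np.flatnonzero([o == SEIZURE_FREE for o in outcome])
    idx_im = np.flatnonzero([o == IMPROVEMENT_ONLY for o in outcome])
    draw = np.concatenate(
        [
            rng.choice(idx_sf, size=idx_sf.size, replace=True),
            rng.choice(idx_im, size=idx_im.size, replace=True),
        ]
    )
    return draw


def bootstrap_selection_frequencies(
    cohort: CohortTable,
    spec: ClassifierSpec,
    B: int = 1000,
    seed: int = 0,
    config: RaceConfig | None = None,
) -> FrequencyRanking:
    """Selection frequency of every feature over B stratified resamples.

    Each resample draws, with replacement, exactly the original number of
    patients from each outcome class (duplicated rows act as distinct
    instances), runs the backward race on it, and counts which features the
    selected subset retains.  Resample r uses an independent RNG stream
    derived from ``(seed, r)``, so runs are reproducible and partial
    parallelism would not change results.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    counts = {f: 0 for f in cohort.feature_names}
    for r in range(B):
        rng = np.random.default_rng([seed, r])
        rows = _stratified_resample(cohort.outcome, rng)
        resampled = cohort.subset(list(rows))
        race_seed = int(rng.integers(2**31 - 1))
        try:
            selected = race_search_backward(resampled, spec, config, seed=race_seed)
        except Exception as exc:  # pragma: no cover - propagated with context
            raise RuntimeError(f"race failed on resample {r}") from exc
        for f in selected:
            counts[f] += 1
    return FrequencyRanking(counts=counts, B=B, spec=spec)


def incremental_subset_evaluation(
    ranking: FrequencyRanking,
    cohort: CohortTable,
    spec: ClassifierSpec,
) -> SelectionCurve:
    """Top-down evaluation of ranking prefixes (most-selected first).

    Prefix subsets of sizes 1..p are each scored with LOOCV; the best point
    has the highest accuracy, with ties resolved toward the smaller subset
    and then toward the higher AUC.
    """
    missing = [f for f in cohort.feature_names if f not in ranking.counts]
    if missing:
        raise ValueError(f"ranking does not cover features {missing}")
    points: list[tuple[tuple[str, ...], CVResult]] = []
    for size in range(1, len(ranking.order) + 1):
        subset = tuple(ranking.order[:size])
        points.append((subset, loocv_evaluate(spec, cohort, subset)))
    best = max(
        points,
        key=lambda pt: (pt[1].accuracy, -len(pt[0]), pt[1].auc),
    )[0]
    return SelectionCurve(points=points, best=best)
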