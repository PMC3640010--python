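"""Exact, tie-aware Wilcoxon tests and class-stratified contingencies.

Categorical clinical features are coded to ordinal ranks (schema listing
order) and compared between outcome groups with an exact two-sample rank-sum
test; the exact null is the permutation distribution of the rank sum over all
group assignments, with midranks inside tie groups.  A paired signed-rank
test (zeros discarded, midranks on |delta| ties, exact over all sign
assignments) covers pre/post-surgery comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .dataset import (
    IMPROVEMENT_ONLY,
    SEIZURE_FREE,
    CohortTable,
)

__all__ = [
    "RankTestResult",
    "StratifiedContingency",
    "exact_rank_sum_test",
    "exact_signed_rank_test",
    "stratified_contingency",
    "rank_table",
    "ordinal_codes",
]

# exact enumeration is used up to this pooled sample size (rank-sum) /
# number of non-zero differences (signed-rank)
_EXACT_RANKSUM_N = 25
_EXACT_SIGNRANK_M = 20


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    n1: int
    n2: int


@dataclass(frozen=True)
class StratifiedContingency:
    """Per-category outcome counts for one feature.

    ``rows[category] = (count seizure_free, count improvement_only)``, in
    schema category order.
    """

    feature: str
    rows: dict[str, tuple[int, int]]

    @property
    def totals(self) -> tuple[int, int]:
        return (
            sum(v[0] for v in self.rows.values()),
            sum(v[1] for v in self.rows.values()),
        )


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _ranksum_exact_tail(ranks2: np.ndarray, n1: int, w2: int) -> tuple[float, float]:
    """Tail probabilities of the rank sum of a size-``n1`` group.

    ``ranks2`` are doubled midranks (integers); ``w2`` the doubled observed
    sum.  Returns (P(W <= w), P(W >= w)) under the uniform permutation null
    over all C(n, n1) assignments, by dynamic programming over items.
    """
    total = int(ranks2.sum())
    # dp[k, s] = number of k-subsets with doubled rank sum s
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        dp[1:, r:] += dp[:-1, : total + 1 - r]
    dist = dp[n1]
    n_total = dist.sum()
    lo = dist[: w2 + 1].sum() / n_total
    hi = dist[w2:].sum() / n_total
    return lo, hi


def exact_rank_sum_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> RankTestResult:
    """Two-sample Wilcoxon rank-sum test, exact under ties.

    Midranks are assigned within tie groups of the pooled sample; the exact
    null distribution of the smaller group's rank sum is computed by
    convolution over all :math:`\\binom{n}{n_1}` group assignments.  The
    two-sided p doubles the smaller tail (including the observed value),
    capped at 1.  For pooled sizes above 25 a normal approximation with tie
    correction is used instead.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    # statistic: rank sum of the smaller group (ties to group a)
    if a.size <= b.size:
        n1, sel = a.size, ranks[: a.size]
    else:
        n1, sel = b.size, ranks[a.size :]
    w = float(sel.sum())
    n = pooled.size
    if n <= _EXACT_RANKSUM_N:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w))
        lo, hi = _ranksum_exact_tail(ranks2, n1, w2)
        p = min(1.0, 2.0 * min(lo, hi))
        method = "exact"
    else:
        mean = n1 * (n + 1) / 2.0
        # variance with tie correction
        _, counts = np.unique(pooled, return_counts=True)
        n2 = n - n1
        var = n1 * n2 / 12.0 * ((n + 1) - ((counts**3 - counts).sum()) / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (w - mean) / np.sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "normal_approx"
    return RankTestResult(
        statistic=w, p_two_sided=float(p), method=method, n1=int(a.size), n2=int(b.size)
    )


def _signrank_exact_tail(ranks2: np.ndarray, w2: int) -> tuple[float, float]:
    """(P(W+ <= w), P(W+ >= w)) over all sign assignments, by convolution."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    n_total = dist.sum()
    return dist[: w2 + 1].sum() / n_total, dist[w2:].sum() / n_total


def exact_signed_rank_test(deltas: Sequence[float]) -> RankTestResult:
    """One-sample Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded; |delta| ties receive midranks; the exact
    null enumerates all :math:`2^m` sign assignments (m = nonzero count)
    when m <= 20, otherwise a tie-corrected normal approximation is used.
    All-zero input returns p = 1 with ``n1 = 0``.
    """
    d = np.asarray(deltas, dtype=float)
    nz = d[d != 0]
    m = nz.size
    if m == 0:
        return RankTestResult(statistic=0.0, p_two_sided=1.0, method="exact", n1=0, n2=0)
    ranks = _midranks(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    if m <= _EXACT_SIGNRANK_M:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        lo, hi = _signrank_exact_tail(ranks2, w2)
        p = min(1.0, 2.0 * min(lo, hi))
        method = "exact"
    else:
        mean = ranks.sum() / 2.0
        var = (ranks**2).sum() / 4.0
        z = (w_plus - mean) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "normal_approx"
    return RankTestResult(
        statistic=w_plus, p_two_sided=float(p), method=method, n1=int(m), n2=0
    )


# ---------------------------------------------------------------------------
# Cohort-level wrappers
# ---------------------------------------------------------------------------


def ordinal_codes(cohort: CohortTable, feature: str) -> np.ndarray:
    """Integer rank codes (1-based, schema listing order) for one feature.

    Raises if the feature still contains missing values: rank tests run on
    the imputed cohort.
    """
    if feature not in cohort.features:
        raise KeyError(f"unknown feature {feature!r}")
    sch = cohort.schema[feature]
    col = cohort.features[feature]
    if any(v is None for v in col):
        raise ValueError(f"feature {feature!r} has missing values; impute first")
    return np.array([sch.index(v) + 1 for v in col], dtype=float)


def stratified_contingency(cohort: CohortTable, feature: str) -> StratifiedContingency:
    """Per-category seizure-free / improvement-only counts for one feature."""
    if feature not in cohort.features:
        raise KeyError(f"unknown feature {feature!r}")
    col = cohort.features[feature]
    if any(v is None for v in col):
        raise ValueError(f"feature {feature!r} has missing values; impute first")
    rows: dict[str, tuple[int, int]] = {}
    for cat in cohort.schema[feature].categories:
        sf = sum(1 for v, o in zip(col, cohort.outcome) if v == cat and o == SEIZURE_FREE)
        im = sum(
            1 for v, o in zip(col, cohort.outcome) if v == cat and o == IMPROVEMENT_ONLY
        )
        if sf or im:
            rows[cat] = (sf, im)
    return StratifiedContingency(feature=feature, rows=rows)


def rank_table(
    cohort: CohortTable,
    features: Sequence[str] | None = None,
    *,
    alpha: float = 0.05,
    correction: str | None = None,
    group_by: Sequence[str] | None = None,
):
    """Per-feature rank-sum tests grouped by outcome, sorted by p-value.

    Each feature's ordinal codes are split into the two outcome groups (or by
    an explicit binary ``group_by`` vector, e.g. a cluster assignment) and
    compared with :func:`exact_rank_sum_test`.  Returns a
    :class:`pandas.DataFrame` with columns ``feature``, ``statistic``, ``p``,
    ``significant`` sorted by ascending p (ties keep cohort feature order).
    No multiplicity correction is applied by default; ``correction`` accepts
    "bonferroni" or "holm".
    """
    import pandas as pd

    names = list(features) if features is not None else cohort.feature_names
    if group_by is None:
        grouping = [o == SEIZURE_FREE for o in cohort.outcome]
    else:
        if len(group_by) != cohort.n:
            raise ValueError("group_by length must equal cohort size")
        grouping = [bool(g) for g in group_by]
    records = []
    for name in names:
        codes = ordinal_codes(cohort, name)
        g1 = codes[np.array(grouping)]
        g0 = codes[~np.array(grouping)]
        res = exact_rank_sum_test(g1, g0)
        records.append(
            {"feature": name, "statistic": res.statistic, "p": res.p_two_sided}
        )
    df = pd.DataFrame.from_records(records)
    pvals = df["p"].to_numpy()
    if correction is None:
        adjusted = pvals
    else:
        from statsmodels.stats.multitest import multipletests

        method = {"bonferroni": "bonferroni", "holm": "holm"}[correction]
        adjusted = multipletests(pvals, alpha=alpha, method=method)[1]
        df["p_adjusted"] = adjusted
    df["significant"] = adjusted <= alpha
    return df.sort_values("p", kind="stable").reset_index(drop=True)
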