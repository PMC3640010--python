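"""Synthetic cohorts with the statistical structure of the study data.

Real per-patient neuropsychological profiles were never published, so every
pipeline stage is exercised on generated cohorts instead: a binary outcome
drawn from the study's 14:5 class prior, a few *planted* features whose
category distribution depends on the outcome (defaults follow the
class-stratified contingencies of the three discriminative features — Side,
P.Style, PIQ), the remaining features drawn class-independently from the
study's marginal category counts, and missing cells knocked out completely
at random at the study's per-feature missingness rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .classifiers import ClassifierSpec
from .dataset import (
    IMPROVEMENT_ONLY,
    SEIZURE_FREE,
    CohortTable,
    FeatureSchema,
    impute_class_conditional_mode,
)
from .feature_selection import (
    RaceConfig,
    bootstrap_selection_frequencies,
    incremental_subset_evaluation,
)

__all__ = [
    "SyntheticConfig",
    "generate_cohort",
    "recovery_harness",
    "separable_mixture_cohort",
    "RecoveryReport",
    "study_like_config",
    "STUDY_CLASS_PRIOR",
    "STUDY_PLANTED_CONTINGENCIES",
    "STUDY_MARGINALS",
    "STUDY_MISSING_RATES",
]

# Class-stratified category counts of the three discriminative features in
# the 19-patient analysis cohort: {feature: {category: (seizure_free,
# improvement_only)}}.  Side: half of Left and all of Right seizure-free;
# P.Style: all EB1 and 11/13 EB2 seizure-free, all EB3 improvement-only;
# PIQ: the arrangement consistent with the published per-category
# percentages and marginals after imputation.
STUDY_PLANTED_CONTINGENCIES: dict[str, dict[str, tuple[int, int]]] = {
    "Side": {"Left": (5, 5), "Right": (9, 0)},
    "P.Style": {"EB1": (3, 0), "EB2": (11, 2), "EB3": (0, 3)},
    "PIQ": {
        "Low": (0, 1),
        "Normal-Low": (0, 1),
        "Normal": (10, 3),
        "Normal-High": (3, 0),
        "High": (1, 0),
    },
}

# Observed marginal category counts over the 19 analysis patients
# (missing cells excluded).
STUDY_MARGINALS: dict[str, dict[str, int]] = {
    "Gender": {"Male": 10, "Female": 9},
    "Side": {"Left": 10, "Right": 9},
    "SurgeryAge": {"17-32": 10, "33-54": 9},
    "OnsetAge": {"0-1": 4, "2-10": 7, "11-20": 8},
    "ElapsedTime": {"7-13": 3, "14-19": 4, "20-39": 12},
    "SeizureType": {"Generalized": 8, "Partial Complex": 7, "Both": 4},
    "SeizureFreq": {
        "Daily": 2,
        "Weekly": 8,
        "2-Weekly": 2,
        "3-Weekly": 3,
        "4-Weekly": 3,
        "Other": 1,
    },
    "Febrile": {"Negative": 10, "Positive": 9},
    "VIQ": {"Low": 1, "Normal-Low": 4, "Normal": 8, "Normal-High": 3, "High": 1},
    "PIQ": {"Low": 1, "Normal-Low": 1, "Normal": 11, "Normal-High": 3, "High": 1},
    "FSIQ": {"Low": 0, "Normal-Low": 4, "Normal": 9, "Normal-High": 3, "High": 1},
    "MlogI": {"Low": 2, "Normal-Low": 5, "Normal": 11, "Normal-High": 0, "High": 0},
    "MlogII": {"Low": 2, "Normal-Low": 3, "Normal": 13, "Normal-High": 0, "High": 0},
    "MvisI": {"Low": 0, "Normal-Low": 2, "Normal": 13, "Normal-High": 1, "High": 2},
    "MvisII": {"Low": 0, "Normal-Low": 6, "Normal": 9, "Normal-High": 1, "High": 2},
    "Sczi": {"Negative": 9, "Positive": 3},
    "Cdi": {"Negative": 5, "Positive": 7},
    "Depi": {"Negative": 4, "Positive": 8},
    "P.Style": {"EB1": 3, "EB2": 6, "EB3": 3},
}

# Missing cells per feature out of 19 analysis patients.
_STUDY_MISSING_COUNTS = {
    "VIQ": 2,
    "PIQ": 2,
    "FSIQ": 2,
    "MlogI": 1,
    "MlogII": 1,
    "MvisI": 1,
    "MvisII": 1,
    "Sczi": 7,
    "Cdi": 7,
    "Depi": 7,
    "P.Style": 7,
}
STUDY_MISSING_RATES: dict[str, float] = {
    f: c / 19.0 for f, c in _STUDY_MISSING_COUNTS.items()
}

STUDY_CLASS_PRIOR = 14.0 / 19.0

_DEFAULT_MISSING_TOKEN = "NA"


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    ``planted`` maps a feature name to per-class category distributions
    (``{outcome: {category: prob}}``); ``noise`` maps a feature name to a
    single class-independent category distribution.  ``missing_rates`` give
    per-feature MCAR knock-out probabilities (default 0).
    """

    n: int
    class_prior: float = STUDY_CLASS_PRIOR
    planted: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    noise: dict[str, dict[str, float]] = field(default_factory=dict)
    missing_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.class_prior <= 1:
            raise ValueError("class_prior must be in [0, 1]")
        for feat, table in self.planted.items():
            for cls in (SEIZURE_FREE, IMPROVEMENT_ONLY):
                if cls not in table:
                    raise ValueError(f"planted feature {feat!r} lacks class {cls!r}")
                probs = np.array(list(table[cls].values()), dtype=float)
                if probs.min() < 0 or abs(probs.sum() - 1) > 1e-9:
                    raise ValueError(f"planted {feat!r}/{cls!r}: invalid distribution")
        for feat, dist in self.noise.items():
            probs = np.array(list(dist.values()), dtype=float)
            if probs.min() < 0 or abs(probs.sum() - 1) > 1e-9:
                raise ValueError(f"noise {feat!r}: invalid distribution")
        for feat, rate in self.missing_rates.items():
            if not 0 <= rate < 1:
                raise ValueError(f"missing rate for {feat!r} must be in [0, 1)")

    @property
    def feature_names(self) -> list[str]:
        return list(self.planted) + list(self.noise)

    def schema(self) -> list[FeatureSchema]:
        out = []
        for feat, table in self.planted.items():
            cats = tuple(table[SEIZURE_FREE])
            out.append(FeatureSchema(name=feat, categories=cats))
        for feat, dist in self.noise.items():
            out.append(FeatureSchema(name=feat, categories=tuple(dist)))
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n": self.n,
            "class_prior": self.class_prior,
            "planted": self.planted,
            "noise": self.noise,
            "missing_rates": self.missing_rates,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        payload = json.loads(Path(path).read_text())
        return cls(
            n=payload["n"],
            class_prior=payload["class_prior"],
            planted={
                f: {c: dict(d) for c, d in t.items()}
                for f, t in payload.get("planted", {}).items()
            },
            noise={f: dict(d) for f, d in payload.get("noise", {}).items()},
            missing_rates=dict(payload.get("missing_rates", {})),
            seed=int(payload.get("seed", 0)),
        )


def _normalize_counts(counts: Mapping[str, int]) -> dict[str, float]:
    total = float(sum(counts.values()))
    if total == 0:
        raise ValueError("all-zero marginal")
    return {c: v / total for c, v in counts.items()}


def study_like_config(
    n: int = 19,
    seed: int = 0,
    *,
    missing: bool = True,
) -> SyntheticConfig:
    """The default study-emulating configuration.

    14:5 class prior; Side, P.Style and PIQ planted from the class-stratified
    contingencies of the analysis cohort; the 16 remaining features drawn
    class-independently from the observed marginal counts; per-feature MCAR
    missingness at the study's rates (disable with ``missing=False``).
    """
    planted = {}
    for feat, rows in STUDY_PLANTED_CONTINGENCIES.items():
        n_sf = sum(v[0] for v in rows.values())
        n_im = sum(v[1] for v in rows.values())
        planted[feat] = {
            SEIZURE_FREE: {c: v[0] / n_sf for c, v in rows.items()},
            IMPROVEMENT_ONLY: {c: v[1] / n_im for c, v in rows.items()},
        }
    noise = {
        feat: _normalize_counts(counts)
        for feat, counts in STUDY_MARGINALS.items()
        if feat not in planted
    }
    rates = dict(STUDY_MISSING_RATES) if missing else {}
    return SyntheticConfig(
        n=n, class_prior=STUDY_CLASS_PRIOR, planted=planted, noise=noise,
        missing_rates=rates, seed=seed,
    )


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Draw one cohort from a :class:`SyntheticConfig` (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    y = rng.random(n) < config.class_prior
    outcome = [SEIZURE_FREE if v else IMPROVEMENT_ONLY for v in y]
    features: dict[str, list[str | None]] = {}
    schema = {s.name: s for s in config.schema()}
    for feat, table in config.planted.items():
        cats = list(table[SEIZURE_FREE])
        p_sf = np.array([table[SEIZURE_FREE][c] for c in cats])
        p_im = np.array([table[IMPROVEMENT_ONLY].get(c, 0.0) for c in cats])
        draws_sf = rng.choice(len(cats), size=n, p=p_sf)
        draws_im = rng.choice(len(cats), size=n, p=p_im)
        col = np.where(y, draws_sf, draws_im)
        features[feat] = [cats[i] for i in col]
    for feat, dist in config.noise.items():
        cats = list(dist)
        p = np.array([dist[c] for c in cats])
        col = rng.choice(len(cats), size=n, p=p)
        features[feat] = [cats[i] for i in col]
    # MCAR knock-outs, independent of outcome
    for feat, rate in config.missing_rates.items():
        if feat not in features or rate == 0:
            continue
        mask = rng.random(n) < rate
        features[feat] = [
            None if m else v for v, m in zip(features[feat], mask)
        ]
    ids = [f"S{i + 1}" for i in range(n)]
    return CohortTable(patient_ids=ids, features=features, outcome=outcome, schema=schema)


def separable_mixture_cohort(
    n: int = 300,
    seed: int = 0,
    *,
    n_features: int = 4,
    n_categories: int = 3,
    dominance: float = 0.95,
    mix_weight: float = 0.5,
) -> tuple[CohortTable, dict[int, dict[str, np.ndarray]], np.ndarray]:
    """Two-component categorical mixture with well-separated profiles.

    Each component concentrates ``dominance`` probability mass on one
    category per feature, the two components favouring different categories
    everywhere, so component recovery is essentially unambiguous and
    estimation error reflects multinomial sampling noise only.  Returns the
    cohort (outcome column is a constant placeholder — this generator feeds
    the unsupervised clustering stage), the true per-component category
    tables, and the latent component of every case.
    """
    if not 0.5 < dominance < 1:
        raise ValueError("dominance must be in (0.5, 1)")
    rng = np.random.default_rng(seed)
    cats = [chr(ord("A") + c) for c in range(n_categories)]
    rest = (1.0 - dominance) / (n_categories - 1)
    theta_true: dict[int, dict[str, np.ndarray]] = {0: {}, 1: {}}
    for j in range(n_features):
        for k in (0, 1):
            p = np.full(n_categories, rest)
            p[(j + k) % n_categories] = dominance
            theta_true[k][f"f{j}"] = p
    z = (rng.random(n) >= mix_weight).astype(int)
    features: dict[str, list[str | None]] = {}
    for j in range(n_features):
        name = f"f{j}"
        probs = np.array([theta_true[0][name], theta_true[1][name]])
        draws = np.array(
            [rng.choice(n_categories, p=probs[zi]) for zi in z]
        )
        features[name] = [cats[d] for d in draws]
    schema = {
        f"f{j}": FeatureSchema(name=f"f{j}", categories=tuple(cats))
        for j in range(n_features)
    }
    cohort = CohortTable(
        patient_ids=[f"c{i + 1}" for i in range(n)],
        features=features,
        outcome=[SEIZURE_FREE] * n,
        schema=schema,
    )
    return cohort, theta_true, z


@dataclass
class RecoveryReport:
    """Outcome of repeated end-to-end selection runs on synthetic cohorts."""

    replicates: int
    planted_outrank_fraction: float
    best_within_planted_plus_one_fraction: float
    best_subsets: list[tuple[str, ...]]
    rankings: list[dict[str, int]]


def recovery_harness(
    config: SyntheticConfig,
    spec: ClassifierSpec,
    B: int = 100,
    replicates: int = 20,
    *,
    race_config: RaceConfig | None = None,
) -> RecoveryReport:
    """Run the full selection pipeline repeatedly and score signal recovery.

    Per replicate: generate a cohort (seed derived from ``config.seed`` and
    the replicate index), impute if it carries missingness, rank features by
    bootstrap selection frequency, and evaluate the incremental curve.
    Reports the fraction of replicates in which every planted feature's
    count strictly exceeds every noise feature's count, and the fraction in
    which the best incremental subset is contained in the planted set plus
    at most one noise feature.
    """
    if not config.planted or not config.noise:
        raise ValueError("recovery harness needs >= 1 planted and >= 1 noise feature")
    outrank = 0
    contained = 0
    best_subsets: list[tuple[str, ...]] = []
    rankings: list[dict[str, int]] = []
    for rep in range(replicates):
        rep_cfg = SyntheticConfig(
            n=config.n,
            class_prior=config.class_prior,
            planted=config.planted,
            noise=config.noise,
            missing_rates=config.missing_rates,
            seed=int(np.random.default_rng([config.seed, rep]).integers(2**31 - 1)),
        )
        cohort = generate_cohort(rep_cfg)
        if cohort.n_missing():
            cohort = impute_class_conditional_mode(cohort)
        ranking = bootstrap_selection_frequencies(
            cohort, spec, B=B, seed=rep_cfg.seed, config=race_config
        )
        curve = incremental_subset_evaluation(ranking, cohort, spec)
        planted = set(config.planted)
        noise = set(config.noise)
        min_planted = min(ranking.counts[f] for f in planted)
        max_noise = max(ranking.counts[f] for f in noise)
        if min_planted > max_noise:
            outrank += 1
        extra = set(curve.best) - planted
        if len(extra) <= 1:
            contained += 1
        best_subsets.append(curve.best)
        rankings.append(dict(ranking.counts))
    return RecoveryReport(
        replicates=replicates,
        planted_outrank_fraction=outrank / replicates,
        best_within_planted_plus_one_fraction=contained / replicates,
        best_subsets=best_subsets,
        rankings=rankings,
    )
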