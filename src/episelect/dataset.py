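"""Categorical cohort data model for epilepsy-surgery outcome analysis.

A cohort is a table of patients described by categorical clinical and
neuropsychological features, together with a binary surgical outcome derived
from the Engel scale (grade I = ``seizure_free``; grades II/III =
``improvement_only``).  This module holds the schema and table types, CSV/JSON
I/O, the Engel grouping rule, discretization of raw clinical measurements into
the study's ordinal bins, and class-conditional mode imputation of missing
values.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEIZURE_FREE",
    "IMPROVEMENT_ONLY",
    "OUTCOMES",
    "FeatureSchema",
    "CohortTable",
    "EncodedCohort",
    "SchemaViolation",
    "engel_to_binary",
    "discretize_clinical",
    "impute_class_conditional_mode",
    "load_schema",
    "load_cohort",
    "write_cohort",
    "load_table1",
    "table1_summary",
    "table1_to_cohort",
    "load_table2_schema",
    "load_table5_responsibilities",
    "cohort_from_contingencies",
]

SEIZURE_FREE = "seizure_free"
IMPROVEMENT_ONLY = "improvement_only"
OUTCOMES = (SEIZURE_FREE, IMPROVEMENT_ONLY)

_DATA = resources.files(__package__) / "data"


class SchemaViolation(ValueError):
    """A cohort value is inconsistent with its feature schema."""


@dataclass(frozen=True)
class FeatureSchema:
    """Vocabulary of one categorical feature.

    Parameters
    ----------
    name :
        Feature name as it appears in cohort CSV headers.
    categories :
        Ordered category labels.  For ordinal features the order is the
        ordinal rank order (e.g. ``Low < Normal-Low < Normal < Normal-High <
        High``); for nominal features it is the canonical listing order, which
        still fixes deterministic tie-breaks and rank codings.
    ordinal :
        Whether the category order carries scale meaning.
    missing_token :
        Token representing a missing value in CSV files.
    """

    name: str
    categories: tuple[str, ...]
    ordinal: bool = False
    missing_token: str = "NA"

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError(f"{self.name}: categories must be non-empty")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"{self.name}: duplicate categories")
        if self.missing_token in self.categories:
            raise ValueError(f"{self.name}: missing token collides with a category")
        object.__setattr__(self, "categories", tuple(self.categories))

    def index(self, value: str) -> int:
        return self.categories.index(value)


@dataclass
class EncodedCohort:
    """Integer-coded view of a cohort for numeric routines.

    ``X[i, j]`` is the index of patient *i*'s category for feature *j* in the
    schema order (``-1`` for missing); ``y[i]`` is 1 for ``seizure_free``.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    n_categories: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class CohortTable:
    """Rows = patients, columns = categorical features, plus a binary outcome.

    Missing cells are ``None``.  The outcome column is always complete.
    """

    patient_ids: list[str]
    features: dict[str, list[str | None]]
    outcome: list[str]
    schema: dict[str, FeatureSchema]

    def __post_init__(self) -> None:
        n = len(self.patient_ids)
        if len(set(self.patient_ids)) != n:
            dup = sorted({p for p in self.patient_ids if self.patient_ids.count(p) > 1})
            raise SchemaViolation(f"duplicate patient ids: {dup}")
        if len(self.outcome) != n:
            raise SchemaViolation("outcome length differs from patient count")
        for o in self.outcome:
            if o not in OUTCOMES:
                raise SchemaViolation(f"unknown outcome label {o!r}")
        for name, column in self.features.items():
            if name not in self.schema:
                raise SchemaViolation(f"feature {name!r} has no schema entry")
            if len(column) != n:
                raise SchemaViolation(f"column {name!r} has length {len(column)} != {n}")
            cats = set(self.schema[name].categories)
            for i, v in enumerate(column):
                if v is not None and v not in cats:
                    raise SchemaViolation(
                        f"row {self.patient_ids[i]!r}, column {name!r}: "
                        f"unknown category {v!r}"
                    )

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features)

    def n_missing(self, feature: str | None = None) -> int:
        cols = [feature] if feature else self.feature_names
        return sum(sum(v is None for v in self.features[c]) for c in cols)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"patient_id": self.patient_ids})
        for name, column in self.features.items():
            df[name] = column
        df["outcome"] = self.outcome
        return df

    def encode(self, features: Sequence[str] | None = None) -> EncodedCohort:
        names = list(features) if features is not None else self.feature_names
        unknown = [f for f in names if f not in self.features]
        if unknown:
            raise KeyError(f"features not in cohort: {unknown}")
        n = self.n
        X = np.empty((n, len(names)), dtype=np.int64)
        n_cat = np.empty(len(names), dtype=np.int64)
        for j, name in enumerate(names):
            sch = self.schema[name]
            lut = {c: i for i, c in enumerate(sch.categories)}
            col = self.features[name]
            X[:, j] = [(-1 if v is None else lut[v]) for v in col]
            n_cat[j] = len(sch.categories)
        y = np.fromiter((1 if o == SEIZURE_FREE else 0 for o in self.outcome), int, n)
        return EncodedCohort(X=X, y=y, feature_names=names, n_categories=n_cat)

    def subset(self, rows: Sequence[int]) -> "CohortTable":
        """Row subset / resample; duplicated rows get suffixed ids."""
        ids: list[str] = []
        seen: dict[str, int] = {}
        for i in rows:
            pid = self.patient_ids[i]
            k = seen.get(pid, 0)
            seen[pid] = k + 1
            ids.append(pid if k == 0 else f"{pid}#{k}")
        return CohortTable(
            patient_ids=ids,
            features={f: [col[i] for i in rows] for f, col in self.features.items()},
            outcome=[self.outcome[i] for i in rows],
            schema=self.schema,
        )


# ---------------------------------------------------------------------------
# Engel grouping
# ---------------------------------------------------------------------------

_ENGEL_MAP = {"I": SEIZURE_FREE, "II": IMPROVEMENT_ONLY, "III": IMPROVEMENT_ONLY}


def engel_to_binary(grade: str) -> str:
    """Collapse an Engel grade to the binary outcome.

    Grade I (seizure-free) maps to ``seizure_free``; grades II (rare
    seizures) and III (worthwhile improvement) both indicate improvement
    without complete recovery and map to ``improvement_only``.  Grade IV does
    not occur in this cohort and is rejected.
    """
    grade = grade.strip()
    if grade not in _ENGEL_MAP:
        raise ValueError(f"unsupported Engel grade {grade!r} (expected I, II or III)")
    return _ENGEL_MAP[grade]


# ---------------------------------------------------------------------------
# Clinical discretization
# ---------------------------------------------------------------------------

# (label, lower edge) per bin, in increasing order.  A value belongs to the
# last bin whose lower edge it reaches; the final bin is open above.  Values
# below the first bin's lower edge are out of range.
SURGERY_AGE_BINS = [("17-32", 17), ("33-54", 33)]
ONSET_AGE_BINS = [("0-1", 0), ("2-10", 2), ("11-20", 11)]
ELAPSED_TIME_BINS = [("7-13", 7), ("14-19", 14), ("20-39", 20)]

SEIZURE_TYPE_MAP = {
    "gen": "Generalized",
    "PC": "Partial Complex",
    "PC, gen": "Both",
}

# Free-text seizure-frequency entries mapped onto the study vocabulary.
# "3-5 weekly" is taken at its lower printed figure; irregular or range
# entries without a single weekly figure fall into "Other".
SEIZURE_FREQ_MAP = {
    "daily": "Daily",
    "weekly": "Weekly",
    "2 weekly": "2-Weekly",
    "3 weekly": "3-Weekly",
    "4 weekly": "4-Weekly",
    "3-5 weekly": "3-Weekly",
    "0-3 weekly": "Other",
    "Not regular": "Other",
}

_SEX_MAP = {"m": "Male", "f": "Female"}
_SIDE_MAP = {"L": "Left", "R": "Right"}


def _bin_value(value: float, bins: list[tuple[str, float]], what: str) -> str:
    # bin boundaries sit at the lower printed edge of each bin after the
    # first; the first bin is open below and the last open above, so every
    # non-negative measurement lands in a bin (fractional onset ages below
    # the 0-1/2-10 boundary, a 4-year duration below the printed 7-13 bin,
    # a 40-year duration above the printed 20-39 bin)
    if value < 0:
        raise ValueError(f"{what} {value} is negative; outside every bin")
    label = bins[0][0]
    for lab, lower in bins:
        if value >= lower:
            label = lab
    return label


def discretize_clinical(record: Mapping[str, object]) -> dict[str, str]:
    """Map one raw clinical record onto the study's categorical vocabulary.

    Expects keys ``age``, ``onset_age``, ``duration`` (numeric) and ``sex``,
    ``side``, ``seizure_type``, ``seizure_freq`` (raw strings as charted).
    Age-like values are binned with bin boundaries at the lower printed edge
    of each subsequent bin, the first bin open below and the last open
    above, so fractional onset ages (0.7 or 1.8 years) fall into "0-1", a
    4-year duration into "7-13", and a 40-year duration into "20-39".
    Negative values raise instead of clamping.
    """
    out = {
        "Gender": _SEX_MAP[str(record["sex"])],
        "Side": _SIDE_MAP[str(record["side"])],
        "SurgeryAge": _bin_value(float(record["age"]), SURGERY_AGE_BINS, "surgery age"),
        "OnsetAge": _bin_value(float(record["onset_age"]), ONSET_AGE_BINS, "onset age"),
        "ElapsedTime": _bin_value(
            float(record["duration"]), ELAPSED_TIME_BINS, "elapsed time"
        ),
        "SeizureType": SEIZURE_TYPE_MAP[str(record["seizure_type"])],
        "SeizureFreq": SEIZURE_FREQ_MAP[str(record["seizure_freq"])],
    }
    return out


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def _mode(values: Iterable[str], schema: FeatureSchema) -> str | None:
    counts: dict[str, int] = {}
    for v in values:
        if v is not None:
            counts[v] = counts.get(v, 0) + 1
    if not counts:
        return None
    best = max(counts.values())
    # ties break by schema category order: first listed wins
    for c in schema.categories:
        if counts.get(c) == best:
            return c
    raise AssertionError("unreachable")


def impute_class_conditional_mode(cohort: CohortTable) -> CohortTable:
    """Fill missing cells with the per-outcome mode of each feature.

    Each missing cell receives the most frequent observed category among
    patients with the same outcome; within-class ties break by schema
    category order.  A feature with no observed value in one class falls back
    to the overall mode (with a warning).  Observed cells, ids and outcomes
    are never altered, so the operation is idempotent.
    """
    new_features: dict[str, list[str | None]] = {}
    for name, column in cohort.features.items():
        sch = cohort.schema[name]
        if not any(v is None for v in column):
            new_features[name] = list(column)
            continue
        class_modes: dict[str, str | None] = {}
        for cls in OUTCOMES:
            vals = [v for v, o in zip(column, cohort.outcome) if o == cls]
            class_modes[cls] = _mode(vals, sch)
        overall = _mode(column, sch)
        if overall is None:
            raise SchemaViolation(f"feature {name!r} has no observed value at all")
        filled: list[str | None] = []
        for v, o in zip(column, cohort.outcome):
            if v is not None:
                filled.append(v)
                continue
            m = class_modes[o]
            if m is None:
                warnings.warn(
                    f"feature {name!r}: no observed value in class {o!r}; "
                    "falling back to overall mode",
                    stacklevel=2,
                )
                m = overall
            filled.append(m)
        new_features[name] = filled
    return replace(cohort, features=new_features)


# ---------------------------------------------------------------------------
# Schema / cohort I/O
# ---------------------------------------------------------------------------


def load_schema(source: str | Path | io.TextIOBase) -> list[FeatureSchema]:
    """Read a feature-schema list from JSON.

    The JSON is a list of objects with keys ``name``, ``categories`` and
    optionally ``ordinal`` and ``missing_token``.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            raw = json.load(fh)
    else:
        raw = json.load(source)
    return [
        FeatureSchema(
            name=entry["name"],
            categories=tuple(entry["categories"]),
            ordinal=bool(entry.get("ordinal", False)),
            missing_token=entry.get("missing_token", "NA"),
        )
        for entry in raw
    ]


def load_cohort(
    source: str | Path | io.TextIOBase,
    schema: Sequence[FeatureSchema],
    *,
    id_column: str = "patient_id",
    outcome_column: str = "outcome",
) -> CohortTable:
    """Read a cohort CSV (header row; one column per schema feature).

    Missing tokens are preserved as missing; any other label outside a
    feature's vocabulary raises :class:`SchemaViolation` naming the row and
    column.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
            header = _csv_header(source)
    else:
        text = source.read()
        rows = list(csv.DictReader(io.StringIO(text)))
        header = next(csv.reader(io.StringIO(text)))
    for col in (id_column, outcome_column):
        if col not in header:
            raise SchemaViolation(f"cohort CSV lacks required column {col!r}")
    schema_map = {s.name: s for s in schema}
    missing_cols = [s.name for s in schema if s.name not in header]
    if missing_cols:
        raise SchemaViolation(f"cohort CSV lacks feature columns {missing_cols}")

    patient_ids = [r[id_column] for r in rows]
    outcome = [r[outcome_column] for r in rows]
    features: dict[str, list[str | None]] = {}
    for s in schema:
        col: list[str | None] = []
        for r in rows:
            v = r[s.name]
            col.append(None if v == s.missing_token else v)
        features[s.name] = col
    return CohortTable(
        patient_ids=patient_ids, features=features, outcome=outcome, schema=schema_map
    )


def _csv_header(path: str | Path) -> list[str]:
    with open(path, newline="", encoding="utf-8") as fh:
        return next(csv.reader(fh))


def write_cohort(cohort: CohortTable, dest: str | Path | io.TextIOBase) -> None:
    """Write a cohort in the canonical CSV dialect (RFC 4180, LF endings)."""

    def _write(fh) -> None:
        w = csv.writer(fh, lineterminator="\n")
        names = cohort.feature_names
        w.writerow(["patient_id", *names, "outcome"])
        for i, pid in enumerate(cohort.patient_ids):
            row = [pid]
            for name in names:
                v = cohort.features[name][i]
                row.append(cohort.schema[name].missing_token if v is None else v)
            row.append(cohort.outcome[i])
            w.writerow(row)

    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            _write(fh)
    else:
        _write(dest)


# ---------------------------------------------------------------------------
# Packaged study fixtures
# ---------------------------------------------------------------------------


def load_table1() -> pd.DataFrame:
    """The packaged 23-patient clinical table (raw, pre-discretization).

    Columns: patient_id, age, sex, side, onset_age, duration, seizure_type,
    seizure_freq, engel, followup_years, behavioral_testing.  Which four
    patients lacked behavioral testing is not recorded in the source data,
    so ``behavioral_testing`` ships entirely missing ("NA"); analysis
    subsets are user-supplied or synthetic.
    """
    with (_DATA / "table1_clinical.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, keep_default_na=False, na_values=["NA"])


def table1_summary(df: pd.DataFrame | None = None) -> dict[str, float]:
    """Cohort summary statistics: mean surgery age, onset age and duration."""
    if df is None:
        df = load_table1()
    return {
        "n": int(len(df)),
        "n_male": int((df["sex"] == "m").sum()),
        "engel_counts": df["engel"].value_counts().to_dict(),
        "mean_surgery_age": float(df["age"].mean()),
        "mean_onset_age": float(df["onset_age"].mean()),
        "mean_duration": float(df["duration"].mean()),
    }


def load_table2_schema() -> list[FeatureSchema]:
    """The packaged 19-feature schema (clinical + neuropsychological)."""
    with (_DATA / "table2_schema.json").open("r", encoding="utf-8") as fh:
        return load_schema(fh)


def table1_to_cohort(df: pd.DataFrame | None = None) -> CohortTable:
    """Discretize the packaged clinical table into a clinical-only cohort.

    Neuropsychological features are not part of the published record, so the
    resulting cohort carries the 8 clinical features only (Febrile status is
    likewise unpublished per patient and is omitted).
    """
    if df is None:
        df = load_table1()
    schema = {
        s.name: s
        for s in load_table2_schema()
        if s.name
        in {"Gender", "Side", "SurgeryAge", "OnsetAge", "ElapsedTime", "SeizureType", "SeizureFreq"}
    }
    features: dict[str, list[str | None]] = {name: [] for name in schema}
    outcome: list[str] = []
    for _, row in df.iterrows():
        rec = discretize_clinical(row)
        for name in schema:
            features[name].append(rec[name])
        outcome.append(engel_to_binary(row["engel"]))
    return CohortTable(
        patient_ids=list(df["patient_id"]),
        features=features,
        outcome=outcome,
        schema=schema,
    )


def load_table5_responsibilities() -> pd.DataFrame:
    """The 15 published post-surgery cluster membership probabilities.

    Columns: case, p_c0, p_c1, outcome.
    """
    with (_DATA / "table5_responsibilities.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def cohort_from_contingencies(
    contingencies: Mapping[str, Mapping[str, tuple[int, int]]],
    schema: Sequence[FeatureSchema],
    *,
    id_prefix: str = "P",
) -> CohortTable:
    """Build a cohort realizing per-feature class-stratified category counts.

    ``contingencies[feature][category] = (n_seizure_free, n_improvement_only)``.
    Class totals must agree across features.  The joint arrangement of
    categories across features within a class is arbitrary (category order),
    which leaves all per-feature marginal statistics — contingency tables and
    two-sample rank tests grouped by outcome — exactly determined.
    """
    schema_map = {s.name: s for s in schema}
    totals = None
    for feat, rows in contingencies.items():
        t = (
            sum(v[0] for v in rows.values()),
            sum(v[1] for v in rows.values()),
        )
        if totals is None:
            totals = t
        elif t != totals:
            raise ValueError(
                f"class totals differ between features: {feat} gives {t}, expected {totals}"
            )
    if totals is None:
        raise ValueError("no contingencies given")
    n_sf, n_imp = totals
    outcome = [SEIZURE_FREE] * n_sf + [IMPROVEMENT_ONLY] * n_imp
    features: dict[str, list[str | None]] = {}
    for feat, rows in contingencies.items():
        sch = schema_map[feat]
        col_sf: list[str] = []
        col_imp: list[str] = []
        for cat in sch.categories:
            if cat in rows:
                a, b = rows[cat]
                col_sf.extend([cat] * a)
                col_imp.extend([cat] * b)
        extra = set(rows) - set(sch.categories)
        if extra:
            raise SchemaViolation(f"{feat}: categories {sorted(extra)} not in schema")
        features[feat] = col_sf + col_imp
    ids = [f"{id_prefix}{i + 1}" for i in range(n_sf + n_imp)]
    used = {f: schema_map[f] for f in contingencies}
    return CohortTable(patient_ids=ids, features=features, outcome=outcome, schema=used)
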