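import pytest

from episelect import (
    IMPROVEMENT_ONLY,
    SEIZURE_FREE,
    CohortTable,
    FeatureSchema,
    cohort_from_contingencies,
    load_table2_schema,
)

# Class-stratified contingencies of the three discriminative features in the
# 19-patient analysis cohort, reconstructed from the published per-category
# outcome percentages and the post-imputation marginals.
RESULTS_CONTINGENCIES = {
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


@pytest.fixture(scope="session")
def table2_schema():
    return load_table2_schema()


@pytest.fixture(scope="session")
def results_cohort(table2_schema):
    """19-patient cohort realizing the reconstructed stratified contingencies."""
    return cohort_from_contingencies(RESULTS_CONTINGENCIES, table2_schema)


def make_cohort(columns, outcome, schema=None, ids=None):
    """Small-cohort helper: columns = {name: list of labels (None = missing)}."""
    if schema is None:
        schema = {}
        for name, col in columns.items():
            cats = []
            for v in col:
                if v is not None and v not in cats:
                    cats.append(v)
            schema[name] = FeatureSchema(name=name, categories=tuple(sorted(cats)))
    n = len(outcome)
    if ids is None:
        ids = [f"p{i + 1}" for i in range(n)]
    return CohortTable(
        patient_ids=ids, features=dict(columns), outcome=list(outcome), schema=schema
    )


def random_cohort(rng, n=12, p=3, n_cats=3, missing_rate=0.0):
    """Random categorical cohort with both outcome classes guaranteed."""
    cats = tuple(chr(ord("A") + i) for i in range(n_cats))
    columns = {}
    schema = {}
    for j in range(p):
        name = f"f{j}"
        col = [cats[rng.integers(n_cats)] for _ in range(n)]
        if missing_rate:
            col = [None if rng.random() < missing_rate else v for v in col]
        columns[name] = col
        schema[name] = FeatureSchema(name=name, categories=cats)
    outcome = [SEIZURE_FREE if rng.random() < 0.6 else IMPROVEMENT_ONLY for _ in range(n)]
    outcome[0] = SEIZURE_FREE
    outcome[1] = IMPROVEMENT_ONLY
    return make_cohort(columns, outcome, schema=schema)
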