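import numpy as np
import pandas as pd
import pytest

from cohortshuffle import (
    CohortSchema,
    CohortTable,
    preprocess_pipeline,
    synthetic_hf_cohort,
)


@pytest.fixture(scope="session")
def tiny_schema() -> CohortSchema:
    """Three binary columns (one endpoint), two numerics."""
    return CohortSchema(
        binary_features=("ep", "b1", "b2"),
        numeric_features=("x", "y"),
        endpoint_features=("ep",),
    )


def make_table(schema: CohortSchema, rows: list[dict]) -> CohortTable:
    """Build a CohortTable from row dicts (None = missing cell)."""
    df = pd.DataFrame(rows, columns=list(schema.columns))
    for col in schema.numeric_features:
        df[col] = df[col].astype(float)
    return CohortTable(schema, df)


@pytest.fixture(scope="session")
def two_class_table(tiny_schema) -> CohortTable:
    """Four complete patients in two classes of two."""
    return make_table(
        tiny_schema,
        [
            {"ep": 0, "b1": 0, "b2": 1, "x": 1.0, "y": 10.0},
            {"ep": 0, "b1": 0, "b2": 1, "x": 2.0, "y": 20.0},
            {"ep": 1, "b1": 1, "b2": 0, "x": 3.0, "y": 30.0},
            {"ep": 1, "b1": 1, "b2": 0, "x": 4.0, "y": 40.0},
        ],
    )


@pytest.fixture(scope="session")
def hf_cohort():
    """The synthetic heart-failure surrogate cohort (711 rows)."""
    return synthetic_hf_cohort(seed=1)


@pytest.fixture(scope="session")
def hf_strat(hf_cohort):
    """Preprocessed surrogate: 385 patients in 61 classes."""
    strat, _ = preprocess_pipeline(hf_cohort)
    return strat


def random_small_cohort(rng: np.random.Generator, n_classes=4, p=3) -> CohortTable:
    """A small complete cohort with random strata for property tests."""
    from cohortshuffle import SyntheticSpec, generate_cohort

    sizes = tuple(int(s) for s in rng.integers(2, 7, size=n_classes))
    spec = SyntheticSpec(
        n_binary=4,
        n_numeric=p,
        n_classes=n_classes,
        class_sizes=sizes,
        endpoint_count=1,
        seed=int(rng.integers(2**31)),
    )
    return generate_cohort(spec)
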