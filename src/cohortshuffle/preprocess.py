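"""Sequential exclusion filters and binary-pattern stratification.

Preprocessing follows three sequential exclusion criteria: drop patients
with any missing endpoint, drop patients with any other missing value,
then group the complete rows into classes by their full binary pattern
and drop the "monoexample" classes (a lone patient cannot take part in
an intraclass shuffle).  The filters only remove rows — surviving cell
values are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortTable, RunReport

__all__ = [
    "StratifiedCohort",
    "filter_missing_endpoints",
    "filter_missing_features",
    "assign_classes",
    "drop_monoexample_classes",
    "preprocess_pipeline",
]


@dataclass
class StratifiedCohort:
    """A complete cohort with a class label per patient.

    The class key is the ordered tuple of a patient's binary feature
    values in the schema's declared column order.  Rows are sorted by
    class key, so each class occupies a contiguous block; classes are
    indexed 0..G-1 in sorted-key order.
    """

    table: CohortTable
    class_index: np.ndarray  # int label per row, classes contiguous
    class_keys: list[tuple[int, ...]]  # G keys in sorted order
    class_sizes: np.ndarray  # G positive ints

    @property
    def n_classes(self) -> int:
        return len(self.class_keys)

    @property
    def n_rows(self) -> int:
        return len(self.table)

    def class_slices(self) -> list[slice]:
        """Row slice of each class block, in class-index order."""
        bounds = np.concatenate([[0], np.cumsum(self.class_sizes)])
        return [slice(int(bounds[g]), int(bounds[g + 1])) for g in range(self.n_classes)]

    def __post_init__(self) -> None:
        if self.class_sizes.sum() != len(self.table):
            raise ValueError("class sizes do not sum to the row count")


def filter_missing_endpoints(table: CohortTable) -> tuple[CohortTable, int]:
    """Remove patients lacking any endpoint value (first filter)."""
    endpoints = list(table.schema.endpoint_features)
    if not endpoints:
        raise ValueError("schema declares no endpoint features")
    keep = ~table.df[endpoints].isna().any(axis=1)
    kept = table.take(np.flatnonzero(keep.to_numpy()))
    return kept, int((~keep).sum())


def filter_missing_features(table: CohortTable) -> tuple[CohortTable, int]:
    """Remove patients with any remaining missing cell (second filter)."""
    cols = list(table.schema.feature_columns)
    keep = ~table.df[cols].isna().any(axis=1)
    kept = table.take(np.flatnonzero(keep.to_numpy()))
    return kept, int((~keep).sum())


def assign_classes(table: CohortTable) -> StratifiedCohort:
    """Group complete rows into classes by their full binary pattern.

    Rows are re-sorted so equal binary patterns are adjacent (ties keep
    input order), which is the grouping a balanced search tree over the
    B-bit keys would traverse; class indices follow sorted-key order.
    """
    if not table.is_complete:
        raise ValueError("assign_classes requires a table with no missing cells")
    if len(table) == 0:
        return StratifiedCohort(table, np.zeros(0, dtype=int), [], np.zeros(0, dtype=int))
    binm = table.binary_matrix().to_numpy(dtype=int)
    order = np.lexsort(binm.T[::-1])  # lexicographic by declared feature order
    sorted_table = table.take(order)
    sorted_bin = binm[order]
    change = np.any(np.diff(sorted_bin, axis=0) != 0, axis=1)
    class_index = np.concatenate([[0], np.cumsum(change)]).astype(int)
    starts = np.flatnonzero(np.concatenate([[True], change]))
    class_keys = [tuple(int(v) for v in sorted_bin[s]) for s in starts]
    class_sizes = np.bincount(class_index)
    return StratifiedCohort(sorted_table, class_index, class_keys, class_sizes)


def drop_monoexample_classes(strat: StratifiedCohort) -> tuple[StratifiedCohort, int]:
    """Remove classes holding a single patient and reindex contiguously."""
    keep_classes = strat.class_sizes >= 2
    keep_rows = keep_classes[strat.class_index]
    removed = int((~keep_rows).sum())
    table = strat.table.take(np.flatnonzero(keep_rows))
    new_index_of = np.cumsum(keep_classes) - 1
    class_index = new_index_of[strat.class_index[keep_rows]]
    class_keys = [k for k, ok in zip(strat.class_keys, keep_classes) if ok]
    class_sizes = strat.class_sizes[keep_classes]
    return StratifiedCohort(table, class_index, class_keys, class_sizes), removed


def preprocess_pipeline(table: CohortTable) -> tuple[StratifiedCohort, RunReport]:
    """Run the full exclusion sequence and stratify.

    Returns the stratified cohort plus a report whose removal counts
    reconcile exactly: ``n_in == n_out + sum(removed)``.
    """
    n_in = len(table)
    t1, r_endpoint = filter_missing_endpoints(table)
    t2, r_feature = filter_missing_features(t1)
    strat = assign_classes(t2)
    strat, r_mono = drop_monoexample_classes(strat)
    report = RunReport(
        stage="preprocess",
        n_in=n_in,
        n_out=strat.n_rows,
        removed={
            "missing_endpoint": r_endpoint,
            "missing_feature": r_feature,
            "monoexample_class": r_mono,
        },
        extra={"n_classes": strat.n_classes,
               "class_sizes": [int(s) for s in strat.class_sizes]},
    )
    return strat, report


def restratify(table: CohortTable) -> StratifiedCohort:
    """Stratify an already-complete table (e.g. an enhanced cohort).

    Identical to :func:`assign_classes`; enhanced tables never contain
    monoexample classes because synthesis copies existing class keys,
    but any that appear (degenerate inputs) are kept as-is.
    """
    return assign_classes(table)
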