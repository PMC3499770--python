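"""Gene filtering, table normalization and mass assignment.

Two preprocessing layers precede the compromise analysis:

1. *Informative-gene filtering* on linear-scale intensities: a gene is kept
   when, in at least one condition, its fold-change relative to the reference
   time point reaches ``fc_threshold`` in at least ``min_fc_timepoints`` time
   points (both induction and repression count), and, in at least one
   condition, its coefficient of variation over the time course reaches
   ``cv_threshold``. With a single array per time point this is the standard
   substitute for a replicate-based differential test.

2. *Table normalization*: each table is column-centered and rescaled to unit
   total sum of squares, so no single condition dominates the congruence
   matrix by scale alone. A column z-scoring variant is available.

An alternative *control normalization* subtracts the control condition's
log2 profile time point by time point from every stress condition, removing
shared diurnal/circadian dynamics before the analysis is repeated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionTable, TableCollection


@dataclass
class GeneFilterStats:
    max_fc_timepoints: int
    max_cv: float
    kept: bool
    reason: str  # pass | fc_fail | cv_fail


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    per_gene: dict[str, GeneFilterStats]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g,
                "max_fc_timepoints": s.max_fc_timepoints,
                "max_cv": s.max_cv,
                "kept": int(s.kept),
                "reason": s.reason,
            }
            for g, s in self.per_gene.items()
        ]
        return pd.DataFrame(rows, columns=["gene_id", "max_fc_timepoints", "max_cv", "kept", "reason"])


@dataclass
class MassVector:
    """Non-negative row weights summing to one; the metric of the analysis."""

    masses: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.ndim != 1 or len(self.masses) == 0:
            raise ValueError("masses must be a non-empty 1-d vector")
        if np.any(self.masses < 0):
            raise ValueError("masses must be non-negative")
        if abs(self.masses.sum() - 1.0) > 1e-12:
            raise ValueError(f"masses must sum to 1, got {self.masses.sum()!r}")

    def __len__(self) -> int:
        return len(self.masses)

    @property
    def diag(self) -> np.ndarray:
        return np.diag(self.masses)


def uniform_masses(n: int) -> MassVector:
    """Uniform masses 1/n over n rows."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return MassVector(np.full(n, 1.0 / n))


def _linear_values(collection: TableCollection) -> list[np.ndarray]:
    if collection.scale == "log2":
        return [np.exp2(t.values) for t in collection.tables]
    return [t.values for t in collection.tables]


def filter_informative_genes(
    collection: TableCollection,
    fc_threshold: float = 2.0,
    min_fc_timepoints: int = 2,
    cv_threshold: float = 1.0,
    cv_scope: str = "per_condition",
) -> tuple[TableCollection, FilterReport]:
    """Keep genes with a reproducible fold-change and high temporal variation.

    Both criteria are evaluated on the linear intensity scale (log2 input is
    exponentiated for filtering only; the returned collection keeps the
    original scale). Fold-change is measured against the reference (first)
    time point in either direction, ``max(x/x0, x0/x)``. The coefficient of
    variation uses the sample standard deviation (ddof=1); with
    ``cv_scope="per_condition"`` the gene passes if any single condition
    reaches the threshold, with ``"pooled"`` the CV is taken over all
    condition/time samples jointly.
    """
    if cv_scope not in ("per_condition", "pooled"):
        raise ValueError("cv_scope must be 'per_condition' or 'pooled'")
    linear = _linear_values(collection)
    genes = collection.gene_ids
    n = len(genes)
    per_gene: dict[str, GeneFilterStats] = {}
    keep: list[str] = []

    for values, table in zip(linear, collection.tables):
        bad = np.where(values[:, 0] <= 0)[0]
        if bad.size:
            raise ValueError(
                f"non-positive reference value for gene {genes[bad[0]]!r} "
                f"in condition {table.condition_id!r}"
            )
        badm = np.where(values.mean(axis=1) <= 0)[0]
        if badm.size:
            raise ValueError(
                f"non-positive mean for gene {genes[badm[0]]!r} "
                f"in condition {table.condition_id!r}"
            )

    # per-condition fold-change counts and CVs, vectorized over genes
    fc_counts = np.zeros((n, collection.K), dtype=int)
    cvs = np.zeros((n, collection.K))
    for k, values in enumerate(linear):
        x0 = values[:, [0]]
        ratio = np.maximum(values[:, 1:] / x0, x0 / values[:, 1:])
        fc_counts[:, k] = (ratio >= fc_threshold).sum(axis=1)
        cvs[:, k] = values.std(axis=1, ddof=1) / values.mean(axis=1)

    fc_pass = (fc_counts >= min_fc_timepoints).any(axis=1)
    if cv_scope == "per_condition":
        cv_stat = cvs.max(axis=1)
    else:
        pooled = np.hstack(linear)
        cv_stat = pooled.std(axis=1, ddof=1) / pooled.mean(axis=1)
    cv_pass = cv_stat >= cv_threshold

    for i, g in enumerate(genes):
        kept = bool(fc_pass[i] and cv_pass[i])
        reason = "pass" if kept else ("fc_fail" if not fc_pass[i] else "cv_fail")
        per_gene[g] = GeneFilterStats(
            max_fc_timepoints=int(fc_counts[i].max()),
            max_cv=float(cv_stat[i]),
            kept=kept,
            reason=reason,
        )
        if kept:
            keep.append(g)

    report = FilterReport(n_input=n, n_kept=len(keep), per_gene=per_gene)
    return collection.subset_genes(keep), report


def center_and_scale_table(
    table: ExpressionTable, method: str = "table_scale"
) -> ExpressionTable:
    """Column-center a table and rescale it to unit total sum of squares.

    ``method="column_zscore"`` additionally divides each column by its sample
    standard deviation before the global rescaling; all-constant columns
    become (and remain) all-zero.
    """
    X = center_and_scale(table.values, method=method)
    return ExpressionTable(
        table.condition_id, table.gene_ids, table.time_points_min, X, table.scale
    )


def center_and_scale(X: np.ndarray, method: str = "table_scale") -> np.ndarray:
    if method not in ("table_scale", "column_zscore"):
        raise ValueError("method must be 'table_scale' or 'column_zscore'")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to center")
    X = X - X.mean(axis=0, keepdims=True)
    if method == "column_zscore":
        sd = X.std(axis=0, ddof=1, keepdims=True)
        nz = sd > 0
        X = np.where(nz, X / np.where(nz, sd, 1.0), 0.0)
    ss = float((X**2).sum())
    if ss <= 1e-300:
        raise ValueError("degenerate table: zero total sum of squares after centering")
    return X / np.sqrt(ss)


def preprocess_collection(
    collection: TableCollection, method: str = "table_scale"
) -> TableCollection:
    """Apply :func:`center_and_scale_table` to every table."""
    return TableCollection(
        tables=[center_and_scale_table(t, method=method) for t in collection.tables],
        control_id=collection.control_id,
    )


def control_normalize(collection: TableCollection) -> TableCollection:
    """Subtract the control condition's log2 profile from every other table.

    For every non-control condition c: x'(g, tau, c) = x(g, tau, c) -
    x(g, tau, control), i.e. the log2 fold-change to the matching control
    time point. The control table itself is passed through unchanged, so
    shared diurnal dynamics are removed from the stress tables while the
    control still documents them.
    """
    if collection.scale != "log2":
        raise ValueError("control normalization requires log2-scale tables")
    control = collection.control
    tables = []
    for t in collection.tables:
        if t.condition_id == collection.control_id:
            tables.append(t)
        else:
            tables.append(
                ExpressionTable(
                    t.condition_id,
                    t.gene_ids,
                    t.time_points_min,
                    t.values - control.values,
                    "log2",
                )
            )
    return TableCollection(tables=tables, control_id=collection.control_id)
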