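"""Readers and writers for expression tables, gene sets and analysis results.

On-disk formats are deliberately plain: one TSV per condition (first column
``gene_id``, remaining headers the time points in minutes), Broad-dialect GMT
for gene sets, TSV for every numeric output and Newick for dendrograms.
Loaders fail fast: missing values, non-numeric cells, duplicated gene ids and
mismatched time grids are rejected with the offending location named, because
the downstream compromise analysis has no missing-data procedure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"

SCALES = ("linear", "log2")


class DataFormatError(ValueError):
    """Raised when an input file violates the expected on-disk format."""


@dataclass
class ExpressionTable:
    """One condition's gene x time-point expression matrix.

    Parameters
    ----------
    condition_id : str
        Short condition label, e.g. ``"21-LL"``.
    gene_ids : list of str
        Ordered, unique row identifiers (treated as opaque, case-sensitive).
    time_points_min : ndarray of shape (t,)
        Strictly increasing sampling times in minutes; index 0 is the
        reference time point.
    values : ndarray of shape (n, t)
        Expression values, linear or log2 scale according to ``scale``.
    scale : {"linear", "log2"}
    """

    condition_id: str
    gene_ids: list[str]
    time_points_min: np.ndarray
    values: np.ndarray
    scale: str = "log2"

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.time_points_min = np.asarray(self.time_points_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise DataFormatError(
                f"duplicate gene_id in table {self.condition_id!r}: {dupes[:5]}"
            )
        if self.time_points_min.ndim != 1 or np.any(np.diff(self.time_points_min) <= 0):
            raise DataFormatError(
                f"time points of table {self.condition_id!r} must be strictly increasing"
            )
        if np.any(self.time_points_min < 0):
            raise DataFormatError(
                f"negative time point in table {self.condition_id!r}"
            )
        n, t = len(self.gene_ids), len(self.time_points_min)
        if self.values.shape != (n, t):
            raise DataFormatError(
                f"table {self.condition_id!r}: values shape {self.values.shape} "
                f"does not match ({n} genes, {t} time points)"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DataFormatError(
                f"non-finite value in table {self.condition_id!r} at gene "
                f"{self.gene_ids[i]!r}, time {self.time_points_min[j]:g} min"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_timepoints(self) -> int:
        return len(self.time_points_min)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=[f"{tp:g}" for tp in self.time_points_min],
        )


@dataclass
class TableCollection:
    """K expression tables sharing one gene list and one time grid."""

    tables: list[ExpressionTable]
    control_id: str

    def __post_init__(self) -> None:
        if len(self.tables) < 1:
            raise ValueError("TableCollection requires at least one table")
        ids = [t.condition_id for t in self.tables]
        if len(set(ids)) != len(ids):
            raise DataFormatError(f"duplicate condition ids: {ids}")
        ref = self.tables[0]
        for t in self.tables[1:]:
            if t.gene_ids != ref.gene_ids:
                raise DataFormatError(
                    f"gene set mismatch between tables {ref.condition_id!r} "
                    f"and {t.condition_id!r}"
                )
            if not np.array_equal(t.time_points_min, ref.time_points_min):
                raise DataFormatError(
                    f"time grid mismatch between tables {ref.condition_id!r} "
                    f"and {t.condition_id!r}"
                )
            if t.scale != ref.scale:
                raise DataFormatError("tables mix linear and log2 scales")
        if self.control_id not in ids:
            raise DataFormatError(
                f"control_id {self.control_id!r} is not among conditions {ids}"
            )

    @property
    def K(self) -> int:
        return len(self.tables)

    @property
    def condition_ids(self) -> list[str]:
        return [t.condition_id for t in self.tables]

    @property
    def gene_ids(self) -> list[str]:
        return self.tables[0].gene_ids

    @property
    def time_points_min(self) -> np.ndarray:
        return self.tables[0].time_points_min

    @property
    def scale(self) -> str:
        return self.tables[0].scale

    @property
    def control(self) -> ExpressionTable:
        return self.tables[self.condition_ids.index(self.control_id)]

    def arrays(self) -> list[np.ndarray]:
        return [t.values for t in self.tables]

    def subset_genes(self, keep: Sequence[str]) -> "TableCollection":
        """Return a collection restricted to ``keep`` (canonical order kept)."""
        keep_set = set(keep)
        missing = keep_set - set(self.gene_ids)
        if missing:
            raise KeyError(f"unknown gene ids: {sorted(missing)[:5]}")
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep_set]
        genes = [self.gene_ids[i] for i in idx]
        return TableCollection(
            tables=[
                ExpressionTable(
                    t.condition_id, genes, t.time_points_min, t.values[idx], t.scale
                )
                for t in self.tables
            ],
            control_id=self.control_id,
        )


@dataclass
class GeneSet:
    description: str
    members: list[str]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. MapMan bins) keyed by set id."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        uni = set(universe)
        return GeneSetCollection(
            {
                sid: GeneSet(s.description, [g for g in s.members if g in uni])
                for sid, s in self.sets.items()
            }
        )


# ---------------------------------------------------------------------------
# readers


def _read_one_table(path: Path, condition_id: str, scale: str) -> ExpressionTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataFormatError(f"{path}: cannot parse TSV ({exc})") from exc
    if df.shape[1] < 2:
        raise DataFormatError(f"{path}: need a gene_id column plus time columns")
    if df.columns[0] != "gene_id":
        raise DataFormatError(
            f"{path}: first column header must be 'gene_id', got {df.columns[0]!r}"
        )
    try:
        times = [float(c) for c in df.columns[1:]]
    except ValueError as exc:
        raise DataFormatError(f"{path}: non-numeric time header ({exc})") from exc

    gene_ids = df["gene_id"].tolist()
    raw = df.iloc[:, 1:]
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell in ("", "."):
                raise DataFormatError(
                    f"{path}: missing value at row {i + 2} (gene {gene_ids[i]!r}), "
                    f"column {col!r}"
                )
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise DataFormatError(
                    f"{path}: non-numeric cell {cell!r} at row {i + 2} "
                    f"(gene {gene_ids[i]!r}), column {col!r}"
                ) from None
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise DataFormatError(f"{path}: duplicate gene_id {dupes[:5]}")
    # canonical row order: lexicographic by gene id, identical across tables
    order = sorted(range(len(gene_ids)), key=lambda i: gene_ids[i])
    return ExpressionTable(
        condition_id=condition_id,
        gene_ids=[gene_ids[i] for i in order],
        time_points_min=np.array(times, dtype=float),
        values=values[order],
        scale=scale,
    )


def read_expression_tables(
    paths: Sequence[str | Path],
    control_id: str,
    scale: str = "log2",
    condition_ids: Sequence[str] | None = None,
) -> TableCollection:
    """Load one TSV per condition into a validated :class:`TableCollection`.

    Each file must have a first column headed ``gene_id`` and numeric time
    headers (minutes). Row order is canonicalized to lexicographic gene id
    order, so the result is independent of on-disk row order. Condition ids
    default to the file stems.
    """
    paths = [Path(p) for p in paths]
    if condition_ids is None:
        condition_ids = [p.stem for p in paths]
    if len(condition_ids) != len(paths):
        raise ValueError("condition_ids must match paths")
    tables = [
        _read_one_table(p, cid, scale) for p, cid in zip(paths, condition_ids)
    ]
    ref = tables[0]
    for t, p in zip(tables[1:], paths[1:]):
        if t.gene_ids != ref.gene_ids:
            raise DataFormatError(
                f"{p}: gene set mismatch with {paths[0]}"
            )
        if not np.array_equal(t.time_points_min, ref.time_points_min):
            raise DataFormatError(f"{p}: time grid mismatch with {paths[0]}")
    return TableCollection(tables=tables, control_id=control_id)


def read_gene_sets(path: str | Path, min_size: int = 3) -> GeneSetCollection:
    """Parse a GMT file (set_id <tab> description <tab> members...).

    Members are deduplicated preserving first occurrence; sets smaller than
    ``min_size`` after deduplication are dropped (the drop count is logged).
    """
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataFormatError(
                    f"{path}: line {lineno} has fewer than 2 tab-separated fields"
                )
            sid, desc, *members = fields
            if sid in sets:
                raise DataFormatError(f"{path}: duplicate set id {sid!r} at line {lineno}")
            members = list(dict.fromkeys(m for m in members if m))
            if len(members) < min_size:
                n_dropped += 1
                continue
            sets[sid] = GeneSet(description=desc, members=members)
    if n_dropped:
        logger.info("read_gene_sets: dropped %d sets smaller than %d", n_dropped, min_size)
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# writers


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=False)


def write_expression_tables(collection: TableCollection, out_dir: str | Path) -> list[Path]:
    """Write one ``<condition_id>.tsv`` per table; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in collection.tables:
        df = t.to_frame().reset_index()
        p = out_dir / f"{t.condition_id}.tsv"
        _write_tsv(df, p)
        paths.append(p)
    return paths


def write_gene_sets(sets: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for sid in sorted(sets.sets):
            s = sets.sets[sid]
            fh.write("\t".join([sid, s.description, *s.members]) + "\n")
    return path


def _component_cols(r: int) -> list[str]:
    return [f"PC{b}" for b in range(1, r + 1)]


def write_results(
    out_dir: str | Path,
    statis=None,
    bootstrap=None,
    enrichment=None,
    dendrogram_newick: str | None = None,
    filter_report=None,
) -> dict[str, Path]:
    """Write all available result objects as TSV/Newick files.

    Floats are printed at 12 significant digits and every table has a
    deterministic row order, so identical inputs yield byte-identical files.
    Returns a mapping from logical name to path.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    written: dict[str, Path] = {}

    if statis is not None:
        inter, dec, sl, ctr = (
            statis.interstructure,
            statis.decomposition,
            statis.scores,
            statis.contributions,
        )
        ids = statis.table_ids
        r = dec.n_components
        comp_cols = _component_cols(r)

        tw = pd.DataFrame(
            {
                "condition": ids,
                "alpha_sum1": inter.alpha_sum1,
                "alpha_l2": inter.alpha_l2,
                "rv_to_compromise": inter.rv_to_compromise,
                "rv2_to_compromise": np.asarray(inter.rv_to_compromise) ** 2,
            }
        )
        _write_tsv(tw, out_dir / "table_weights.tsv")
        written["table_weights"] = out_dir / "table_weights.tsv"

        rv = pd.DataFrame(inter.rv_matrix, columns=ids)
        rv.insert(0, "condition", ids)
        _write_tsv(rv, out_dir / "rv_matrix.tsv")
        written["rv_matrix"] = out_dir / "rv_matrix.tsv"

        ev = pd.DataFrame(
            {
                "component": _component_cols(len(dec.eigenvalues)),
                "eigenvalue": dec.eigenvalues,
                "proportion": dec.eigenvalues / dec.eigenvalues.sum()
                if dec.eigenvalues.sum() > 0
                else dec.eigenvalues,
            }
        )
        _write_tsv(ev, out_dir / "eigenvalues.tsv")
        written["eigenvalues"] = out_dir / "eigenvalues.tsv"

        fs = pd.DataFrame(sl.F, columns=comp_cols)
        fs.insert(0, "observation", statis.row_ids)
        _write_tsv(fs, out_dir / "factor_scores.tsv")
        written["factor_scores"] = out_dir / "factor_scores.tsv"

        rows = []
        for cid, Fi in zip(ids, sl.F_partial):
            df = pd.DataFrame(Fi, columns=comp_cols)
            df.insert(0, "observation", statis.row_ids)
            df.insert(0, "condition", cid)
            rows.append(df)
        _write_tsv(pd.concat(rows, ignore_index=True), out_dir / "partial_factor_scores.tsv")
        written["partial_factor_scores"] = out_dir / "partial_factor_scores.tsv"

        ld = pd.DataFrame(sl.Q, columns=comp_cols)
        ld.insert(0, "column", statis.column_ids)
        ld.insert(1, "alpha_weight", sl.a)
        _write_tsv(ld, out_dir / "loadings.tsv")
        written["loadings"] = out_dir / "loadings.tsv"

        cr = pd.DataFrame(ctr.rows, columns=comp_cols)
        cr.insert(0, "observation", statis.row_ids)
        _write_tsv(cr, out_dir / "contributions_rows.tsv")
        written["contributions_rows"] = out_dir / "contributions_rows.tsv"

        cc = pd.DataFrame(ctr.columns, columns=comp_cols)
        cc.insert(0, "column", statis.column_ids)
        _write_tsv(cc, out_dir / "contributions_columns.tsv")
        written["contributions_columns"] = out_dir / "contributions_columns.tsv"

        ct = pd.DataFrame(ctr.tables, columns=comp_cols)
        ct.insert(0, "condition", ids)
        _write_tsv(ct, out_dir / "contributions_tables.tsv")
        written["contributions_tables"] = out_dir / "contributions_tables.tsv"

    if bootstrap is not None:
        r = bootstrap.ratios.shape[1]
        comp_cols = _component_cols(r)
        df = pd.DataFrame(
            np.where(np.isinf(bootstrap.ratios),
                     np.sign(bootstrap.ratios) * np.inf, bootstrap.ratios),
            columns=[f"ratio_{c}" for c in comp_cols],
        )
        df.insert(0, "observation", bootstrap.row_ids)
        for j, c in enumerate(comp_cols):
            df[f"significant_{c}"] = bootstrap.significant[:, j].astype(int)
        _write_tsv(df, out_dir / "bootstrap_ratios.tsv")
        written["bootstrap_ratios"] = out_dir / "bootstrap_ratios.tsv"

    if enrichment is not None:
        df = enrichment.to_frame()
        _write_tsv(df, out_dir / "enrichment.tsv")
        written["enrichment"] = out_dir / "enrichment.tsv"

    if dendrogram_newick is not None:
        p = out_dir / "dendrogram.nwk"
        p.write_text(dendrogram_newick + ("\n" if not dendrogram_newick.endswith("\n") else ""))
        written["dendrogram"] = p

    if filter_report is not None:
        df = filter_report.to_frame()
        _write_tsv(df, out_dir / "filter_report.tsv")
        written["filter_report"] = out_dir / "filter_report.tsv"

    return written
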