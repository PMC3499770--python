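"""The STATIS / dual-STATIS compromise machinery.

Given K centered and scaled tables X_1..X_K (n genes x t time points), the
analysis proceeds in three steps:

1. Within-table structure: a cross-product matrix per table,
   S_i = X_i X_i^T (STATIS, n x n over genes) or S_i = X_i^T X_i
   (dual-STATIS, t x t over time points).

2. Between-table structure (*interstructure*): the congruence matrix
   C_ij = <S_i, S_j>_F of Frobenius inner products. The leading eigenvector
   u1 of C (entrywise non-negative by Perron-Frobenius, since C >= 0) gives
   the table weights: alpha = u1 / sum(u1) is used to build the compromise
   S = sum_i alpha_i S_i as a weighted average; the Euclidean-normalized
   variant u1 / ||u1|| is reported alongside. The RV coefficient
   RV(A, B) = <A, B>_F / (||A||_F ||B||_F) is the cosine between two PSD
   matrices and underlies both C and the pairwise similarity heatmap.

3. Compromise decomposition under the row-mass metric M = diag(m):
   S = P Lambda P^T with P^T M P = I, computed as a standard symmetric
   eigendecomposition of M^(1/2) S M^(1/2). Factor scores F = S M P Delta^-1
   (identically P Delta), per-table scores F_i = S_i M P Delta^-1, loadings
   Q = X^T M P Delta^-1 over the K*t stacked columns, and contributions
   ctr_row(i,b) = m_i f_ib^2 / lambda_b,  ctr_col(j,b) = a_j q_jb^2,
   ctr_table(l,b) = sum over table l's columns, each summing to 1 per
   component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import TableCollection
from .preprocessing import MassVector, center_and_scale, uniform_masses

MODES = ("rows", "columns")

#: relative symmetry / PSD tolerance used throughout
PSD_RTOL = 1e-8


@dataclass
class CrossProductSet:
    """Per-table cross-product matrices S_i plus their Frobenius norms."""

    mode: str
    matrices: list[np.ndarray]
    frobenius_norms: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.matrices = [np.asarray(S, dtype=float) for S in self.matrices]
        self.frobenius_norms = np.array(
            [np.linalg.norm(S, "fro") for S in self.matrices]
        )

    @property
    def K(self) -> int:
        return len(self.matrices)


@dataclass
class InterstructureResult:
    """Congruence matrix C, table weights and pairwise RV similarities."""

    C: np.ndarray
    leading_eigenvector: np.ndarray
    alpha_sum1: np.ndarray
    alpha_l2: np.ndarray
    rv_matrix: np.ndarray
    rv_to_compromise: np.ndarray | None = None


@dataclass
class CompromiseDecomposition:
    """Eigendecomposition of the compromise under the mass metric."""

    S: np.ndarray
    eigenvalues: np.ndarray  # all non-negative eigenvalues, descending
    P: np.ndarray  # n x r, P^T M P = I on the r retained components
    Delta: np.ndarray  # r-vector of sqrt(eigenvalues[:r])
    masses: MassVector
    n_components: int


@dataclass
class ScoresAndLoadings:
    F: np.ndarray  # n x r global factor scores
    F_partial: list[np.ndarray]  # K matrices, n x r
    Q: np.ndarray  # (K*t) x r loadings
    a: np.ndarray  # K*t column weights [alpha_1 1^T | ... | alpha_K 1^T]


@dataclass
class ContributionSet:
    rows: np.ndarray  # n x r
    columns: np.ndarray  # (K*t) x r
    tables: np.ndarray  # K x r


@dataclass
class StatisResults:
    """Everything a full STATIS (or dual-STATIS) run produces."""

    mode: str
    table_ids: list[str]
    row_ids: list[str]
    column_ids: list[str]
    interstructure: InterstructureResult
    decomposition: CompromiseDecomposition
    scores: ScoresAndLoadings
    contributions: ContributionSet
    cross_products: CrossProductSet


# ---------------------------------------------------------------------------


def cross_products(tables: Sequence[np.ndarray], mode: str = "rows") -> CrossProductSet:
    """S_i = X_i X_i^T (mode='rows') or X_i^T X_i (mode='columns').

    Symmetry is enforced as (S + S^T)/2 to wash out floating-point noise.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    mats = []
    for X in tables:
        X = np.asarray(X, dtype=float)
        S = X @ X.T if mode == "rows" else X.T @ X
        mats.append((S + S.T) / 2.0)
    return CrossProductSet(mode=mode, matrices=mats)


def rv_coefficient(S1: np.ndarray, S2: np.ndarray) -> float:
    """Cosine of two cross-product matrices under the Frobenius inner product.

    For positive semidefinite inputs the value lies in [0, 1]; 1 means
    identical similarity structure up to scale, 0 orthogonal structure.
    """
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    if S1.shape != S2.shape:
        raise ValueError(f"shape mismatch: {S1.shape} vs {S2.shape}")
    n1 = np.linalg.norm(S1, "fro")
    n2 = np.linalg.norm(S2, "fro")
    if n1 == 0 or n2 == 0:
        raise ValueError("RV coefficient undefined for a zero matrix")
    return float(np.tensordot(S1, S2) / (n1 * n2))


def interstructure(cps: CrossProductSet) -> InterstructureResult:
    """Congruence matrix, leading-eigenvector table weights and RV matrix."""
    K = cps.K
    if np.all(cps.frobenius_norms == 0):
        raise ValueError("all tables are zero; interstructure undefined")
    C = np.empty((K, K))
    for i in range(K):
        for j in range(i, K):
            C[i, j] = C[j, i] = float(np.tensordot(cps.matrices[i], cps.matrices[j]))
    evals, evecs = np.linalg.eigh(C)
    u1 = evecs[:, -1]
    # C is entrywise non-negative, so u1 can always be flipped non-negative
    if u1.sum() < 0:
        u1 = -u1
    u1 = np.clip(u1, 0.0, None)
    s = u1.sum()
    if s <= 0:
        raise ValueError("degenerate congruence matrix: zero leading eigenvector")
    rv = np.empty((K, K))
    for i in range(K):
        for j in range(i, K):
            rv[i, j] = rv[j, i] = rv_coefficient(cps.matrices[i], cps.matrices[j])
    return InterstructureResult(
        C=C,
        leading_eigenvector=u1,
        alpha_sum1=u1 / s,
        alpha_l2=u1 / np.linalg.norm(u1),
        rv_matrix=rv,
    )


def compromise(cps: CrossProductSet, weights: Sequence[float]) -> np.ndarray:
    """Weighted average S = sum_i alpha_i S_i of the cross-products."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (cps.K,):
        raise ValueError(f"expected {cps.K} weights, got shape {weights.shape}")
    if np.any(weights < 0):
        raise ValueError("compromise weights must be non-negative")
    S = np.zeros_like(cps.matrices[0])
    for a, Si in zip(weights, cps.matrices):
        S += a * Si
    return (S + S.T) / 2.0


def _fix_signs(P: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|entry| coordinate is positive.

    Ties on |entry| are broken by the lowest row index, making output signs
    reproducible across LAPACK builds.
    """
    P = P.copy()
    for b in range(P.shape[1]):
        col = P[:, b]
        i = int(np.argmax(np.abs(col)))  # argmax takes the first maximum
        if col[i] < 0:
            P[:, b] = -col
    return P


def decompose_compromise(
    S: np.ndarray, masses: MassVector, n_components: int = 3
) -> CompromiseDecomposition:
    """S = P Lambda P^T with P^T M P = I, via the symmetric reduction.

    Computed as the eigendecomposition of M^(1/2) S M^(1/2) = V Lambda V^T
    followed by P = M^(-1/2) V. Eigenvalues within floating-point noise of
    zero are clipped to zero; a genuinely negative eigenvalue (below
    -1e-6 * lambda_1) raises, since the compromise of PSD matrices with
    non-negative weights must be PSD.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("S must be square")
    if np.max(np.abs(S - S.T)) > PSD_RTOL * max(1.0, np.max(np.abs(S))):
        raise ValueError("S must be symmetric")
    if len(masses) != n:
        raise ValueError("masses length does not match S")
    if np.any(masses.masses <= 0):
        raise ValueError("decomposition requires strictly positive masses")
    sqm = np.sqrt(masses.masses)
    Sw = (S * sqm[None, :]) * sqm[:, None]
    evals, V = np.linalg.eigh(Sw)
    evals = evals[::-1]
    V = V[:, ::-1]
    lam1 = max(evals[0], 0.0)
    if evals[-1] < -1e-6 * max(lam1, 1e-300):
        raise ValueError(f"compromise not PSD: eigenvalue {evals[-1]:.3e}")
    evals = np.clip(evals, 0.0, None)
    r = int(min(n_components, n))
    P = _fix_signs(V[:, :r] / sqm[:, None])
    return CompromiseDecomposition(
        S=S,
        eigenvalues=evals,
        P=P,
        Delta=np.sqrt(evals[:r]),
        masses=masses,
        n_components=r,
    )


def _check_rank(dec: CompromiseDecomposition) -> None:
    lam1 = dec.eigenvalues[0] if len(dec.eigenvalues) else 0.0
    if np.any(dec.Delta**2 <= 1e-12 * max(lam1, 1e-300)):
        raise ValueError(
            "rank deficient: a retained eigenvalue is zero; reduce n_components"
        )


def factor_scores(S: np.ndarray, dec: CompromiseDecomposition) -> np.ndarray:
    """Global factor scores F = S M P Delta^-1 (algebraically P Delta)."""
    _check_rank(dec)
    return (S * dec.masses.masses[None, :]) @ dec.P / dec.Delta[None, :]


def partial_factor_scores(
    cps: CrossProductSet, dec: CompromiseDecomposition
) -> list[np.ndarray]:
    """Per-table factor scores F_i = S_i M P Delta^-1.

    Their alpha-weighted average (with the compromise weights) equals the
    global factor scores.
    """
    _check_rank(dec)
    m = dec.masses.masses[None, :]
    return [(Si * m) @ dec.P / dec.Delta[None, :] for Si in cps.matrices]


def loadings(
    tables: Sequence[np.ndarray],
    dec: CompromiseDecomposition,
    alpha_sum1: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked loadings Q = X^T M P Delta^-1 and column weights a.

    Columns are stacked in table order ([X_1 | ... | X_K]); the column-weight
    vector repeats each table's compromise weight over its t columns, so that
    Q^T diag(a) Q = I on the retained components.
    """
    _check_rank(dec)
    m = dec.masses.masses[:, None]
    blocks = [np.asarray(X, dtype=float).T @ (m * dec.P) / dec.Delta[None, :] for X in tables]
    Q = np.vstack(blocks)
    a = np.concatenate(
        [np.full(np.asarray(X).shape[1], al) for X, al in zip(tables, alpha_sum1)]
    )
    return Q, a


def contributions(
    dec: CompromiseDecomposition,
    F: np.ndarray,
    Q: np.ndarray,
    a: np.ndarray,
    table_sizes: Sequence[int],
) -> ContributionSet:
    """Row, column and table contributions; each sums to 1 per component."""
    lam = dec.Delta**2
    rows = dec.masses.masses[:, None] * F**2 / lam[None, :]
    cols = a[:, None] * Q**2
    tables = np.empty((len(table_sizes), dec.n_components))
    start = 0
    for l, size in enumerate(table_sizes):
        tables[l] = cols[start : start + size].sum(axis=0)
        start += size
    return ContributionSet(rows=rows, columns=cols, tables=tables)


# ---------------------------------------------------------------------------
# orchestration


def _as_arrays_and_ids(
    collection: TableCollection | Sequence[np.ndarray],
) -> tuple[list[np.ndarray], list[str], list[str], list[str]]:
    if isinstance(collection, TableCollection):
        arrays = collection.arrays()
        table_ids = collection.condition_ids
        row_ids = list(collection.gene_ids)
        col_labels = [f"{tp:g}" for tp in collection.time_points_min]
    else:
        arrays = [np.asarray(X, dtype=float) for X in collection]
        table_ids = [f"table{i + 1}" for i in range(len(arrays))]
        row_ids = [f"row{i + 1}" for i in range(arrays[0].shape[0])]
        col_labels = [f"col{j + 1}" for j in range(arrays[0].shape[1])]
    column_ids = [f"{tid}:{c}" for tid in table_ids for c in col_labels]
    return arrays, table_ids, row_ids, column_ids


def run_statis(
    collection: TableCollection | Sequence[np.ndarray],
    masses: MassVector | None = None,
    n_components: int = 3,
    mode: str = "rows",
    preprocess: bool = True,
    table_norm: str = "table_scale",
    weight_norm: str = "sum1",
) -> StatisResults:
    """Full STATIS run: preprocess, interstructure, compromise, projections.

    With ``mode="columns"`` this is dual-STATIS: tables are transposed after
    preprocessing-equivalent handling, observations become time points and
    masses default to uniform over columns. ``preprocess=False`` assumes the
    caller already centered/scaled the tables. ``weight_norm`` selects which
    normalization of the leading congruence eigenvector builds the
    compromise: ``"sum1"`` (a true weighted average, the default) or
    ``"l2"`` (unit Euclidean norm; rescales S and the eigenvalues by a
    positive constant without changing any normalized quantity).
    """
    if weight_norm not in ("sum1", "l2"):
        raise ValueError("weight_norm must be 'sum1' or 'l2'")
    arrays, table_ids, row_ids, column_ids = _as_arrays_and_ids(collection)
    if preprocess:
        arrays = [center_and_scale(X, method=table_norm) for X in arrays]
    if mode == "columns":
        arrays = [X.T for X in arrays]
        row_ids, column_ids = (
            [cid.split(":", 1)[1] for cid in column_ids[: arrays[0].shape[0]]],
            [f"{tid}:{r}" for tid in table_ids for r in row_ids],
        )
    n = arrays[0].shape[0]
    if masses is None:
        masses = uniform_masses(n)
    cps = cross_products(arrays, mode="rows")
    inter = interstructure(cps)
    weights = inter.alpha_sum1 if weight_norm == "sum1" else inter.alpha_l2
    S = compromise(cps, weights)
    inter.rv_to_compromise = np.array(
        [rv_coefficient(Si, S) for Si in cps.matrices]
    )
    # retain only components with strictly positive eigenvalue
    dec = decompose_compromise(S, masses, n_components=n_components)
    lam1 = max(dec.eigenvalues[0], 1e-300)
    r_eff = int(np.sum(dec.eigenvalues[: dec.n_components] > 1e-12 * lam1))
    if r_eff < dec.n_components:
        dec = CompromiseDecomposition(
            S=dec.S,
            eigenvalues=dec.eigenvalues,
            P=dec.P[:, :r_eff],
            Delta=dec.Delta[:r_eff],
            masses=dec.masses,
            n_components=r_eff,
        )
    F = factor_scores(S, dec)
    F_partial = partial_factor_scores(cps, dec)
    Q, a = loadings(arrays, dec, weights)
    ctr = contributions(
        dec, F, Q, a, table_sizes=[X.shape[1] for X in arrays]
    )
    return StatisResults(
        mode=mode,
        table_ids=table_ids,
        row_ids=row_ids,
        column_ids=column_ids,
        interstructure=inter,
        decomposition=dec,
        scores=ScoresAndLoadings(F=F, F_partial=F_partial, Q=Q, a=a),
        contributions=ctr,
        cross_products=cps,
    )


def run_dual_statis(
    collection: TableCollection | Sequence[np.ndarray],
    n_components: int = 3,
    preprocess: bool = True,
    table_norm: str = "table_scale",
) -> StatisResults:
    """Dual-STATIS: the identical pipeline on transposed tables.

    The compromise is then t x t over time points, with uniform masses 1/t.
    """
    return run_statis(
        collection,
        masses=None,
        n_components=n_components,
        mode="columns",
        preprocess=preprocess,
        table_norm=table_norm,
    )
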