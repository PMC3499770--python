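"""scikit-learn style estimators wrapping the compromise analysis.

``STATIS`` and ``DualSTATIS`` are decomposition estimators in the mold of
:class:`sklearn.decomposition.PCA`: ``fit`` consumes a list of K equally
shaped (n x t) arrays or a :class:`~statispy.io_formats.TableCollection`,
fitted attributes carry a trailing underscore, and ``transform`` projects
(new) tables onto the fitted compromise space. ``InformativeGeneFilter`` is
the matching transformer for the fold-change / coefficient-of-variation
gene filter.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import core
from .io_formats import TableCollection
from .preprocessing import MassVector, center_and_scale, filter_informative_genes


class STATIS(BaseEstimator):
    """Compromise analysis of K gene x time-point tables.

    Parameters
    ----------
    n_components : int, default=3
        Number of compromise components to retain (reduced automatically if
        the compromise has lower rank).
    preprocess : bool, default=True
        Column-center and rescale every table to unit total sum of squares
        before the analysis.
    table_norm : {"table_scale", "column_zscore"}, default="table_scale"
        Normalization variant applied when ``preprocess`` is True.

    Attributes
    ----------
    alpha_ : ndarray of shape (K,)
        Sum-to-one table weights used to build the compromise.
    alpha_l2_ : ndarray of shape (K,)
        The same leading eigenvector normalized to unit Euclidean norm.
    C_ : ndarray of shape (K, K)
        Congruence matrix of Frobenius inner products of cross-products.
    rv_matrix_ : ndarray of shape (K, K)
        Pairwise RV coefficients between tables.
    rv_to_compromise_ : ndarray of shape (K,)
        RV coefficient of each table's cross-product with the compromise.
    compromise_ : ndarray
        The compromise cross-product matrix S.
    eigenvalues_ : ndarray
        All non-negative eigenvalues of S under the mass metric, descending.
    components_ : ndarray of shape (n, r)
        Generalized eigenvectors P with P^T M P = I.
    factor_scores_ : ndarray of shape (n, r)
        Global factor scores F = S M P Delta^-1.
    partial_factor_scores_ : list of K ndarrays of shape (n, r)
        Per-table factor scores F_i = S_i M P Delta^-1.
    loadings_ : ndarray of shape (K*t, r)
        Loadings of the stacked columns, Q = X^T M P Delta^-1.
    contributions_rows_, contributions_columns_, contributions_tables_ :
        Contribution matrices; each column sums to 1.
    results_ : :class:`statispy.core.StatisResults`
        The complete underlying result bundle.
    """

    _mode = "rows"

    def __init__(
        self,
        n_components: int = 3,
        preprocess: bool = True,
        table_norm: str = "table_scale",
    ):
        self.n_components = n_components
        self.preprocess = preprocess
        self.table_norm = table_norm

    def fit(self, X: TableCollection | Sequence[np.ndarray], y=None, masses: MassVector | None = None):
        res = core.run_statis(
            X,
            masses=masses,
            n_components=self.n_components,
            mode=self._mode,
            preprocess=self.preprocess,
            table_norm=self.table_norm,
        )
        self.results_ = res
        inter, dec, sl, ctr = (
            res.interstructure,
            res.decomposition,
            res.scores,
            res.contributions,
        )
        self.table_ids_ = res.table_ids
        self.alpha_ = inter.alpha_sum1
        self.alpha_l2_ = inter.alpha_l2
        self.C_ = inter.C
        self.rv_matrix_ = inter.rv_matrix
        self.rv_to_compromise_ = inter.rv_to_compromise
        self.compromise_ = dec.S
        self.eigenvalues_ = dec.eigenvalues
        self.components_ = dec.P
        self.masses_ = dec.masses
        self.n_components_ = dec.n_components
        self.factor_scores_ = sl.F
        self.partial_factor_scores_ = sl.F_partial
        self.loadings_ = sl.Q
        self.column_weights_ = sl.a
        self.contributions_rows_ = ctr.rows
        self.contributions_columns_ = ctr.columns
        self.contributions_tables_ = ctr.tables
        return self

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y, **fit_params).factor_scores_

    def transform(self, X: TableCollection | Sequence[np.ndarray]) -> list[np.ndarray]:
        """Project tables onto the fitted compromise space.

        Each table is preprocessed like the training tables, its
        cross-product is formed, and the partial factor scores
        S M P Delta^-1 are returned (one (n, r) array per table).
        """
        if not hasattr(self, "results_"):
            raise AttributeError("STATIS instance is not fitted yet")
        arrays = X.arrays() if isinstance(X, TableCollection) else [np.asarray(A, float) for A in X]
        if self.preprocess:
            arrays = [center_and_scale(A, method=self.table_norm) for A in arrays]
        if self._mode == "columns":
            arrays = [A.T for A in arrays]
        cps = core.cross_products(arrays, mode="rows")
        return core.partial_factor_scores(cps, self.results_.decomposition)


class DualSTATIS(STATIS):
    """STATIS on transposed tables: a time-point x time-point compromise.

    Observations are the t time points (uniform masses 1/t); the loadings
    refer to the stacked gene columns of the transposed tables.
    """

    _mode = "columns"


class InformativeGeneFilter(BaseEstimator, TransformerMixin):
    """Filter genes by fold-change and coefficient of variation.

    ``fit`` computes, on the linear intensity scale, which genes show a
    fold-change of at least ``fc_threshold`` versus the reference time point
    in at least ``min_fc_timepoints`` time points of some condition AND a
    coefficient of variation of at least ``cv_threshold`` in some condition
    (or pooled over all samples); ``transform`` subsets a collection to the
    kept genes.
    """

    def __init__(
        self,
        fc_threshold: float = 2.0,
        min_fc_timepoints: int = 2,
        cv_threshold: float = 1.0,
        cv_scope: str = "per_condition",
    ):
        self.fc_threshold = fc_threshold
        self.min_fc_timepoints = min_fc_timepoints
        self.cv_threshold = cv_threshold
        self.cv_scope = cv_scope

    def fit(self, X: TableCollection, y=None):
        _, report = filter_informative_genes(
            X,
            fc_threshold=self.fc_threshold,
            min_fc_timepoints=self.min_fc_timepoints,
            cv_threshold=self.cv_threshold,
            cv_scope=self.cv_scope,
        )
        self.report_ = report
        self.kept_genes_ = [g for g, s in report.per_gene.items() if s.kept]
        self.n_input_ = report.n_input
        self.n_kept_ = report.n_kept
        return self

    def transform(self, X: TableCollection) -> TableCollection:
        if not hasattr(self, "kept_genes_"):
            raise AttributeError("InformativeGeneFilter instance is not fitted yet")
        return X.subset_genes(self.kept_genes_)
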