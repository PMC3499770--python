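"""Unit and oracle tests for the compromise machinery.

The independent oracles are deliberately naive: triple-loop cross-products,
double-loop Frobenius inner products, and the SVD of the mass-weighted
stacked matrix M^(1/2)[sqrt(a_1)X_1|...|sqrt(a_K)X_K], whose squared
singular values must match the eigen-route compromise eigenvalues.
"""

import numpy as np
import pytest

from statispy import core
from statispy.preprocessing import center_and_scale, uniform_masses


def brute_cross_product(X, mode):
    n, t = X.shape
    if mode == "rows":
        S = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                for k in range(t):
                    S[i, j] += X[i, k] * X[j, k]
    else:
        S = np.zeros((t, t))
        for i in range(t):
            for j in range(t):
                for k in range(n):
                    S[i, j] += X[k, i] * X[k, j]
    return S


def brute_frobenius_inner(A, B):
    total = 0.0
    for i in range(A.shape[0]):
        for j in range(A.shape[1]):
            total += A[i, j] * B[i, j]
    return total


def preprocessed_tables(rng, K=3, n=8, t=5):
    return [center_and_scale(rng.normal(size=(n, t))) for _ in range(K)]


class TestCrossProducts:
    def test_identity_table(self):
        cps = core.cross_products([np.eye(2)], mode="rows")
        np.testing.assert_allclose(cps.matrices[0], np.eye(2))

    @pytest.mark.parametrize("mode", ["rows", "columns"])
    def test_matches_triple_loop_oracle(self, rng, mode):
        X = rng.normal(size=(3, 2))
        cps = core.cross_products([X], mode=mode)
        np.testing.assert_allclose(cps.matrices[0], brute_cross_product(X, mode), atol=1e-12)

    def test_row_and_column_modes_share_nonzero_spectrum(self, rng):
        X = rng.normal(size=(6, 4))
        Sr = core.cross_products([X], "rows").matrices[0]
        Sc = core.cross_products([X], "columns").matrices[0]
        er = np.sort(np.linalg.eigvalsh(Sr))[::-1][:4]
        ec = np.sort(np.linalg.eigvalsh(Sc))[::-1][:4]
        np.testing.assert_allclose(er, ec, atol=1e-8)


class TestRVCoefficient:
    def test_self_similarity_is_one(self, rng):
        X = rng.normal(size=(5, 3))
        S = X @ X.T
        assert core.rv_coefficient(S, S) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_structures_give_zero(self):
        assert core.rv_coefficient(np.diag([1.0, 0.0]), np.diag([0.0, 1.0])) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        A = rng.normal(size=(4, 4)); A = A @ A.T
        B = rng.normal(size=(4, 4)); B = B @ B.T
        expected = brute_frobenius_inner(A, B) / np.sqrt(
            brute_frobenius_inner(A, A) * brute_frobenius_inner(B, B)
        )
        assert core.rv_coefficient(A, B) == pytest.approx(expected, abs=1e-12)

    def test_rotation_invariance(self, rng):
        X = rng.normal(size=(6, 4))
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        S1 = X @ X.T
        S2 = (X @ Q) @ (X @ Q).T
        assert core.rv_coefficient(S1, S2) == pytest.approx(1.0, abs=1e-10)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            core.rv_coefficient(np.zeros((2, 2)), np.eye(2))


class TestInterstructure:
    def test_identical_tables_get_uniform_weights(self, rng):
        X = center_and_scale(rng.normal(size=(6, 4)))
        cps = core.cross_products([X] * 4)
        inter = core.interstructure(cps)
        np.testing.assert_allclose(inter.alpha_sum1, np.full(4, 0.25), atol=1e-10)
        np.testing.assert_allclose(inter.alpha_l2, np.full(4, 0.5), atol=1e-10)

    def test_single_table(self, rng):
        X = center_and_scale(rng.normal(size=(5, 3)))
        inter = core.interstructure(core.cross_products([X]))
        assert inter.alpha_sum1[0] == pytest.approx(1.0)

    def test_eight_near_identical_tables_l2_weights(self, rng):
        # weights ~ 1/sqrt(8) = 0.354 for highly congruent tables
        base = rng.normal(size=(30, 6))
        tabs = [center_and_scale(base + 1e-3 * rng.normal(size=base.shape)) for _ in range(8)]
        inter = core.interstructure(core.cross_products(tabs))
        assert np.all(np.abs(inter.alpha_l2 - 1 / np.sqrt(8)) < 0.02)

    def test_congruence_matches_rv_up_to_norms(self, rng):
        tabs = preprocessed_tables(rng)
        cps = core.cross_products(tabs)
        inter = core.interstructure(cps)
        for i in range(3):
            for j in range(3):
                expected = inter.rv_matrix[i, j] * cps.frobenius_norms[i] * cps.frobenius_norms[j]
                assert inter.C[i, j] == pytest.approx(expected, rel=1e-10)

    def test_rv_matrix_properties(self, rng):
        inter = core.interstructure(core.cross_products(preprocessed_tables(rng, K=4)))
        rv = inter.rv_matrix
        np.testing.assert_allclose(rv, rv.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(rv), 1.0, atol=1e-12)
        assert np.all(rv >= 0) and np.all(rv <= 1 + 1e-12)


class TestCompromise:
    def test_identical_tables_average_to_self(self, rng):
        X = center_and_scale(rng.normal(size=(5, 3)))
        S1 = core.cross_products([X, X]).matrices[0]
        S = core.compromise(core.cross_products([X, X]), [0.5, 0.5])
        np.testing.assert_allclose(S, S1, atol=1e-12)

    def test_degenerate_weight_selects_table(self, rng):
        cps = core.cross_products(preprocessed_tables(rng, K=2))
        np.testing.assert_allclose(core.compromise(cps, [1.0, 0.0]), cps.matrices[0])

    def test_matches_weighted_sum_oracle(self, rng):
        cps = core.cross_products(preprocessed_tables(rng, K=3))
        w = np.array([0.5, 0.3, 0.2])
        expected = sum(wi * Si for wi, Si in zip(w, cps.matrices))
        np.testing.assert_allclose(core.compromise(cps, w), expected, atol=1e-12)

    def test_weight_length_mismatch(self, rng):
        cps = core.cross_products(preprocessed_tables(rng, K=3))
        with pytest.raises(ValueError):
            core.compromise(cps, [1.0, 0.0])


class TestDecomposition:
    def test_hand_forced_two_by_two(self):
        dec = core.decompose_compromise(np.diag([4.0, 1.0]), uniform_masses(2), 2)
        np.testing.assert_allclose(dec.eigenvalues, [2.0, 0.5], atol=1e-12)
        np.testing.assert_allclose(np.abs(dec.P), np.sqrt(2) * np.eye(2), atol=1e-12)

    def test_mass_orthonormality(self, rng):
        tabs = preprocessed_tables(rng, K=3, n=10, t=5)
        cps = core.cross_products(tabs)
        inter = core.interstructure(cps)
        S = core.compromise(cps, inter.alpha_sum1)
        dec = core.decompose_compromise(S, uniform_masses(10), 3)
        M = dec.masses.diag
        np.testing.assert_allclose(dec.P.T @ M @ dec.P, np.eye(3), atol=1e-8)

    def test_reconstruction_full_rank(self, rng):
        tabs = preprocessed_tables(rng, K=2, n=6, t=8)
        cps = core.cross_products(tabs)
        S = core.compromise(cps, [0.5, 0.5])
        dec = core.decompose_compromise(S, uniform_masses(6), 6)
        recon = dec.P @ np.diag(dec.eigenvalues[:6]) @ dec.P.T @ dec.masses.diag @ np.diag(
            1.0 / dec.masses.masses
        )
        # S = P Lambda P^T in the M-metric sense: M^(1/2)SM^(1/2) = V L V^T
        sqm = np.sqrt(dec.masses.masses)
        Sw = (S * sqm[None, :]) * sqm[:, None]
        V = dec.P * sqm[:, None]
        np.testing.assert_allclose(V @ np.diag(dec.eigenvalues[:6]) @ V.T, Sw, atol=1e-8)

    def test_not_psd_rejected(self):
        with pytest.raises(ValueError, match="PSD"):
            core.decompose_compromise(np.diag([1.0, -0.5]), uniform_masses(2), 2)

    def test_sign_convention_largest_entry_positive(self, rng):
        tabs = preprocessed_tables(rng, K=2, n=7, t=4)
        cps = core.cross_products(tabs)
        S = core.compromise(cps, [0.6, 0.4])
        dec = core.decompose_compromise(S, uniform_masses(7), 3)
        for b in range(3):
            col = dec.P[:, b]
            assert col[np.argmax(np.abs(col))] > 0


class TestScoresLoadingsContributions:
    @pytest.fixture
    def fitted(self, rng):
        tabs = preprocessed_tables(rng, K=3, n=9, t=5)
        return core.run_statis(tabs, preprocess=False)

    def test_factor_scores_equal_P_delta(self, fitted):
        dec = fitted.decomposition
        np.testing.assert_allclose(
            fitted.scores.F, dec.P * dec.Delta[None, :], atol=1e-8
        )

    def test_eigenvalue_is_mass_weighted_score_variance(self, fitted):
        # lambda_b = sum_i m_i f_ib^2
        dec = fitted.decomposition
        lam = (dec.masses.masses[:, None] * fitted.scores.F**2).sum(axis=0)
        np.testing.assert_allclose(lam, dec.Delta**2, atol=1e-8)

    def test_partial_scores_average_to_global(self, fitted):
        avg = sum(
            a * Fi
            for a, Fi in zip(fitted.interstructure.alpha_sum1, fitted.scores.F_partial)
        )
        np.testing.assert_allclose(avg, fitted.scores.F, atol=1e-8)

    def test_partial_scores_match_direct_product(self, fitted):
        dec = fitted.decomposition
        m = dec.masses.masses
        for Si, Fi in zip(fitted.cross_products.matrices, fitted.scores.F_partial):
            expected = (Si * m[None, :]) @ dec.P / dec.Delta[None, :]
            np.testing.assert_allclose(Fi, expected, atol=1e-12)

    def test_loadings_weighted_orthonormality(self, fitted):
        # Q^T A Q = I with A = diag of repeated table weights
        Q, a = fitted.scores.Q, fitted.scores.a
        np.testing.assert_allclose(Q.T @ (a[:, None] * Q), np.eye(Q.shape[1]), atol=1e-8)

    def test_contribution_conservation(self, fitted):
        ctr = fitted.contributions
        for mat in (ctr.rows, ctr.columns, ctr.tables):
            np.testing.assert_allclose(mat.sum(axis=0), 1.0, atol=1e-8)
            assert np.all(mat >= -1e-12) and np.all(mat <= 1 + 1e-8)

    def test_identical_tables_contribute_equally(self, rng):
        X = center_and_scale(rng.normal(size=(8, 4)))
        res = core.run_statis([X, X, X], preprocess=False)
        np.testing.assert_allclose(res.contributions.tables, 1 / 3, atol=1e-8)


class TestRunStatis:
    def test_eigen_route_matches_svd_oracle(self, rng):
        # compromise eigenvalues = squared singular values of
        # M^(1/2) [sqrt(a1) X1 | ... | sqrt(aK) XK]
        for _ in range(50):
            K = int(rng.integers(1, 5))
            n = int(rng.integers(3, 13))
            t = int(rng.integers(2, 7))
            tabs = [center_and_scale(rng.normal(size=(n, t))) for _ in range(K)]
            res = core.run_statis(tabs, preprocess=False, n_components=min(n, K * t))
            alpha = res.interstructure.alpha_sum1
            stacked = np.hstack([np.sqrt(a) * X for a, X in zip(alpha, tabs)])
            sv = np.linalg.svd(stacked / np.sqrt(n), compute_uv=False)
            lam_svd = np.sort(sv**2)[::-1]
            lam = res.decomposition.eigenvalues[: len(lam_svd)]
            np.testing.assert_allclose(lam, lam_svd, atol=1e-8)

    def test_single_table_reduces_to_pca(self, rng):
        X = center_and_scale(rng.normal(size=(10, 5)))
        res = core.run_statis([X], preprocess=False, n_components=4)
        U, sv, _ = np.linalg.svd(X / np.sqrt(10))
        np.testing.assert_allclose(res.decomposition.eigenvalues[:4], (sv**2)[:4], atol=1e-8)
        pca_scores = np.sqrt(10) * U[:, :4] * sv[:4]
        for b in range(4):
            diff = min(
                np.max(np.abs(res.scores.F[:, b] - pca_scores[:, b])),
                np.max(np.abs(res.scores.F[:, b] + pca_scores[:, b])),
            )
            assert diff < 1e-8

    def test_table_permutation_equivariance(self, rng):
        tabs = preprocessed_tables(rng, K=4, n=8, t=5)
        res = core.run_statis(tabs, preprocess=False)
        perm = [2, 0, 3, 1]
        res_p = core.run_statis([tabs[i] for i in perm], preprocess=False)
        np.testing.assert_allclose(
            res_p.interstructure.alpha_sum1,
            res.interstructure.alpha_sum1[perm],
            atol=1e-10,
        )
        np.testing.assert_allclose(res_p.decomposition.S, res.decomposition.S, atol=1e-10)
        np.testing.assert_allclose(
            res_p.decomposition.eigenvalues, res.decomposition.eigenvalues, atol=1e-10
        )
        np.testing.assert_allclose(res_p.scores.F, res.scores.F, atol=1e-8)

    def test_duplicating_a_table_increases_its_weight_share(self, rng):
        tabs = preprocessed_tables(rng, K=3, n=8, t=5)
        res = core.run_statis(tabs, preprocess=False)
        res_dup = core.run_statis(tabs + [tabs[0]], preprocess=False)
        share = res.interstructure.alpha_sum1[0]
        share_dup = res_dup.interstructure.alpha_sum1[[0, 3]].sum()
        assert share_dup > share

    def test_rv_to_compromise_filled(self, rng):
        res = core.run_statis(preprocessed_tables(rng), preprocess=False)
        rvc = res.interstructure.rv_to_compromise
        assert rvc is not None and np.all(rvc > 0) and np.all(rvc <= 1 + 1e-12)


class TestDualStatis:
    def test_dual_equals_statis_on_transposed_tables(self, rng):
        tabs = [rng.normal(size=(9, 5)) for _ in range(3)]
        pre = [center_and_scale(X) for X in tabs]
        dual = core.run_dual_statis(tabs)
        direct = core.run_statis([X.T for X in pre], preprocess=False)
        np.testing.assert_allclose(
            dual.decomposition.eigenvalues, direct.decomposition.eigenvalues, atol=1e-10
        )
        np.testing.assert_allclose(dual.scores.F, direct.scores.F, atol=1e-10)

    def test_identical_tables_dual_compromise_is_single_cross_product(self, rng):
        X = center_and_scale(rng.normal(size=(7, 4)))
        dual = core.run_dual_statis([X, X], preprocess=False)
        np.testing.assert_allclose(dual.decomposition.S, X.T @ X, atol=1e-10)

    def test_dual_eigenvalues_match_svd_oracle(self, rng):
        tabs = [center_and_scale(rng.normal(size=(8, 5))) for _ in range(3)]
        dual = core.run_dual_statis(tabs, preprocess=False)
        alpha = dual.interstructure.alpha_sum1
        stacked = np.hstack([np.sqrt(a) * X.T for a, X in zip(alpha, tabs)])
        sv = np.linalg.svd(stacked / np.sqrt(5), compute_uv=False)
        np.testing.assert_allclose(
            dual.decomposition.eigenvalues[: len(sv)], np.sort(sv**2)[::-1], atol=1e-8
        )
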