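"""SVD-PLS: decomposition, permutation inference, bootstrap ratios, scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ftdpls import (bootstrap_ratios, cross_block_correlation, permutation_pvalues,
                    pls_fit, project_scores, svd_latent_variables, threshold_bsr)
from ftdpls.cohort import zscore_columns


def _z(arr):
    df = pd.DataFrame(np.asarray(arr, dtype=float))
    z, _ = zscore_columns(df)
    return z


class TestCrossBlockCorrelation:
    def test_identical_column_gives_unit_entry(self, rng):
        x = _z(rng.normal(size=(20, 2)))
        y = x.iloc[:, [0]].copy()
        y.columns = ["y1"]
        R = cross_block_correlation(x, y).R
        assert R[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_column_gives_zero_row(self):
        n = 8
        x = _z(np.column_stack([np.sin(2 * np.pi * np.arange(n) / n)]))
        y = _z(np.column_stack([np.cos(2 * np.pi * np.arange(n) / n),
                                np.cos(4 * np.pi * np.arange(n) / n)]))
        R = cross_block_correlation(x, y).R
        np.testing.assert_allclose(R[0], 0, atol=1e-12)

    def test_matches_pairwise_pearson(self, rng):
        X = _z(rng.normal(size=(4, 2)))
        Y = _z(rng.normal(size=(4, 3)))
        R = cross_block_correlation(X, Y).R
        for i in range(2):
            for j in range(3):
                r, _ = sps.pearsonr(X.iloc[:, i], Y.iloc[:, j])  # per-pair oracle
                assert R[i, j] == pytest.approx(r, abs=1e-12)

    def test_row_mismatch_and_small_n(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            cross_block_correlation(_z(rng.normal(size=(5, 2))),
                                    _z(rng.normal(size=(6, 2))))
        with pytest.raises(ValueError, match="3"):
            X = pd.DataFrame(np.array([[1.0, 2.0], [2.0, 1.0]]))
            cross_block_correlation(X, X)


class TestSVD:
    def test_rank_one(self, rng):
        u = rng.normal(size=5)
        u /= np.linalg.norm(u)
        v = rng.normal(size=7)
        v /= np.linalg.norm(v)
        R = 3.0 * np.outer(u, v)
        lv = svd_latent_variables(R)
        assert lv.d[0] == pytest.approx(np.linalg.norm(R, "fro"))
        assert lv.covexp[0] == pytest.approx(1.0)

    def test_diagonal_two_one(self):
        lv = svd_latent_variables(np.diag([2.0, 1.0]))
        np.testing.assert_allclose(lv.d, [2.0, 1.0])
        np.testing.assert_allclose(lv.covexp, [0.8, 0.2])

    def test_reconstruction_and_orthonormality(self, rng):
        R = rng.normal(size=(12, 102))
        lv = svd_latent_variables(R)
        recon = lv.U @ np.diag(lv.d) @ lv.V.T
        assert np.abs(recon - R).max() < 1e-10
        K = lv.U.shape[1]
        np.testing.assert_allclose(lv.U.T @ lv.U, np.eye(K), atol=1e-8)
        np.testing.assert_allclose(lv.V.T @ lv.V, np.eye(K), atol=1e-8)

    def test_covexp_sums_to_one_and_survives_truncation(self, rng):
        R = rng.normal(size=(6, 9))
        full = svd_latent_variables(R)
        trunc = svd_latent_variables(R, K=2)
        assert full.covexp.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_array_equal(full.covexp, trunc.covexp)
        assert trunc.U.shape[1] == 2

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            svd_latent_variables(np.array([[1.0, np.nan]]))


class TestPermutation:
    def test_perfect_coupling_minimum_p(self, rng):
        X = _z(rng.normal(size=(60, 5)))
        p = permutation_pvalues(X, X, n_perm=500, seed=0)
        assert p[0] == pytest.approx(1 / 501)

    def test_zero_permutations_rejected(self, rng):
        X = _z(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_pvalues(X, X, n_perm=0)

    def test_deterministic_given_seed(self, rng):
        X = _z(rng.normal(size=(30, 4)))
        Y = _z(rng.normal(size=(30, 6)))
        p1 = permutation_pvalues(X, Y, n_perm=50, seed=7)
        p2 = permutation_pvalues(X, Y, n_perm=50, seed=7)
        np.testing.assert_array_equal(p1, p2)

    def test_joint_row_shuffle_preserves_decomposition(self, planted_cohort, rng):
        """Subject relabeling: permuting both blocks' rows together leaves
        the observed statistics (hence strong-signal p-values) unchanged."""
        Xz, Yz = planted_cohort["Xz"], planted_cohort["Yz"]
        perm = rng.permutation(len(Xz))
        lv_a = svd_latent_variables(cross_block_correlation(Xz, Yz))
        Xs = Xz.iloc[perm].reset_index(drop=True)
        Ys = Yz.iloc[perm].reset_index(drop=True)
        lv_b = svd_latent_variables(cross_block_correlation(Xs, Ys))
        np.testing.assert_allclose(lv_a.d, lv_b.d, atol=1e-10)
        p_a = permutation_pvalues(Xz, Yz, n_perm=200, seed=3)
        p_b = permutation_pvalues(Xs, Ys, n_perm=200, seed=3)
        assert p_a[0] == p_b[0] == pytest.approx(1 / 201)

    def test_covexp_statistic_flag(self, planted_cohort):
        # the covariance-explained fraction is a relative statistic (its
        # permutation denominator collapses), so only contract properties
        # are asserted here; rank-wise singular values are the default
        Xz, Yz = planted_cohort["Xz"], planted_cohort["Yz"]
        p = permutation_pvalues(Xz, Yz, n_perm=100, seed=1, statistic="covexp")
        assert p.shape == (min(Xz.shape[1], Yz.shape[1]),)
        assert np.all((p >= 1 / 101) & (p <= 1.0))
        np.testing.assert_array_equal(
            p, permutation_pvalues(Xz, Yz, n_perm=100, seed=1, statistic="covexp"))
        with pytest.raises(ValueError, match="statistic"):
            permutation_pvalues(Xz, Yz, n_perm=10, statistic="bogus")


class TestBootstrap:
    def test_sign_flip_invariance(self, planted_cohort):
        Xz, Yz = planted_cohort["Xz"], planted_cohort["Yz"]
        lv = svd_latent_variables(cross_block_correlation(Xz, Yz))
        b1 = bootstrap_ratios(Xz, Yz, lv, n_boot=50, seed=4)
        lv.U, lv.V = -lv.U, -lv.V
        b2 = bootstrap_ratios(Xz, Yz, lv, n_boot=50, seed=4)
        np.testing.assert_allclose(np.abs(b1[0]), np.abs(b2[0]), atol=1e-10)
        np.testing.assert_allclose(np.abs(b1[1]), np.abs(b2[1]), atol=1e-10)

    def test_too_few_resamples_rejected(self, planted_cohort):
        Xz, Yz = planted_cohort["Xz"], planted_cohort["Yz"]
        lv = svd_latent_variables(cross_block_correlation(Xz, Yz))
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_ratios(Xz, Yz, lv, n_boot=1)

    def test_planted_loadings_flagged(self, planted_cohort):
        """Variables carrying a planted loading should show reliable
        bootstrap ratios; planted-zero variables should not."""
        Xz, Yz = planted_cohort["Xz"], planted_cohort["Yz"]
        truth = planted_cohort["truth"]
        lv = pls_fit(Xz, Yz, n_perm=10, n_boot=200, seed=2)
        active = truth.U_true[:, 0] != 0
        assert lv.sig_mask_x[active, 0].mean() >= 0.9
        assert lv.sig_mask_x[~active, 0].mean() <= 0.1


class TestThreshold:
    def test_boundary(self):
        mask = threshold_bsr(np.array([1.96, 1.95, -2.5, 0.0]))
        assert mask.tolist() == [True, False, True, False]

    def test_all_zero_empty_mask(self):
        assert not threshold_bsr(np.zeros(7)).any()

    def test_matches_bruteforce_loop(self, rng):
        bsr = rng.normal(0, 2, size=(10, 3))
        crit = sps.norm.ppf(0.975)
        want = np.array([[abs(b) >= crit for b in row] for row in bsr])  # loop oracle
        np.testing.assert_array_equal(threshold_bsr(bsr), want)

    def test_alpha_validated(self):
        with pytest.raises(ValueError, match="alpha"):
            threshold_bsr(np.zeros(3), alpha=1.5)


class TestProjection:
    def test_zero_row_zero_scores(self, planted_cohort):
        Xz, Yz = planted_cohort["Xz"], planted_cohort["Yz"]
        lv = svd_latent_variables(cross_block_correlation(Xz, Yz))
        zx = pd.DataFrame(np.zeros((1, Xz.shape[1])), columns=Xz.columns)
        zy = pd.DataFrame(np.zeros((1, Yz.shape[1])), columns=Yz.columns)
        s = project_scores(zx, zy, lv)
        assert (s.score_x.to_numpy() == 0).all() and (s.score_y.to_numpy() == 0).all()

    def test_salience_row_projects_to_unit_score(self, planted_cohort):
        Xz, Yz = planted_cohort["Xz"], planted_cohort["Yz"]
        lv = svd_latent_variables(cross_block_correlation(Xz, Yz))
        row = pd.DataFrame(lv.U[:, 1][None, :], columns=Xz.columns)
        zy = pd.DataFrame(np.zeros((1, Yz.shape[1])), columns=Yz.columns)
        s = project_scores(row, zy, lv)
        want = np.zeros(lv.n_lv)
        want[1] = 1.0
        np.testing.assert_allclose(s.score_x.to_numpy()[0], want, atol=1e-10)

    def test_matches_matrix_product(self, planted_cohort, rng):
        Xz, Yz = planted_cohort["Xz"], planted_cohort["Yz"]
        lv = svd_latent_variables(cross_block_correlation(Xz, Yz))
        rows = rng.normal(size=(3, Xz.shape[1]))
        rowsy = rng.normal(size=(3, Yz.shape[1]))
        s = project_scores(pd.DataFrame(rows, columns=Xz.columns),
                           pd.DataFrame(rowsy, columns=Yz.columns), lv)
        np.testing.assert_allclose(s.score_x.to_numpy(), rows @ lv.U, atol=1e-12)
        np.testing.assert_allclose(s.score_y.to_numpy(), rowsy @ lv.V, atol=1e-12)

    def test_score_covariance_equals_singular_value(self, planted_cohort):
        """cov(score_x_k, score_y_k) = d_k links decomposition and scores."""
        Xz, Yz = planted_cohort["Xz"], planted_cohort["Yz"]
        lv = svd_latent_variables(cross_block_correlation(Xz, Yz))
        s = project_scores(Xz, Yz, lv)
        for k in range(min(4, lv.n_lv)):
            cov = np.cov(s.score_x.iloc[:, k], s.score_y.iloc[:, k], ddof=1)[0, 1]
            assert cov == pytest.approx(lv.d[k], abs=1e-8)

    def test_column_mismatch_rejected(self, planted_cohort):
        Xz, Yz = planted_cohort["Xz"], planted_cohort["Yz"]
        lv = svd_latent_variables(cross_block_correlation(Xz, Yz))
        bad = Xz.iloc[:2, :5]
        with pytest.raises(ValueError, match="mismatch|column"):
            project_scores(bad, Yz.iloc[:2], lv)


class TestRecovery:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_planted_saliences_recovered(self, seed):
        from conftest import planted_config
        from ftdpls import generate_cohort
        cfg = planted_config(seed=seed)
        cohort, truth = generate_cohort(cfg)
        pat = cohort.patients().baseline()
        Xz, _ = zscore_columns(pat.cognition())
        Yz, _ = zscore_columns(pat.brain())
        lv = svd_latent_variables(cross_block_correlation(Xz, Yz))
        for k in range(2):
            for est, true in ((lv.U[:, k], truth.U_true[:, k]),
                              (lv.V[:, k], truth.V_true[:, k])):
                assert abs(np.corrcoef(est, true)[0, 1]) >= 0.9
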