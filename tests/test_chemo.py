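"""Multivariate layer: PCA vs an eigendecomposition oracle, OSC behavior,
NIPALS PLS-DA vs an independent PLS implementation, cross-validated Q2Y and
the permutation test, S-plot and loading pseudo-spectrum."""

import numpy as np
import pytest

import wormetab as w
from wormetab import chemo


def _centered(rng, n, p):
    X = rng.normal(size=(n, p))
    return X - X.mean(axis=0)


def _two_class(n_per):
    labels = np.array(["A"] * n_per + ["B"] * n_per)
    Y, _ = w.dummy_code(labels)
    return labels, Y


class TestPca:
    def test_rank_one_matrix_first_ratio_is_one(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.normal(size=6), rng.normal(size=5))
        X -= X.mean(axis=0)
        m = w.pca(X, 1)
        assert m.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(1)
        X = _centered(rng, 20, 50)
        m = w.pca(X, 19)
        np.testing.assert_allclose(m.scores @ m.loadings.T, X, atol=1e-8)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        X = _centered(rng, 10, 10)
        m = w.pca(X, 3)
        vals, vecs = np.linalg.eigh(X.T @ X)
        order = np.argsort(vals)[::-1]
        for j in range(3):
            s = X @ vecs[:, order[j]]
            err = min(np.abs(m.scores[:, j] - s).max(),
                      np.abs(m.scores[:, j] + s).max())
            assert err < 1e-8

    def test_loadings_orthonormal_ratios_nonincreasing(self):
        rng = np.random.default_rng(3)
        m = w.pca(_centered(rng, 15, 30), 5)
        G = m.loadings.T @ m.loadings
        np.testing.assert_allclose(G, np.eye(5), atol=1e-8)
        assert (np.diff(m.explained_variance_ratio) <= 1e-12).all()

    def test_k_out_of_range(self):
        rng = np.random.default_rng(4)
        with pytest.raises(w.InputError):
            w.pca(_centered(rng, 5, 3), 5)

    def test_uncentered_rejected(self):
        with pytest.raises(w.InputError):
            w.pca(np.ones((5, 3)) + np.arange(3), 1)


class TestOsc:
    def test_removed_scores_orthogonal_to_class_matrix(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = _centered(rng, 14, 25)
            _, Y = _two_class(7)
            _, filt = w.osc_filter(X, Y, n_osc=2)
            for j in range(2):
                t = filt.removed_scores[:, j]
                assert np.abs(Y.T @ t).max() < 1e-6 * np.linalg.norm(t) * np.linalg.norm(Y)

    def test_pure_class_structure_removes_little(self):
        """X an exact function of Y: no orthogonal variation to remove."""
        rng = np.random.default_rng(6)
        labels, Y = _two_class(8)
        yc = (labels == "B").astype(float)
        X = np.outer(yc - yc.mean(), rng.normal(size=30))
        X += 1e-3 * rng.normal(size=X.shape)  # avoid exact degeneracy
        X -= X.mean(axis=0)
        q_before = w.cross_validate_q2(X, Y, 1, repeats=10, seed=0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            Xf, filt = w.osc_filter(X, Y, 1)
        q_after = w.cross_validate_q2(Xf + X.mean(axis=0), Y, 1, repeats=10, seed=0)
        assert filt.r2x_removed < 0.05
        assert abs(q_after - q_before) < 0.05

    def test_confounder_removed_and_q2_improves(self):
        """Large class-orthogonal confounder: OSC finds it and Q2Y rises."""
        wins = 0
        corr_ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, p = 20, 50
            yc = np.array([0.0] * 10 + [1.0] * 10)
            yc -= yc.mean()
            conf = rng.normal(size=n)
            conf -= conf @ yc / (yc @ yc) * yc
            X = (np.outer(yc, rng.normal(size=p))
                 + 4 * np.outer(conf, rng.normal(size=p))
                 + 0.3 * rng.normal(size=(n, p)))
            _, Y = _two_class(10)
            Xc = X - X.mean(axis=0)
            Xf, filt = w.osc_filter(Xc, Y, 1)
            t = filt.removed_scores[:, 0]
            corr_ok += abs(np.corrcoef(t, conf)[0, 1]) > 0.95
            q_before = w.cross_validate_q2(X, Y, 1, repeats=20, seed=seed)
            q_after = w.cross_validate_q2(X, Y, 1, repeats=20, seed=seed, n_osc=1)
            wins += q_after > q_before
        assert corr_ok == 10
        assert wins >= 9

    def test_never_increases_frobenius_norm(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = _centered(rng, 12, 20)
            _, Y = _two_class(6)
            Xf, filt = w.osc_filter(X, Y, 1)
            assert (Xf**2).sum() <= (X**2).sum() + 1e-9
            assert 0.0 <= filt.r2x_removed < 1.0


class TestPlsda:
    def test_separable_single_variable_r2_one(self):
        labels, Y = _two_class(5)
        X = np.zeros((10, 3))
        X[:, 1] = np.where(labels == "A", -1.0, 1.0)
        m = w.plsda_fit(X, Y, 1)
        assert m.r2y == pytest.approx(1.0, abs=1e-6)

    def test_matches_independent_pls_oracle(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(7)
        X = _centered(rng, 12, 8)
        _, Y = _two_class(6)
        m = w.plsda_fit(X, Y, 3)
        sk = PLSRegression(n_components=3, scale=False).fit(X, Y - Y.mean(axis=0))
        np.testing.assert_allclose(
            m.predict(X), sk.predict(X) + Y.mean(axis=0), atol=1e-6)

    def test_r2y_monotone_in_components(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = _centered(rng, 14, 10)
            _, Y = _two_class(7)
            r2 = [w.plsda_fit(X, Y, k).r2y for k in (1, 2, 3)]
            assert r2[0] <= r2[1] + 1e-10 <= r2[2] + 2e-10

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(8)
        X = _centered(rng, 16, 12)
        _, Y = _two_class(8)
        T = w.plsda_fit(X, Y, 4).scores
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_zero_variance_rejected(self):
        _, Y = _two_class(3)
        with pytest.raises(w.InputError):
            w.plsda_fit(np.zeros((6, 4)), Y, 1)


class TestCrossValidation:
    def test_strong_effect_crosses_q2_threshold(self, library43):
        """Fold-8 two-group study at low noise: Q2Y clears 0.5 easily."""
        d = w.StudyDesign(groups=[("CON", 10), ("T", 10)],
                          effects={"betaine": {"T": 8.0}, "alanine": {"T": 8.0}},
                          noise_sd=0.2, seed=11)
        sset, _ = w.simulate_study(library43, d)
        fm = w.pqn_normalize(w.adaptive_bin(w.exclude_region(sset, 4.70, 5.25)))
        Y, _ = w.dummy_code(fm.group_labels())
        assert w.cross_validate_q2(fm.X, Y, 1, repeats=20, seed=0) > 0.5

    def test_random_labels_on_noise_q2_near_zero(self):
        q2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(16, 60))
            _, Y = _two_class(8)
            q2s.append(w.cross_validate_q2(X, Y, 1, repeats=7, seed=seed))
        assert np.mean(q2s) <= 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 30))
        _, Y = _two_class(6)
        a = w.cross_validate_q2(X, Y, 2, repeats=10, seed=5)
        b = w.cross_validate_q2(X, Y, 2, repeats=10, seed=5)
        assert a == b

    def test_group_smaller_than_folds_rejected(self):
        X = np.zeros((4, 3))
        Y, _ = w.dummy_code(np.array(["A", "A", "A", "B"]))
        with pytest.raises(w.InputError):
            w.cross_validate_q2(X + np.random.default_rng(0).normal(size=X.shape),
                                Y, 1, folds=2)

    def test_q2_not_above_r2(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(14, 20))
            X[:7] += 1.0
            _, Y = _two_class(7)
            Xc = X - X.mean(axis=0)
            r2 = w.plsda_fit(Xc, Y, 1).r2y
            q2 = w.cross_validate_q2(X, Y, 1, repeats=10, seed=seed)
            assert q2 <= r2 + 1e-9


class TestPermutationTest:
    def test_single_permutation_edge(self):
        """n_perm=1 with a null >= observed gives p = 1."""
        rng = np.random.default_rng(10)
        X = rng.normal(size=(8, 10))
        _, Y = _two_class(4)
        val = w.permutation_test(X, Y, 1, n_perm=1, seed=0, cv_repeats=3,
                                 perm_repeats=3)
        assert val.p_perm in (0.5, 1.0)
        assert val.null_stats.shape == (1,)

    def test_small_floor(self):
        """Complete separation: observed beats all 99 permutations."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 30))
        X[:10, :5] += 4.0
        _, Y = _two_class(10)
        val = w.permutation_test(X, Y, 1, n_perm=99, seed=1, cv_repeats=7)
        assert val.p_perm == pytest.approx(1 / 100)
        assert (val.null_stats < val.observed_stat).all()

    def test_p_formula(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(12, 15))
        _, Y = _two_class(6)
        val = w.permutation_test(X, Y, 1, n_perm=49, seed=2, cv_repeats=3,
                                 perm_repeats=3)
        b = int(np.count_nonzero(val.null_stats >= val.observed_stat))
        assert val.p_perm == pytest.approx((1 + b) / 50)


class TestSplotAndLoading:
    def _fit(self, seed=13, n=10, p=12):
        rng = np.random.default_rng(seed)
        X = _centered(rng, 2 * n, p)
        _, Y = _two_class(n)
        X[:, 0] += np.where(np.arange(2 * n) < n, -1.0, 1.0)
        X -= X.mean(axis=0)
        return w.plsda_fit(X, Y, 1), X

    def test_feature_equal_to_score_has_corr_one(self):
        model, X = self._fit()
        X2 = np.column_stack([X, model.scores[:, 0]])
        sp = w.splot(model, X2)
        assert sp["correlation"].iloc[-1] == pytest.approx(1.0, abs=1e-10)

    def test_cov_corr_same_sign(self):
        model, X = self._fit()
        sp = w.splot(model, X)
        nz = sp["correlation"] != 0
        assert (np.sign(sp.loc[nz, "covariance"])
                == np.sign(sp.loc[nz, "correlation"])).all()

    def test_zero_variance_feature_warns(self):
        model, X = self._fit()
        X2 = np.column_stack([X, np.zeros(X.shape[0])])
        with pytest.warns(RuntimeWarning):
            sp = w.splot(model, X2)
        assert sp["correlation"].iloc[-1] == 0.0

    def test_noise_feature_correlation_small(self):
        model, X = self._fit(n=25, p=5)
        rng = np.random.default_rng(99)
        X2 = np.column_stack([X, rng.normal(size=X.shape[0])])
        sp = w.splot(model, X2)
        assert abs(sp["correlation"].iloc[-1]) < 0.4

    def test_critical_r_value(self):
        # n=10, alpha=0.05: t(0.975, 8) = 2.306 -> |r| = 0.632
        assert chemo.pearson_critical_r(10, 0.05) == pytest.approx(0.632, abs=5e-4)

    def test_loading_windows_and_flags(self):
        model, X = self._fit()
        ppm = np.linspace(0.5, 9.0, X.shape[1])
        df = w.correlation_loading_plot(model, X, ppm)
        assert not ((df.ppm > 4.3) & (df.ppm < 5.7)).any()
        flagged = df[df.significant]
        assert (flagged.abs_correlation > df.attrs["critical_r"]).all()

    def test_too_few_samples_rejected(self):
        model, X = self._fit()
        with pytest.raises(w.InputError):
            w.correlation_loading_plot(model, X[:3], np.linspace(1, 2, X.shape[1]))
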