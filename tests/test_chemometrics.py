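"""PCA, interclass Monte-Carlo test, OPLS fitting/validation, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from omicsweave import chemometrics as chem


def rank1_data(n=20, p=8, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([-1.0, 1.0] * (n // 2))
    v = rng.standard_normal(p)
    return y[:, None] * v[None, :], y


class TestPCA:
    def test_rank1_explains_everything_on_first_axis(self):
        X, _ = rank1_data()
        m = chem.fit_pca(X)
        assert m.explained_variance_ratio[0] == pytest.approx(1.0)
        assert np.all(m.explained_variance_ratio[1:] < 1e-12)

    def test_duplicate_rows_give_duplicate_scores(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.standard_normal((5, 4))] * 2)
        m = chem.fit_pca(X)
        assert np.allclose(m.scores.iloc[:5], m.scores.iloc[5:])

    def test_scores_covariance_matches_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 5))
        m = chem.fit_pca(X)
        cov = np.cov(m.scores.to_numpy(), rowvar=False)
        # independent oracle: eigenvalues of the sample covariance
        eig = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        assert np.allclose(np.diag(cov), eig, atol=1e-10)
        assert np.allclose(cov - np.diag(np.diag(cov)), 0, atol=1e-10)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((8, 5))
        m = chem.fit_pca(X, scale_mode="uv")
        assert np.allclose(m.reconstruct(), X, atol=1e-8)

    def test_constant_variable_under_uv_errors_with_name(self):
        X = pd.DataFrame({"ok": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="flat"):
            chem.fit_pca(X, scale_mode="uv")


class TestInterclassPCA:
    def test_statistic_is_an_inertia_fraction(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((12, 4))
        labels = ["a"] * 6 + ["b"] * 6
        res = chem.interclass_pca_test(X, labels, n_perm=49, seed=0)
        assert 0.0 <= res.statistic <= 1.0
        assert np.all((res.permuted >= 0) & (res.permuted <= 1))

    def test_maximal_separation_reaches_minimum_p(self):
        rng = np.random.default_rng(1)
        block = rng.standard_normal((10, 5))
        X = np.vstack([block, block + 50.0])
        labels = ["T0"] * 10 + ["T1"] * 10
        res = chem.interclass_pca_test(X, labels, n_perm=999, seed=4)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(2)
        rejections = 0
        for i in range(200):
            X = rng.standard_normal((16, 5))
            labels = np.array(["a", "b"] * 8)
            res = chem.interclass_pca_test(X, labels, n_perm=99, seed=i)
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / 200 <= 0.09

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            chem.interclass_pca_test(np.eye(4), ["a"] * 4, n_perm=9)


class TestOPLSFit:
    def test_noiseless_rank1_signal_is_fit_perfectly(self):
        X, y = rank1_data()
        res = chem.fit_opls(X, y, n_ortho=0, scale=None)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)
        cv = chem.cross_validate(X, y, n_ortho=0, scale=None, k=10, seed=0)
        assert cv.rmsep < 1e-6
        assert cv.q2 == pytest.approx(1.0, abs=1e-10)

    def test_zero_ortho_equals_single_component_pls(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, 6))
        y = np.array([-1.0, 1.0] * 10)
        res = chem.fit_opls(X, y, n_ortho=0, scale=None)
        # closed form: PLS1 weight is proportional to X'y
        Xc = X - X.mean(axis=0)
        w_ref = Xc.T @ (y - y.mean())
        w_ref = w_ref / np.linalg.norm(w_ref)
        assert np.allclose(res.components.w, w_ref * np.sign(w_ref @ res.components.w),
                           atol=1e-8)
        # independent implementation: scikit-learn's NIPALS PLS
        skl = PLSRegression(n_components=1, scale=False).fit(Xc, y - y.mean())
        w_skl = skl.x_weights_[:, 0]
        assert np.allclose(res.components.w, w_skl * np.sign(w_skl @ res.components.w),
                           atol=1e-8)

    def test_orthogonal_scores_uncorrelated_with_y(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 10))
        y = np.array([-1.0, 1.0] * 15)
        res = chem.fit_opls(X, y, n_ortho=2)
        for k in range(res.components.T_o.shape[1]):
            assert abs(np.corrcoef(res.components.T_o[:, k], y)[0, 1]) < 1e-8

    def test_confound_removed_leaves_predictive_loadings_unchanged(self):
        rng = np.random.default_rng(7)
        n, p = 20, 10
        y = np.array([-1.0, 1.0] * (n // 2))
        t_c = rng.standard_normal(n)
        t_c -= t_c @ y / (y @ y) * y          # confound scores orthogonal to y
        t_c -= t_c.mean()
        v = rng.standard_normal(p)
        c = rng.standard_normal(p)
        c -= c @ v / (v @ v) * v              # confound loadings orthogonal to v
        X0 = np.outer(y, v)
        X = X0 + 3.0 * np.outer(t_c, c)
        base = chem.fit_opls(X0, y, n_ortho=0, scale=None)
        osc = chem.fit_opls(X, y, n_ortho=1, scale=None)
        assert np.allclose(base.components.p, osc.components.p, atol=1e-6)

    def test_osc_never_reduces_predictive_r2(self):
        rng = np.random.default_rng(8)
        n, p = 24, 12
        y = np.array([-1.0, 1.0] * (n // 2))
        X = 0.8 * np.outer(y, rng.standard_normal(p)) + rng.standard_normal((n, p))
        conf = 4.0 * np.outer(rng.standard_normal(n), rng.standard_normal(p))
        X = X + conf - conf.mean(axis=0)
        r2_plain = chem.fit_opls(X, y, n_ortho=0).r2
        r2_osc = chem.fit_opls(X, y, n_ortho=1).r2
        assert r2_osc >= r2_plain - 1e-12

    def test_permuted_y_usually_fits_worse(self):
        rng = np.random.default_rng(9)
        n, p = 20, 15
        y = np.array([-1.0, 1.0] * (n // 2))
        X = rng.standard_normal((n, p))
        X[:, :5] += 1.5 * y[:, None]
        obs = chem.fit_opls(X, y).r2
        worse = 0
        for _ in range(100):
            yp = y[rng.permutation(n)]
            worse += chem.fit_opls(X, yp).r2 < obs
        assert worse >= 95

    def test_n_ortho_at_rank_errors(self):
        X, y = rank1_data()
        with pytest.raises(ValueError, match="rank"):
            chem.fit_opls(X, y, n_ortho=1, scale=None)


class TestCrossValidation:
    def test_q2_matches_independent_press_computation(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((20, 8))
        y = np.array([-1.0, 1.0] * 10)
        cv = chem.cross_validate(X, y, seed=0)
        press = float(((y - cv.predictions.to_numpy()) ** 2).sum())
        tss = float(((y - y.mean()) ** 2).sum())
        assert cv.q2 == pytest.approx(1 - press / tss, abs=1e-12)
        assert cv.rmsep == pytest.approx(np.sqrt(press / len(y)), abs=1e-12)

    def test_null_q2_is_negative_on_average(self):
        rng = np.random.default_rng(11)
        q2s = []
        for s in range(50):
            X = rng.standard_normal((20, 15))
            y = np.array([-1.0, 1.0] * 10)
            q2s.append(chem.cross_validate(X, y, seed=s).q2)
        assert np.mean(q2s) <= 0

    def test_k_larger_than_n_rejected(self):
        X, y = rank1_data(n=6)
        with pytest.raises(ValueError):
            chem.cross_validate(X, y, k=10)


class TestPermutationValidation:
    def test_planted_effect_reaches_minimal_p(self):
        rng = np.random.default_rng(12)
        n, p = 20, 10
        y = np.array([-1.0, 1.0] * (n // 2))
        X = rng.standard_normal((n, p))
        X[:, :4] += 3.0 * y[:, None] / 2     # standardized delta = 3
        res = chem.permutation_validate(X, y, n=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.permuted.shape == (999, 3)

    def test_summary_reports_mean_and_sd(self):
        X, y = rank1_data(n=12, p=4, seed=3)
        X = X + np.random.default_rng(0).normal(0, 0.1, X.shape)
        res = chem.permutation_validate(X, y, n=19, seed=1)
        text = res.summary()
        assert "±" in text and "Q2" in text


class TestVariableSelection:
    def test_planted_discriminants_recovered(self):
        recalls, fps = [], []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            n = 40
            y = np.array([-1.0, 1.0] * (n // 2))
            X = rng.standard_normal((n, 40))
            X[:, :5] += 1.5 * y[:, None] / 2
            res = chem.fit_opls(X, y, n_ortho=1)
            res.cross_validate(k=10, seed=s)
            sel = chem.select_discriminant_variables(res)
            chosen = set(np.flatnonzero(sel["selected"].to_numpy()))
            recalls.append(len(chosen & set(range(5))))
            fps.append(len(chosen - set(range(5))))
        assert np.median(recalls) == 5
        assert np.median(fps) <= 1

    def test_no_signal_variable_never_selected(self):
        missed = 0
        for s in range(50):
            rng = np.random.default_rng(200 + s)
            n = 20
            y = np.array([-1.0, 1.0] * (n // 2))
            X = rng.standard_normal((n, 10))
            X[:, :3] += 2.0 * y[:, None]
            flat = np.tile(rng.standard_normal(10), 2)[: n // 2]
            X[:, 9] = np.repeat(flat, 2)      # identical across classes by pairs
            res = chem.fit_opls(X, y)
            res.cross_validate(k=10, seed=s)
            sel = chem.select_discriminant_variables(res)
            missed += bool(sel["selected"].iloc[9])
        assert missed == 0

    def test_selection_invariant_to_variable_order(self):
        rng = np.random.default_rng(13)
        n = 20
        y = np.array([-1.0, 1.0] * (n // 2))
        X = pd.DataFrame(rng.standard_normal((n, 6)),
                         columns=[f"v{j}" for j in range(6)])
        X["v0"] += 2.0 * y
        perm_cols = ["v3", "v0", "v5", "v1", "v4", "v2"]
        out1 = {}
        for cols in (list(X.columns), perm_cols):
            res = chem.fit_opls(X[cols], y)
            res.cross_validate(k=10, seed=9)
            sel = chem.select_discriminant_variables(res)
            out1[tuple(cols)] = sel["selected"].sort_index()
        a, b = out1.values()
        pd.testing.assert_series_equal(a, b)

    def test_requires_stored_cv_rounds(self):
        X, y = rank1_data()
        res = chem.fit_opls(X, y, n_ortho=0, scale=None)
        with pytest.raises(ValueError, match="CV"):
            chem.select_discriminant_variables(res)


class TestAnovaBonferroni:
    def test_two_group_f_equals_squared_t(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.standard_normal((16, 5)))
        labels = np.array(["a"] * 8 + ["b"] * 8)
        out = chem.anova_bonferroni(X, labels)
        for j, col in enumerate(X.columns):
            t, _ = stats.ttest_ind(X[col][labels == "a"], X[col][labels == "b"])
            assert out["F"].iloc[j] == pytest.approx(t**2, abs=1e-10)

    def test_bonferroni_multiplies_by_m(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.standard_normal((10, 54)))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        out = chem.anova_bonferroni(X, labels)
        assert np.allclose(out["p_corrected"], np.minimum(1.0, out["p"] * 54))

    def test_single_peak_corrected_equals_raw(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 7, 8, 9]})
        out = chem.anova_bonferroni(X, np.array(["x"] * 3 + ["y"] * 3))
        assert out["p_corrected"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_zero_within_group_variance_flagged(self):
        X = pd.DataFrame({"a": [1.0, 1, 1, 2, 2, 2]})
        out = chem.anova_bonferroni(X, np.array(["x"] * 3 + ["y"] * 3))
        assert out["degenerate"].iloc[0]
        assert out["p"].iloc[0] == 0.0
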