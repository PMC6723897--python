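"""PLS calibration, PCA, cross-validation and metrics."""

import numpy as np
import pytest

from dissosurrogate.composition import (contiguous_block_cv, metrics, pca,
                                        pls_fit, predict_composition,
                                        select_n_lv)
from dissosurrogate.preprocess import DEFAULT_RECIPES, SpectrumSet, apply_recipe


class TestPlsFit:
    def test_exact_recovery_of_linear_response(self, rng):
        X = rng.normal(size=(20, 5))
        beta = np.array([1.0, -2.0, 0.5, 3.0, 0.0])
        y = X @ beta + 4.0
        model = pls_fit(X, y, n_lv=5)
        rmsec = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rmsec < 1e-8

    def test_full_rank_pls_equals_ols_oracle(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ np.array([2.0, -1.0, 0.3, 1.5]) + rng.normal(size=30)
        model = pls_fit(X, y, n_lv=4)
        # independent oracle: ordinary least squares with intercept
        A = np.column_stack([np.ones(30), X])
        coef = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), A @ coef, atol=1e-6)

    def test_sample_permutation_invariance(self, rng):
        X = rng.normal(size=(25, 8))
        y = X[:, 0] - X[:, 3] + 0.1 * rng.normal(size=25)
        m1 = pls_fit(X, y, 3)
        perm = rng.permutation(25)
        m2 = pls_fit(X[perm], y[perm], 3)
        np.testing.assert_allclose(m1.coef, m2.coef, atol=1e-10)

    def test_matches_sklearn_reference(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(40, 12))
        y = X[:, 2] + 0.5 * X[:, 7] + 0.05 * rng.normal(size=40)
        ours = pls_fit(X, y, 3)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        np.testing.assert_allclose(ours.predict(X),
                                   ref.predict(X).ravel(), atol=1e-8)

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            pls_fit(rng.normal(size=(10, 3)), np.full(10, 2.0), 1)


class TestPca:
    def test_rank_one_explains_everything(self, rng):
        u = rng.normal(size=12)
        v = rng.normal(size=7)
        X = np.outer(u, v)
        scores, loadings, ev = pca(X, 1)
        assert ev[0] == pytest.approx(1.0, abs=1e-10)

    def test_scores_orthogonal_and_loadings_orthonormal(self, rng):
        X = rng.normal(size=(15, 10))
        X -= X.mean(axis=0)
        scores, loadings, ev = pca(X, 4)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8
        np.testing.assert_allclose(loadings.T @ loadings, np.eye(4), atol=1e-8)
        assert np.all(np.diff(ev) <= 1e-10)

    def test_agrees_with_svd_oracle(self, rng):
        X = rng.normal(size=(10, 20))
        X -= X.mean(axis=0)
        scores, loadings, ev = pca(X, 3)
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        for a in range(3):
            sign = np.sign(loadings[:, a] @ Vt[a])
            np.testing.assert_allclose(loadings[:, a], sign * Vt[a], atol=1e-7)
            np.testing.assert_allclose(scores[:, a], sign * U[:, a] * S[a],
                                       atol=1e-6)
        np.testing.assert_allclose(ev, S[:3] ** 2 / np.sum(S ** 2), atol=1e-9)

    def test_n_pc_beyond_rank_rejected(self, rng):
        u = rng.normal(size=8)
        X = np.outer(u, rng.normal(size=5))
        with pytest.raises(ValueError, match="rank"):
            pca(X, 3)


class TestContiguousBlockCV:
    def test_even_block_sizes(self):
        blocks = np.array_split(np.arange(120), 30)
        assert all(len(b) == 4 for b in blocks)

    def test_remainder_rule_31_samples(self, rng):
        # 31 samples in 30 splits: one block of 2, twenty-nine singletons
        X = rng.normal(size=(31, 3))
        y = X @ np.ones(3) + rng.normal(size=31)
        rmsecv, r2cv = contiguous_block_cv(X, y, 2, n_splits=30)
        assert rmsecv.shape == (2,)
        sizes = sorted(len(b) for b in np.array_split(np.arange(31), 30))
        assert sizes == [1] * 29 + [2]

    def test_noise_free_linear_data_cross_validates_exactly(self, rng):
        X = rng.normal(size=(60, 6))
        y = X @ np.array([1.0, 2.0, -1.0, 0.5, 0.0, 3.0])
        rmsecv, r2cv = contiguous_block_cv(X, y, 6, n_splits=30)
        assert rmsecv[-1] < 1e-6
        assert r2cv[-1] > 1 - 1e-12

    def test_rmsecv_invariant_to_consistent_channel_permutation(self, rng):
        X = rng.normal(size=(40, 10))
        y = X[:, 1] + rng.normal(size=40)
        a, _ = contiguous_block_cv(X, y, 3, n_splits=10)
        perm = rng.permutation(10)
        b, _ = contiguous_block_cv(X[:, perm], y, 3, n_splits=10)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_too_few_splits_rejected(self, rng):
        with pytest.raises(ValueError):
            contiguous_block_cv(rng.normal(size=(10, 2)), rng.normal(size=10),
                                1, n_splits=1)


class TestMetrics:
    def test_perfect_and_mean_predictors(self, rng):
        X = rng.normal(size=(10, 3))
        y = X @ np.ones(3) + 5.0
        model = pls_fit(X, y, 3)
        mt = metrics(model, X, y, X, y)
        assert mt.rmsec == pytest.approx(0.0, abs=1e-8)
        assert mt.r2c == pytest.approx(1.0, abs=1e-10)
        # a model predicting the training mean everywhere has R^2 = 0
        resid = y - y.mean()
        r2 = 1.0 - np.sum(resid ** 2) / np.sum(resid ** 2)
        assert r2 == 0.0

    def test_hand_computed_four_sample_fixture(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.array([1.5, 1.5, 3.5, 3.5])
        rmse = np.sqrt(np.mean((yhat - y) ** 2))
        assert rmse == pytest.approx(0.5, abs=1e-12)
        r2 = 1 - np.sum((yhat - y) ** 2) / np.sum((y - 2.5) ** 2)
        assert r2 == pytest.approx(1 - 1.0 / 5.0, abs=1e-12)

    def test_empty_test_set_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        y = X @ np.ones(3) + rng.normal(size=10)
        model = pls_fit(X, y, 2)
        with pytest.raises(ValueError):
            metrics(model, X, y, X[:0], y[:0])


class TestPredictComposition:
    def test_training_spectrum_reproduces_fitted_value(self, rng):
        X = rng.normal(size=(20, 30))
        y = X[:, 5] + 10.0
        wn = np.arange(30.0)
        model = pls_fit(X, y, 2, wavenumbers=wn)
        s = SpectrumSet(wavenumbers=wn, intensities=X[:1], sample_ids=("t",))
        assert predict_composition(model, s)[0] == pytest.approx(
            model.predict(X[:1])[0], abs=1e-12)

    def test_grid_mismatch_rejected(self, rng):
        X = rng.normal(size=(20, 30))
        model = pls_fit(X, X[:, 0] + 1.0, 2, wavenumbers=np.arange(30.0))
        s = SpectrumSet(wavenumbers=np.arange(30.0) + 0.5, intensities=X[:1],
                        sample_ids=("t",))
        with pytest.raises(ValueError, match="grid"):
            predict_composition(model, s)


def _calibrate(dataset, modality, analyte):
    y = np.array([getattr(tb, f"{analyte}_true") for tb in dataset.tablets])
    tr, te = dataset.train_mask, dataset.test_mask
    s = dataset.spectra[modality]
    ftr, state = apply_recipe(s.subset(tr), DEFAULT_RECIPES[modality])
    fte, _ = apply_recipe(s.subset(te), DEFAULT_RECIPES[modality], state)
    rmsecv, _ = contiguous_block_cv(ftr.intensities, y[tr], 6, n_splits=30)
    model = pls_fit(ftr.intensities, y[tr], select_n_lv(rmsecv),
                    analyte=analyte, wavenumbers=ftr.wavenumbers)
    pred = predict_composition(model, fte)
    return float(np.sqrt(np.mean((pred - y[te]) ** 2)))


class TestModalityRanking:
    """Prediction quality must rank as in the underlying study: transmission
    beats reflection, Raman is best for the drug and NIR for the polymer."""

    def test_dr_raman_transmission_beats_reflection(self, dataset):
        assert _calibrate(dataset, "raman_trans", "dr") < \
            _calibrate(dataset, "raman_refl", "dr")

    def test_hpmc_nir_transmission_is_best_of_all_modalities(self, dataset):
        rmseps = {m: _calibrate(dataset, m, "hpmc")
                  for m in ("raman_trans", "raman_refl", "nir_trans", "nir_refl")}
        assert min(rmseps, key=rmseps.get) == "nir_trans"

    def test_rmsep_decreases_with_simulator_noise(self):
        """Parameter recovery: less spectral noise, better composition recovery."""
        from dissosurrogate.synthetic import SimulatorConfig, generate_dataset
        import dataclasses
        results = {"dr": [], "hpmc": []}
        for scale in (4.0, 1.0, 0.25):
            cfg = SimulatorConfig(seed=31, noise_scale=scale)
            data = generate_dataset(cfg)
            results["dr"].append(_calibrate(data, "raman_trans", "dr"))
            results["hpmc"].append(_calibrate(data, "raman_trans", "hpmc"))
        for analyte, vals in results.items():
            assert vals[0] > vals[1] > vals[2], (analyte, vals)
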