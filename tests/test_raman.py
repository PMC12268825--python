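"""Spectral preprocessing and PLS-DA contracts."""

import numpy as np
import pytest

from fibroscar.raman import (
    PLSDA,
    RamanPreprocessConfig,
    als_baseline,
    despike_spectrum,
    loo_cross_validate,
    multiclass_metrics,
    preprocess_spectra,
    vector_normalize,
)
from fibroscar.synthetic.raman import RamanSpectrumSet, generate_raman_set
from fibroscar.tissue import CLASS_ORDER, TissueClass


class TestPreprocessing:
    def test_linear_baseline_removed(self):
        """A pure straight-line baseline is flattened to well under 1e-3 of
        its slope amplitude."""
        x = np.linspace(0, 1, 400)
        baseline = 5.0 * x
        resid = baseline - als_baseline(baseline, lam=1e5, p=0.01)
        assert np.abs(resid).max() < 1e-3 * 5.0

    def test_unit_norm_after_chain(self):
        sset = generate_raman_set(3, seed=0)
        out = preprocess_spectra(sset)
        norms = np.linalg.norm(out.intensities, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_spike_removed_others_untouched(self):
        rng = np.random.default_rng(0)
        y = 1.0 + 0.01 * rng.normal(size=300)
        y_spiked = y.copy()
        y_spiked[150] *= 100.0
        out = despike_spectrum(y_spiked)
        assert abs(out[150] - 1.0) < 0.1
        others = np.delete(np.arange(300), 150)
        np.testing.assert_allclose(out[others], y_spiked[others], rtol=0.01)

    def test_zero_spectrum_normalization_rejected(self):
        with pytest.raises(ValueError):
            vector_normalize(np.zeros(10))

    def test_steps_switchable(self):
        sset = generate_raman_set(2, seed=1)
        cfg = RamanPreprocessConfig(despike=False, baseline=False,
                                    smooth=False, normalize=False)
        out = preprocess_spectra(sset, cfg)
        np.testing.assert_array_equal(out.intensities, sset.intensities)


def _two_class_set(n=10, n_chan=50, informative=20, delta=1.0):
    X = np.zeros((2 * n, n_chan))
    X[n:, informative] = delta
    labels = ([TissueClass.HEALTHY] * n) + ([TissueClass.FIBROTIC] * n)
    return X, labels


class TestPLSDAFit:
    def test_single_discriminative_channel_dominates_lv1(self):
        X, labels = _two_class_set()
        res = PLSDA(X, labels, n_components=1).fit()
        w = np.abs(res.weights[:, 0])
        assert np.argmax(w) == 20
        others = np.delete(w, 20)
        assert others.max() < 1e-6 * w[20]

    def test_k1_scores_single_column(self):
        X, labels = _two_class_set()
        res = PLSDA(X, labels, n_components=1).fit()
        assert res.scores.shape[1] == 1

    def test_score_orthogonality_default_set(self):
        sset = preprocess_spectra(generate_raman_set(20, seed=2))
        res = PLSDA.from_spectrum_set(sset, 4).fit()
        G = res.scores.T @ res.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_x_residual_norm_monotone_decreasing(self):
        sset = preprocess_spectra(generate_raman_set(15, seed=3))
        res = PLSDA.from_spectrum_set(sset, 4).fit()
        assert np.all(np.diff(res.x_residual_norms) <= 1e-9)

    def test_matches_svd_deflation_oracle(self):
        """Each NIPALS weight vector equals the dominant left singular
        vector of the deflated cross-covariance Xd'Yd (up to sign)."""
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (30, 12))
        labels = [CLASS_ORDER[i % 4] for i in range(30)]
        res = PLSDA(X, labels, n_components=3).fit()
        Y = np.zeros((30, 4))
        for i, lab in enumerate(labels):
            Y[i, CLASS_ORDER.index(lab)] = 1.0
        Xd = X - X.mean(axis=0)
        Yd = Y - Y.mean(axis=0)
        for a in range(3):
            w_ref = np.linalg.svd(Xd.T @ Yd, full_matrices=False)[0][:, 0]
            w = res.weights[:, a]
            sign = np.sign(w @ w_ref)
            np.testing.assert_allclose(w, sign * w_ref, atol=1e-8)
            t = Xd @ w_ref
            Xd = Xd - np.outer(t, Xd.T @ t / (t @ t))
            Yd = Yd - np.outer(t, Yd.T @ t / (t @ t))

    def test_matches_sklearn_pls_cross_check(self):
        """Scores agree with sklearn's independent PLS2 implementation to
        within its iterative convergence tolerance (per-component sign)."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (30, 12))
        labels = [CLASS_ORDER[i % 4] for i in range(30)]
        res = PLSDA(X, labels, n_components=3).fit()
        Y = np.zeros((30, 4))
        for i, lab in enumerate(labels):
            Y[i, CLASS_ORDER.index(lab)] = 1.0
        ref = PLSRegression(n_components=3, scale=False, tol=1e-10,
                            max_iter=5000).fit(X, Y)
        for a in range(3):
            t_mine = res.scores[:, a]
            t_ref = ref.x_scores_[:, a]
            sign = np.sign(t_mine @ t_ref)
            np.testing.assert_allclose(t_mine, sign * t_ref, atol=1e-3)

    def test_single_class_rejected(self):
        X = np.zeros((5, 10))
        with pytest.raises(ValueError):
            PLSDA(X, [TissueClass.HEALTHY] * 5, 1)

    def test_k_too_large_rejected(self):
        X, labels = _two_class_set(n=3)
        with pytest.raises(ValueError):
            PLSDA(X, labels, n_components=10)


def _four_class_fixture(seed):
    """Each class lights up its own block of 5 channels."""
    rng = np.random.default_rng(seed)
    blocks = []
    for k in range(4):
        block = rng.normal(0, 0.05, (8, 20))
        block[:, 5 * k:5 * k + 5] += 3.0
        blocks.append(block)
    labels = sum(([c] * 8 for c in CLASS_ORDER), [])
    return np.concatenate(blocks), labels


class TestPLSDAPredict:
    def test_separable_fixture_fully_correct(self):
        X, labels = _four_class_fixture(5)
        res = PLSDA(X, labels, 4).fit()
        assert res.predict(X) == labels

    def test_class_mean_maps_to_class(self):
        X, labels = _four_class_fixture(6)
        res = PLSDA(X, labels, 4).fit()
        for k, cls in enumerate(CLASS_ORDER):
            mean_spec = X[8 * k:8 * (k + 1)].mean(axis=0)
            assert res.predict(mean_spec[None, :])[0] is cls

    def test_zero_spectrum_predicts_largest_intercept_class(self):
        X, labels = _two_class_set(n=4)
        res = PLSDA(X, labels, 1).fit()
        pred = res.predict(np.zeros((1, X.shape[1])))[0]
        yhat = res.predict_indicator(np.zeros((1, X.shape[1])))[0]
        assert pred is CLASS_ORDER[int(np.argmax(yhat))]

    def test_channel_mismatch_rejected(self):
        X, labels = _two_class_set()
        res = PLSDA(X, labels, 1).fit()
        with pytest.raises(ValueError):
            res.predict(np.zeros((1, 7)))


class TestSubspaceStability:
    def test_class_relabelling_preserves_lv12_subspace(self):
        """Consistently permuting class labels permutes Y columns only, so
        the (LV1, LV2) subspace is unchanged (principal-angle check)."""
        sset = preprocess_spectra(generate_raman_set(15, seed=7))
        res1 = PLSDA.from_spectrum_set(sset, 2).fit()
        perm = {TissueClass.HEALTHY: TissueClass.FIBROTIC,
                TissueClass.FIBROTIC: TissueClass.HEALTHY,
                TissueClass.NECROTIC: TissueClass.GRANULATED,
                TissueClass.GRANULATED: TissueClass.NECROTIC}
        relabelled = [perm[lab] for lab in sset.labels]
        res2 = PLSDA(sset.intensities, relabelled, 2).fit()
        s = np.linalg.svd(
            np.linalg.qr(res1.weights)[0].T @ np.linalg.qr(res2.weights)[0],
            compute_uv=False)
        assert np.all(s > 1 - 1e-6)  # cos of principal angles ~ 1


class TestMulticlassMetrics:
    def test_perfect_predictions(self):
        labels = sum(([c] * 5 for c in CLASS_ORDER), [])
        rep = multiclass_metrics(labels, labels)
        np.testing.assert_allclose(rep.sensitivity, 1.0)
        np.testing.assert_allclose(rep.specificity, 1.0)

    def test_single_offdiagonal_error_arithmetic(self):
        truth = sum(([c] * 9 for c in CLASS_ORDER), []) + [TissueClass.HEALTHY]
        preds = sum(([c] * 9 for c in CLASS_ORDER), []) + [TissueClass.NECROTIC]
        rep = multiclass_metrics(preds, truth)
        # muscle: 9 of 10 correct
        assert rep.sensitivity[0] == pytest.approx(0.9)
        # necrotic: 1 false positive out of 28 non-necrotic truths
        assert rep.specificity[1] == pytest.approx(27 / 28)
        # row sums = truth counts
        np.testing.assert_array_equal(rep.confusion.sum(axis=1), [10, 9, 9, 9])

    def test_constant_predictor(self):
        truth = sum(([c] * 5 for c in CLASS_ORDER), [])
        preds = [TissueClass.HEALTHY] * 20
        rep = multiclass_metrics(preds, truth)
        assert rep.sensitivity[0] == 1.0
        assert rep.specificity[0] == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            multiclass_metrics([TissueClass.HEALTHY], [])


def test_loo_on_small_default_set_is_accurate():
    sset = preprocess_spectra(generate_raman_set(15, seed=8))
    rep = loo_cross_validate(sset, 4)
    assert rep.macro_sensitivity >= 0.9
    assert rep.macro_specificity >= 0.9
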