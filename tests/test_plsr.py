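"""Kernel PLS1: agreement with NIPALS and least squares, CV, beta attribution."""

import numpy as np
import pytest

from neuroftir import pipeline, preprocess as pp, synth
from neuroftir.plsr import CVScheme, beta_peaks, cross_validate, fit_pls


def nipals_pls1(X, y, n_factors):
    """Independent NIPALS oracle with explicit X deflation."""
    X = np.asarray(X, float).copy()
    y = np.asarray(y, float).ravel().copy()
    x_mean, y_mean = X.mean(axis=0), y.mean()
    E = X - x_mean
    f = y - y_mean
    W, T, P, q = [], [], [], []
    for _ in range(n_factors):
        w = E.T @ f
        w = w / np.linalg.norm(w)
        t = E @ w
        tt = t @ t
        p = E.T @ t / tt
        qk = f @ t / tt
        E = E - np.outer(t, p)
        f = f - qk * t
        W.append(w)
        T.append(t)
        P.append(p)
        q.append(qk)
    W, T, P = np.column_stack(W), np.column_stack(T), np.column_stack(P)
    q = np.asarray(q)
    B = W @ np.linalg.inv(P.T @ W) @ np.diag(q)
    B = np.cumsum(B, axis=1)  # column k-1: coefficients with k factors
    return W, T, P, q, B, x_mean, y_mean


@pytest.fixture()
def random_problem(rng):
    X = rng.normal(size=(12, 30))
    y = X @ rng.normal(size=30) + rng.normal(scale=0.1, size=12)
    return X, y


class TestFitPLS:
    def test_matches_nipals_oracle_up_to_sign(self, random_problem):
        X, y = random_problem
        model = fit_pls(X, y, 3)
        W, T, P, q, B, _, _ = nipals_pls1(X, y, 3)
        for k in range(3):
            s = np.sign(W[:, k] @ model.W[:, k])
            assert abs(s) == 1
            np.testing.assert_allclose(model.W[:, k], s * W[:, k], atol=1e-8)
            np.testing.assert_allclose(model.T[:, k], s * T[:, k], atol=1e-8)
            np.testing.assert_allclose(model.P[:, k], s * P[:, k], atol=1e-8)
            assert model.q[k] == pytest.approx(s * q[k], abs=1e-8)
        np.testing.assert_allclose(model.B, B, atol=1e-8)

    def test_full_rank_equals_least_squares(self, rng):
        X = rng.normal(size=(20, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=20)
        model = fit_pls(X, y, 5)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        np.testing.assert_allclose(model.B[:, -1], beta, atol=1e-6)

    def test_noiseless_rank_one(self, rng):
        col = rng.normal(size=15)
        X = np.outer(col, rng.normal(size=8))  # rank 1
        y = 3.0 * X[:, 2] + 5.0
        model = fit_pls(X, y, 1)
        pred = model.predict(X)
        assert np.sqrt(np.mean((pred - y) ** 2)) == pytest.approx(0.0, abs=1e-10)
        assert np.corrcoef(pred, y)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_scores_orthogonal(self, random_problem):
        X, y = random_problem
        model = fit_pls(X, y, 4)
        G = model.T.T @ model.T
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)

    def test_coefficient_prediction_equals_factorwise(self, random_problem):
        X, y = random_problem
        model = fit_pls(X, y, 4)
        for k in range(1, 5):
            via_b = model.predict(X, k)
            via_t = model.y_mean + model.T[:, :k] @ model.q[:k]
            np.testing.assert_allclose(via_b, via_t, atol=1e-10)

    def test_centering_invariance_and_y_shift_equivariance(self, random_problem):
        X, y = random_problem
        m0 = fit_pls(X, y, 3)
        m1 = fit_pls(X + 7.5, y + 100.0, 3)
        np.testing.assert_allclose(m1.predict(X + 7.5, 3), m0.predict(X, 3) + 100.0, atol=1e-8)

    def test_matches_sklearn_coefficients(self, random_problem):
        from sklearn.cross_decomposition import PLSRegression

        X, y = random_problem
        model = fit_pls(X, y, 3)
        ref = PLSRegression(n_components=3, scale=False).fit(X, y)
        np.testing.assert_allclose(model.B[:, 2], ref.coef_.ravel(), atol=1e-8)

    def test_degenerate_inputs_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="constant"):
            fit_pls(X, np.ones(10), 2)
        with pytest.raises(ValueError, match="variance"):
            fit_pls(np.ones((10, 4)), np.arange(10.0), 2)


class TestCrossValidate:
    def test_noiseless_rank_one_perfect(self, rng):
        col = rng.normal(size=20)
        X = np.outer(col, rng.normal(size=6))
        y = 2.0 * X[:, 0] + 1.0
        met = cross_validate(X, y, CVScheme(n_segments=5, grouping="by_sample", seed=0), 1)
        assert met.rmsecv[0] <= 1e-8
        assert met.correlation_val[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_leave_one_out_oracle(self, rng):
        X = rng.normal(size=(10, 6))
        y = X @ rng.normal(size=6) + rng.normal(scale=0.5, size=10)
        scheme = CVScheme(n_segments=10, grouping="by_sample", seed=3)
        met = cross_validate(X, y, scheme, 2)
        # explicit hold-out oracle: with 10 segments of 10 samples this is LOO
        preds = np.empty((10, 2))
        for i in range(10):
            tr = [j for j in range(10) if j != i]
            m = fit_pls(X[tr], y[tr], 2)
            for k in (1, 2):
                preds[i, k - 1] = m.predict(X[i : i + 1], k)[0]
        for k in (1, 2):
            rmse = np.sqrt(np.mean((y - preds[:, k - 1]) ** 2))
            assert met.rmsecv[k - 1] == pytest.approx(rmse, abs=1e-10)

    def test_rmsec_non_increasing_and_bounded_by_rmsecv(self, default_regions):
        _, deriv = default_regions
        nu, X, meta = synth.spectra_to_matrix(deriv[pp.Region.PROTEIN])
        y = meta["div"].to_numpy(float)
        groups = list(zip(meta["div"], meta["bio_rep"]))
        met = cross_validate(X, y, CVScheme(seed=4), 5, groups=groups)
        assert np.all(np.diff(met.rmsec) <= 1e-10)
        assert np.all(met.rmsec <= met.rmsecv + 1e-10)
        assert np.all(np.abs(met.correlation_cal) <= 1.0)
        assert np.all(np.abs(met.correlation_val) <= 1.0)

    def test_grouped_cv_keeps_bio_replicates_together(self, rng):
        from neuroftir.plsr import _segments

        groups = [(d, b) for d in range(4) for b in range(5) for _ in range(3)]
        segs = _segments(len(groups), groups, CVScheme(n_segments=6, seed=1))
        for seg in segs:
            for g in {groups[i] for i in seg}:
                members = [i for i, gg in enumerate(groups) if gg == g]
                assert set(members) <= set(seg.tolist())

    def test_permuted_y_has_no_information(self, default_regions):
        _, deriv = default_regions
        nu, X, meta = synth.spectra_to_matrix(deriv[pp.Region.PROTEIN])
        y = meta["div"].to_numpy(float)
        hits = 0
        for seed in range(5):
            y_perm = np.random.default_rng(seed).permutation(y)
            met = cross_validate(
                X, y_perm, CVScheme(n_segments=10, grouping="by_sample", seed=seed), 1
            )
            if -0.5 < met.correlation_val[0] < 0.5:
                hits += 1
        assert hits >= 4

    def test_constant_training_fold_rejected(self, rng):
        X = rng.normal(size=(4, 3))
        y = np.array([1.0, 1.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            cross_validate(X, y, CVScheme(n_segments=2, grouping="by_sample", seed=0), 1)


class TestBetaPeaks:
    def _model_with_beta(self, beta):
        model = fit_pls(np.random.default_rng(0).normal(size=(8, len(beta))), np.arange(8.0), 1)
        model.B = np.asarray(beta, float)[:, None]
        return model

    def test_single_maximum_positive_peak(self):
        nu = 1700.0 - 4.0 * np.arange(26)  # 1700..1600
        beta = np.exp(-((nu - 1656.0) ** 2) / 50.0)
        model = self._model_with_beta(beta)
        peaks = beta_peaks(model, 1, synth.default_band_library(), nu, spectrum_mode="raw")
        assert len(peaks) == 1
        w, sign, name = peaks[0]
        assert sign == 1 and abs(w - 1656.0) <= 4.0 and name == "beta_turn"

    def test_negating_y_flips_signs(self, rng):
        X = rng.normal(size=(12, 20))
        y = X @ rng.normal(size=20)
        nu = 1700.0 - 4.0 * np.arange(20)
        lib = synth.default_band_library()
        p1 = beta_peaks(fit_pls(X, y, 1), 1, lib, nu, spectrum_mode="raw")
        p2 = beta_peaks(fit_pls(X, -y, 1), 1, lib, nu, spectrum_mode="raw")
        assert [(w, -s) for w, s, _ in p1] == [(w, s) for w, s, _ in p2]

    def test_attribution_signs_on_clean_fixture(self, clean_regions):
        _, deriv = clean_regions
        nu, X, meta = synth.spectra_to_matrix(deriv[pp.Region.PROTEIN])
        y = meta["div"].to_numpy(float)
        model = fit_pls(X, y, 1)
        peaks = beta_peaks(model, 1, synth.default_band_library(), nu)

        def sign_near(center):
            close = [(abs(w - center), s) for w, s, _ in peaks if abs(w - center) <= 6]
            assert close, f"no beta extremum near {center}"
            return min(close)[1]

        # rising bands characterize late DIV, the falling 1693 band early DIV
        assert sign_near(1740) == 1
        assert sign_near(1628) == 1
        assert sign_near(1545) == 1
        assert sign_near(1651) == 1
        assert sign_near(1693) == -1
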