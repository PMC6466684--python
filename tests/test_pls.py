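"""NIPALS PLS1: algebraic invariants, oracle equivalence, coefficient
spectra, explained variance."""

import numpy as np
import pytest

from ftircell import (RankWarning, explained_variance, fit_pls1, load_model,
                      predict, regression_coefficient_spectrum, save_model)


@pytest.fixture()
def random_fixture(rng):
    X = rng.normal(size=(10, 20))
    y = rng.normal(size=10)
    return X, y


class TestFit:
    def test_single_latent_direction_exact_with_one_component(self, rng):
        X = np.outer(rng.normal(size=12), rng.normal(size=8))
        X += 0.0  # rank-1 plus centering
        v = rng.normal(size=8)
        y = X @ v + 3.0
        m = fit_pls1(X, y, 1)
        resid = y - predict(m, X)
        assert np.abs(resid).max() <= 1e-10

    def test_score_orthogonality(self, random_fixture):
        X, y = random_fixture
        m = fit_pls1(X, y, 6)
        T = m.T
        G = T.T @ T
        norms = np.sqrt(np.diag(G))
        off = G - np.diag(np.diag(G))
        assert np.all(np.abs(off) <= 1e-8 * np.outer(norms, norms))

    def test_weights_unit_norm(self, random_fixture):
        X, y = random_fixture
        m = fit_pls1(X, y, 5)
        np.testing.assert_allclose(np.linalg.norm(m.W, axis=0), 1.0,
                                   rtol=1e-12)

    def test_full_rank_matches_pseudoinverse_oracle(self, random_fixture):
        """At A = rank(X) the PLS fit equals the minimum-norm least-squares
        fit computed by an independent pinv oracle."""
        X, y = random_fixture
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        m = fit_pls1(X, y, 9)  # rank of centered 10x20 matrix
        oracle = Xc @ (np.linalg.pinv(Xc) @ yc) + y.mean()
        np.testing.assert_allclose(predict(m, X), oracle, atol=1e-8)

    def test_deflation_conserves_frobenius_norm(self, random_fixture):
        X, y = random_fixture
        Xc = X - X.mean(axis=0)
        m = fit_pls1(X, y, 4)
        explained = sum(
            float(m.T[:, a] @ m.T[:, a]) * float(m.P[:, a] @ m.P[:, a])
            for a in range(4))
        residual = Xc - m.T @ m.P.T
        total = float(np.sum(Xc ** 2))
        assert abs(total - explained - float(np.sum(residual ** 2))) \
            <= 1e-8 * total

    def test_permutation_equivariance(self, random_fixture, rng):
        X, y = random_fixture
        perm = rng.permutation(len(y))
        m1 = fit_pls1(X, y, 5)
        m2 = fit_pls1(X[perm], y[perm], 5)
        np.testing.assert_allclose(m1.B, m2.B, atol=1e-10)

    def test_error_conditions(self, random_fixture):
        X, y = random_fixture
        with pytest.raises(ValueError, match="zero-variance"):
            fit_pls1(X, np.ones(10), 2)
        with pytest.raises(ValueError, match="exceeds"):
            fit_pls1(X, y, 10)   # > n - 1
        with pytest.raises(ValueError):
            fit_pls1(X, y, 0)

    def test_rank_deficiency_stops_early_with_warning(self, rng):
        X = np.outer(rng.normal(size=15), rng.normal(size=12))  # rank 1
        y = X @ rng.normal(size=12)
        with pytest.warns(RankWarning):
            m = fit_pls1(X, y, 5)
        assert m.n_components < 5
        assert m.requested_components == 5


class TestPredict:
    def test_mean_input_gives_mean_response(self, random_fixture):
        X, y = random_fixture
        m = fit_pls1(X, y, 3)
        np.testing.assert_allclose(predict(m, X.mean(axis=0)), y.mean(),
                                   atol=1e-12)

    def test_training_consistency(self, random_fixture):
        X, y = random_fixture
        m = fit_pls1(X, y, 4)
        np.testing.assert_allclose(predict(m, X, a=4), m.training_fitted(),
                                   atol=1e-10)

    def test_null_model_and_feature_mismatch(self, random_fixture):
        X, y = random_fixture
        m = fit_pls1(X, y, 3)
        np.testing.assert_array_equal(predict(m, X, a=0),
                                      np.full(10, y.mean()))
        with pytest.raises(ValueError, match="feature mismatch"):
            predict(m, X[:, :5])

    def test_matches_sklearn_cross_check(self, random_fixture):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_fixture
        m = fit_pls1(X, y, 4)
        ref = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(predict(m, X),
                                   ref.predict(X).ravel(), atol=1e-8)


class TestCoefficients:
    def test_one_component_closed_form(self, random_fixture):
        X, y = random_fixture
        m = fit_pls1(X, y, 3)
        np.testing.assert_allclose(m.B[:, 0], m.W[:, 0] * m.q[0],
                                   atol=1e-12)

    def test_accumulation_matches_score_space_oracle(self, random_fixture):
        """B_A equals the coefficients from regressing y on the score matrix
        and back-transforming through the weights."""
        X, y = random_fixture
        A = 5
        m = fit_pls1(X, y, A)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        R = m.W @ np.linalg.inv(m.P.T @ m.W)     # X-rotation: T = Xc R
        b_scores, *_ = np.linalg.lstsq(Xc @ R, yc, rcond=None)
        np.testing.assert_allclose(m.B[:, A - 1], R @ b_scores, atol=1e-8)

    def test_protein_model_peaks_at_amide_one(self, calibration):
        """On the synthetic noise-free calibration set the strongest protein
        coefficient in 1600-1700 cm^-1 sits on the grid point nearest the
        Amide I band."""
        from ftircell import (NoiseParams, generate_calibration_set,
                              savgol_second_derivative, cut_ranges)
        import warnings
        raw, table = generate_calibration_set(noise=NoiseParams.none(),
                                              rng=42)
        deriv = savgol_second_derivative(cut_ranges(raw))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RankWarning)
            m = fit_pls1(deriv.absorbance, table["protein"].to_numpy(), 7,
                         wavenumbers=deriv.wavenumbers)
        series = regression_coefficient_spectrum(m, m.n_components)
        window = series[(series["wavenumber_cm-1"] >= 1600)
                        & (series["wavenumber_cm-1"] <= 1700)]
        top = window.loc[window["coefficient"].abs().idxmax(),
                         "wavenumber_cm-1"]
        assert abs(top - 1658.0) <= 2.0

    def test_out_of_range_component_rejected(self, random_fixture):
        X, y = random_fixture
        m = fit_pls1(X, y, 3, wavenumbers=np.arange(20.0))
        with pytest.raises(ValueError):
            regression_coefficient_spectrum(m, 0)
        with pytest.raises(ValueError):
            regression_coefficient_spectrum(m, 4)


class TestExplainedVariance:
    def test_nonnegative_and_bounded(self, random_fixture):
        X, y = random_fixture
        xv, yv = explained_variance(fit_pls1(X, y, 6))
        assert np.all(xv >= 0) and np.all(yv >= 0)
        assert xv.sum() <= 100 + 1e-6 and yv.sum() <= 100 + 1e-6
        assert np.all(np.diff(np.cumsum(xv)) >= 0)

    def test_rank3_x_fully_explained_in_three(self, rng):
        X = sum(np.outer(rng.normal(size=12), rng.normal(size=9))
                for _ in range(3))
        y = rng.normal(size=12)
        with pytest.warns(RankWarning):      # 4th direction does not exist
            m = fit_pls1(X, y, 4)
        xv, _ = explained_variance(m)
        assert abs(xv.sum() - 100.0) <= 1e-6

    def test_two_latent_factor_y_fully_explained(self, rng):
        T = rng.normal(size=(15, 2))
        P = rng.normal(size=(10, 2))
        X = T @ P.T + 0.0
        y = T @ np.array([2.0, -1.0]) + 5.0
        m = fit_pls1(X, y, 2)
        _, yv = explained_variance(m)
        assert abs(yv.sum() - 100.0) <= 1e-6


class TestSerialization:
    def test_json_round_trip(self, random_fixture, tmp_path):
        X, y = random_fixture
        m = fit_pls1(X, y, 3, wavenumbers=np.linspace(1000, 1019, 20),
                     response="protein")
        m.preprocessing = {"sg_window": 9}
        path = tmp_path / "model.json"
        save_model(m, path)
        m2 = load_model(path)
        np.testing.assert_allclose(m2.B, m.B, atol=0)
        np.testing.assert_allclose(m2.x_mean, m.x_mean, atol=0)
        assert m2.response == "protein"
        assert m2.preprocessing["sg_window"] == 9
        np.testing.assert_allclose(predict(m2, X), predict(m, X), atol=0)
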