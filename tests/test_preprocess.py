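"""Preprocessing chain: range cutting arithmetic, Savitzky-Golay second
derivative exactness, baseline immunity, centering, state machine."""

import numpy as np
import pytest

from ftircell import (SpectrumSet, StateError, cut_ranges, make_meta,
                      mean_center, preprocess, savgol_second_derivative)


def _set_from_matrix(grid, matrix):
    matrix = np.atleast_2d(matrix)
    return SpectrumSet(segments=[grid.values], absorbance=matrix,
                       meta=make_meta([f"s{i}" for i in
                                       range(matrix.shape[0])]))


class TestCutRanges:
    def test_default_ranges_point_counts(self, grid, rng):
        sset = _set_from_matrix(grid, rng.normal(size=(2, grid.n_points)))
        cut = cut_ranges(sset)
        sizes = sorted(s.size for s in cut.segments)
        assert sizes == [100, 426]          # C-H window + fingerprint window
        assert cut.n_points == 526
        assert cut.state == "cut"

    def test_recut_same_ranges_is_identity(self, grid, rng):
        sset = _set_from_matrix(grid, rng.normal(size=(1, grid.n_points)))
        cut1 = cut_ranges(sset)
        cut2 = cut_ranges(cut1)
        np.testing.assert_array_equal(cut1.absorbance, cut2.absorbance)
        for a, b in zip(cut1.segments, cut2.segments):
            np.testing.assert_array_equal(a, b)

    def test_interval_outside_grid_rejected(self, grid, rng):
        sset = _set_from_matrix(grid, rng.normal(size=(1, grid.n_points)))
        with pytest.raises(ValueError, match="outside grid"):
            cut_ranges(sset, [(5000.0, 4500.0)])

    def test_overlapping_intervals_rejected(self, grid, rng):
        sset = _set_from_matrix(grid, rng.normal(size=(1, grid.n_points)))
        with pytest.raises(ValueError, match="overlapping"):
            cut_ranges(sset, [(2000.0, 1000.0), (1500.0, 900.0)])

    def test_values_are_selected_not_interpolated(self, grid):
        spec = np.arange(grid.n_points, dtype=float)
        cut = cut_ranges(_set_from_matrix(grid, spec))
        idx = np.isin(grid.values, cut.wavenumbers)
        np.testing.assert_array_equal(cut.absorbance[0], spec[idx])


class TestSavgolSecondDerivative:
    def test_exact_for_quadratic(self, grid):
        a, b, c = 3e-4, -0.2, 5.0
        nu = grid.values
        sset = cut_ranges(_set_from_matrix(grid, a * nu**2 + b * nu + c))
        out = savgol_second_derivative(sset)
        np.testing.assert_allclose(out.absorbance, 2 * a, rtol=1e-8)

    def test_zero_for_constant_and_linear(self, grid):
        nu = grid.values
        sset = cut_ranges(_set_from_matrix(
            grid, np.vstack([np.full_like(nu, 7.0), 0.3 * nu + 1.0])))
        out = savgol_second_derivative(sset)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-10)

    def test_segments_shrink_by_window_minus_one(self, grid, rng):
        sset = cut_ranges(_set_from_matrix(grid,
                                           rng.normal(size=grid.n_points)))
        out = savgol_second_derivative(sset, window=9)
        assert sorted(s.size for s in out.segments) == [92, 418]
        assert out.n_points == 510

    def test_matches_local_polyfit_oracle(self, grid, rng):
        """Each output equals twice the leading coefficient of a quadratic
        least-squares fit in the 9-point window around that point."""
        y = rng.normal(size=grid.n_points)
        sset = cut_ranges(_set_from_matrix(grid, y))
        out = savgol_second_derivative(sset, window=9, polyorder=2)
        col = 0
        for seg_in, cols in sset.segment_slices():
            y_seg = sset.absorbance[0, cols]
            for j in range(4, seg_in.size - 4):
                x = seg_in[j - 4:j + 5] - seg_in[j]
                coef = np.polynomial.polynomial.polyfit(x, y_seg[j - 4:j + 5],
                                                        2)
                np.testing.assert_allclose(out.absorbance[0, col],
                                           2.0 * coef[2], rtol=1e-7,
                                           atol=1e-12)
                col += 1
        assert col == out.n_points

    def test_baseline_immunity(self, grid, rng):
        y = rng.normal(size=grid.n_points)
        ramp = np.linspace(-0.3, 0.8, grid.n_points)
        out1 = savgol_second_derivative(cut_ranges(_set_from_matrix(grid, y)))
        out2 = savgol_second_derivative(
            cut_ranges(_set_from_matrix(grid, y + ramp)))
        np.testing.assert_allclose(out1.absorbance, out2.absorbance,
                                   atol=1e-10)

    def test_segment_isolation(self, grid, rng):
        """Perturbing one segment never changes the other's derivatives."""
        y = rng.normal(size=grid.n_points)
        y2 = y.copy()
        y2[np.abs(grid.values - 2900).argmin()] += 5.0   # in C-H window
        d1 = savgol_second_derivative(cut_ranges(_set_from_matrix(grid, y)))
        d2 = savgol_second_derivative(cut_ranges(_set_from_matrix(grid, y2)))
        fingerprint = d1.wavenumbers <= 1800
        np.testing.assert_array_equal(d1.absorbance[0, fingerprint],
                                      d2.absorbance[0, fingerprint])
        assert not np.array_equal(d1.absorbance[0, ~fingerprint],
                                  d2.absorbance[0, ~fingerprint])

    def test_window_validation(self, grid, rng):
        sset = cut_ranges(_set_from_matrix(grid,
                                           rng.normal(size=grid.n_points)))
        with pytest.raises(ValueError):
            savgol_second_derivative(sset, window=8)
        with pytest.raises(ValueError):
            savgol_second_derivative(sset, polyorder=1)
        short = cut_ranges(_set_from_matrix(grid,
                                            rng.normal(size=grid.n_points)),
                           [(1010.0, 1000.0)])
        with pytest.raises(ValueError, match="shorter than window"):
            savgol_second_derivative(short)


class TestMeanCenter:
    def _deriv(self, grid, rng, n=4):
        return savgol_second_derivative(cut_ranges(_set_from_matrix(
            grid, rng.normal(size=(n, grid.n_points)))))

    def test_self_centering_and_inverse(self, grid, rng):
        deriv = self._deriv(grid, rng)
        centered, mean = mean_center(deriv)
        assert np.abs(centered.absorbance.mean(axis=0)).max() < 1e-12
        np.testing.assert_allclose(centered.absorbance + mean,
                                   deriv.absorbance, atol=1e-12)

    def test_single_spectrum_centers_to_zero(self, grid, rng):
        deriv = self._deriv(grid, rng, n=1)
        centered, _ = mean_center(deriv)
        np.testing.assert_array_equal(centered.absorbance, 0.0)

    def test_reference_mean_mode_and_mismatch(self, grid, rng):
        deriv = self._deriv(grid, rng)
        ref = np.ones(deriv.n_points)
        centered, mean = mean_center(deriv, reference_mean=ref)
        np.testing.assert_array_equal(mean, ref)
        np.testing.assert_allclose(centered.absorbance,
                                   deriv.absorbance - 1.0)
        with pytest.raises(ValueError):
            mean_center(deriv, reference_mean=np.ones(3))


class TestChain:
    def test_preprocess_equals_three_stage_chain(self, grid, rng):
        raw = _set_from_matrix(grid, rng.normal(size=(5, grid.n_points)))
        chained, mean = preprocess(raw)
        manual, mmean = mean_center(
            savgol_second_derivative(cut_ranges(raw)))
        np.testing.assert_array_equal(chained.absorbance, manual.absorbance)
        np.testing.assert_array_equal(mean, mmean)
        assert chained.n_points == 510
        assert chained.state == "centered"

    def test_state_machine_forbids_reprocessing(self, grid, rng):
        raw = _set_from_matrix(grid, rng.normal(size=(3, grid.n_points)))
        processed, _ = preprocess(raw)
        with pytest.raises(StateError):
            preprocess(processed)
        with pytest.raises(StateError):
            savgol_second_derivative(processed)
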