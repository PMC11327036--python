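"""Correlation matrices, banding regularization, and the IDAR iteration."""

import math

import numpy as np
import pytest
from scipy.linalg import toeplitz

from idar.armodel import ARModelFit
from idar.evaluate import adequacy, sample_acf
from idar.synthetic import (GeneratorSpec, ar_acf, gen_ar, gen_stacked,
                            gen_white, stacked_correlation)
from idar.timeseries import TimeSeries
from idar.whiten import (band_regularize, baseline_whiten, build_corr_matrix,
                         default_p_max, idar, inv_sqrt, whiten_once)


def _ar_fit(lag_set, coeffs):
    return ARModelFit(tuple(lag_set), np.asarray(coeffs, float),
                      0.0, 1.0, 0.0, 0.0, 100)


class TestBuildCorrMatrix:
    def test_white_is_identity(self):
        m = build_corr_matrix(np.array([1.0, 0, 0]), 3)
        np.testing.assert_array_equal(m.matrix, np.eye(3))
        assert m.condition_number == pytest.approx(1.0)

    def test_ar1_toeplitz_entries(self):
        m = build_corr_matrix(np.array([1.0, 0.5, 0.25]), 3)
        np.testing.assert_allclose(
            m.matrix, [[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]])

    def test_rank_one_has_infinite_condition(self):
        m = build_corr_matrix(np.ones(3), 3)
        assert m.condition_number == math.inf

    def test_out_of_range_acf_rejected(self):
        with pytest.raises(ValueError):
            build_corr_matrix(np.array([1.0, 1.4, 0.2]), 3)


class TestBandRegularize:
    def test_identity_unchanged(self):
        m = build_corr_matrix(np.array([1.0, 0, 0, 0]), 4)
        out = band_regularize(m)
        assert out.bandwidth is None
        np.testing.assert_array_equal(out.matrix, np.eye(4))

    def test_rank_one_floors_eigenvalues(self):
        # ones matrix: eigenvalues (3, 0, 0) -> (3, 3e-8, 3e-8)
        m = build_corr_matrix(np.ones(3), 3)
        out = band_regularize(m)
        assert out.floored
        vals = np.sort(np.linalg.eigvalsh(out.matrix))
        np.testing.assert_allclose(vals, [3e-8, 3e-8, 3.0], rtol=1e-6)
        assert out.condition_number <= 1e8 * (1 + 1e-12)

    def test_moderate_near_unit_root_left_alone(self):
        # AR(1) phi = 0.999 at T = 200 stays under the 1e8 threshold, so
        # regularization must not touch it
        m = build_corr_matrix(ar_acf((0.999,), 199), 200)
        assert m.condition_number < 1e8
        out = band_regularize(m)
        assert out.bandwidth is None
        np.testing.assert_array_equal(out.matrix, m.matrix)

    def test_banding_removes_indefinite_tail(self):
        # an ACF whose distant lags jump back up makes the Toeplitz matrix
        # indefinite; zeroing those bands restores positive definiteness
        # and only entries beyond the final bandwidth change
        T = 60
        acf = 0.5 ** np.arange(T)
        acf[40:] = 0.9
        m = build_corr_matrix(acf, T)
        assert m.condition_number == math.inf
        out = band_regularize(m)
        assert out.bandwidth == 40
        assert out.condition_number < 1e8
        assert not out.floored
        j, k = np.meshgrid(np.arange(T), np.arange(T), indexing="ij")
        inside = np.abs(j - k) < out.bandwidth
        np.testing.assert_array_equal(out.matrix[inside], m.matrix[inside])
        assert np.all(out.matrix[~inside] == 0)

    def test_flooring_fallback_when_banding_cannot_fix(self):
        # extreme near-unit-root case: banding never reaches the threshold
        # and eigenvalue flooring takes over
        m = build_corr_matrix(ar_acf((0.999999,), 199), 200)
        assert m.condition_number >= 1e8
        out = band_regularize(m)
        assert out.floored
        assert out.condition_number <= 1e8 * (1 + 1e-9)
        assert np.linalg.eigvalsh(out.matrix)[0] > 0


class TestInvSqrt:
    def test_identity(self):
        m = build_corr_matrix(np.array([1.0, 0]), 2)
        np.testing.assert_allclose(inv_sqrt(m), np.eye(2), atol=1e-12)

    def test_2x2_hand_eigendecomposition(self):
        m = build_corr_matrix(np.array([1.0, 0.5]), 2)
        F = inv_sqrt(m)
        np.testing.assert_allclose(
            F, [[1.115355, -0.298858], [-0.298858, 1.115355]], atol=1e-6)

    def test_inverse_square_root_property(self):
        m = build_corr_matrix(ar_acf((0.7, -0.2), 49), 50)
        F = inv_sqrt(m)
        np.testing.assert_allclose(F @ m.matrix @ F, np.eye(50), atol=1e-6)
        np.testing.assert_allclose(F, F.T, atol=1e-10)

    def test_non_pd_rejected(self):
        m = build_corr_matrix(np.ones(3), 3)
        with pytest.raises(ValueError):
            inv_sqrt(m)


class TestWhitenOnce:
    def test_ar0_fit_is_demeaning_only(self, white_series):
        w, F = whiten_once(white_series, _ar_fit((), ()))
        np.testing.assert_allclose(w.values, white_series.demeaned(), atol=1e-10)
        np.testing.assert_allclose(F, np.eye(white_series.n), atol=1e-10)

    def test_true_model_whitens_ar(self):
        y = gen_ar(GeneratorSpec("ar", (0.8,), 1.0, 500, 1.0, 6))
        w, _ = whiten_once(y, _ar_fit((1,), (0.8,)))
        assert abs(sample_acf(w, 1)[1]) < 3 / np.sqrt(y.n)

    def test_transform_consistency(self):
        y = gen_ar(GeneratorSpec("ar", (0.6,), 1.0, 300, 1.0, 2))
        w, F = whiten_once(y, _ar_fit((1,), (0.6,)))
        np.testing.assert_allclose(w.values, F @ y.demeaned(), atol=1e-10)

    def test_variance_preserved(self):
        y = gen_ar(GeneratorSpec("ar", (0.7,), 1.0, 400, 1.0, 3))
        w, _ = whiten_once(y, _ar_fit((1,), (0.7,)))
        assert w.values.std() == pytest.approx(y.values.std(), rel=1e-8)


class TestDefaultPMax:
    def test_tr_rule_and_caps(self):
        assert default_p_max(2.5, 1000) == 4
        assert default_p_max(0.49, 1000) == 20
        assert default_p_max(0.1, 200) == 40  # 100 capped at T/5
        assert default_p_max(20.0, 1000) == 1  # floor at 1


class TestIDAR:
    def test_white_input_often_stops_immediately(self):
        hits = sum(idar(gen_white(600, 1.0, s, tr=0.49)).iterations == 0
                   for s in range(40))
        # AICc's overfitting probability keeps this below 1 but above 1/2
        assert hits / 40 >= 0.5

    def test_white_input_reports_white_fit_reason(self):
        res = idar(gen_white(600, 1.0, 12, tr=0.49))
        if res.iterations == 0:
            assert res.stop_reason == "white_fit"
            assert res.transform.factors == ()

    def test_stacked_short_tr_is_whitened(self):
        specs = (GeneratorSpec("ar", (0.8,)), GeneratorSpec("ar", (0.5,)))
        flags = [idar(gen_stacked(specs, 600, s, tr=0.49)).adequacy.inadequate
                 for s in range(25)]
        assert np.mean(flags) < 0.1

    def test_max_iter_bound_honored(self):
        specs = (GeneratorSpec("ar", (0.8,)), GeneratorSpec("ar", (0.5,)))
        for s in range(5):
            res = idar(gen_stacked(specs, 400, s, tr=0.49), max_iter=1)
            assert res.iterations <= 1

    def test_composite_equals_sequential(self):
        specs = (GeneratorSpec("ar", (0.9,)), GeneratorSpec("ar", (0.6,)))
        y = gen_stacked(specs, 300, 7, tr=0.49)
        res = idar(y, max_iter=3)
        x = y.demeaned()
        seq = res.transform.apply(x.copy())
        np.testing.assert_allclose(res.transform.composite @ x, seq, atol=1e-8)
        np.testing.assert_allclose(res.whitened.values, seq, atol=1e-8)

    def test_factors_spd_and_conditioned(self):
        specs = (GeneratorSpec("ar", (0.9,)), GeneratorSpec("ar", (0.7,)))
        res = idar(gen_stacked(specs, 300, 1, tr=0.49))
        for F in res.transform.factors:
            np.testing.assert_allclose(F, F.T, atol=1e-8)
            assert np.linalg.eigvalsh(F)[0] > 0
        for m in res.correlation_models:
            assert m.condition_number <= 1e8 * (1 + 1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            idar(gen_white(10, 1.0, 0, tr=0.1), p_max=20)


class TestBaselines:
    def test_none_is_identity(self, white_series):
        res = baseline_whiten(white_series, method="none")
        np.testing.assert_allclose(res.whitened.values,
                                   white_series.demeaned(), atol=1e-12)
        assert res.transform.factors == ()

    def test_ar1_whitens_ar1(self):
        y = gen_ar(GeneratorSpec("ar", (0.9,), 1.0, 1000, 1.0, 3))
        res = baseline_whiten(y, method="ar1")
        assert abs(sample_acf(res.whitened, 1)[1]) < 3 / np.sqrt(y.n)

    def test_ar1_fails_on_stacked(self):
        specs = (GeneratorSpec("ar", (0.8,)), GeneratorSpec("ar", (0.5,)))
        flags = [baseline_whiten(gen_stacked(specs, 600, s, tr=0.49),
                                 method="ar1").adequacy.inadequate
                 for s in range(20)]
        assert np.mean(flags) >= 0.7

    def test_arma11_whitens_arma11(self):
        from idar.synthetic import gen_arma11

        y = gen_arma11(GeneratorSpec("arma11", (0.6, 0.2), 1.0, 1000, 1.0, 4))
        res = baseline_whiten(y, method="arma11")
        assert not res.adequacy.inadequate

    def test_unknown_method_rejected(self, white_series):
        with pytest.raises(ValueError):
            baseline_whiten(white_series, method="spectral")


class TestSelfWhiteningOracle:
    def test_true_correlation_calibrates_adequacy(self):
        # whitening with the exact generating correlation matrix should
        # flag at about the nominal family-wise rate
        specs = (GeneratorSpec("ar", (0.8,)), GeneratorSpec("ar", (0.5,)))
        T = 400
        C = stacked_correlation(specs, T)
        vals, vecs = np.linalg.eigh(C)
        F = (vecs / np.sqrt(np.clip(vals, 1e-12, None))) @ vecs.T
        R = 200
        flags = 0
        for s in range(R):
            y = gen_stacked(specs, T, 1000 + s, tr=0.49)
            w = TimeSeries(F @ y.demeaned(), 0.49)
            flags += adequacy(w).inadequate
        rate = flags / R
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / R)
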