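"""Region extraction, baseline correction, area normalization, SG second derivative."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroftir.preprocess import (
    PreprocessParams,
    Region,
    area_normalize,
    baseline_correct,
    extract_region,
    preprocess_pipeline,
    second_derivative,
)
from neuroftir.synth import Spectrum


def _grid(start=4000.0, stop=600.0, step=4.0):
    n = int(round((start - stop) / step)) + 1
    return start - step * np.arange(n)


def _spec(nu, a, **meta):
    return Spectrum(nu, a, {"sample_id": "s", **meta})


def brute_force_lower_hull(nu, a):
    """O(n^3) rubber-band oracle: hull edges are chords whose supporting line
    keeps every point on or above it."""
    nu, a = np.asarray(nu, float), np.asarray(a, float)
    order = np.argsort(nu)
    x, y = nu[order], a[order]
    n = len(x)
    base = np.full(n, -np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            line = y[i] + (y[j] - y[i]) * (x - x[i]) / (x[j] - x[i])
            if np.all(y >= line - 1e-12):
                seg = slice(i, j + 1)
                base[seg] = np.maximum(base[seg], line[seg])
    base[0], base[-1] = y[0], y[-1]
    out = np.empty(n)
    out[order] = base
    return out


class TestExtractRegion:
    def test_protein_region_point_count(self):
        nu = _grid()
        s = extract_region(_spec(nu, np.zeros_like(nu)), Region.PROTEIN)
        assert len(s) == (1800 - 1500) // 4 + 1 == 76
        assert s.wavenumbers[0] == 1800.0 and s.wavenumbers[-1] == 1500.0

    def test_closed_interval_includes_endpoints(self):
        nu = _grid(1800.0, 1500.0, 4.0)
        s = extract_region(_spec(nu, np.ones_like(nu)), Region.PROTEIN)
        assert 1800.0 in s.wavenumbers and 1500.0 in s.wavenumbers

    def test_region_outside_span_errors(self):
        nu = _grid(1400.0, 1000.0, 4.0)
        with pytest.raises(ValueError, match="outside grid span"):
            extract_region(_spec(nu, np.zeros_like(nu)), Region.PROTEIN)


class TestBaseline:
    def test_straight_line_maps_to_zero(self):
        nu = _grid(1800.0, 1500.0, 4.0)
        s = baseline_correct(_spec(nu, 0.3 + 0.001 * nu))
        np.testing.assert_allclose(s.absorbance, 0.0, atol=1e-12)

    def test_positive_gaussian_preserved_inside(self):
        nu = _grid(1800.0, 1500.0, 4.0)
        g = np.exp(-((nu - 1650.0) ** 2) / (2 * 15.0**2))
        s = baseline_correct(_spec(nu, g))
        # endpoints anchored to 0; elsewhere the peak is essentially untouched
        assert abs(s.absorbance[0]) < 1e-12 and abs(s.absorbance[-1]) < 1e-12
        np.testing.assert_allclose(s.absorbance, g, atol=1e-3)

    def test_gaussian_plus_line_recovered_vs_hull_oracle(self):
        nu = _grid(1800.0, 1500.0, 4.0)
        g = 0.7 * np.exp(-((nu - 1660.0) ** 2) / (2 * 12.0**2))
        a = g + 0.2 + 0.0005 * nu
        s = baseline_correct(_spec(nu, a))
        oracle = a - brute_force_lower_hull(nu, a)
        np.testing.assert_allclose(s.absorbance, oracle, atol=1e-10)
        center = np.argmin(np.abs(nu - 1660.0))
        assert s.absorbance[center] == pytest.approx(0.7, abs=0.007)  # within 1% of peak

    def test_rubber_band_idempotent(self, rng):
        nu = _grid(1800.0, 1500.0, 4.0)
        a = np.abs(rng.normal(size=nu.shape)).cumsum() / 50 + np.exp(
            -((nu - 1650.0) ** 2) / 800.0
        )
        once = baseline_correct(_spec(nu, a))
        twice = baseline_correct(once)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-10)

    def test_polynomial_baseline_removes_fitted_trend(self):
        nu = _grid(1800.0, 1500.0, 4.0)
        a = 2.0 - 0.001 * nu + 3e-7 * nu**2
        s = baseline_correct(_spec(nu, a), PreprocessParams(baseline_method="polynomial"))
        np.testing.assert_allclose(s.absorbance, 0.0, atol=1e-8)

    def test_non_finite_rejected(self):
        nu = _grid(1800.0, 1500.0, 4.0)
        a = np.zeros_like(nu)
        a[5] = np.nan
        with pytest.raises(ValueError, match="finite"):
            baseline_correct(_spec(nu, a))


class TestAreaNormalize:
    def test_uniform_case(self):
        nu = _grid(1800.0, 1500.0, 4.0)
        s = area_normalize(_spec(nu, np.full(nu.shape, 2.0)))
        np.testing.assert_allclose(s.absorbance, 1.0 / 300.0, rtol=1e-12)

    def test_idempotent(self, rng):
        nu = _grid(1800.0, 1500.0, 4.0)
        s = area_normalize(_spec(nu, rng.uniform(0.1, 1.0, nu.shape)))
        s2 = area_normalize(s)
        np.testing.assert_allclose(s2.absorbance, s.absorbance, rtol=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_unit_absolute_integral(self, seed):
        rng = np.random.default_rng(seed)
        nu = _grid(1800.0, 1500.0, 4.0)
        s = area_normalize(_spec(nu, rng.uniform(0.05, 2.0, nu.shape)))
        # independent trapezoid oracle on the ascending grid
        asc = np.argsort(s.wavenumbers)
        integral = np.trapezoid(np.abs(s.absorbance[asc]), s.wavenumbers[asc])
        assert integral == pytest.approx(1.0, abs=1e-10)

    def test_zero_area_rejected(self):
        nu = _grid(1800.0, 1500.0, 4.0)
        with pytest.raises(ValueError, match="area"):
            area_normalize(_spec(nu, np.zeros_like(nu)))


class TestSecondDerivative:
    def test_quadratic_exact(self):
        nu = _grid(1800.0, 1500.0, 4.0)
        a = 3e-4 * nu**2
        d2 = second_derivative(_spec(nu, a))
        np.testing.assert_allclose(d2.absorbance, 2 * 3e-4, atol=1e-10)

    def test_linear_is_zero(self):
        nu = _grid(1800.0, 1500.0, 4.0)
        d2 = second_derivative(_spec(nu, 5.0 + 0.01 * nu))
        np.testing.assert_allclose(d2.absorbance, 0.0, atol=1e-10)

    def test_sinusoid_matches_closed_form(self):
        # quartic 7-point filter: quadratic smoothing attenuates a sinusoid of
        # this frequency by ~3%, the quartic fit tracks it to < 1e-3
        nu = _grid(1800.0, 1500.0, 4.0)
        params = PreprocessParams(sg_points_per_side=3, sg_polyorder=4)
        d2 = second_derivative(_spec(nu, np.sin(nu / 20.0)), params)
        expected = -np.sin(nu / 20.0) / 400.0
        interior = slice(3, -3)
        err = np.abs(d2.absorbance[interior] - expected[interior])
        assert err.max() <= 1e-3 * np.abs(expected[interior]).max()

    def test_linearity(self, rng):
        nu = _grid(1800.0, 1500.0, 4.0)
        f = rng.normal(size=nu.shape)
        g = rng.normal(size=nu.shape)
        a, b = 2.5, -1.25
        lhs = second_derivative(_spec(nu, a * f + b * g)).absorbance
        rhs = (
            a * second_derivative(_spec(nu, f)).absorbance
            + b * second_derivative(_spec(nu, g)).absorbance
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_window_longer_than_region_errors(self):
        nu = _grid(1800.0, 1780.0, 4.0)  # 6 points
        with pytest.raises(ValueError, match="window"):
            second_derivative(
                _spec(nu, np.zeros_like(nu)), PreprocessParams(sg_points_per_side=4)
            )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PreprocessParams(sg_points_per_side=1, sg_polyorder=3)  # window 3 <= order


class TestPipeline:
    def test_normalization_postcondition(self, clean_dataset):
        out = preprocess_pipeline(clean_dataset[:4], Region.PROTEIN)
        for s in out:
            asc = np.argsort(s.wavenumbers)
            integral = np.trapezoid(np.abs(s.absorbance[asc]), s.wavenumbers[asc])
            assert integral == pytest.approx(1.0, abs=1e-10)
            assert "area_normalize" in s.meta["steps"]

    def test_derivative_locates_band_center(self):
        nu = _grid()
        a = np.exp(-((nu - 1650.0) ** 2) / (2 * 12.0**2))
        out = preprocess_pipeline(
            [_spec(nu, a, div=2, bio_rep=1)], Region.PROTEIN, derivative=True
        )[0]
        found = out.wavenumbers[np.argmin(out.absorbance)]
        assert abs(found - 1650.0) <= 4.0  # within one grid step

    def test_empty_list(self):
        assert preprocess_pipeline([], Region.PROTEIN) == []
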