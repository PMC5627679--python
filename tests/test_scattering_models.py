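import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import saxsizer as sx
from saxsizer.scattering_models import (
    LognormalParams,
    lognormal_grid,
    lognormal_moments,
    lognormal_pdf,
    polydisperse_intensity,
    reweight_distribution,
    sld,
    sphere_form_factor,
    xray_contrast,
)


class TestLognormal:
    def test_pdf_normalizes_to_area(self):
        p = LognormalParams(1.0, 3.0, 0.25)
        val, _ = quad(lambda r: lognormal_pdf(r, p), 1e-6, 50.0)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mode_and_median(self):
        p = LognormalParams(1.0, 3.0, 0.2)
        r = np.linspace(0.5, 8, 20000)
        mode = r[np.argmax(lognormal_pdf(r, p))]
        assert mode == pytest.approx(3.0 * np.exp(-0.04), rel=1e-3)
        # median: half the area lies below R0 for any w
        below, _ = quad(lambda x: lognormal_pdf(x, p), 1e-6, 3.0)
        assert below == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("r0,w", [(2.73, 0.229), (1.0, 0.05), (8.0, 0.6)])
    def test_moments_match_quadrature(self, r0, w):
        p = LognormalParams(1.0, r0, w)
        mean, sd = lognormal_moments(p)
        m1, _ = quad(lambda r: r * lognormal_pdf(r, p), 1e-9, r0 * 50)
        m2, _ = quad(lambda r: r ** 2 * lognormal_pdf(r, p), 1e-9, r0 * 50)
        assert mean == pytest.approx(m1, rel=1e-6)
        assert sd == pytest.approx(np.sqrt(m2 - m1 ** 2), rel=1e-6)

    def test_degenerate_width(self):
        mean, sd = lognormal_moments(LognormalParams(1.0, 2.5, 0.0))
        assert mean == 2.5 and sd == 0.0
        with pytest.raises(ValueError):
            lognormal_pdf(2.5, LognormalParams(1.0, 2.5, 0.0))

    def test_scale_equivariance(self):
        m1, s1 = lognormal_moments(LognormalParams(1.0, 2.0, 0.3))
        m2, s2 = lognormal_moments(LognormalParams(1.0, 4.0, 0.3))
        assert m2 == pytest.approx(2 * m1) and s2 == pytest.approx(2 * s1)


class TestSphereFormFactor:
    def test_limit_at_zero(self):
        assert sphere_form_factor(1e-9, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_first_zero(self):
        # first root of sin x - x cos x
        assert sphere_form_factor(4.4934, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_matches_direct_formula_at_one(self):
        direct = (3 * (np.sin(1) - np.cos(1))) ** 2
        assert sphere_form_factor(1.0, 1.0) == pytest.approx(direct, rel=1e-12)

    def test_series_branch_agrees_with_exact_formula(self):
        # just below the switchover the series must match the closed form
        x = 0.99e-2
        exact = (3 * (np.sin(x) - x * np.cos(x)) / x ** 3) ** 2
        assert sphere_form_factor(x, 1.0) == pytest.approx(exact, rel=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(1e-6, 50.0))
    def test_bounded_in_unit_interval(self, x):
        p = sphere_form_factor(x, 1.0)
        assert 0.0 <= p <= 1.0 + 1e-12


class TestPolydisperseIntensity:
    def test_monodisperse_forward_value_at_low_q(self, contrast):
        dist = lognormal_grid(LognormalParams(1.0, 3.0, 1e-3), n=400)
        n, B = 1e20, 2.0
        I0 = polydisperse_intensity(1e-6, dist, contrast, n, B)
        V = (4 / 3) * np.pi * (3.0e-9) ** 3
        expected = n * (contrast.delta_rho_m2() * V) ** 2 + B
        assert I0 == pytest.approx(expected, rel=1e-3)

    def test_linearity_in_number_density(self, contrast, truth):
        q = np.geomspace(0.1, 3, 30)
        dist = lognormal_grid(truth.params)
        full = polydisperse_intensity(q, dist, contrast, 2e20, 0.0)
        half = polydisperse_intensity(q, dist, contrast, 1e20, 0.0)
        np.testing.assert_allclose(full, 2 * half, rtol=1e-12)

    def test_quadrature_refinement_oracle(self, contrast, truth):
        # value stable to 0.1% under a 10x denser radius grid
        coarse = lognormal_grid(truth.params, n=200)
        fine = lognormal_grid(truth.params, n=2000)
        n = truth.number_density()
        for q in (0.1, 0.7, 3.0):
            a = polydisperse_intensity(q, coarse, contrast, n, 0.0)
            b = polydisperse_intensity(q, fine, contrast, n, 0.0)
            assert a == pytest.approx(b, rel=1e-3)

    def test_monotone_before_first_form_factor_minimum(self, contrast, truth):
        dist = lognormal_grid(truth.params)
        mean = lognormal_moments(truth.params)[0]
        q = np.linspace(1e-3, 4.4934 / mean, 200)
        I = polydisperse_intensity(q, dist, contrast, truth.number_density(), 0.0)
        assert np.all(np.diff(I) <= 0)

    def test_guinier_limit_for_narrow_distribution(self, contrast):
        R = 3.0
        dist = lognormal_grid(LognormalParams(1.0, R, 1e-3), n=400)
        q = np.linspace(1e-4, 0.05, 50)
        I = polydisperse_intensity(q, dist, contrast, 1e20, 0.0)
        slope = np.polyfit(q ** 2, np.log(I), 1)[0]
        assert -3 * slope == pytest.approx(0.6 * R ** 2, rel=0.01)


class TestContrast:
    def test_silver_in_water_at_8_kev(self):
        c = xray_contrast("Ag", 10.49, "H2O", 0.997, energy=8.0)
        assert c.delta_rho == pytest.approx(6.8e-5, abs=0.05e-5)

    def test_identical_materials_cancel(self):
        c = xray_contrast("H2O", 0.997, "H2O", 0.997)
        assert c.delta_rho == 0.0

    def test_water_sld_hand_computed(self):
        # 0.997/18.015 * N_A * 10 electrons * r_e / 1e24
        expected = 0.997 / 18.015 * 6.02214076e23 * 10 * 2.8179403262e-5 / 1e24
        assert sld("H2O", 0.997) == pytest.approx(expected, rel=1e-6)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="unknown element"):
            sld("Xx2O", 1.0)


class TestReweighting:
    def test_narrow_spike_nearly_invariant(self):
        d = lognormal_grid(LognormalParams(1.0, 3.0, 1e-3), n=600)
        v = reweight_distribution(d, "volume")
        assert v.mean() == pytest.approx(d.mean(), rel=1e-4)

    def test_lognormal_median_shift(self):
        p = LognormalParams(1.0, 2.73, 0.229)
        d = lognormal_grid(p, n=1500, span=7)
        v = reweight_distribution(d, "volume")
        fit = sx.extract_lognormal(v)
        assert fit.params.R0 == pytest.approx(2.73 * np.exp(3 * 0.229 ** 2), rel=1e-4)
        assert fit.params.w == pytest.approx(0.229, rel=1e-3)

    def test_round_trip_exact_on_cutoff_safe_grid(self):
        d = lognormal_grid(LognormalParams(1.0, 3.0, 0.25), n=500)
        back = reweight_distribution(reweight_distribution(d, "volume"), "number",
                                     r_min_cutoff=d.radii[0])
        np.testing.assert_allclose(back.density, d.density, rtol=1e-6)

    def test_volume_to_number_requires_cutoff(self):
        d = reweight_distribution(lognormal_grid(LognormalParams(1.0, 3.0, 0.25)),
                                  "volume")
        with pytest.raises(ValueError, match="cutoff"):
            reweight_distribution(d, "number")
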