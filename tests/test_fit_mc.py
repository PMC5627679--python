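import numpy as np
import pytest

import saxsizer as sx
from saxsizer.fit_mc import (
    McConfig,
    mc_fit,
    population_stats,
    volume_fraction_to_mass,
    weighted_population_stats,
)
from saxsizer.scattering_models import NM_TO_M, lognormal_raw_moment, sphere_form_factor

from conftest import make_rebinned


def _monodisperse_curve(contrast, R=3.0, n=1e20, B=1.0, npts=80, sig=1e-3):
    q = np.geomspace(0.1, 3.0, npts)
    V = (4 / 3) * np.pi * (R * NM_TO_M) ** 3
    I = n * (contrast.delta_rho_m2() * V) ** 2 * sphere_form_factor(q, R) + B
    return sx.ScatteringCurve("mono", q, I, sig * np.abs(I),
                              absolute_units=True, i_unit="m^-1")


class TestMcFit:
    def test_same_seed_is_bit_identical(self, truth, noisy_rebinned, fast_mc_config):
        a = mc_fit(noisy_rebinned, contrast=truth.contrast, config=fast_mc_config)
        b = mc_fit(noisy_rebinned, contrast=truth.contrast, config=fast_mc_config)
        for ra, rb in zip(a.repetitions, b.repetitions):
            np.testing.assert_array_equal(ra.radii, rb.radii)
            assert ra.chi2 == rb.chi2 and ra.scale == rb.scale
        assert a.volume_fraction == b.volume_fraction

    def test_monodisperse_volume_concentrates_at_truth(self, contrast):
        curve = _monodisperse_curve(contrast)
        cfg = McConfig(n_contributions=100, n_repetitions=3,
                       max_iterations=60_000, seed=2)
        # the 1e-3 relative uncertainties make chi2 <= 1 demand a near-exact
        # match, so the accepted volume must concentrate at the true radius
        res = mc_fit(curve, contrast=contrast, config=cfg)
        for rep in res.repetitions:
            vols = rep.radii ** 3
            inside = (rep.radii >= 2.9) & (rep.radii <= 3.1)
            assert vols[inside].sum() / vols.sum() >= 0.95

    def test_chi2_trace_is_non_increasing(self, truth, noisy_rebinned):
        cfg = McConfig(n_contributions=60, n_repetitions=2,
                       max_iterations=20_000, seed=3, record_trace=True)
        res = mc_fit(noisy_rebinned, contrast=truth.contrast, config=cfg)
        for rep in res.repetitions:
            assert rep.trace is not None
            assert np.all(np.diff(rep.trace) <= 0)

    def test_histogram_nonnegative_and_volume_consistent(self, truth, noisy_rebinned,
                                                         fast_mc_config):
        res = mc_fit(noisy_rebinned, contrast=truth.contrast, config=fast_mc_config)
        assert np.all(res.histogram.density >= 0)
        # integral of the volume-weighted histogram equals the volume fraction
        edges = np.geomspace(np.pi / (2 * noisy_rebinned.q[-1]),
                             np.pi / noisy_rebinned.q[0],
                             fast_mc_config.n_hist_bins + 1)
        total = float(np.sum(res.histogram.density * np.diff(edges)))
        assert total == pytest.approx(res.volume_fraction, rel=1e-9)

    def test_unreachable_target_raises_criterion(self, truth):
        # severely under-reported sigma makes chi2 = 1 unreachable
        reb = make_rebinned(truth, noise_level=0.02, seed=31,
                            sigma_report_factor=0.05)
        cfg = McConfig(n_contributions=60, n_repetitions=2,
                       max_iterations=15_000, seed=4)
        res = mc_fit(reb, contrast=truth.contrast, config=cfg)
        assert res.flagged
        assert res.criterion_used > 1.0
        assert res.criterion_used == pytest.approx(res.repetitions[0].chi2 * 1.02)

    def test_noise_increases_achieved_chi2(self, truth):
        # with a fixed move budget, noisier data cannot fit better on average
        cfg = McConfig(n_contributions=50, n_repetitions=2, chi2_target=0.0,
                       max_iterations=8_000, seed=6)
        lo, hi = [], []
        for seed in range(3):
            quiet = make_rebinned(truth, noise_level=0.004, seed=400 + seed)
            loud = make_rebinned(truth, noise_level=0.03, seed=400 + seed)
            lo.append(mc_fit(quiet, contrast=truth.contrast, config=cfg).reduced_chi2)
            hi.append(mc_fit(loud, contrast=truth.contrast, config=cfg).reduced_chi2)
        assert np.mean(hi) >= np.mean(lo)


class TestPopulationStats:
    def test_equal_radii_have_zero_spread(self):
        m, s = weighted_population_stats([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert m == 2.0 and s == 0.0

    def test_two_point_set_with_equal_volume_weights(self):
        m, s = weighted_population_stats([2.0, 4.0], [1.0, 1.0])
        assert m == pytest.approx(3.0) and s == pytest.approx(1.0)

    def test_lognormal_truth_volume_weighted_mean(self, truth, noisy_rebinned):
        # oracle: <R^4>/<R^3> of the lognormal = R0 exp(7 w^2 / 2)
        cfg = McConfig(n_contributions=200, n_repetitions=6,
                       max_iterations=100_000, seed=8)
        res = mc_fit(noisy_rebinned, contrast=truth.contrast, config=cfg)
        mean_v, _, _, _ = population_stats(res, "volume")
        oracle = (lognormal_raw_moment(truth.params, 4)
                  / lognormal_raw_moment(truth.params, 3))
        assert mean_v == pytest.approx(oracle, rel=0.02)

    def test_empty_result_rejected(self, truth, noisy_rebinned, fast_mc_config):
        res = mc_fit(noisy_rebinned, contrast=truth.contrast, config=fast_mc_config)
        res.repetitions = []
        with pytest.raises(ValueError):
            population_stats(res)


class TestVolumeFractionToMass:
    @pytest.mark.parametrize("phi,rho,expected",
                             [(2.73e-4, 10.49, 2.8638), (0.0, 10.49, 0.0)])
    def test_direct_multiplication(self, phi, rho, expected):
        assert volume_fraction_to_mass(phi, rho) == pytest.approx(expected, rel=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            volume_fraction_to_mass(-0.1)
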