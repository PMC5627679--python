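import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import saxsizer as sx
from saxsizer.preprocess import clip_q, ensemble_bands, match_ensemble, rebin_log, scale_match


def _curve(q, I, sigma=None, **kw):
    return sx.ScatteringCurve("t", np.asarray(q, float), np.asarray(I, float),
                              None if sigma is None else np.asarray(sigma, float), **kw)


class TestClip:
    def test_closed_interval_membership(self):
        c = _curve([0.05, 0.1, 1.0, 3.0, 3.5], np.ones(5))
        out = clip_q(c, min_points=1)
        np.testing.assert_array_equal(out.q, [0.1, 1.0, 3.0])

    def test_curve_inside_window_unchanged(self):
        q = np.geomspace(0.15, 2.5, 40)
        out = clip_q(_curve(q, np.ones(40)))
        np.testing.assert_array_equal(out.q, q)

    def test_log_spaced_survivor_count_matches_enumeration(self):
        # oracle: direct enumeration of the grid inside the closed window
        q = np.geomspace(0.08, 4.0, 200)
        expected = int(np.sum((q >= 0.1) & (q <= 3.0)))
        assert expected == 173
        out = clip_q(_curve(q, np.ones(200)))
        assert len(out) == expected

    def test_too_few_survivors_rejected(self):
        c = _curve(np.geomspace(5.0, 9.0, 30), np.ones(30))
        with pytest.raises(ValueError, match="survive"):
            clip_q(c)


class TestRebin:
    # five points, the first four land in bin 0 and the last in bin 1
    _Q5 = [0.1, 0.101, 0.102, 0.103, 2.9]

    def test_propagated_uncertainty_of_mean(self):
        # 4 points in one bin, I=100, sigma=10 -> sqrt(400)/4 = 5; floor 1 not binding
        c = _curve(self._Q5, [100.0] * 5, [10.0] * 5)
        out = rebin_log(c, n_bins=2)
        assert out.bin_count[0] == 4
        assert out.sigma[0] == pytest.approx(5.0)

    def test_floor_binds_for_tiny_sigma(self):
        c = _curve(self._Q5, [100.0] * 5, [0.1] * 5)
        out = rebin_log(c, n_bins=2)
        assert out.sigma[0] == pytest.approx(1.0)   # floored to 1% of 100
        assert out.floored_fraction == 1.0

    def test_sem_branch_when_sigma_absent(self):
        vals = [90.0, 100.0, 110.0, 100.0]
        c = _curve(self._Q5, vals + [100.0])
        out = rebin_log(c, n_bins=2)
        sem = np.std(vals, ddof=1) / 2.0
        assert out.sigma[0] == pytest.approx(max(sem, 0.01 * 100))

    def test_passthrough_when_bins_exceed_points(self):
        q = np.geomspace(0.1, 3.0, 50)
        I = 1.0 / q
        c = _curve(q, I, 0.05 * I)
        out = rebin_log(c, n_bins=100)
        np.testing.assert_array_equal(out.q, q)
        np.testing.assert_array_equal(out.intensity, I)

    def test_rejects_degenerate_bin_count(self):
        c = _curve(np.geomspace(0.1, 3, 30), np.ones(30))
        with pytest.raises(ValueError):
            rebin_log(c, n_bins=1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_floor_rule_holds_everywhere(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 200))
        q = np.sort(rng.uniform(0.1, 3.0, n))
        q += np.arange(n) * 1e-9  # enforce strict monotonicity
        I = rng.normal(100.0, 30.0, n)
        sig = rng.uniform(0.01, 20.0, n)
        out = rebin_log(_curve(q, I, sig), n_bins=int(rng.integers(5, 60)))
        pos = out.intensity > 0
        assert np.all(out.sigma[pos] >= 0.01 * out.intensity[pos] - 1e-12)
        assert 0.0 <= out.floored_fraction <= 1.0


class TestScaleMatch:
    def _pair(self):
        q = np.geomspace(0.1, 3, 80)
        I = 1e3 / (1 + (q * 3) ** 2) ** 2
        ref = _curve(q, I, 0.01 * I)
        return q, I, ref

    def test_identity_and_exact_scaling(self):
        q, I, ref = self._pair()
        assert scale_match(ref, ref) == pytest.approx(1.0)
        double = _curve(q, 2 * I)
        assert scale_match(double, ref) == pytest.approx(0.5)

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 3.0])
    def test_inverse_scaling_law(self, alpha):
        q, I, ref = self._pair()
        assert scale_match(_curve(q, alpha * I), ref) == pytest.approx(1 / alpha)

    def test_noisy_recovery_unbiased_within_standard_error(self):
        # Monte Carlo oracle: the closed-form estimator applied to noisy data
        # should recover the true scale within 3 SE of its empirical spread
        q, I, ref = self._pair()
        true_s = 0.7
        rng = np.random.default_rng(42)
        estimates = []
        for _ in range(1000):
            noisy = I / true_s + rng.normal(0, 0.01 * I / true_s)
            estimates.append(scale_match(_curve(q, noisy), ref))
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - true_s) < 3 * se

    def test_degenerate_curve_rejected(self):
        q, I, ref = self._pair()
        with pytest.raises(ValueError, match="degenerate"):
            scale_match(_curve(q, np.zeros_like(q)), ref)


class TestEnsembleBands:
    def test_identical_curves_have_zero_deviation(self):
        q = np.geomspace(0.1, 3, 50)
        I = 1.0 / q
        curves = [_curve(q, I, 0.01 * I) for _ in range(5)]
        bands = ensemble_bands(curves)
        np.testing.assert_allclose(bands["relative"]["hi_90"], 0.0, atol=1e-14)
        np.testing.assert_allclose(bands["band_2sd"][0], bands["median"])

    def test_90_band_spans_extremes_of_three_scaled_curves(self):
        q = np.geomspace(0.1, 3, 50)
        I = 1.0 / q
        curves = [_curve(q, f * I) for f in (0.9, 1.0, 1.1)]
        bands = ensemble_bands(curves)
        np.testing.assert_allclose(bands["band_90"][0], 0.9 * I + 0.01 * I, rtol=0.02)
        np.testing.assert_allclose(bands["band_90"][1], 1.1 * I - 0.01 * I, rtol=0.02)

    def test_mismatched_grids_rejected(self):
        q = np.geomspace(0.1, 3, 50)
        curves = [_curve(q, 1 / q), _curve(q * 1.01, 1 / q), _curve(q, 1 / q)]
        with pytest.raises(ValueError, match="common q grid"):
            ensemble_bands(curves)

    def test_synthetic_ensemble_band_is_a_few_percent(self, truth):
        # with ~5% per-lab scale jitter the scale-matched 2-SD intensity band
        # should sit in the few-to-ten-percent range of the median
        rr = sx.simulate_round_robin(n_labs=45, truth=truth, master_seed=21)
        rebinned = [rebin_log(clip_q(sx.harmonize_units(c))) for c in rr.curves]
        matched = match_ensemble(rebinned)
        bands = ensemble_bands(matched)
        rel = np.abs(np.vstack([bands["relative"]["lo_2sd"], bands["relative"]["hi_2sd"]]))
        mid = slice(10, 90)  # away from grid edges
        assert 0.005 < np.median(rel[:, mid]) < 0.12
        assert np.percentile(rel[:, mid], 95) < 0.25
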