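"""Lineage and growth-curve estimators."""

import numpy as np
import pandas as pd
import pytest

from mazsim.errors import InsufficientDataError, ParameterError
from mazsim import lineage


class TestElongationRate:
    def test_exact_on_noiseless_exponential(self):
        t = np.arange(0, 31, 5.0)
        L = 2.0 * np.exp(0.02 * t)
        assert lineage.elongation_rate(L, t) == pytest.approx(0.02, abs=1e-12)

    def test_zero_for_constant_length(self):
        got = lineage.elongation_rate([3.0] * 5, [0, 5, 10, 15, 20])
        assert got == pytest.approx(0.0, abs=1e-12)

    def test_requires_three_frames(self):
        with pytest.raises(InsufficientDataError):
            lineage.elongation_rate([2.0, 2.1], [0.0, 5.0])

    def test_monte_carlo_coverage_under_multiplicative_noise(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 35, 5.0)
        hits = 0
        for _ in range(1000):
            L = 2.0 * np.exp(0.02 * t) * np.exp(0.02 * rng.standard_normal(t.size))
            if 0.015 <= lineage.elongation_rate(L, t) <= 0.025:
                hits += 1
        assert hits >= 950


class TestMaxGrowthRate:
    def test_pure_exponential_returns_its_rate(self):
        t = np.arange(0, 200, 10.0)
        assert lineage.max_growth_rate(0.01 * np.exp(0.012 * t), t) == \
            pytest.approx(0.012, abs=1e-12)

    def test_flat_curve_returns_zero(self):
        assert lineage.max_growth_rate(np.ones(20)) == pytest.approx(0.0)

    def test_matches_exhaustive_window_enumeration(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 400, 10.0)
        biomass = 0.01 * np.exp(0.01 * t) * np.exp(0.05 * rng.standard_normal(t.size))
        got = lineage.max_growth_rate(biomass, t, window=5)
        logb = np.log(biomass)
        brute = max(np.polyfit(t[i:i + 5], logb[i:i + 5], 1)[0]
                    for i in range(len(t) - 4))
        assert got == pytest.approx(brute, abs=1e-12)

    def test_logistic_curve_peaks_early_in_exponential_phase(self):
        t = np.arange(0, 600, 10.0)
        K, r, x0 = 1.0, 0.02, 1e-3
        x = K / (1 + (K / x0 - 1) * np.exp(-r * t))
        rate, t_max, _ = lineage.max_growth_rate(x, t, return_time=True)
        assert rate == pytest.approx(r, rel=0.02)
        assert t_max < 150

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            lineage.max_growth_rate([1.0, 2.0, 3.0])


class TestRecoveryTime:
    def _curve(self, t, lag):
        # lag phase, then decelerating exponential growth: the maximum
        # log-slope window sits just after the lag ends (unique maximum)
        u = np.clip(t - lag, 0.0, None)
        return 0.01 * np.exp(0.015 * u - 1.5e-5 * u ** 2)

    def test_identical_curves_give_zero_delay(self):
        t = np.arange(0, 600, 10.0)
        x = self._curve(t, 100.0)
        assert lineage.recovery_time(x, x, t).delay_min == 0.0

    def test_time_shift_recovered_within_half_interval(self):
        t = np.arange(0, 900, 10.0)
        control = self._curve(t, 100.0)
        induced = self._curve(t, 220.0)
        rec = lineage.recovery_time(induced, control, t)
        assert rec.delay_min == pytest.approx(120.0, abs=5.0)
        assert not rec.lower_bound

    def test_boundary_maximum_flagged_as_lower_bound(self):
        t = np.arange(0, 300, 10.0)
        control = self._curve(t, 20.0)
        induced = 0.01 * np.exp(0.00004 * t ** 2)  # still accelerating at end
        assert lineage.recovery_time(induced, control, t).lower_bound


class TestRecoverySlope:
    def test_constant_rates_give_zero_slope(self):
        t = np.linspace(550, 700, 6)
        assert lineage.recovery_slope(np.full(6, 0.02), t) == pytest.approx(0.0)

    def test_linear_ramp_recovered(self):
        t = np.linspace(545, 725, 10)
        rates = 0.001 * t
        assert lineage.recovery_slope(rates, t) == pytest.approx(0.001)

    def test_points_outside_window_ignored(self):
        t = np.array([100.0, 560.0, 600.0, 700.0, 900.0])
        rates = np.array([9.9, 0.01, 0.02, 0.03, 9.9])
        got = lineage.recovery_slope(rates, t, window=(545.0, 725.0))
        assert got == pytest.approx(np.polyfit(t[1:4], rates[1:4], 1)[0])

    def test_by_lineage_skips_sparse_lineages_with_warning(self):
        df = pd.DataFrame({
            "cell_id": [0, 0, 0, 1],
            "t_div_min": [560.0, 620.0, 700.0, 600.0],
            "elongation_rate_per_min": [0.01, 0.015, 0.02, 0.01],
        })
        with pytest.warns(UserWarning, match="skipped 1"):
            out = lineage.recovery_slopes_by_lineage(df)
        assert list(out.index) == [0]


class TestLengthFluctuationSlopes:
    def test_equal_lengths_give_zero_slopes(self):
        out = lineage.length_fluctuation_slopes([0, 30, 60], [4.0, 4.0, 4.0])
        assert np.allclose(out, 0.0)

    def test_single_pair_arithmetic(self):
        out = lineage.length_fluctuation_slopes([0.0, 30.0], [4.0, 5.0])
        assert out == pytest.approx([1.0 / 30.0])

    def test_fewer_than_two_divisions_empty(self):
        assert lineage.length_fluctuation_slopes([10.0], [4.0]).size == 0

    def test_antisymmetric_under_time_reversal(self):
        rng = np.random.default_rng(2)
        t = np.cumsum(rng.uniform(20, 40, size=8))
        L = rng.uniform(3.5, 4.5, size=8)
        fwd = lineage.length_fluctuation_slopes(t, L)
        rev = lineage.length_fluctuation_slopes(t.max() - t[::-1], L[::-1])
        assert np.allclose(rev, -fwd[::-1])

    def test_from_table_uses_pre_division_frames(self):
        rows = []
        for i, (t, L) in enumerate([(30, 4.0), (60, 4.4), (95, 3.9)]):
            rows.append((float(t), 0, L, 0.5 * L, 100.0, True))
            rows.append((float(t) + 5.0, 0, L / 2, 0.25 * L, 50.0, False))
        df = pd.DataFrame(rows, columns=list(lineage.LINEAGE_COLUMNS))
        slopes = lineage.length_fluctuation_slopes_from_table(df)[0]
        assert slopes == pytest.approx([0.4 / 30.0, -0.5 / 35.0])


class TestNormalizedFluorescence:
    def test_examples(self):
        assert lineage.normalized_fluorescence(1000.0, 100.0) == 10.0
        assert lineage.normalized_fluorescence(2000.0, 200.0) == 10.0
        assert lineage.normalized_fluorescence(0.0, 50.0) == 0.0

    def test_zero_area_rejected(self):
        with pytest.raises(ParameterError):
            lineage.normalized_fluorescence(10.0, 0.0)


class TestCompareDistributions:
    def test_identical_samples_do_not_reject(self):
        x = np.arange(20.0)
        out = lineage.compare_distributions(x, x)
        assert out.ks_p == pytest.approx(1.0)

    def test_disjoint_supports_reject_strongly(self):
        x = np.linspace(0, 1, 100)
        y = np.linspace(10, 11, 100)
        out = lineage.compare_distributions(x, y)
        assert out.mannwhitney_p < 1e-6
        assert out.ks_p < 1e-6

    def test_antimonotone_pairs_have_rho_minus_one(self):
        x = np.arange(30.0)
        out = lineage.compare_distributions(x, -x ** 3, paired=True)
        assert out.spearman_rho == pytest.approx(-1.0)

    def test_degenerate_samples_flagged(self):
        out = lineage.compare_distributions(np.ones(10), np.arange(10.0))
        assert out.degenerate

    def test_minimum_sample_size(self):
        with pytest.raises(InsufficientDataError):
            lineage.compare_distributions([1.0] * 4, [2.0] * 10)
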