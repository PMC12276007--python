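"""Kinetic model fitting: exponentials, HDX decays, melts, conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pugfold.kinetics import (ExchangeSeries, FitError, KineticTrace,
                              convert_rate, convert_time,
                              fit_boltzmann_melt, fit_hdx_biexponential,
                              fit_hdx_mono, fit_single_exponential,
                              halflife_from_rate, rate_from_halflife,
                              split_fit_consistency)
from pugfold import synth

LN2 = math.log(2.0)


class TestConversions:
    def test_13_min_halflife_rate(self):
        k_s = convert_rate(rate_from_halflife(13.0), "min", "s")
        assert k_s == pytest.approx(0.0009, abs=5e-5)
        assert k_s == pytest.approx(LN2 / 780.0)

    def test_g17_quartet_halflife(self):
        assert halflife_from_rate(0.0114) == pytest.approx(60.8, abs=0.15)

    def test_unit_halflife(self):
        assert halflife_from_rate(LN2) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            halflife_from_rate(0.0)
        with pytest.raises(ValueError):
            rate_from_halflife(-1.0)

    @given(st.floats(1e-6, 1e6))
    @settings(deadline=None, derandomize=True)
    def test_exact_inverse(self, k):
        assert rate_from_halflife(halflife_from_rate(k)) == pytest.approx(k, rel=1e-14)
        assert halflife_from_rate(k) * k == pytest.approx(LN2, rel=1e-14)

    def test_time_unit_roundtrip(self):
        assert convert_time(1.0, "day", "h") == 24.0
        assert convert_rate(convert_rate(0.5, "h", "s"), "s", "h") == pytest.approx(0.5)


class TestSingleExponential:
    def test_recovers_17_min_halflife(self):
        trace = synth.generate_folding_trace(17.0, noise_sd=0.0)
        fit = fit_single_exponential(trace)
        assert abs(fit.t_half - 17.0) / 17.0 < 1e-6
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_signal_is_no_transition(self):
        trace = KineticTrace(np.linspace(0, 100, 50), np.full(50, 3.0))
        fit = fit_single_exponential(trace)
        assert fit.no_transition
        assert fit.k is None

    def test_unit_rate(self):
        t = np.linspace(0, 5, 60)
        trace = KineticTrace(t, 2.0 + 3.0 * np.exp(-LN2 * t))
        fit = fit_single_exponential(trace)
        assert fit.t_half == pytest.approx(1.0, rel=1e-8)

    @pytest.mark.parametrize("t_half", [5.0, 17.0, 13.0, 30.0, 120.0])
    def test_noiseless_sweep_exact(self, t_half):
        fit = fit_single_exponential(synth.generate_folding_trace(t_half, noise_sd=0.0))
        assert abs(fit.t_half - t_half) / t_half < 1e-6


class TestHdxMono:
    def test_recovers_g9_15_rate(self):
        series = synth.generate_hdx_series("mono", i0=0.99, k=0.0054, noise_sd=0.0)
        fit = fit_hdx_mono(series)
        assert fit.k_ex == pytest.approx(0.0054, rel=1e-8)
        assert fit.i_inf == 0.0

    def test_flat_series_boundary_flag(self):
        t = np.linspace(0.3, 2.0, 10)
        fit = fit_hdx_mono(ExchangeSeries(t, np.ones_like(t)))
        assert fit.boundary

    def test_noisy_recovery_within_10pct(self):
        series = synth.generate_hdx_series("mono", i0=1.0, k=0.009,
                                           noise_sd=0.02, seed=7)
        fit = fit_hdx_mono(series)
        assert abs(fit.k_ex - 0.009) / 0.009 < 0.10

    @pytest.mark.parametrize("k", np.geomspace(1e-3, 1.0, 7).tolist())
    def test_noiseless_sweep_exact(self, k):
        series = synth.generate_hdx_series("mono", i0=1.0, k=k, noise_sd=0.0)
        assert abs(fit_hdx_mono(series).k_ex - k) / k < 1e-6

    def test_free_floor_recovers_offset(self):
        t = synth.default_hdx_schedule()
        y = 0.8 * np.exp(-0.05 * t) + 0.1
        fit = fit_hdx_mono(ExchangeSeries(t, y), constrain_floor_to_zero=False)
        assert fit.i_inf == pytest.approx(0.1, abs=1e-6)
        assert fit.k_ex == pytest.approx(0.05, rel=1e-6)


class TestHdxBiexponential:
    GU13 = dict(i0=1.14, k_fast=1.34, k_slow=0.008, fast_fraction=0.502)

    def test_noiseless_recovery_exact(self):
        series = synth.generate_hdx_series("biexp", noise_sd=0.0, **self.GU13)
        fit = fit_hdx_biexponential(series)
        assert fit.model == "biexp"
        assert fit.k_ex_fast == pytest.approx(1.34, rel=1e-6)
        assert fit.k_ex_slow == pytest.approx(0.008, rel=1e-6)
        assert fit.fast_ratio_percent == pytest.approx(50.2, rel=1e-6)
        assert fit.k_ex_fast > fit.k_ex_slow

    def test_fast_ratio_unbiased_over_replicates(self):
        """Mean fitted fast ratio over seeded noisy replicates stays within
        the reported uncertainty of the generating 50.2%."""
        ratios = []
        for seed in range(60):
            series = synth.generate_hdx_series("biexp", noise_sd=0.02,
                                               seed=2000 + seed, **self.GU13)
            ratios.append(fit_hdx_biexponential(series).fast_ratio_percent)
        assert abs(np.mean(ratios) - 50.2) < 1.1

    def test_pure_mono_input_degenerates(self):
        series = synth.generate_hdx_series("biexp", i0=1.0, k_fast=0.7,
                                           k_slow=0.01, fast_fraction=0.0,
                                           noise_sd=0.0)
        fit = fit_hdx_biexponential(series)
        assert fit.degenerate
        assert fit.model == "mono"
        assert fit.k_ex == pytest.approx(0.01, rel=1e-6)

    def test_equal_rates_degenerate(self):
        series = synth.generate_hdx_series("biexp", i0=1.0, k_fast=0.02,
                                           k_slow=0.02, fast_fraction=0.5,
                                           noise_sd=0.0)
        fit = fit_hdx_biexponential(series)
        assert fit.degenerate
        assert fit.k_ex == pytest.approx(0.02, rel=1e-4)

    def test_mono_fit_of_biphasic_data_is_worse(self):
        series = synth.generate_hdx_series("biexp", noise_sd=0.01, seed=11,
                                           **self.GU13)
        mono = fit_hdx_mono(series)
        biexp = fit_hdx_biexponential(series)
        assert biexp.r2 > mono.r2


class TestSplitFitConsistency:
    def test_identical_halves_consistent(self):
        t = synth.default_hdx_schedule()
        y = np.exp(-0.01 * t)
        series = ExchangeSeries(t, y)
        halves = [ExchangeSeries(t, 0.5 * y), ExchangeSeries(t, 0.5 * y)]
        report = split_fit_consistency(series, halves)
        assert report["max_rel_discrepancy"] < 1e-9
        assert report["consistent"]

    def test_inconsistent_halves_flagged(self):
        t = synth.default_hdx_schedule()
        a = 0.5 * np.exp(-0.005 * t)
        b = 0.5 * np.exp(-0.010 * t)
        report = split_fit_consistency(
            ExchangeSeries(t, a + b),
            [ExchangeSeries(t, a), ExchangeSeries(t, b)])
        assert not report["consistent"]
        assert report["max_rel_discrepancy"] > 0.2

    def test_global_rate_between_regional_rates(self):
        """Pooling quartet signals with different rates yields a global fit
        bracketed by the regional fits."""
        t = synth.default_hdx_schedule()
        slow = 0.5 * np.exp(-0.0054 * t)  # buried quartet
        fast = 0.5 * np.exp(-0.0179 * t)  # 3'-terminal G
        report = split_fit_consistency(
            ExchangeSeries(t, slow + fast),
            [ExchangeSeries(t, slow), ExchangeSeries(t, fast)])
        ks = sorted(report["k_regions"])
        assert ks[0] < report["k_global"] < ks[-1]


class TestBoltzmannMelt:
    def test_recovers_tm_515(self):
        curve = synth.generate_melt_curve(51.5, noise_sd=0.0)
        assert fit_boltzmann_melt(curve).tm == pytest.approx(51.5, abs=1e-6)

    def test_noisy_tm_331_within_half_degree(self):
        curve = synth.generate_melt_curve(33.1, noise_sd=0.02, seed=5)
        assert abs(fit_boltzmann_melt(curve).tm - 33.1) < 0.5

    def test_tm_at_half_amplitude(self):
        """For a symmetric sigmoid the fitted Tm sits at the half-amplitude
        temperature."""
        curve = synth.generate_melt_curve(47.9, dt_c=3.0, noise_sd=0.0)
        fit = fit_boltzmann_melt(curve)
        half = 0.5 * (fit.a1 + fit.a2)
        t_half = float(np.interp(half, curve.signal[::1], curve.times[::1])
                       if curve.signal[0] < curve.signal[-1]
                       else np.interp(half, curve.signal[::-1], curve.times[::-1]))
        assert fit.tm == pytest.approx(t_half, abs=0.05)

    def test_flat_curve_rejected(self):
        t = np.arange(20.0, 82.0, 1.5)
        with pytest.raises(FitError):
            fit_boltzmann_melt(KineticTrace(t, np.full_like(t, -3.0), "C"))

    def test_increasing_direction_accepted(self):
        curve = synth.generate_melt_curve(48.3, baseline_folded=1.0,
                                          baseline_unfolded=6.0, noise_sd=0.0)
        assert fit_boltzmann_melt(curve).tm == pytest.approx(48.3, abs=1e-6)
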