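"""Spike-train analyses on constructed fixtures and generator round trips."""

import math

import numpy as np
import pytest

from fracspike.fractional_core import fractional_sine_derivative
from fracspike.spike_analysis import (RateSeries, SpikeTrain, avalanches,
                                      classify_complex, classify_on_off,
                                      cumulative_relative, detect_spikes,
                                      firing_rate, fit_adaptation,
                                      fractional_exponents, gain_phase,
                                      spectrum_exponent)
from fracspike.stimuli import deterministic_wave, pink_noise


def pulse_trace(pulse_times, duration=100.0, dt=0.1, width=1.0, high=30.0):
    t = np.arange(0, duration + dt / 2, dt)
    v = np.full_like(t, -70.0)
    for pt in pulse_times:
        v[(t >= pt) & (t < pt + width)] = high
    return t, v


class TestDetectSpikes:
    def test_pulse_onsets(self):
        t, v = pulse_trace([10.0, 40.0, 70.0])
        st = detect_spikes(t, v, threshold=0.0)
        np.testing.assert_allclose(st.times, [10.0, 40.0, 70.0])

    def test_flat_trace_empty(self):
        t, v = pulse_trace([])
        assert len(detect_spikes(t, v, threshold=0.0)) == 0

    def test_dc_shift_below_threshold_invariant(self):
        t, v = pulse_trace([10.0, 40.0])
        a = detect_spikes(t, v, threshold=0.0)
        b = detect_spikes(t, v + 5.0, threshold=0.0)   # stays below 0 at rest
        np.testing.assert_array_equal(a.times, b.times)

    def test_min_separation_filters(self):
        t, v = pulse_trace([10.0, 11.0, 40.0], width=0.3)
        st = detect_spikes(t, v, threshold=0.0, min_separation=5.0)
        np.testing.assert_allclose(st.times, [10.0, 40.0])


class TestClassifyComplex:
    def test_single_plateau_among_narrow_spikes(self):
        t, v = pulse_trace([10.0, 40.0, 120.0], duration=150.0)
        v[(t >= 40.0) & (t < 90.0)] = 30.0    # one 50 ms plateau
        st = detect_spikes(t, v, threshold=0.0)
        lab = classify_complex(t, v, st, plateau_level=0.0, min_plateau=10.0)
        assert list(lab.labels) == ["S", "C", "S"]

    def test_all_narrow_no_complex(self):
        t, v = pulse_trace([10.0, 40.0, 70.0])
        st = detect_spikes(t, v, threshold=0.0)
        lab = classify_complex(t, v, st, plateau_level=0.0, min_plateau=10.0)
        assert list(lab.labels) == ["S", "S", "S"]

    def test_boundary_duration_counts_as_complex(self):
        t, v = pulse_trace([10.0], duration=60.0, width=20.0)
        st = detect_spikes(t, v, threshold=0.0)
        lab = classify_complex(t, v, st, plateau_level=0.0, min_plateau=20.0)
        assert list(lab.labels) == ["C"]


class TestFiringRate:
    def test_uniform_train_constant_rate(self):
        st = SpikeTrain(times=np.arange(0, 1000.0, 50.0))
        rs = firing_rate(st, grid_dt=10.0)
        np.testing.assert_allclose(rs.rate, 20.0)

    def test_two_spikes_instantaneous_value(self):
        st = SpikeTrain(times=np.array([0.0, 500.0]))
        rs = firing_rate(st, grid_dt=100.0)
        assert rs.time[-1] == pytest.approx(500.0)
        np.testing.assert_allclose(rs.rate, 2.0)

    def test_fewer_than_two_spikes_yields_empty(self):
        rs = firing_rate(SpikeTrain(times=np.array([10.0])))
        assert len(rs.time) == 0

    def test_decreasing_isis_give_nondecreasing_rate(self):
        times = np.cumsum(100.0 / np.arange(1, 30) ** 0.5)
        rs = firing_rate(SpikeTrain(times=times), grid_dt=1.0)
        assert np.all(np.diff(rs.rate) >= -1e-9)

    def test_windowed_count_convention(self):
        st = SpikeTrain(times=np.array([100.0, 150.0, 220.0, 800.0]))
        rs = firing_rate(st, method="windowed", window=200.0)
        # 3 spikes in [100, 300] over 0.2 s
        assert rs.rate[0] == pytest.approx(15.0)
        assert rs.time[0] == pytest.approx(300.0)


class TestFitAdaptation:
    def test_recovers_generation_time_constant(self):
        period = 2000.0
        t = np.arange(0, 2 * period, 5.0)
        tau = 300.0
        phase = (t % period) < period / 2
        r = np.where(phase, 40 - 15 * np.exp(-(t % (period / 2)) / tau),
                     20 + 10 * np.exp(-(t % (period / 2)) / tau))
        rs = RateSeries(time=t, rate=r)
        boundaries = np.arange(0, 2 * period + 1, period / 2)
        fit = fit_adaptation(rs, boundaries)
        assert fit.tau_up == pytest.approx(300.0, abs=15.0)
        assert fit.tau_down == pytest.approx(300.0, abs=15.0)

    def test_constant_phase_flagged(self):
        t = np.arange(0, 1000.0, 5.0)
        rs = RateSeries(time=t, rate=np.full_like(t, 30.0))
        fit = fit_adaptation(rs, [0.0, 500.0, 1000.0])
        assert math.isnan(fit.tau_up)
        assert fit.flags


class TestGainPhase:
    def make_stim(self, lam=1000.0, dur=6000.0, dt=1.0, amp=2.0):
        return deterministic_wave("sinusoid", DC=5.0, amplitude=amp, period=lam,
                                  duration=dur, dt=dt)

    def test_rate_equal_to_stimulus(self):
        stim = self.make_stim()
        rs = RateSeries(time=stim.time, rate=stim.current + 10.0)
        g, p = gain_phase(rs, stim)
        assert g == pytest.approx(1.0, rel=1e-9)
        assert p == pytest.approx(0.0, abs=1e-9)

    def test_time_derivative_has_quarter_phase(self):
        stim = self.make_stim()
        w = 2 * math.pi / 1000.0
        rate = 50.0 + 2.0 * w * np.cos(w * stim.time)
        rs = RateSeries(time=stim.time, rate=rate)
        g, p = gain_phase(rs, stim)
        assert p == pytest.approx(math.pi / 2, abs=1e-9)
        assert g == pytest.approx(w, rel=1e-9)

    def test_fractional_derivative_phase(self):
        stim = self.make_stim()
        r = fractional_sine_derivative(2.0, 1 / 1000.0, 0.4, stim.time)
        rs = RateSeries(time=stim.time, rate=50.0 + r)
        _, p = gain_phase(rs, stim)
        assert p == pytest.approx(0.4 * math.pi / 2, abs=1e-9)

    def test_requires_sinusoid(self):
        stim = deterministic_wave("square", 5.0, 1.0, 100.0, 1000.0, 1.0)
        rs = RateSeries(time=stim.time, rate=stim.current)
        with pytest.raises(ValueError):
            gain_phase(rs, stim)


class TestFractionalExponents:
    @pytest.mark.parametrize("eta", [0.25, 0.6, 1.0])
    def test_analytic_self_consistency(self, eta):
        sweep = []
        for lam in (400.0, 1000.0, 2500.0, 6000.0):
            g = (2 * math.pi / lam) ** eta
            sweep.append((lam, g, eta * math.pi / 2))
        fx = fractional_exponents(sweep)
        assert fx.eta_G.exponent == pytest.approx(eta, rel=1e-9)
        assert fx.eta_phi == pytest.approx(eta, rel=1e-9)

    def test_flat_sweep_gives_zero(self):
        sweep = [(lam, 3.0, 0.0) for lam in (100.0, 300.0, 900.0, 2700.0)]
        fx = fractional_exponents(sweep)
        assert fx.eta_G.exponent == pytest.approx(0.0, abs=1e-12)
        assert fx.eta_phi == pytest.approx(0.0, abs=1e-12)

    def test_requires_enough_points_and_span(self):
        with pytest.raises(ValueError):
            fractional_exponents([(100.0, 1, 0), (200.0, 1, 0), (400.0, 1, 0)])
        with pytest.raises(ValueError):
            fractional_exponents([(100.0, 1, 0), (150.0, 1, 0),
                                  (200.0, 1, 0), (400.0, 1, 0)])


class TestSpectrumExponent:
    def test_roundtrip_on_pink_rate(self):
        slopes = []
        for seed in range(5):
            stim = pink_noise(-0.5, (0.5, 10.0), DC=30.0, rms_amplitude=5.0,
                              duration=120_000.0, dt=10.0, seed=seed)
            rs = RateSeries(time=stim.time, rate=stim.current)
            slopes.append(spectrum_exponent(rs, (0.5, 10.0)).exponent)
        assert np.mean(slopes) == pytest.approx(-0.5, abs=0.1)

    def test_white_rate_flat(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 60_000.0, 10.0)
        rs = RateSeries(time=t, rate=30.0 + rng.standard_normal(len(t)))
        fit = spectrum_exponent(rs, (0.5, 10.0))
        assert fit.exponent == pytest.approx(0.0, abs=0.1)

    def test_invariant_to_dc_offset(self):
        stim = pink_noise(-0.4, (0.5, 10.0), DC=30.0, rms_amplitude=5.0,
                          duration=60_000.0, dt=10.0, seed=3)
        rs1 = RateSeries(time=stim.time, rate=stim.current)
        rs2 = RateSeries(time=stim.time, rate=stim.current + 17.0)
        a = spectrum_exponent(rs1, (0.5, 10.0))
        b = spectrum_exponent(rs2, (0.5, 10.0))
        assert a.exponent == pytest.approx(b.exponent, rel=1e-9)

    def test_whitening_shift_definition(self):
        stim = pink_noise(-0.4, (0.5, 10.0), 30.0, 5.0, 60_000.0, 10.0, seed=3)
        fit = spectrum_exponent(RateSeries(time=stim.time, rate=stim.current),
                                (0.5, 10.0))
        assert fit.whitening_shift(-0.2) == pytest.approx(fit.exponent + 0.2)


class TestAvalanches:
    def label_train(self, pattern):
        times = np.arange(1.0, len(pattern) + 1.0)
        return SpikeTrain(times=times, labels=np.asarray(list(pattern)))

    def test_definition_on_sequence(self):
        res = avalanches(self.label_train("CSSSCSC"))
        np.testing.assert_array_equal(res.sizes, [3, 1])

    def test_no_complex_spikes_empty(self):
        res = avalanches(self.label_train("SSSS"))
        assert len(res.sizes) == 0 and res.fit is None

    def test_count_conservation(self):
        rng = np.random.default_rng(2)
        pattern = "".join(rng.choice(["S", "C"], p=[0.85, 0.15], size=500))
        train = self.label_train(pattern)
        res = avalanches(train)
        lab = np.asarray(train.labels)
        cpos = np.flatnonzero(lab == "C")
        outside = cpos[0] + (len(lab) - 1 - cpos[-1])
        assert res.sizes.sum() + len(cpos) + outside == len(lab)

    def test_power_law_recovery(self):
        rng = np.random.default_rng(7)
        # discrete power-law sizes p(s) ~ s^-1.5 via inverse CDF
        u = rng.uniform(size=5000)
        sizes = np.floor((1 - u) ** (-1 / 0.5)).astype(int)   # alpha = 1.5
        sizes = sizes[sizes < 10_000]
        labels, times = ["C"], [0.0]
        tcur = 0.0
        for s in sizes:
            for _ in range(s):
                tcur += 1.0
                times.append(tcur); labels.append("S")
            tcur += 1.0
            times.append(tcur); labels.append("C")
        res = avalanches(SpikeTrain(times=np.array(times),
                                    labels=np.array(labels)))
        assert res.fit.exponent == pytest.approx(-1.5, abs=0.1)


class TestClassifyOnOff:
    def setup_method(self):
        self.stim = deterministic_wave("sinusoid", 5.0, 1.0, 500.0, 3000.0, 1.0)

    def test_on(self):
        rs = RateSeries(time=self.stim.time, rate=self.stim.current * 3.0)
        assert classify_on_off(rs, self.stim)[0] == "ON"

    def test_off(self):
        rs = RateSeries(time=self.stim.time, rate=20.0 - self.stim.current)
        assert classify_on_off(rs, self.stim)[0] == "OFF"

    def test_ambiguous_flagged(self):
        rng = np.random.default_rng(0)
        rs = RateSeries(time=self.stim.time,
                        rate=20.0 + rng.standard_normal(len(self.stim.time)))
        label, corr = classify_on_off(rs, self.stim)
        assert label == "ambiguous" and abs(corr) < 0.1


class TestCumulativeRelative:
    def poisson_train(self, rate_hz, duration_s, rng):
        n = rng.poisson(rate_hz * duration_s)
        return SpikeTrain(times=np.sort(rng.uniform(0, duration_s * 1000.0, n)))

    def test_unchanged_rate_stays_near_one(self):
        # the 95% band is Poisson in the post count, conditional on the
        # pre-window rate, so coverage is checked with an exact-rate pre
        rng = np.random.default_rng(42)
        pre = SpikeTrain(times=np.arange(0.0, 100_000.0, 50.0))   # exactly 20 Hz
        inside = 0
        trials = 100
        for _ in range(trials):
            post = self.poisson_train(20.0, 100.0, rng)
            c = cumulative_relative(pre, post, grid_dt=5.0)
            if c.ci95_lo[-1] <= 1.0 <= c.ci95_hi[-1]:
                inside += 1
        assert inside >= 88

    def test_halved_rate_approaches_half(self):
        rng = np.random.default_rng(1)
        pre = self.poisson_train(40.0, 100.0, rng)
        post = self.poisson_train(20.0, 100.0, rng)
        c = cumulative_relative(pre, post, grid_dt=5.0)
        assert c.relative_cumulative[-1] == pytest.approx(0.5, abs=0.05)

    def test_requires_long_pre_window(self):
        rng = np.random.default_rng(2)
        pre = self.poisson_train(20.0, 30.0, rng)
        post = self.poisson_train(20.0, 60.0, rng)
        with pytest.raises(ValueError):
            cumulative_relative(pre, post)
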