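"""Simulators: classic limits, fractional signatures, scheme correctness."""

import math

import numpy as np
import pytest

from fracspike.fractional_core import mittag_leffler
from fracspike.neuron_models import (HHParams, LIFParams, hh_rates,
                                     hh_steady_state, simulate_fhh,
                                     simulate_flif)
from fracspike.stimuli import deterministic_wave


def constant(dc, duration, dt):
    return deterministic_wave("constant", DC=dc, amplitude=0.0, period=0.0,
                              duration=duration, dt=dt)


class TestHHRates:
    def test_values_at_offset_voltage(self):
        a_n, b_n, a_m, b_m, a_h, b_h = hh_rates(-65.0, V0=-65.0)
        assert b_n == pytest.approx(0.125)
        assert a_h == pytest.approx(0.07)
        assert b_m == pytest.approx(4.0)

    def test_removable_singularities(self):
        # alpha_n at u = 10 mV -> 0.1; alpha_m at u = 25 mV -> 1.0
        a_n = hh_rates(-55.0, V0=-65.0)[0]
        a_m = hh_rates(-40.0, V0=-65.0)[2]
        assert a_n == pytest.approx(0.1, rel=1e-9)
        assert a_m == pytest.approx(1.0, rel=1e-9)
        # continuous through the singular point
        eps = 1e-9
        assert hh_rates(-55.0 + eps, V0=-65.0)[0] == pytest.approx(0.1, rel=1e-5)

    def test_classic_resting_gates(self):
        n, m, h = hh_steady_state(-65.0, V0=-65.0)
        assert n == pytest.approx(0.3177, abs=1e-3)
        assert m == pytest.approx(0.0529, abs=1e-3)
        assert h == pytest.approx(0.5961, abs=1e-3)


class TestFractionalLIF:
    def test_classic_limit_matches_closed_form_isi(self):
        p = LIFParams(eta=1.0)
        res = simulate_flif(p, constant(3.0, 2000.0, p.dt))
        drive = p.r_m * 3.0
        closed = p.t_r + p.tau_m * math.log(drive / (drive - (p.v_th - p.v_r)))
        assert np.abs(res.spikes.isis() - closed).max() <= 2 * p.dt

    def test_subthreshold_is_silent(self):
        p = LIFParams(eta=1.0)
        res = simulate_flif(p, constant(1.5, 1000.0, p.dt))   # r_m I = 15 < 20 mV
        assert len(res.spikes) == 0

    def test_fractional_latency_and_powerlaw_isi_shortening(self):
        stim = constant(6.0, 10_000.0, 0.1)
        frac = simulate_flif(LIFParams(eta=0.2), stim)
        classic = simulate_flif(LIFParams(eta=1.0), stim)
        assert frac.spikes.times[0] > classic.spikes.times[0]
        isis = frac.spikes.isis()
        # shortening ISIs: monotone within grid quantization, straight in log-log
        assert np.all(np.diff(isis) <= 0.1 + 1e-9)
        assert isis[0] > 2 * isis[-1]
        k = np.arange(1, len(isis) + 1)
        slope, _ = np.polyfit(np.log(k), np.log(isis), 1)
        r = np.corrcoef(np.log(k), np.log(isis))[0, 1]
        assert slope < -0.1 and r < -0.98

    def test_deterministic_repeatability(self):
        stim = constant(6.0, 3000.0, 0.1)
        a = simulate_flif(LIFParams(eta=0.3), stim)
        b = simulate_flif(LIFParams(eta=0.3), stim)
        np.testing.assert_array_equal(a.spikes.times, b.spikes.times)
        np.testing.assert_array_equal(a.voltage, b.voltage)

    def test_rate_nondecreasing_in_current(self):
        rates = []
        for dc in (4.0, 6.0, 8.0):
            res = simulate_flif(LIFParams(eta=0.5), constant(dc, 5000.0, 0.1))
            t = res.spikes.times
            rates.append(np.sum(t > 2500.0))
        assert rates[0] <= rates[1] <= rates[2]

    def test_stimulus_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            simulate_flif(LIFParams(dt=0.1), constant(3.0, 100.0, 0.2))


class TestFractionalHH:
    def test_rest_is_stable_without_input(self):
        p = HHParams.from_preset("normal", eta_n=1.0, dt=0.01)
        res = simulate_fhh(p, constant(0.0, 150.0, 0.01))
        assert len(res.spikes) == 0
        # settles to a fixed point: late derivative negligible
        late = res.voltage[-1000:]
        assert np.ptp(late) < 0.01

    def test_classic_period_matches_reference_integrator(self):
        from scipy.integrate import solve_ivp
        p = HHParams.from_preset("normal", eta_n=1.0, dt=0.01)
        I0 = 10.0
        res = simulate_fhh(p, constant(I0, 400.0, 0.01))
        isis = res.spikes.isis()
        period = isis[len(isis) // 2:].mean()

        def rhs(t, y):
            v, m, h, n = y
            a_n, b_n, a_m, b_m, a_h, b_h = hh_rates(v, -65.0)
            dv = (-(0.3 * (v + 65) + 36 * n**4 * (v + 77)
                    + 120 * m**3 * h * (v - 50)) + I0) / 0.47
            return [dv, a_m * (1 - m) - b_m * m, a_h * (1 - h) - b_h * h,
                    a_n * (1 - n) - b_n * n]

        n0, m0, h0 = hh_steady_state(-65.0, -65.0)
        sol = solve_ivp(rhs, (0, 400.0), [-65.0, m0, h0, n0], rtol=1e-10,
                        atol=1e-12, max_step=0.5)
        v, t = sol.y[0], sol.t
        crossings = t[1:][(v[1:] >= 0) & (v[:-1] < 0)]
        ref_isis = np.diff(crossings)
        ref_period = ref_isis[len(ref_isis) // 2:].mean()
        assert period == pytest.approx(ref_period, rel=0.01)

    def test_gates_stay_in_unit_interval(self):
        p = HHParams.from_preset("criticality", eta_n=0.25, dt=0.05)
        res = simulate_fhh(p, constant(10.7, 2000.0, 0.05), record_gates=True)
        for g in res.gates.values():
            assert g.min() >= -1e-6 and g.max() <= 1 + 1e-6

    @pytest.mark.parametrize("eta", [0.3, 0.6])
    def test_l1_gate_converges_to_mittag_leffler_relaxation(self, eta):
        # freeze the voltage (no Na/K/leak currents, I = 0) and relax the
        # n-gate from a displaced value: the exact solution is
        # n_inf + (n0 - n_inf) E_eta(-(t^eta)/tau_n)
        p = HHParams(c_m=1.0, gbar_Na=0.0, gbar_K=0.0, g_m=0.0, v_r=-65.0,
                     V0=-65.0, eta_n=eta, dt=0.005, memory_window="full")
        n_inf, m0, h0 = hh_steady_state(-65.0, -65.0)
        res = simulate_fhh(p, constant(0.0, 30.0, 0.005), record_gates=True,
                           initial_state=(-65.0, m0, h0, 0.9))
        from fracspike.neuron_models import hh_rates as rates
        a_n, b_n = rates(-65.0, -65.0)[:2]
        tau_n = 1.0 / (a_n + b_n)
        t = res.time[1:]
        exact = n_inf + (0.9 - n_inf) * mittag_leffler(eta, -(t**eta) / tau_n)
        assert np.abs(res.gates["n"][1:] - exact).max() < 0.01

    def test_eta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            HHParams.from_preset("normal", eta_n=1.3)

    def test_deterministic_repeatability(self):
        stim = constant(10.7, 1000.0, 0.05)
        p = HHParams.from_preset("criticality", eta_n=0.25, dt=0.05)
        a = simulate_fhh(p, stim)
        b = simulate_fhh(p, stim)
        np.testing.assert_array_equal(a.voltage, b.voltage)
        np.testing.assert_array_equal(a.spikes.times, b.spikes.times)

    def test_preset_fields(self):
        p = HHParams.from_preset("criticality")
        assert (p.c_m, p.gbar_Na, p.gbar_K) == (1.0, 70.0, 5.0)
        assert (p.E_K, p.v_r) == (-77.0, -54.4)
        # E_Na and leak inherited from the normal set
        assert (p.E_Na, p.g_m) == (50.0, 0.3)
        n = HHParams.from_preset("normal")
        assert (n.c_m, n.gbar_Na, n.gbar_K, n.v_r) == (0.47, 120.0, 36.0, -65.0)
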