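"""Fractional leaky integrate-and-fire and Hodgkin–Huxley simulators.

Two models, two discretizations:

* ``simulate_flif`` — LIF with a Caputo-order membrane equation

      D^eta v = (-(v - v_r) + r_m I) / tau_m

  advanced with Grünwald–Letnikov binomial weights; the weighted sum
  over all past voltages is the intrinsic memory trace.  At eta = 1 the
  update collapses to forward Euler and the model is the classic LIF.

* ``simulate_fhh`` — Hodgkin–Huxley in which only the potassium
  activation gate n obeys a fractional-order relaxation
  D^eta_n n = (n_inf(v) - n) / tau_n(v), discretized with the L1 scheme
  (weighted first differences of the gate history) while (v, m, h)
  advance by classic RK4.  Small eta_n makes the potassium gate sluggish
  and history-laden: under strong constant drive the model emits
  *complex spikes* — action potentials carrying a depolarized plateau —
  interleaved with simple spikes, the signature of critical dynamics.

Units: mV, ms, µA, µF, mS throughout; the LIF membrane resistance r_m
is in MΩ with currents in nA (MΩ·nA = mV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .fractional_core import _check_eta, gl_weights
from .spike_analysis import SpikeTrain, detect_spikes
from .stimuli import StimulusWaveform

__all__ = [
    "LIFParams",
    "HHParams",
    "SimResult",
    "simulate_flif",
    "simulate_fhh",
    "hh_rates",
    "hh_steady_state",
]


@dataclass(frozen=True)
class LIFParams:
    """Fractional LIF parameters (defaults follow the lineage computer model).

    ``memory_window`` bounds the GL memory sum; "full" keeps every past
    sample.  A 10 s window reproduces full-memory spike times to within
    one time step on runs of tens of seconds.
    """

    v_r: float = -70.0          # mV, rest / reset
    v_th: float = -50.0         # mV, threshold
    t_r: float = 2.0            # ms, refractory period
    tau_m: float = 10.0         # ms
    r_m: float = 10.0           # MΩ  (current then in nA)
    eta: float = 1.0
    dt: float = 0.1             # ms
    memory_window: float | str = 10_000.0   # ms, or "full"

    def __post_init__(self):
        _check_eta(self.eta)
        if self.v_th <= self.v_r:
            raise ValueError("v_th must exceed v_r")
        if self.t_r < 0 or self.dt <= 0 or self.tau_m <= 0 or self.r_m <= 0:
            raise ValueError("t_r >= 0 and dt, tau_m, r_m > 0 required")
        if self.memory_window != "full":
            if float(self.memory_window) < 10.0 * self.tau_m:
                raise ValueError("finite memory_window must be >= 10 * tau_m")

    @property
    def c_m(self) -> float:
        """Membrane capacitance tau_m / r_m (nF)."""
        return self.tau_m / self.r_m


_HH_PRESETS = {
    "normal": dict(c_m=0.47, gbar_Na=120.0, gbar_K=36.0, g_m=0.3,
                   E_Na=50.0, E_K=-77.0, v_r=-65.0),
    # reduced sodium/potassium conductances and depolarized leak: the
    # regime in which the fractional n-gate produces complex spikes
    # (E_Na and g_m inherited from the normal set; see run manifests)
    "criticality": dict(c_m=1.0, gbar_Na=70.0, gbar_K=5.0, g_m=0.3,
                        E_Na=50.0, E_K=-77.0, v_r=-54.4),
}


@dataclass(frozen=True)
class HHParams:
    """Hodgkin–Huxley parameters with a fractional potassium n-gate.

    ``V0`` is the voltage offset of the rate functions (rates are
    evaluated on v - V0); it defaults to the preset's resting voltage so
    the classic rate curves sit at their textbook positions relative to
    rest.
    """

    c_m: float = 0.47           # µF
    gbar_Na: float = 120.0      # mS
    gbar_K: float = 36.0        # mS
    g_m: float = 0.3            # mS (leak)
    E_Na: float = 50.0          # mV
    E_K: float = -77.0          # mV
    v_r: float = -65.0          # mV (leak reversal)
    V0: float | None = None     # mV rate offset; None -> v_r
    eta_n: float = 1.0
    dt: float = 0.01            # ms
    memory_window: float | str = 10_000.0   # ms, or "full"
    preset: str = "custom"

    def __post_init__(self):
        _check_eta(self.eta_n)
        if self.dt <= 0 or self.c_m <= 0:
            raise ValueError("dt and c_m must be positive")

    @classmethod
    def from_preset(cls, preset: str, **overrides) -> "HHParams":
        if preset not in _HH_PRESETS:
            raise ValueError(f"unknown preset {preset!r}; options {list(_HH_PRESETS)}")
        kw = dict(_HH_PRESETS[preset])
        kw.update(overrides)
        return cls(preset=preset, **kw)

    @property
    def rate_offset(self) -> float:
        return self.v_r if self.V0 is None else self.V0


@dataclass(frozen=True)
class SimResult:
    """Simulation output: trace, optional gate trajectories, spike times."""

    time: np.ndarray            # ms
    voltage: np.ndarray         # mV
    spikes: SpikeTrain
    gates: dict = field(default_factory=dict)   # name -> series
    params_echo: dict = field(default_factory=dict)


def _window_steps(memory_window, dt: float, n: int) -> int:
    if memory_window == "full":
        return n
    return max(int(round(float(memory_window) / dt)), 1)


def simulate_flif(params: LIFParams, stimulus: StimulusWaveform) -> SimResult:
    """Run the GL fractional LIF on a stimulus sampled at ``params.dt``.

    The membrane deviation u = v - v_r is advanced with the GL scheme;
    a spike is emitted when v >= v_th, after which the voltage is
    clamped to v_r for the refractory period (the clamped samples enter
    the memory sum at rest).  Current is interpreted in nA.
    """
    if not math.isclose(stimulus.dt, params.dt, rel_tol=1e-9):
        raise ValueError(
            f"stimulus dt {stimulus.dt} does not match params.dt {params.dt}"
        )
    n = len(stimulus.time)
    W = min(_window_steps(params.memory_window, params.dt, n), n)
    if W >= n:
        # exact full memory
        B = 0
        w = gl_weights(params.eta, n + 1).values
        w_rev = w[1:][::-1].copy()
        Cw = np.zeros(1)
    else:
        # exact window + block-compressed tail (near-exact, see docs)
        B = max(min(1000, W // 10), 1)
        w = gl_weights(params.eta, n + 1).values
        w_rev = w[1:W + B + 1][::-1].copy()
        Cw = np.cumsum(w)
    drive = params.r_m * np.ascontiguousarray(stimulus.current, dtype=np.float64)
    u, spk_idx = _kernels.flif_gl_kernel(
        drive, params.dt ** params.eta, params.tau_m,
        params.v_th - params.v_r, int(round(params.t_r / params.dt)),
        w_rev, Cw, W, B,
    )
    times = stimulus.time
    spikes = SpikeTrain(times=times[spk_idx],
                        source_meta={"model": "flif", **stimulus.meta})
    echo = {"model": "flif", "window_steps": W, **vars_dict(params)}
    return SimResult(time=times, voltage=u + params.v_r, spikes=spikes,
                     params_echo=echo)


def vars_dict(obj) -> dict:
    return {k: v for k, v in obj.__dict__.items()}


def hh_rates(V, V0: float = -65.0):
    """The six HH rate functions (α_n, β_n, α_m, β_m, α_h, β_h) in 1/ms.

    Evaluated on the shifted voltage u = V - V0, with the removable
    0/0 singularities of α_n (at u = 10 mV) and α_m (at u = 25 mV)
    handled by series expansion.
    """
    u = np.asarray(V, dtype=float) - V0

    def xexprel(x):
        x = np.asarray(x, dtype=float)
        small = np.abs(x) < 1e-6
        safe = np.where(small, 1.0, x)
        out = np.where(small, 1.0 - x / 2.0 + x * x / 12.0,
                       safe / np.expm1(safe))
        return out

    a_n = 0.1 * xexprel((10.0 - u) / 10.0)
    b_n = 0.125 * np.exp(-u / 80.0)
    a_m = 1.0 * xexprel((25.0 - u) / 10.0)
    b_m = 4.0 * np.exp(-u / 18.0)
    a_h = 0.07 * np.exp(-u / 20.0)
    b_h = 1.0 / (1.0 + np.exp(3.0 - 0.1 * u))
    return a_n, b_n, a_m, b_m, a_h, b_h


def hh_steady_state(V: float, V0: float = -65.0) -> tuple[float, float, float]:
    """Equilibrium gate values (n∞, m∞, h∞) at a fixed voltage."""
    a_n, b_n, a_m, b_m, a_h, b_h = hh_rates(V, V0)
    return (float(a_n / (a_n + b_n)), float(a_m / (a_m + b_m)),
            float(a_h / (a_h + b_h)))


def simulate_fhh(params: HHParams, stimulus: StimulusWaveform,
                 record_gates: bool = False,
                 spike_threshold: float = 0.0,
                 gate_tolerance: float = 1e-6,
                 initial_state: tuple[float, float, float, float] | None = None
                 ) -> SimResult:
    """Run the fractional-n-gate HH model on a stimulus sampled at params.dt.

    (v, m, h) advance by RK4 holding n; n advances by the L1 scheme with
    per-step gate differences weighted by the Caputo memory
    coefficients.  Current is in µA.  Spikes are detected as upward
    crossings of ``spike_threshold`` (mV).
    """
    if not math.isclose(stimulus.dt, params.dt, rel_tol=1e-9):
        raise ValueError(
            f"stimulus dt {stimulus.dt} does not match params.dt {params.dt}"
        )
    n = len(stimulus.time)
    W = min(_window_steps(params.memory_window, params.dt, n), n)
    eta = params.eta_n
    if eta >= 1.0:
        d_rev = np.zeros(1)
        W_eff = 1
    else:
        j = np.arange(1, W + 1, dtype=np.float64)
        d = (j + 1.0) ** (1.0 - eta) - j ** (1.0 - eta)
        d_rev = d[::-1].copy()
        W_eff = W
    V0 = params.rate_offset
    if initial_state is None:
        n0, m0, h0 = hh_steady_state(params.v_r, V0)
        v_init = params.v_r
    else:
        v_init, m0, h0, n0 = initial_state
    I = np.ascontiguousarray(stimulus.current, dtype=np.float64)
    v, m, h, ng, viol = _kernels.fhh_l1_kernel(
        I, params.dt, eta, math.gamma(2.0 - eta), params.c_m, params.gbar_Na,
        params.gbar_K, params.g_m, params.E_Na, params.E_K, params.v_r, V0,
        v_init, m0, h0, n0, d_rev, W_eff,
    )
    if viol > gate_tolerance:
        raise ArithmeticError(
            f"gating variable left [0, 1] by {viol:.3g} (> {gate_tolerance:.1g}); "
            "reduce dt"
        )
    spikes = detect_spikes(stimulus.time, v, threshold=spike_threshold,
                           min_separation=1.0)
    gates = {"n": ng}
    if record_gates:
        gates.update({"m": m, "h": h})
    echo = {"model": "fhh", "window_steps": W_eff, "V0": V0, **vars_dict(params)}
    return SimResult(time=stimulus.time, voltage=v, spikes=spikes, gates=gates,
                     params_echo=echo)
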