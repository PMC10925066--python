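"""Seeded stimulus generators.

Every waveform the simulators consume is produced here: constant,
square and sinusoidal drives, band-limited pink noise with a prescribed
spectral exponent, and the masking protocol used to probe long-term
adaptation.  Time is in milliseconds, frequency bands in Hz; the
current unit (µA for the computer models, mA for circuit-scale
quantities) is declared in the waveform metadata, not converted.

A waveform's ``meta`` mapping plus the seed fully determines the
samples, so any waveform can be regenerated from its sidecar metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusWaveform",
    "deterministic_wave",
    "pink_noise",
    "masking_protocol",
]


@dataclass(frozen=True)
class StimulusWaveform:
    time: np.ndarray            # ms, uniform grid
    current: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.time) != len(self.current):
            raise ValueError("time and current must have equal length")
        dt = np.diff(self.time)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("stimulus grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


def _grid(duration: float, dt: float) -> np.ndarray:
    if dt <= 0 or duration <= 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration / dt)) + 1
    return np.arange(n) * dt


def deterministic_wave(kind: str, DC: float, amplitude: float, period: float,
                       duration: float, dt: float, units: str = "uA") -> StimulusWaveform:
    """Constant, square (50% duty, starting high) or sinusoidal drive.

    The square wave alternates DC ± amplitude; the sinusoid is
    DC + amplitude·sin(2πt/period).  Whether the result stays
    suprathreshold is the caller's concern — nothing is auto-tuned.
    """
    t = _grid(duration, dt)
    if kind == "constant":
        i = np.full_like(t, DC)
    elif kind in ("square", "sinusoid"):
        if period <= 0:
            raise ValueError("periodic kinds need a positive period")
        if duration < period:
            raise ValueError("duration must cover at least one period")
        phase = (t % period) / period
        if kind == "square":
            i = DC + amplitude * np.where(phase < 0.5, 1.0, -1.0)
        else:
            i = DC + amplitude * np.sin(2.0 * np.pi * t / period)
    else:
        raise ValueError(f"unknown waveform kind {kind!r}")
    meta = {"kind": kind, "DC": DC, "amplitude": amplitude, "period": period,
            "duration": duration, "dt": dt, "units": units}
    return StimulusWaveform(time=t, current=i, meta=meta)


def pink_noise(beta: float, band: tuple[float, float], DC: float,
               rms_amplitude: float, duration: float, dt: float, seed: int,
               units: str = "uA") -> StimulusWaveform:
    """Band-limited noise with power spectral density ∝ f^beta inside ``band``.

    ``beta`` is the PSD exponent as fitted in log–log coordinates, so
    pink noise has beta < 0 and beta = 0 is band-limited white noise.
    Synthesis is spectral: Fourier amplitudes f^(beta/2) inside
    [f_lo, f_hi] Hz, exactly zero outside, phases uniform from ``seed``;
    the series is then rescaled to ``rms_amplitude`` and offset by
    ``DC``.  Band-limited synthesis (rather than filtering white noise)
    gives exact in-band exponent control.
    """
    if beta > 0:
        raise ValueError("beta is a PSD exponent; expected beta <= 0")
    f_lo, f_hi = band
    t = _grid(duration, dt)
    n = len(t)
    freqs = np.fft.rfftfreq(n, d=dt / 1000.0)   # Hz (grid is in ms)
    nyquist = freqs[-1]
    if not 0.0 < f_lo < f_hi <= nyquist * (1 + 1e-12):
        raise ValueError(f"band {band} must satisfy 0 < f_lo < f_hi <= Nyquist ({nyquist:.3g} Hz)")
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    if not np.any(in_band):
        raise ValueError(f"band {band} contains no resolvable frequency bins")
    rng = np.random.default_rng(seed)
    amp = np.zeros_like(freqs)
    amp[in_band] = freqs[in_band] ** (beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(freqs))
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real   # Nyquist bin must be real
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x *= rms_amplitude / rms
    meta = {"kind": "pink_noise", "beta": beta, "band": (f_lo, f_hi), "DC": DC,
            "rms_amplitude": rms_amplitude, "duration": duration, "dt": dt,
            "seed": int(seed), "units": units}
    return StimulusWaveform(time=t, current=DC + x, meta=meta)


def masking_protocol(baseline: float, masked: float, mask_duration: float,
                     monitor_duration: float, repetitions: int, dt: float,
                     pre_duration: float | None = None,
                     units: str = "uA") -> tuple[StimulusWaveform, list[dict]]:
    """Masking-step protocol: pre-window, then (mask | monitor) repetitions.

    The drive sits at ``baseline``, drops to ``masked`` for
    ``mask_duration`` and returns to baseline for ``monitor_duration``,
    ``repetitions`` times.  Both levels are normally suprathreshold (the
    mask lowers, but does not silence, firing).  Returns the waveform
    plus segment annotations (label, t_start, t_end in ms) for the
    cumulative-spike analysis.
    """
    if masked > baseline:
        raise ValueError("masked level must not exceed baseline")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if pre_duration is None:
        pre_duration = monitor_duration
    total = pre_duration + repetitions * (mask_duration + monitor_duration)
    t = _grid(total, dt)
    i = np.full_like(t, baseline)
    segments = [{"label": "pre", "t_start": 0.0, "t_end": pre_duration}]
    cursor = pre_duration
    for r in range(repetitions):
        m0, m1 = cursor, cursor + mask_duration
        i[(t >= m0) & (t < m1)] = masked
        segments.append({"label": f"mask_{r}", "t_start": m0, "t_end": m1})
        segments.append({"label": f"monitor_{r}", "t_start": m1,
                         "t_end": m1 + monitor_duration})
        cursor = m1 + monitor_duration
    meta = {"kind": "masking", "baseline": baseline, "masked": masked,
            "mask_duration": mask_duration, "monitor_duration": monitor_duration,
            "pre_duration": pre_duration, "repetitions": repetitions, "dt": dt,
            "units": units}
    return StimulusWaveform(time=t, current=i, meta=meta), segments
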