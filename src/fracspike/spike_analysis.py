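"""Spike-train analyses: detection, complex-spike labelling, rates,
adaptation fits, fractional gain/phase, spectrum whitening, avalanches,
ON/OFF classification and cumulative relative spiking.

All operations accept plain spike-time arrays (ms) wrapped in
``SpikeTrain`` — they are agnostic to whether the train came from a
simulator or from recorded data supplied as a text file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal, stats
from scipy.optimize import curve_fit

__all__ = [
    "SpikeTrain",
    "RateSeries",
    "PowerLawFit",
    "AdaptationFit",
    "FractionalExponents",
    "AvalancheResult",
    "CumulativeCurve",
    "detect_spikes",
    "classify_complex",
    "firing_rate",
    "fit_adaptation",
    "gain_phase",
    "fractional_exponents",
    "spectrum_exponent",
    "avalanches",
    "classify_on_off",
    "cumulative_relative",
]

SIMPLE, COMPLEX = "S", "C"


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms), optionally labelled simple/complex."""

    times: np.ndarray
    labels: np.ndarray | None = None    # per-spike "S" or "C"
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.labels is not None:
            lab = np.asarray(self.labels)
            if len(lab) != len(t):
                raise ValueError("labels length must match times")
            object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return len(self.times)

    def isis(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass(frozen=True)
class RateSeries:
    """Firing rate (Hz) on a uniform time grid (ms)."""

    time: np.ndarray
    rate: np.ndarray
    method: str = "instantaneous"

    def __post_init__(self):
        if len(self.time) != len(self.rate):
            raise ValueError("time and rate must have equal length")
        if np.any(np.asarray(self.rate) < -1e-12):
            raise ValueError("rates must be non-negative")

    @property
    def grid_dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else math.nan


@dataclass(frozen=True)
class PowerLawFit:
    """Log–log (or semilog) linear fit: exponent, intercept, 95% CI."""

    exponent: float
    intercept: float
    ci95: tuple[float, float]
    fit_band: tuple[float, float] | None = None
    n_points: int = 0

    def whitening_shift(self, beta: float) -> float:
        """Δη = fitted output exponent minus the input exponent β."""
        return self.exponent - beta


@dataclass(frozen=True)
class AdaptationFit:
    """Exponential time constants of rate accommodation in one square cycle."""

    period: float               # ms
    tau_up: float               # ms (nan when undefined)
    tau_down: float             # ms
    ci95: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FractionalExponents:
    """Fractional order read out from a frequency sweep of gain and phase."""

    eta_G: PowerLawFit
    eta_phi: float
    eta_phi_sem: float


@dataclass(frozen=True)
class AvalancheResult:
    sizes: np.ndarray
    fit: PowerLawFit | None


@dataclass(frozen=True)
class CumulativeCurve:
    """Relative cumulative spike count R(t); R = 1 means no change."""

    time: np.ndarray            # s
    relative_cumulative: np.ndarray
    ci95_lo: np.ndarray
    ci95_hi: np.ndarray


# ---------------------------------------------------------------------------


def detect_spikes(time, voltage, threshold: float, min_separation: float = 1.0,
                  meta: dict | None = None) -> SpikeTrain:
    """Upward threshold crossings of a uniformly sampled voltage trace.

    The spike time is the first sample at or above ``threshold`` of each
    crossing; crossings closer than ``min_separation`` (ms) to the
    previous accepted spike are ignored.
    """
    time = np.asarray(time, dtype=float)
    voltage = np.asarray(voltage, dtype=float)
    dt = np.diff(time)
    if len(dt) and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("detect_spikes requires a uniform time grid")
    above = voltage >= threshold
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0] if len(above) else False:
        onsets = np.concatenate([[0], onsets])
    accepted = []
    last = -math.inf
    for i in onsets:
        if time[i] - last >= min_separation:
            accepted.append(i)
            last = time[i]
    return SpikeTrain(times=time[np.asarray(accepted, dtype=int)],
                      source_meta=meta or {})


def classify_complex(time, voltage, spikes: SpikeTrain,
                     plateau_level: float | None = None,
                     min_plateau: float | None = None) -> SpikeTrain:
    """Label each spike simple or complex by its plateau duration.

    A spike is *complex* iff the voltage stays above ``plateau_level``
    for at least ``min_plateau`` ms somewhere within its event window
    (from the spike to the next spike); a duration of exactly
    ``min_plateau`` counts as complex.  Defaults: ``plateau_level`` is
    the midpoint between the resting level (20th percentile of the
    trace) and the mean spike peak; ``min_plateau`` is 3x the median
    above-level width of the events.
    """
    time = np.asarray(time, dtype=float)
    voltage = np.asarray(voltage, dtype=float)
    if len(spikes) == 0:
        return replace(spikes, labels=np.asarray([], dtype="<U1"))
    dt = time[1] - time[0]
    idx = np.searchsorted(time, spikes.times)
    windows = list(zip(idx, np.append(idx[1:], len(time))))
    peaks = np.array([voltage[a:b].max() for a, b in windows])
    if plateau_level is None:
        resting = np.percentile(voltage, 20)
        plateau_level = 0.5 * (resting + peaks.mean())

    def longest_run(a: int, b: int) -> float:
        above = voltage[a:b] >= plateau_level
        if not above.any():
            return 0.0
        # lengths of contiguous True runs
        edges = np.diff(np.concatenate([[0], above.astype(int), [0]]))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        return float((ends - starts).max() * dt)

    widths = np.array([longest_run(a, b) for a, b in windows])
    if min_plateau is None:
        min_plateau = 3.0 * float(np.median(widths))
    labels = np.where(widths >= min_plateau, COMPLEX, SIMPLE)
    return replace(spikes, labels=labels)


def firing_rate(spikes: SpikeTrain, method: str = "instantaneous",
                window: float | None = None, grid_dt: float = 1.0) -> RateSeries:
    """Firing rate from a spike train.

    instantaneous: 1/ISI (Hz) assigned at the second spike of each pair
    and linearly interpolated onto a uniform grid of step ``grid_dt``
    (ms).  Fewer than 2 spikes yields an empty series, not an error.

    windowed: the spike count in [t_first, t_first + window] divided by
    the window, reported as a single sample at the window end — the
    rate "as seen" over a given observation window from first-spike
    onset.
    """
    t = spikes.times
    if method == "windowed":
        if window is None or window <= 0:
            raise ValueError("windowed method requires a positive window (ms)")
        if len(t) == 0:
            return RateSeries(time=np.asarray([]), rate=np.asarray([]), method=method)
        t0 = t[0]
        count = int(np.sum((t >= t0) & (t <= t0 + window)))
        return RateSeries(time=np.asarray([t0 + window]),
                          rate=np.asarray([1000.0 * count / window]), method=method)
    if method != "instantaneous":
        raise ValueError(f"unknown rate method {method!r}")
    if len(t) < 2:
        return RateSeries(time=np.asarray([]), rate=np.asarray([]), method=method)
    isi = np.diff(t)
    inst_t = t[1:]
    inst_r = 1000.0 / isi
    grid = np.arange(inst_t[0], inst_t[-1] + grid_dt / 2.0, grid_dt)
    rate = np.interp(grid, inst_t, inst_r)
    return RateSeries(time=grid, rate=rate, method=method)


def _fit_phase_exponential(tt: np.ndarray, rr: np.ndarray):
    """Fit r(t) = r_inf + dr * exp(-t/tau) on one phase; tau and its SE."""
    if np.ptp(rr) < 1e-9 or len(tt) < 5:
        return math.nan, math.nan
    t0 = tt[0]
    tau0 = max((tt[-1] - t0) / 3.0, 1e-3)

    def model(t, r_inf, dr, tau):
        return r_inf + dr * np.exp(-(t - t0) / tau)

    try:
        popt, pcov = curve_fit(
            model, tt, rr, p0=[rr[-1], rr[0] - rr[-1], tau0],
            bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=2000,
        )
    except RuntimeError:
        return math.nan, math.nan
    return float(popt[2]), float(np.sqrt(max(pcov[2, 2], 0.0)))


def fit_adaptation(rate: RateSeries, cycle_boundaries) -> AdaptationFit:
    """Exponential accommodation constants over the phases of a square drive.

    ``cycle_boundaries`` are the switch times (ms) of the square input,
    starting with the beginning of a *high* phase.  A single exponential
    r(t) = r_inf + dr exp(-t/tau) is fitted to each phase; phases with a
    constant rate are flagged undefined.  tau_up/tau_down are averaged
    over cycles with 95% CI from per-fit standard errors (single cycle)
    or across-cycle scatter.
    """
    b = np.sort(np.asarray(cycle_boundaries, dtype=float))
    if len(b) < 2:
        raise ValueError("need at least two cycle boundaries (one phase)")
    period = 2.0 * float(np.median(np.diff(b)))
    taus: dict[str, list[tuple[float, float]]] = {"up": [], "down": []}
    flags: dict[str, list[str]] = {"up": [], "down": []}
    for i in range(len(b) - 1):
        phase = "up" if i % 2 == 0 else "down"
        m = (rate.time >= b[i]) & (rate.time < b[i + 1])
        tau, se = _fit_phase_exponential(rate.time[m], rate.rate[m])
        if math.isnan(tau):
            flags[phase].append(f"phase {i}: constant or unfittable")
        else:
            taus[phase].append((tau, se))

    def summarize(entries):
        if not entries:
            return math.nan, (math.nan, math.nan)
        vals = np.array([t for t, _ in entries])
        mean = float(vals.mean())
        if len(vals) >= 3:
            half = 1.96 * vals.std(ddof=1) / math.sqrt(len(vals))
        else:
            half = 1.96 * float(np.mean([se for _, se in entries]))
        return mean, (mean - half, mean + half)

    tau_up, ci_up = summarize(taus["up"])
    tau_down, ci_down = summarize(taus["down"])
    return AdaptationFit(period=period, tau_up=tau_up, tau_down=tau_down,
                         ci95={"tau_up": ci_up, "tau_down": ci_down},
                         flags={k: v for k, v in flags.items() if v})


def gain_phase(rate: RateSeries, stimulus) -> tuple[float, float]:
    """Gain and phase of the rate at the (known) stimulus frequency.

    Least-squares sinusoid fit at the drive frequency after discarding
    the first period as transient.  gain = rate amplitude / stimulus
    amplitude; phase = rate phase - stimulus phase, wrapped to (-π, π].
    """
    meta = stimulus.meta
    if meta.get("kind") != "sinusoid":
        raise ValueError("gain_phase requires a sinusoidal stimulus")
    period = float(meta["period"])
    amp = float(meta["amplitude"])
    t_start = stimulus.time[0] + period
    if rate.time[-1] - t_start < 2.0 * period:
        raise ValueError("rate must cover >= 3 stimulus periods")
    m = rate.time >= t_start
    tt, rr = rate.time[m], rate.rate[m]
    w = 2.0 * math.pi / period
    design = np.column_stack([np.ones_like(tt), np.sin(w * tt), np.cos(w * tt)])
    coef, *_ = np.linalg.lstsq(design, rr, rcond=None)
    _, bs, bc = coef
    r_amp = math.hypot(bs, bc)
    phase = math.atan2(bc, bs)          # stimulus is DC + A sin(w t): phase 0
    phase = (phase + math.pi) % (2.0 * math.pi) - math.pi
    if phase == -math.pi:
        phase = math.pi
    return r_amp / amp, phase


def fractional_exponents(sweep) -> FractionalExponents:
    """Fractional order from a sweep of (wavelength, gain, phase) triples.

    A fractional differentiator of order η has gain (2πω)^η and a
    frequency-independent phase advance ηπ/2, so η is read out twice:
    η_G as the log gain vs log(2πω) slope (with 95% CI) and η_φ as the
    mean of 2·phase/π with its SEM.
    """
    sweep = sorted(sweep)
    if len(sweep) < 4:
        raise ValueError("need at least 4 wavelengths")
    lam = np.array([s[0] for s in sweep], dtype=float)
    if math.log10(lam.max() / lam.min()) < 1.0 - 1e-9:
        raise ValueError("wavelengths must span at least one decade")
    gain = np.array([s[1] for s in sweep], dtype=float)
    phase = np.array([s[2] for s in sweep], dtype=float)
    x = np.log(2.0 * math.pi / lam)
    res = stats.linregress(x, np.log(gain))
    tcrit = stats.t.ppf(0.975, len(lam) - 2)
    eta_g = PowerLawFit(
        exponent=float(res.slope), intercept=float(res.intercept),
        ci95=(res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr),
        fit_band=(float(lam.min()), float(lam.max())), n_points=len(lam),
    )
    etas = 2.0 * phase / math.pi
    sem = float(etas.std(ddof=1) / math.sqrt(len(etas))) if len(etas) > 1 else 0.0
    return FractionalExponents(eta_G=eta_g, eta_phi=float(etas.mean()),
                               eta_phi_sem=sem)


def spectrum_exponent(rate: RateSeries, band: tuple[float, float]) -> PowerLawFit:
    """Power-law exponent of the firing-rate power spectrum within ``band``.

    Segment-averaged periodogram (Welch, mean removed) of the uniformly
    resampled rate, followed by linear regression of log power on log
    frequency inside [f_lo, f_hi] Hz.  The whitening statistic
    Δη = exponent - β is available as ``PowerLawFit.whitening_shift``.
    """
    f_lo, f_hi = band
    if f_lo <= 0 or f_hi <= f_lo:
        raise ValueError("band must satisfy 0 < f_lo < f_hi")
    dt_s = rate.grid_dt / 1000.0
    fs = 1.0 / dt_s
    n = len(rate.rate)
    if n * dt_s < 3.0 / f_lo:
        raise ValueError("rate series must span at least 3 periods of f_lo")
    nperseg = min(n, int(round(3.0 / f_lo * fs)))
    x = rate.rate - rate.rate.mean()
    freqs, pxx = signal.welch(x, fs=fs, nperseg=nperseg)
    m = (freqs >= f_lo) & (freqs <= f_hi) & (pxx > 0)
    if m.sum() < 4:
        raise ValueError("band contains too few resolvable frequencies")
    res = stats.linregress(np.log10(freqs[m]), np.log10(pxx[m]))
    tcrit = stats.t.ppf(0.975, int(m.sum()) - 2)
    return PowerLawFit(
        exponent=float(res.slope), intercept=float(res.intercept),
        ci95=(res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr),
        fit_band=(f_lo, f_hi), n_points=int(m.sum()),
    )


def avalanches(labeled: SpikeTrain, bins_per_decade: int = 8,
               min_count: int = 2) -> AvalancheResult:
    """Avalanche sizes and the power-law fit of their histogram.

    An avalanche is the number of simple spikes strictly between two
    consecutive complex spikes.  The size histogram is log-binned,
    zero-count bins dropped, and the exponent obtained by least squares
    on the log–log density.  Fewer than 2 complex spikes gives an empty
    result with ``fit=None``.
    """
    if labeled.labels is None:
        raise ValueError("avalanches requires a labelled spike train")
    lab = np.asarray(labeled.labels)
    cpos = np.flatnonzero(lab == COMPLEX)
    if len(cpos) < 2:
        return AvalancheResult(sizes=np.asarray([], dtype=int), fit=None)
    sizes = np.diff(cpos) - 1
    pos = sizes[sizes > 0]
    if len(pos) < 4:
        return AvalancheResult(sizes=sizes, fit=None)
    lo, hi = pos.min(), pos.max()
    n_bins = max(int(math.log10(hi / lo + 1e-12) * bins_per_decade), 3)
    edges = np.geomspace(lo, hi + 1, n_bins + 1)
    counts, edges = np.histogram(pos, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = counts >= min_count
    if keep.sum() < 3:
        return AvalancheResult(sizes=sizes, fit=None)
    density = counts[keep] / widths[keep]
    res = stats.linregress(np.log10(centers[keep]), np.log10(density))
    tcrit = stats.t.ppf(0.975, int(keep.sum()) - 2) if keep.sum() > 2 else math.nan
    fit = PowerLawFit(
        exponent=float(res.slope), intercept=float(res.intercept),
        ci95=(res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr),
        fit_band=(float(lo), float(hi)), n_points=int(keep.sum()),
    )
    return AvalancheResult(sizes=sizes, fit=fit)


def classify_on_off(rate: RateSeries, stimulus) -> tuple[str, float]:
    """ON/OFF classification from the rate–stimulus correlation.

    ON cells follow the drive (positive correlation over the cycle);
    OFF cells fire more when the drive is low.  Returns the label and
    the correlation; |r| < 0.1 is reported as "ambiguous".
    """
    meta = stimulus.meta
    if meta.get("kind") not in ("sinusoid", "square"):
        raise ValueError("classify_on_off requires a periodic stimulus")
    stim_on_grid = np.interp(rate.time, stimulus.time, stimulus.current)
    r = float(np.corrcoef(rate.rate, stim_on_grid)[0, 1])
    if abs(r) < 0.1:
        return "ambiguous", r
    return ("ON", r) if r > 0 else ("OFF", r)


def cumulative_relative(pre: SpikeTrain, post: SpikeTrain, grid_dt: float = 1.0,
                        pre_duration: float | None = None) -> CumulativeCurve:
    """Relative cumulative spikes of a post window against its pre baseline.

    R(t) = N_post(0, t) / (r_pre · t) with r_pre the mean rate of the
    pre window; no change in firing keeps R at 1 (a horizontal line).
    Spike times are in ms, ``grid_dt`` and the returned time axis in s.
    The 95% band treats N_post(0, t) as Poisson.
    """
    if len(pre) == 0:
        raise ValueError("empty pre-window train; cannot normalize")
    if len(post) == 0:
        raise ValueError("empty post-window train")
    if pre_duration is None:
        pre_duration = float(pre.times[-1] - pre.times[0])
    pre_duration_s = pre_duration / 1000.0
    if pre_duration_s < 60.0:
        raise ValueError("pre window must span at least 60 s")
    r_pre = len(pre) / pre_duration_s                 # Hz
    post_rel_s = (post.times - post.times[0]) / 1000.0
    t_end = post_rel_s[-1]
    grid = np.arange(grid_dt, t_end + grid_dt / 2.0, grid_dt)
    n_post = np.searchsorted(post_rel_s, grid, side="right").astype(float)
    expected = r_pre * grid
    ratio = n_post / expected
    half = 1.96 * np.sqrt(np.maximum(n_post, 1.0)) / expected
    return CumulativeCurve(time=grid, relative_cumulative=ratio,
                           ci95_lo=ratio - half, ci95_hi=ratio + half)
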