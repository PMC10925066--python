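"""Fractional super-capacitor / memcapacitor component model.

A super-capacitor charged at constant current does not follow the ideal
RC exponential: its voltage relaxes with a Mittag–Leffler law whose
order ``eta`` < 1 reflects the distributed (power-law) nature of the
double-layer.  The same element, driven by a periodic voltage, traces a
charge–voltage loop pinched at the origin with frequency-dependent
amplitude — the memcapacitor signature.

The circuit picture is a fractional capacitance ``C_o`` (units mF·s^(eta-1))
in parallel with a leak conductance ``G_c`` (mS):

    i_c(t) = G_c v_C(t) + C_o D^eta v_C(t)

Units in this module: volts, milliamps, millifarads, milli-siemens,
seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

from .fractional_core import _check_eta, mittag_leffler

__all__ = [
    "SupercapParams",
    "ChargeVoltageLoop",
    "SupercapFit",
    "series_capacitance",
    "step_response",
    "asymptotic_response",
    "fit_fractional_order",
    "memcap_loop",
]


@dataclass(frozen=True)
class SupercapParams:
    """Parameters of the leaky fractional capacitor.

    ``tau_c = C_o / G_c`` is the relaxation scale (s^eta); ``G_c = 0`` is
    allowed only together with ``eta = 1`` (ideal-capacitor limit).
    """

    C_o: float          # mF (times s^(eta-1) for eta < 1)
    G_c: float          # mS
    eta: float
    v0: float = 0.0     # V, initial voltage

    def __post_init__(self):
        if self.C_o <= 0:
            raise ValueError(f"C_o must be positive, got {self.C_o}")
        if self.G_c < 0:
            raise ValueError(f"G_c must be non-negative, got {self.G_c}")
        _check_eta(self.eta)

    @property
    def tau_c(self) -> float:
        if self.G_c == 0:
            return math.inf
        return self.C_o / self.G_c


@dataclass(frozen=True)
class ChargeVoltageLoop:
    """A traced q–V loop; pinched (q = 0 wherever v = 0) by construction."""

    time: np.ndarray        # s
    voltage: np.ndarray     # V
    charge: np.ndarray      # C
    drive_frequency: float | None = None   # Hz


@dataclass(frozen=True)
class SupercapFit:
    """Result of fitting the constant-current charging law to a trace."""

    eta: float
    C_o: float
    G_c: float
    v0: float
    ci95: dict = field(default_factory=dict)   # param -> (lo, hi)
    covariance: np.ndarray | None = None


def series_capacitance(capacitances) -> float:
    """Equivalent capacitance of capacitors connected in series.

    ``1/C_eq = sum_i 1/C_i``; e.g. four 22 mF cells in series give 5.5 mF.
    """
    caps = np.asarray(capacitances, dtype=float)
    if caps.size == 0 or np.any(caps <= 0):
        raise ValueError("capacitances must be a non-empty sequence of positive values")
    return 1.0 / np.sum(1.0 / caps)


def step_response(params: SupercapParams, I: float, t) -> np.ndarray:
    """Voltage of the leaky fractional capacitor under constant current I (mA).

    v_C(t) = v0 + (I/G_c) (1 - E_eta(-G_c t^eta / C_o)).

    At eta = 1 this is the RC exponential; with eta = 1 and G_c = 0 the
    ideal-capacitor ramp v0 + I t / C_o is returned through a dedicated
    limit path.  (G_c = 0 with eta < 1 has no finite relaxation and is
    rejected.)
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("t must be non-negative and strictly increasing")
    if params.G_c == 0.0:
        if params.eta != 1.0:
            raise ValueError(
                "G_c = 0 is only supported in the ideal-capacitor limit eta = 1"
            )
        return params.v0 + I * t / params.C_o
    arg = -(params.G_c / params.C_o) * t**params.eta
    return params.v0 + (I / params.G_c) * (1.0 - mittag_leffler(params.eta, arg))


def asymptotic_response(params: SupercapParams, I: float, t) -> np.ndarray:
    """Ohmic-offset-plus-power-law charging form.

    v_C(t) = v0 + I (1/G_c + t^eta / (C_o Gamma(1+eta))).

    The t^eta term is the fractional integral of the constant current
    (the capacitive part alone); 1/G_c is the resistive offset.  The
    log–log slope of v - v0 - I/G_c against t is exactly eta, which is
    what makes this form the practical fitting target for measured
    charging curves.
    """
    t = np.asarray(t, dtype=float)
    if params.G_c == 0.0:
        raise ValueError("asymptotic form requires G_c > 0 (offset 1/G_c)")
    return params.v0 + I * (
        1.0 / params.G_c + t**params.eta / (params.C_o * math.gamma(1.0 + params.eta))
    )


def _check_charging_trace(t: np.ndarray, v: np.ndarray) -> None:
    """Reject traces that are not (secularly) monotone charging curves."""
    if len(t) < 100:
        raise ValueError("need at least 100 samples to fit the charging law")
    if t[-1] <= 0 or t[t > 0][0] <= 0 or math.log10(t[-1] / t[t > 0][0]) < 1.0:
        raise ValueError("trace must span at least two decades of time")
    # smooth over ~5% of samples so sample-level noise does not trip the
    # check, then require a strongly monotone secular trend
    win = max(len(v) // 20, 3)
    kernel = np.ones(win) / win
    smooth = np.convolve(v, kernel, mode="valid")
    rho = spearmanr(np.arange(len(smooth)), smooth).statistic
    if smooth[-1] <= smooth[0] or rho < 0.8:
        raise ValueError("trace is not monotonically charging")


def fit_fractional_order(t, v, I: float, p0: dict | None = None) -> SupercapFit:
    """Estimate (eta, C_o, G_c) from a constant-current charging trace.

    Fits the full Mittag–Leffler charging law by nonlinear least squares
    in (eta, ln C_o, ln G_c, v0).  eta is initialized from the late-time
    log–log slope of v - v(0) against t; samples are thinned to be
    uniform in log time so late decades do not dominate the residual.
    95% confidence intervals come from the fit covariance.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.shape != v.shape:
        raise ValueError("time and voltage must have the same shape")
    order = np.argsort(t)
    t, v = t[order], v[order]
    _check_charging_trace(t, v)

    # thin to <= 250 points, uniform in log time (balanced leverage)
    pos = t > 0
    tp, vp = t[pos], v[pos]
    if len(tp) > 250:
        idx = np.unique(
            np.searchsorted(tp, np.geomspace(tp[0], tp[-1], 250))
        ).clip(max=len(tp) - 1)
        tp, vp = tp[idx], vp[idx]

    v0_init = v[0]
    dv = vp - v0_init
    good = dv > 0
    if p0 is None:
        # late-time log-log slope as the eta seed
        tail = max(int(0.3 * good.sum()), 8)
        lt = np.log(tp[good][-tail:])
        lv = np.log(dv[good][-tail:])
        slope = np.polyfit(lt, lv, 1)[0]
        eta0 = float(np.clip(slope, 0.1, 1.0))
        c0 = I * tp[-1] ** eta0 / (dv[-1] * math.gamma(1 + eta0))
        g0 = max(I / (4.0 * dv[-1]), 1e-6)
        p0 = {"eta": eta0, "C_o": max(c0, 1e-9), "G_c": g0, "v0": v0_init}

    def model(tt, eta, lnC, lnG, v0):
        p = SupercapParams(C_o=math.exp(lnC), G_c=math.exp(lnG), eta=eta, v0=v0)
        return step_response(p, I, tt)

    x0 = [p0["eta"], math.log(p0["C_o"]), math.log(p0["G_c"]), p0["v0"]]
    scale = max(abs(vp).max(), 1e-12)
    try:
        popt, pcov = curve_fit(
            model, tp, vp, p0=x0,
            bounds=([0.05, -30.0, -30.0, v0_init - scale],
                    [1.0, 30.0, 30.0, v0_init + scale]),
            maxfev=2000,
        )
    except RuntimeError as exc:   # pragma: no cover - diagnostic path
        raise ArithmeticError(f"charging-law fit did not converge: {exc}") from exc

    eta_hat, lnC, lnG, v0_hat = popt
    C_hat, G_hat = math.exp(lnC), math.exp(lnG)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    z = 1.959963984540054
    ci = {
        "eta": (eta_hat - z * se[0], eta_hat + z * se[0]),
        # delta method on the log-parameters
        "C_o": (C_hat * math.exp(-z * se[1]), C_hat * math.exp(z * se[1])),
        "G_c": (G_hat * math.exp(-z * se[2]), G_hat * math.exp(z * se[2])),
        "v0": (v0_hat - z * se[3], v0_hat + z * se[3]),
    }
    return SupercapFit(eta=float(eta_hat), C_o=C_hat, G_c=G_hat, v0=float(v0_hat),
                       ci95=ci, covariance=pcov)


def memcap_loop(t, v, C0: float, drive_frequency: float | None = None) -> ChargeVoltageLoop:
    """Charge response of the flux-controlled memcapacitor q = C0 (∫v dτ) v.

    With capacitance proportional to flux, the charge is the running
    integral of the drive times the instantaneous drive, so q = 0 at
    every zero crossing of v: the q–V loop is pinched at the origin.
    For a fixed-amplitude periodic drive the flux (hence the loop
    amplitude) shrinks as 1/frequency.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    flux = cumulative_trapezoid(v, t, initial=0.0)
    q = C0 * flux * v
    return ChargeVoltageLoop(time=t, voltage=v, charge=q, drive_frequency=drive_frequency)
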