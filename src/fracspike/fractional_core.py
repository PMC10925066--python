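"""Fractional-calculus kernels shared by the simulators and fits.

Everything here works with the Caputo derivative of order ``eta`` in
(0, 1].  The module provides the two discretizations used by the neuron
models (Grünwald–Letnikov binomial weights and L1 first-difference
coefficients), a numerical Mittag–Leffler function ``E_eta(z)`` for the
capacitor relaxation, and the closed-form fractional derivative of a
sinusoid used as an analytic reference for gain/phase estimation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.integrate import IntegrationWarning, quad

__all__ = [
    "FractionalOrder",
    "WeightKind",
    "WeightSequence",
    "gl_weights",
    "l1_coefficients",
    "mittag_leffler",
    "fractional_sine_derivative",
]


def _check_eta(eta: float) -> float:
    """Validate a fractional order, returning it as a float.

    Orders must lie in (0, 1]; eta = 1 is the classic (integer) limit.
    """
    eta = float(eta)
    if not 0.0 < eta <= 1.0:
        raise ValueError(f"fractional order eta must be in (0, 1], got {eta}")
    return eta


# FractionalOrder is a plain float with the (0, 1] invariant enforced at
# entry points; we keep an alias for annotation clarity.
FractionalOrder = float


class WeightKind(str, Enum):
    GL = "GL"
    L1 = "L1"


@dataclass(frozen=True)
class WeightSequence:
    """Discretization weights for a fractional derivative of order ``eta``.

    For the GL kind, ``values[k] = (-1)^k * binom(eta, k)``: the head
    value is 1, all later values are negative for 0 < eta < 1, and the
    partial sums decay like k^-eta toward zero.  For the L1 kind the
    values are the non-negative first-difference coefficients
    ``(N+1-k)^(1-eta) - (N-k)^(1-eta)``, all zero at eta = 1.
    """

    kind: WeightKind
    eta: float
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def gl_weights(eta: FractionalOrder, n_terms: int, convention: str = "binomial") -> WeightSequence:
    """Grünwald–Letnikov weights w_k = (-1)^k binom(eta, k), k = 0..n_terms-1.

    Computed by the stable recursion w_0 = 1, w_k = (1 - (1+eta)/k) w_{k-1}.
    With ``convention="scaled"`` the sequence is multiplied by eta so that
    the head value is eta (the convention some derivations start from);
    the recursion between consecutive terms is identical in both cases.

    At eta = 1 the sequence is [1, -1, 0, 0, ...], which makes the
    GL voltage update collapse to forward Euler.
    """
    eta = _check_eta(eta)
    n_terms = int(n_terms)
    if n_terms < 1:
        raise ValueError(f"n_terms must be >= 1, got {n_terms}")
    w = np.empty(n_terms)
    w[0] = 1.0
    for k in range(1, n_terms):
        w[k] = (1.0 - (1.0 + eta) / k) * w[k - 1]
    if convention == "scaled":
        w = eta * w
    elif convention != "binomial":
        raise ValueError(f"unknown convention {convention!r}")
    return WeightSequence(WeightKind.GL, eta, w)


def l1_coefficients(eta: FractionalOrder, n_steps: int) -> WeightSequence:
    """L1-scheme memory coefficients b_k at step N = n_steps.

    Returns ``b_k = (N+1-k)^(1-eta) - (N-k)^(1-eta)`` for k = 0..N-1,
    the coefficients weighting the past first differences
    n(t_{k+1}) - n(t_k) in the Caputo memory sum.  They are non-negative,
    increase toward the current step, and vanish identically at eta = 1
    (the scheme is then memoryless).
    """
    eta = _check_eta(eta)
    n_steps = int(n_steps)
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    k = np.arange(n_steps)
    vals = (n_steps + 1.0 - k) ** (1.0 - eta) - (n_steps - k) ** (1.0 - eta)
    return WeightSequence(WeightKind.L1, eta, vals)


# ---------------------------------------------------------------------------
# Mittag–Leffler function
# ---------------------------------------------------------------------------

_SERIES_RADIUS = 5.0
# for z > 0 the series has no cancellation; small eta just needs many terms
# before Gamma(1 + eta k) overtakes z^k
_SERIES_MAX_TERMS = 4000


def _ml_series(eta: float, z: float) -> float:
    """Power series sum_k z^k / Gamma(1 + eta k); reliable for |z| <= ~5."""
    if z == 0.0:
        return 1.0
    total = 1.0
    term_scale = 1.0
    log_absz = math.log(abs(z))
    for k in range(1, _SERIES_MAX_TERMS):
        term = math.exp(k * log_absz - math.lgamma(1.0 + eta * k))
        if z < 0.0 and k % 2 == 1:
            term = -term
        total += term
        term_scale = abs(term)
        if term_scale < 1e-18 * max(1.0, abs(total)) and k > 4:
            break
    if not math.isfinite(total) or term_scale > 1e-10 * max(1.0, abs(total)):
        raise ArithmeticError(
            f"Mittag-Leffler series did not converge (eta={eta}, z={z})"
        )
    return total


def _series_safe(eta: float, z: float, max_term: float = 1e4) -> bool:
    """True when the alternating series loses < ~10 digits to cancellation.

    The absolute rounding error of the float64 series is about
    eps * n_terms * max_k |z|^k / Gamma(1 + eta k); keep the series
    whenever that peak stays below ``max_term`` (error < ~1e-11)."""
    log_peak = 0.0
    log_absz = math.log(abs(z)) if z != 0.0 else -math.inf
    k = 1
    prev = -math.inf
    while k < _SERIES_MAX_TERMS:
        cur = k * log_absz - math.lgamma(1.0 + eta * k)
        log_peak = max(log_peak, cur)
        if cur < prev and cur < log_peak - 5.0:
            break
        prev = cur
        k += 1
    return log_peak < math.log(max_term)


def _ml_integral(eta: float, x: float) -> float:
    """Spectral-representation evaluation of E_eta(-x) for x > 0, 0 < eta < 1.

    Uses the complete-monotonicity (spectral) representation
    E_eta(-t^eta) = ∫_0^∞ e^{-r t} K_eta(r) dr with
    K_eta(r) = sin(eta π)/π · r^{eta-1} / (r^{2 eta} + 2 r^eta cos(eta π) + 1).
    The substitution s = r^eta removes the endpoint singularity; with
    t = x^{1/eta}:

        E_eta(-x) = sin(eta π)/(eta π)
                    ∫_0^∞ exp(-s^{1/eta} t) / (s^2 + 2 s cos(eta π) + 1) ds
    """
    t = x ** (1.0 / eta)
    cos_e = math.cos(eta * math.pi)
    sin_e = math.sin(eta * math.pi)

    def integrand(s: float) -> float:
        return math.exp(-(s ** (1.0 / eta)) * t) / (s * s + 2.0 * s * cos_e + 1.0)

    # the denominator is minimized near s0 = -cos(eta π); seed the adaptive
    # quadrature with breakpoints around it so near-poles (eta -> 1) resolve
    s0 = max(-cos_e, 0.0)
    width = max(sin_e, 1e-6)
    pts = sorted({max(s0 - 30 * width, 0.0), max(s0 - 3 * width, 0.0),
                  max(s0 - width, 0.0), s0, s0 + width, s0 + 3 * width,
                  s0 + 30 * width, s0 + 1.0})
    total = 0.0
    err_total = 0.0
    lo = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IntegrationWarning)
        for p in pts:
            if p > lo:
                val, err = quad(integrand, lo, p, epsabs=1e-13, epsrel=1e-11, limit=200)
                total += val
                err_total += err
                lo = p
        val, err = quad(integrand, lo, np.inf, epsabs=1e-13, epsrel=1e-11, limit=200)
        total += val
        err_total += err
    if err_total > 1e-8:
        raise ArithmeticError(
            f"Mittag-Leffler quadrature error {err_total:.2e} exceeds 1e-9 "
            f"(eta={eta}, z={-x})"
        )
    return sin_e / (eta * math.pi) * total


def mittag_leffler(eta: FractionalOrder, z):
    """One-parameter Mittag–Leffler function E_eta(z) for real z.

    E_1(z) = exp(z) exactly; E_eta(0) = 1.  For negative arguments (the
    relaxation regime, the primary use) the function decreases
    monotonically from 1 toward 0 with a power-law ~ z^-1/Γ(1-eta) tail.
    Accurate to better than 1e-8 absolute on z in [-50, 5].

    Accepts a scalar or array ``z``; returns matching shape.
    """
    eta = _check_eta(eta)
    z_arr = np.asarray(z, dtype=float)
    scalar = z_arr.ndim == 0
    flat = np.atleast_1d(z_arr).ravel()
    out = np.empty_like(flat)
    for i, zi in enumerate(flat):
        if eta == 1.0:
            out[i] = math.exp(zi)
        elif zi >= 0.0 or _series_safe(eta, zi):
            out[i] = _ml_series(eta, zi)
        else:
            # deeper negative (relaxation) arguments: the alternating
            # series cancels catastrophically, so use the spectral
            # integral, exact for all x > 0 and 0 < eta < 1
            out[i] = _ml_integral(eta, -zi)
    result = out.reshape(np.atleast_1d(z_arr).shape)
    return float(result[0]) if scalar else result


def fractional_sine_derivative(amplitude: float, omega: float, eta: FractionalOrder, t):
    """Caputo fractional derivative (steady state) of A sin(2π ω t).

    Returns ``A (2π ω)^eta sin(2π ω t + eta π/2)`` on the grid ``t``:
    the gain of a fractional differentiator grows as frequency^eta and
    the phase advances by eta π/2.  At eta = 1 this is the ordinary
    derivative; as eta -> 0 it approaches the input sinusoid.

    ``omega`` is in cycles per unit of ``t`` (use consistent units).
    """
    eta = _check_eta(eta)
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    t = np.asarray(t, dtype=float)
    w = 2.0 * math.pi * omega
    return amplitude * w**eta * np.sin(w * t + eta * math.pi / 2.0)
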