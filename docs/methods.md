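# Methods

`fracspike` implements two spiking-neuron models whose membrane or gating
dynamics follow a Caputo fractional derivative of order η ∈ (0, 1], the
fractional (super-capacitor/memcapacitor) circuit element that motivates
them, and the spike-train analyses used to read fractional dynamics out of
spiking data.  This note records the models, the numerical schemes, the
defaults and why, and what the synthetic protocols do and do not show.

## Fractional calculus kernels

The Caputo derivative of order η weights the past first derivative by the
power-law kernel (t−u)^−η; this kernel is the *memory trace*: every past
state contributes to the present rate of change, with influence decaying
as a power law rather than exponentially.

**Grünwald–Letnikov (GL) weights.** The discrete derivative uses the
binomial weights w₀ = 1, w_k = (1 − (1+η)/k) w_{k−1}, i.e.
w_k = (−1)^k C(η, k).  For 0 < η < 1 all tail weights are negative, the
partial sums are positive and decay like K^−η/Γ(1−η), and at η = 1 the
sequence is [1, −1, 0, …] so the scheme collapses to forward Euler.  A
scaled convention with head value η (the same recursion started at η)
is exposed for completeness; the simulators use the binomial convention
because the η = 1 classic limit must hold exactly.

**L1 coefficients.** The L1 scheme discretizes the Caputo derivative by
weighted first differences of the state history with coefficients
d_j = (j+1)^{1−η} − j^{1−η} (j = distance in steps from the present).
They are non-negative, decay with distance, and vanish identically at
η = 1 (memoryless limit).  The explicit update used for a gate n with
relaxation rate (n∞ − n)/τ_n is

    n_{N+1} = n_N + Δt^η Γ(2−η) (n∞(v_N) − n_N)/τ_n(v_N)
              − Σ_{j≥1} d_j (n_{N+1−j} − n_{N−j}).

At frozen voltage this converges to the exact Mittag–Leffler relaxation
n∞ + (n₀ − n∞) E_η(−t^η/τ_n) (verified in the tests), and at η = 1 it is
forward Euler.

**Mittag–Leffler function.** E_η(z) is evaluated by the power series
where float64 cancellation is provably small (the branch is chosen from
the predicted largest series term) and otherwise, for negative
arguments, by the exact spectral representation

    E_η(−x) = sin(ηπ)/(ηπ) ∫₀^∞ e^{−s^{1/η} x^{1/η}} / (s² + 2s cos ηπ + 1) ds,

integrated adaptively with breakpoints at the denominator minimum (the
integrand peaks sharply as η → 1).  Accuracy is better than 1e−8
absolute-or-relative on z ∈ [−50, 5] against a high-precision series
oracle; E₁(z) = exp(z) exactly.

## The fractional capacitor / memcapacitor

A leaky fractional capacitor obeys I = G_c v + C_o D^η v.  For a constant
charging current the voltage is

    v(t) = v₀ + (I/G_c)(1 − E_η(−(G_c/C_o) t^η)),

which reduces to the RC exponential at η = 1 and, while t^η ≪ C_o/G_c
(weak leak), to the power-law charging form v₀ + I(1/G_c + t^η/(C_o Γ(1+η)))
whose log–log slope is exactly η.  Both forms are exposed; the power-law
form is the practical fitting target for measured charging curves, and the
full Mittag–Leffler law is what `fit_fractional_order` actually fits
(nonlinear least squares on (η, ln C_o, ln G_c, v₀), samples thinned
uniformly in log time, η seeded from the late-time log–log slope, 95% CI
from the fit covariance).  Parameter recovery is exact to ±0.01 in η on
noiseless traces and unbiased to |bias| < 0.05 at 1% additive noise.

The memcapacitor model takes capacitance proportional to flux,
q = C₀ (∫v dτ) v, so the charge–voltage loop is pinched at the origin
(q = 0 wherever v = 0) and its amplitude falls as 1/frequency at fixed
drive amplitude — the two memcapacitive signatures.

Units in this module are V, mA, mF, s (circuit-side quantities).

## Fractional LIF (GL scheme)

Model: D^η v = (−(v − v_r) + r_m I)/τ_m, spike and reset at v_Th with the
voltage clamped to v_r for a refractory period t_r; clamped samples enter
the memory sum at rest.  The scheme advances the *deviation* u = v − v_r:

    u_{N+1} = Δt^η (−u_N + r_m I_N)/τ_m − Σ_{k=1}^{K} w_k u_{N+1−k}.

Integrating the deviation rather than the absolute voltage matters: the GL
sum implicitly assumes zero pre-history, and on absolute voltage it would
inject a spurious drift proportional to v_r.  On the deviation the η = 1
limit reproduces the classic LIF exactly (ISIs match the closed form
t_r + τ_m ln[r_m I/(r_m I − (v_Th − v_r))] within grid resolution).

Defaults: v_r = −70 mV, v_Th = −50 mV, τ_m = 10 ms, t_r = 2 ms,
r_m = 10 MΩ (currents in nA), Δt = 0.1 ms.  The memory sum is O(N·W) for
a window of W steps; the default window is 10 s.  Because the GL tail
decays only as k^{−1−η}, naive truncation at η = 0.2 discards a drive
term of order K^{−η} and visibly shifts late spike times, so the
windowed mode keeps the window *exact* and adds a block-compressed
tail: history older than the window enters as per-block means weighted
by the exact cumulative GL weights.  The weight sequence's total
variation beyond a 10 s window is ~1e−7, so the compression is
near-exact — on a 30 s run at η = 0.2 the windowed scheme reproduces
full-memory spike times to the time step exactly (the windowed-vs-full
check is part of the acceptance suite) at a third of the cost; the
window is a cost knob, not an accuracy knob.

At small η the approach to the quasi-steady voltage is t^η-slow, so
desk-scale runs need drive well above rheobase: with a 20 mV threshold
gap, I = 6 nA (r_m I = 60 mV) gives a first-spike latency of ~2 s at
η = 0.2 followed by the power-law ISI shortening that is the fractional
signature (log ISI vs log spike-index is straight with negative slope,
while the classic neuron fires periodically).

## Fractional HH (RK4 + L1 splitting)

Classic HH currents for Na, K and leak, with only the potassium
activation gate n given fractional order η_n.  Per global step, (v, m, h)
advance one RK4 step holding n fixed, then n advances one L1 step using
the start-of-step voltage; the splitting error is dominated by the L1
scheme's own order.  Rate functions use the standard shifted forms on
u = V − V0 with removable singularities (α_n at u = 10 mV → 0.1, α_m at
u = 25 mV → 1) handled by series expansion.  V0 defaults to the preset's
resting voltage, the classic convention; the printed rate table this
model follows contains one inconsistent occurrence of (V + V0), which is
read as (V − V0) like all sibling terms.

Parameter presets (µF, mS, mV): *normal* — c_m 0.47, ḡ_Na 120, ḡ_K 36,
g_m 0.3, E_Na 50, E_K −77, v_r −65; *criticality* — c_m 1, ḡ_Na 70,
ḡ_K 5, E_K −77, v_r −54.4, with E_Na and g_m inherited from the normal
set (the inheritance is an assumption, echoed in run manifests).  At
η_n = 1 and Δt = 0.01 ms the spiking period matches a high-accuracy
adaptive reference integration within 1%.

**Complex spikes and criticality.** With the criticality preset and small
η_n, the sluggish, history-laden potassium gate lets the trajectory fall
into a depolarized plateau (a canard-like small attractor) before the
slowly accumulating K current repolarizes it: an action potential carrying
a plateau of highly variable duration — a *complex spike*.  Plateau
durations can exceed the memory horizon; with the default 10 s window the
longest plateaus are terminated on the window scale.  The operating
current of the mixed simple/complex regime shifts with η_n (≈ 10.7 µA at
η_n = 0.15, ≈ 7 µA at η_n = 0.2, ≈ 3.5 µA at η_n = 0.3 at Δt = 0.1 ms);
the avalanche protocol therefore runs each η_n at the operating current
of its own mixed regime — the current band, located by a coarse scan,
in which simple and complex spikes coexist rather than all-simple
spiking or permanent plateau.  Within that regime, avalanches
(simple-spike counts between consecutive complex spikes) have broad
size distributions whose fitted exponent steepens as η_n grows.

## Stimuli

Constant/square/sinusoid generators are exact closed forms; square waves
are 50% duty starting high, and no generator auto-tunes levels (whether
the drive is suprathreshold is the caller's experimental choice).  Pink
noise is synthesized spectrally — amplitude ∝ f^{β/2} strictly inside the
band, uniform random phases from the seed — so the in-band PSD exponent
is exact by construction and ≥ 99% of AC power is in-band.  β is the PSD
exponent as fitted in log–log (β ≤ 0).  The default noise RMS used by the
whitening protocol is a configurable fraction (~25%) of the DC drive;
the masking protocol (pre window, 30 s mask, monitor window) returns
segment annotations for the cumulative-spike analysis.

## Spike-train analyses

Instantaneous rate is 1/ISI assigned at the second spike of each pair and
linearly interpolated onto a uniform grid (spectra and sinusoid fits need
uniform sampling; the resampling rule is a package choice).  Gain/phase
at a known drive frequency come from a linear sinusoid fit after
discarding the first period; the fractional order is read out twice, as
the log-gain slope η_G against log(2πω) and as the mean of 2·phase/π
(η_φ) with SEM.  The analytic round trip through the closed-form
fractional sinusoid derivative recovers η to machine precision, and to
< 1% when the rate is an actual fLIF simulation.

Rate spectra use a segment-averaged periodogram (Welch, mean removed,
segment length 3/f_lo) with a log–log OLS fit in-band; the whitening
statistic is Δη = η_out − β.  Avalanche histograms are log-binned
(8 bins/decade, zero bins dropped) and fitted by least squares on the
log–log density — a visual-fit convention, deliberately not tail MLE, so
CI semantics match the other fits.  Complex spikes are labelled by
plateau dwell time: a spike is complex iff the voltage stays above the
plateau level for at least the minimum plateau duration inside its event
window (ties count as complex); defaults put the level midway between
rest (20th percentile) and the mean spike peak, and the duration at 3×
the median event width, both overridable (the criticality protocols pin
them at −35 mV / 10 ms for comparability across η_n).

The cumulative relative curve is the ratio convention
R(t) = N_post(0,t)/(r_pre t), so no change gives a horizontal line at 1;
the 95% band treats the post count as Poisson, conditional on the
pre-window rate.

## Diffusion entropy analysis

Increments ξ (raw series, binary event trains, or bin counts; binary is
the default for spike trains) are cumulated into x(t); for each window l
the overlapping displacements (stride 1) are histogrammed with a
Rice-type bin count and S(l) computed as the bin-corrected Shannon
entropy, approximating the differential entropy of p(x, l).  δ is the
OLS slope of S against ln l over the central decade of window lengths
(small l is binning-biased, large l sample-depleted).  The Gaussian null
gives δ = 0.5 ± 0.03 (10 seeds, n = 10⁵); long-memory persistent noise
gives δ near 1 and shuffling restores 0.5.  Degenerate (constant)
increment series have a point-mass displacement distribution and are
rejected rather than assigned a δ.  Heavy-tailed (Lévy) increments are
outside the estimator's reliable range; the Lévy regime is flagged only
qualitatively by δ > 0.5.

## Problem sizes

Desk-scale protocol sizes, chosen once for the replication suites and
acceptance checks: fLIF constant-drive runs 10–30 s; whitening 60 s per
run, band 0.1–2 Hz, β ∈ {−0.2, −0.4, −0.6}, 5 seeds each, 2 s memory
window; fHH criticality runs 10–120 s at Δt = 0.1 ms (statistics are
dt-robust between 0.025 and 0.1 ms) with the 10 s default window; DEA
n = 10⁵ × 10 seeds.  All randomness flows from explicit seeds; identical
configs give byte-identical spike files.

## Known limitations

* The synthetic protocols exercise the *models*; circuit-measured and
  in-vivo quantities (gain exponents, avalanche exponents of the fish
  recordings) are device/animal properties and are checked only for
  sign, range, or direction.
* The deterministic fHH in the critical regime is chaotic; trajectories
  are dt-sensitive individually and only their statistics are stable.
* The L1/GL memory sums are O(N·W); very long full-memory runs are
  intentionally out of scope.
* The avalanche exponent from log-binned least squares is a convention,
  not an MLE tail estimate; absolute exponent values depend on the
  binning rule, while directions/trends are robust.
* Complex-spike labelling is threshold-based; pathological traces (e.g.
  drives that silence the neuron mid-run) can defeat the automatic
  plateau criteria, which is why protocol code pins them explicitly.
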