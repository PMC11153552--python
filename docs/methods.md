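# Methods

## The measurement being modeled

A well holds a population of ~50 adult *C. elegans* carrying a ubiquitously
expressed luciferase reporter; a plate luminometer integrates each well's
luminescence every 30 minutes for 7–10 days. Two protocols are supported:
three days of dual 12:12 light/temperature cycles followed by four days of
constant conditions (entrainment then free run), or constant conditions
throughout. The analysis works on one internal time axis — decimal hours
since the start of the recording — with zeitgeber anchoring carried by a
protocol schedule (`zt0_recording_offset` plus ordered cyclic/free-run
epochs), never by the series themselves. Missing readings are kept as gaps
and dropped point-wise; nothing is interpolated.

## Signal conditioning

Raw traces are dominated by two non-circadian components: the luciferase
accumulation transient over the first 12–24 h, and a slow multiplicative
decline of the baseline (substrate consumption, ageing). Conditioning runs
in a fixed order:

1. **Background subtraction** — a scalar, or the pooled median of wells
   flagged as blanks. Negatives are not clamped. When nothing is supplied
   the background defaults to 0 with a warning (detrending later absorbs
   any constant offset).
2. **Initial truncation** — default 24 h (accepted range in practice is
   12–24 h); the time axis is *not* re-zeroed, so the schedule stays
   aligned.
3. **Detrending** — subtraction of a centered moving average with a 24-h
   window. One full circadian cycle is the natural window: the mean of a
   24-h sinusoid over any full cycle is zero, so the circadian component
   passes through unattenuated while baseline decay is removed.
4. **Smoothing** — a centered moving average, default 2.5 h (5 samples at
   30-min sampling), suppressing integration noise while displacing a
   symmetric hourly-scale peak by less than one sample.
5. **Normalization** — division by the maximum over the first 24 h of the
   conditioned (truncated, detrended, smoothed) series. Normalization is
   cosmetic: periodogram peak location and cosinor R² are scale-invariant,
   so the convention only affects plots. A near-zero initial maximum is
   reported as a dead well.

Moving averages are time-window based (`[t − w/2, t + w/2]`, shrinking at
the series edges) so they are well defined on uneven, gappy grids. Points
landing exactly on a window edge get half weight (trapezoid rule). This
choice is load-bearing twice over: with full endpoint weights a 24-h boxcar
applied to a 24-h cosine on a half-hour grid leaves a residual of 1/49 of
the amplitude (the duplicated endpoint phase), and a half-open window would
break the symmetry that makes the filter exact on linear trends. With
trapezoid weights both are exact to rounding.

## Period estimation

The endogenous period is estimated with the classical Scargle periodogram
on the mean-subtracted conditioned free-run segment, using the standard
per-frequency offset τ(ω) defined by `tan(2ωτ) = Σsin(2ωt) / Σcos(2ωt)`,
and normalized by the sample variance (ddof = 1). With this normalization
the power at each frequency equals `(N−1)/2` times the variance fraction
explained by the best-fitting single sinusoid at that frequency — the
property the test suite checks against explicit per-frequency least-squares
fits, and which reduces to the classical DFT periodogram on even sampling.

The frequency grid runs from `1/35` to `1/18` cycles/h (periods 18–35 h)
with spacing `1/(ofac · span)` and both band edges included; `ofac = 30`
by default. On a 4-day free-run window this gives a period resolution of
about 0.2 h near 24 h, growing quadratically to ~0.4 h near 35 h. The peak
is taken as the grid argmax, with exact ties resolved toward the shorter
period and band-edge maxima logged. No analytic Lomb–Scargle significance
test is used anywhere: rhythmicity is decided by cosinor R², not
periodogram p-values, so none is exposed.

## Cosinor fitting and classification

The cosinor model `y(t) = M + A·cos(2π(t−φ)/τ)` is linear in
`(M, A·cos(2πφ/τ), A·sin(2πφ/τ))` once τ is fixed, so the fit is computed
exactly by ordinary least squares on the `[1, cos ωt, sin ωt]` design —
the same optimum an iterative nonlinear solver would reach, with no
initialization or convergence concerns. Amplitude and acrophase follow as
`A = √(βc² + βs²)`, `φ = (τ/2π)·atan2(βs, βc) mod τ`; R² is defined against
the mean model (`1 − SSres/SStot`, possibly negative) rather than adjusted
R² — with two effective regressors and 150–300 points the two differ by
under 0.01. A design with fewer than three distinct sampling phases modulo
τ is rejected as degenerate.

A free-period variant profiles τ deterministically: fixed-τ fits on a
0.05-h grid over the band, then golden-section refinement of the best
bracket to 10⁻³ h. It is provided for validation; the pipeline itself
fixes τ at the Lomb–Scargle estimate so that the reported period and the
reported R²/amplitude/acrophase describe the same sinusoid.

Classification is a deterministic function of (period, R²), thresholds
inclusive:

- entrained epoch, fit at τ = 24 h: **SYNCHRONIZED** iff R² ≥ 0.5;
- free-run epoch, fit at the Lomb–Scargle period τ̂: **CIRCADIAN** iff
  18 ≤ τ̂ ≤ 35 and R² ≥ 0.5;
- otherwise **ARRHYTHMIC**.

The R² ≥ 0.5 bar is stringent for noise: a 2-regressor fit on ~290
independent noise points has E[R²] ≈ 2/(n−1) < 0.01, and even after
smoothing-induced autocorrelation (~5× dof reduction) plus selection of
the best band frequency, spurious R² stays far below 0.5 — the calibration
test measures a 0% false-call rate on 200 pure-noise wells.

## Phase extraction and circular statistics

A well's phase in a context is the time of the global maximum of its
conditioned trace within a one-cycle window — the last full entrained cycle
(phase expressed in ZT), or the first 26 h after release (phase expressed
as hours after release mod 24; 26 h rather than 24 so the first peak of
long-period genotypes is not missed). Ties go to the earliest sample;
boundary maxima raise a warning. Cosinor acrophase is available as an
alternative detector, but the raw maximum of the smoothed trace is the
default because it is the most direct reading of "the bioluminescent peak".

Phases θᵢ = 2π·phaseᵢ/24 are summarized by the circular mean direction and
the mean resultant length `R = |Σ exp(iθᵢ)|/n`; for degenerate sets
(R ≈ 0, e.g. antipodal pairs) the mean direction is reported as missing.
Uniformity is tested with the Rayleigh statistic `Z = nR²` using Zar's
second-order approximation

    p = exp( √(1 + 4n + 4(n² − (nR)²)) − (1 + 2n) ),

clipped to (0, 1], and the significance circle on Rayleigh plots is its
numerical inverse (bisection to 10⁻⁶). Calibration: at n = 20 the test
rejects uniform phases at 5.0% ± 1% (10⁴ simulations), and the
approximation tracks a 10⁶-draw Monte-Carlo null to < 0.005 at moderate n
(e.g. n = 100, R = 0.05). Known limitation: in the extreme small-sample
tail the approximation overestimates p substantially — at n = 3, R = 1 it
returns 0.034 although `P(R ≥ 1)` is exactly 0 under the null; the same is
true of every closed-form Rayleigh approximation in common use. Group
phase summaries cover the wells classified rhythmic, matching how Rayleigh
plots of population records are conventionally drawn.

## Synthetic data: what it emulates, and what it does not

Each simulated well draws `rhythmic ~ Bernoulli(rhythmic_fraction)`,
`τ ~ Normal(period_mean, period_sd)` clipped to [18, 35] h (so generator
truth is always recoverable in-band), and an entrained acrophase jittered
±1 h about the group value, then emits

    L(t) = background + B(t)·[1 + a(t)·cos ψ(t)] + mask(t) + ε(t)
    B(t) = baseline·(1 − e^(−t/8 h))·e^(−t/120 h)

The oscillation is multiplicative on the decaying baseline — the observed
shape of luciferase records, and the reason detrending is non-trivially
exercised. During cyclic epochs ψ is phase-locked to the zeitgeber
(instantly; no gradual re-entrainment dynamics are modeled, which keeps
truth analytic); at release ψ continues from its current value at the
well's own period, with amplitude damping of 0.15/day thereafter. Masking
is a separate additive transient (10% of baseline in the first hour after
each lights-on/off transition) because direct zeitgeber effects on output
are distinct from entrainment. Noise is Poisson-like by default
(Gaussian with SD = √L̄). Blank wells carry background plus noise only.

Defaults mirror the study conditions the generator stands in for: 0.5-h
sampling, 3 d cyclic + 4 d free run (or 7 d free run), baseline 5000
counts, amplitude 0.3 of baseline, 60% rhythmic wells, group period means
near 24.4 vs 26.4 h. The well-to-well period SD of real populations is not
directly published (only SEMs at given n); the default SD of 1.0 h
reproduces the printed SEM scale (≈ 0.2–1 h) at the printed group sizes.
Per-well RNG substreams derive from (seed, well index), so recordings are
bit-reproducible and adding wells never perturbs existing ones.

What the generator deliberately omits — and hence what passing tests do
not establish about real data: no mechanistic oscillator (no
transcription–translation feedback dynamics, no temperature compensation),
no gradual re-entrainment, no inter-well crosstalk or plate-geometry
effects, no drift in sampling times, no developmental or mortality trends
beyond the smooth baseline. Tests against the generator certify the
*estimators* (that true periods, phases, and rhythmic fractions are
recovered under realistic noise), not the biology.

## Numerical and design choices

- Fixed-τ cosinor by linearized OLS instead of iterative NLS: identical
  optimum, exact, deterministic.
- Reported period for rhythmic free-run wells is the Lomb–Scargle
  estimate; the cosinor at that period supplies R², amplitude, acrophase.
- Thresholds are inclusive exactly as written (≥ 0.5; closed band
  [18, 35]).
- Epoch splitting happens after conditioning the full trace, so the
  detrend window may straddle the release boundary; the free-run analysis
  window starts at release when an entrained epoch precedes it, and the
  24-h truncation plays that role for constant-only protocols.
- SEM denominators count wells (populations), the experimental unit.
- Floating-point mod can round `−ε mod c` up to `c`; all phase/ZT wrapping
  canonicalizes that edge back to 0.
- CSV values are written with shortest-roundtrip float repr and parsed
  with correctly-rounded conversion, making the plate-CSV roundtrip
  bit-exact (pandas' fast parser is deliberately bypassed for values).
- Problem sizes in the test suite (e.g. 20 simulation replicates of the
  60-well study, 200-well calibration plates, 10⁶-draw Monte-Carlo nulls)
  were chosen to bound each check's sampling error well below its
  assertion margin while keeping the whole suite interactive.

## Known limitations

- Period resolution is grid-limited (~τ²/(ofac·span)); sub-grid refinement
  is available only through the free-period cosinor.
- The Rayleigh approximation's extreme-tail behavior at n < 5, noted above.
- Only moving-average detrending is offered (no spline/LOESS variants);
  heavily nonstationary baselines beyond smooth decay are out of scope.
- Proprietary luminometer export formats are not parsed; convert to CSV.
- No inferential group comparisons (ANOVA, post-hoc); summaries are
  descriptive by design.
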