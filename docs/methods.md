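# Methods

## Signal model and scope

A single-channel scalp recording is modelled as d̃[n] = ã[n] + b̃[n] +
c̃[n]: artefacts (EMG, ocular, movement), background EEG the subject
cannot control, and the consciously controlled component.  Everything
the analysis sees is the causally filtered d[n]; the package never
assumes access to the components separately except in the synthetic
generator, where the decomposition is the ground truth.

The decision problem is binary hypothesis testing with an energy
detector: T(x) = mean(x²) over N samples against a threshold γ.  T is
deliberately the plain mean square, *without* mean subtraction — after
the mandatory high-pass stages the mean is ≈ 0 anyway, and keeping the
estimator literal keeps the closed forms exact.

## Detection theory

For real Gaussian samples, T is asymptotically Normal with
Var[T] = 2σ⁴/N (the complex-signal variant with σ⁴/N from the
telecommunications literature is out of scope).  With noise uncertainty
ρ ≥ 1 the worst cases are noise at ρσ² when controlling false alarms
and signal riding on σ²/ρ when controlling detection, giving

- P_FA = Q((γ − ρσ²) / (√(2/N)·ρσ²))
- P_D  = Q((γ − (T(c) + σ²/ρ)) / (√(2/N)·(T(c) + σ²/ρ)))
- N    = 2[Q⁻¹(P_FA) − Q⁻¹(P_D)]² / [SNR − (ρ − 1/ρ)]²  (low-SNR regime)

N diverges at SNR = ρ − 1/ρ: the SNR-wall.  The low-SNR simplification
SNR + 1 ≈ 1 is kept as is; no attempt is made to "improve" the formula.
N is reported both raw and ceiling-rounded, and an infinite requirement
is a value (`math.inf`), not an error.  The Monte-Carlo verifier draws
the signal as an independent Gaussian of power T(c), which makes the
simulated statistic exactly a scaled χ²_N — the distribution the normal
forms approximate.  Closed-form/simulation agreement is therefore only
asserted in the regime the asymptotics target (N of a few hundred,
moderate error rates); in far tails at small N the χ² skewness exceeds
the Monte-Carlo resolution, which is a property of the approximation,
not of the code.

## Measuring the wall and the SNR

ρ is measured by scanning the filtered recording with a τ = 2 s window,
sample by sample (stride configurable; for strides up to fs/10 the
resulting ρ changes by well under 2 %).  ρ is the ratio of standard
deviations — the printed worked example (2.00e-8 / 1.15e-10 → 13.2, not
174) fixes that reading.  The nominal noise power σ²_r is the
whole-recording mean square (the direct route; the alternative ρ·σ²_min
is exposed by the profile fields but the direct route matches the
walk-through's printed σ²_r = 2.75e-9 V² and is the default).  The
first 2 s (one window, configurable) are discarded before the scan so
that IIR startup transients cannot masquerade as σ²_max.  A flatlined
window (σ²_min = 0) is a degenerate-input error, since ρ would be
infinite.

The conscious power comes from the P300: epochs of −200…+600 ms around
each oddball event are baseline-corrected (mean of −200…0 ms),
averaged, and the peak is read in 150…500 ms.  Three estimator details
matter and were fixed against a noise-free template oracle:

- the average is detrended by a straight line fitted to its
  response-free parts (outside the search interval plus a 30 ms guard).
  Background EEG has strong low-frequency power, and the residual drift
  after a few hundred averages is the dominant error on c_max; the
  linear fit removes it while subtracting nothing from a drift-free
  response.
- the peak is read from a 20 ms boxcar-smoothed copy, so single-sample
  excursions cannot pose as the peak; 20 ms costs < 1 % of a 200 ms-wide
  deflection.
- amplitude estimation runs on the *raw* recording, not on the
  detection chain's output: a causal 0.1 Hz 4th-order highpass alone
  shaves ~8 % off a 200 ms transient, and averaging needs fidelity, not
  band-limiting.  (The detection chain still defines the wall and the
  noise power.)

c_max is the signed maximum — the P300 is a positive deflection.  For
frequency-domain BCIs the usable power assumes a 40 % conscious
band-power reduction; both readings of "40 % reduction" are
implemented (`power_scaled`, 0.6·T_t, the default; and
`amplitude_scaled`, (0.6·c_max)² = 0.36·T_t) because both appear in
practice, and the choice is recorded in result metadata.

The decision SNR > SNR_wall is strict: on the wall, N is already
infinite.

## Filter chains

All five setups are causal single-pass IIR cascades — the use case is
realtime BCI, so zero-phase forward–backward filtering is off the
table.  The mains bandstop is a 4th-order Butterworth with ±2 Hz width
(narrow enough to spare the 20–45 Hz EMG-diagnostic band); whether a
notch biquad or a Butterworth bandstop is used upstream of a given
dataset is recorded in output metadata since the reference leaves it
open.  The wide/alpha bandpasses already have zero DC gain, so no extra
DC-removal stage exists.  The derivative is the plain first difference
y[n] = x[n] − x[n−1], not scaled by fs.

## Synthetic data

The generator is a pure function of (spec, seed) and returns every
component separately (the recording is their exact sum):

- background: 1/f^slope coloured noise (slope 1, flattened below
  0.5 Hz), normalised to 20 µV RMS — the resting amplitude at Cz; an
  optional constant 10 Hz sine models the eyes-closed alpha peak
  (6 µV in the lying-eyes-closed preset).
- EMG bursts: white noise high-passed at 20 Hz (6th order — muscle
  power below 20 Hz is small), flat-topped raised-cosine envelope
  (0.25 s ramps), RMS = gain × background RMS.  The jaw-clench preset
  uses gain 50 every 15 s, putting peak excursions near 1 mV over the
  ~20 µV quiet floor.
- ocular/movement artefacts: blinks as biphasic ~400 ms pulses (150 µV
  default), saccades and movement artefacts as 50 ms-ramped voltage
  steps.  These amplitudes are order-of-magnitude choices, exposed as
  config, and are never used as numeric anchors.
- mains: a 10 µV sine at 50 Hz (or 60 Hz).
- oddball sessions: inter-stimulus intervals uniform in 7–13 s; the
  P300 template is a positive raised-cosine bump, 200 ms wide, peaking
  300 ms after the event (19 µV by default).

Eight task presets map activity phenomenology to schedule densities:
lying eyes-closed (alpha peak, rare swallows, slow eye rolls), lying
eyes-open (blinks, saccades), phone app / Sudoku / word search
(sustained low-grade EMG tone, frequent saccades), colouring (movement
steps and EMG bursts), reading (dense blinks, saccades and irregular
facial EMG), jaw clench (as above).

The ground truth includes the *realized* max/min window-std ratio of
the clean physiological sum (same 2 s scan, mains excluded since every
chain notches it) next to the analytic √(1 + gain²) implied by the
schedule.  The two differ systematically: extrema over ~60 effective
windows of correlated noise sit beyond the ensemble value by ~10–30 %
depending on the background's correlation, a textbook extreme-value
effect.  Parameter-recovery tests therefore compare the pipeline
against the realized ratio (agreement within a few percent); the
analytic value is a generator-level sanity bound only.

What the generator does *not* emulate: true EMG spectra (it uses
band-limited white noise), alpha waxing/waning, electrode drift and
impedance changes, inter-channel structure (single channel only), and
any physiologically detailed neural-mass dynamics.  Passing tests show
the pipeline recovers programmed non-stationarity and evoked
amplitudes and that the detectability logic behaves as the theory
predicts — not that real recordings will match specific numbers.

## Group analysis

Each subject contributes one (SNR, wall) pair per task × filter cell.
The test is a one-sided paired t-test on d_i = SNR_i − wall_i (H1:
mean d > 0) at α = 0.05, uncorrected per cell; a Holm-adjusted p-value
set is computed alongside for transparency, and an independent-samples
variant is available behind a flag.  Pairing is the natural choice
because both numbers come from the same subject, but the reference
leaves paired-vs-independent open, so the choice is carried in the
result metadata.  Zero-variance differences (every subject identical)
are degenerate: the verdict follows the common sign and the result is
flagged rather than reporting a fabricated p-value.

Non-finite walls (ρ = 1 ⇒ −∞ dB) are excluded from group cells by the
`SubjectPair` validator with an error, so silent −∞ propagation is
impossible.

## Problem sizes and defaults

Simulated studies in the tests use 8 subjects × 8 tasks × 120 s task
recordings with a 300 s oddball session per subject at fs = 250 Hz
(2-minute tasks and a 5-minute oddball run are the protocol the
presets emulate; 250 Hz is typical for the relevant acquisition-device
class and is always explicit — no computation assumes it silently).
Amplitude-recovery suites use ~300-event sessions, where the
averaging noise floor is ~20 µV/√300 ≈ 1.2 µV.  Monte-Carlo checks use
10⁵ trials.  Internally everything is volts; the V²-scale worked-example
variances (10⁻¹⁰…10⁻⁸) confirm that scale.  Event files carry seconds,
not sample indices, so recordings at different rates can share them.

## Known limitations

- The wall estimate inherits extreme-value bias: longer recordings
  yield (slightly) higher measured ρ from the same process.  Walls of
  recordings of very different lengths are not directly comparable.
- The SNR borrows c_max from a separate oddball session; any gain
  drift between sessions shifts the SNR by the same factor (the wall,
  a ratio, is immune).
- The χ²-vs-normal mismatch of the closed forms at small N is left as
  is; the package reports the asymptotic numbers.
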