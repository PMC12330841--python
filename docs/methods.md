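# Methods

## Signal model

A cortical spreading depolarization (SD) reaching the recording
electrodes is modelled, over an analysis epoch of a few minutes, as a
Gaussian voltage pulse riding on a slowly varying baseline:

    v(t) = A · exp(−(t − t₀)² / (2σ²)) + c₀ + c₁ t + c₂ t²

with amplitude `A` (µV, negative for SD), peak time `t₀` (s), width `σ`
(s), and a quadratic baseline absorbing electrode drift. Two derived
quantities characterise the pulse: the full width at half maximum,
FWHM = 2.355 σ (2√(2 ln 2) ≈ 2.3548, rounded to the conventional
2.355), and the pulse frequency 1/FWHM. The Gaussian is an empirical
description of the DC-shift's rise and recovery at the ~1-minute scale,
not a biophysical model; real SD waveforms are mildly asymmetric, which
this package does not represent (see Limitations).

Scalp and ECoG observations of the same event differ by an attenuation
factor (the scalp/brain voltage ratio, ~0.12 for the forehead montage
this package targets), a temporal widening (scalp FWHM / ECoG FWHM
≈ 1.12), a delay of a few seconds, and a broad spatial footprint at the
scalp, taken radially Gaussian with scale `s` (cm). The half-max disc
of that footprint has area 2π ln 2 · s² ≈ 4.355 s².

## Pipeline

**Binning.** The DC signal is reduced to the mean voltage of
non-overlapping 8-second segments (256 Hz → 0.125 Hz). The SD band
(~0.006 Hz) is still oversampled ~20-fold. Masked samples are excluded
from bin means; an all-masked bin becomes a missing bin; a trailing
partial bin is dropped. Bin timestamps are bin centres.

**Brick-layer epochs.** Binned data are cut into overlapping 2-hour
epochs staggered by 1 hour and linearly detrended per channel
(least squares over the epoch). The stagger is a package choice — the
overlap fraction matters only insofar as every event should sit well
inside at least one epoch, which 50% guarantees (≥ 30 min from an
edge). Trend coefficients are retained so the raw series is exactly
reconstructible.

**Readability.** An epoch is unreadable when any of four rules fires:
(a) the display span exceeds 1000 µV (artifact); (b) it is below 50 µV
("no recording"); (c) in some bin at least 95% of live channels deviate
from their epoch median by more than 6× their median absolute deviation
with the same sign (device-wide deflection); (d) more than 10% of one
channel's bins exceed the same 6×MAD threshold (burst activity). The
span is the middle 99% of the pooled live-channel values (0.5th to
99.5th percentile). Rules (a)/(b) are protocol constants; the robust
quantifications in (c)/(d) — the MAD multiplier, the 95% channel
fraction and the 10% bin fraction — are package choices, all exposed in
configuration. Readability is deliberately insensitive to genuine SDs:
a cluster of minute-scale pulses occupies too few bins to trip the
burst rule and too few channels at full amplitude to trip rule (c).

**Fitting.** Each channel's window (default 240 s, a value that holds
the whole shift plus stable baseline; 720 s for slow or cluttered
events) is fitted by bounded nonlinear least squares. Because the model
is linear in (A, c₀, c₁, c₂) once (t₀, σ) are fixed, initialisation is
global: a (t₀, σ) grid — every bin time × ten log-spaced widths — is
profiled with linear least squares and the best basin is polished with
`scipy.optimize.curve_fit`. This removes the classic failure mode of
extremum-based starts, where a wide pulse leaks into the detrending
line and the optimizer converges to a sign-flipped or
baseline-degenerate solution. The baseline is fitted in window-centred
time for conditioning and reported in absolute time (covariance mapped
through the reparametrisation). Parameter uncertainties are the square
roots of the covariance diagonal, reported relative to the estimates;
for genuine events at the package's default 2% noise the pulse
parameters (A, t₀, σ) carry relative errors well under the 11% ceiling
the pipeline asserts. Relative errors on baseline coefficients are not
meaningful when the true coefficient is near zero and are reported but
not gated. A fit is flagged `"no shift"` when its amplitude is within
4× the post-fit residual noise, its width exceeds the window (the
Gaussian is then degenerate with the baseline), or its peak lies
outside the window.

**Comparison.** Per side, the peak channel maximises |A| among
converged, unflagged fits (ties: smaller amplitude error, then label
order; flagged fits are eligible only if nothing resolved a pulse —
without this exclusion a no-signal channel's baseline-degenerate fit
can win the amplitude contest outright). Both peak series are
baseline-subtracted with their own fitted quadratics; the scalp series
is scaled by the inverse of the fitted amplitude ratio A_scalp/A_ecog
and compared with the ECoG series by the square of the Pearson
correlation (CoD). CoD > 0.80 (raw, not rounded) declares structural
similarity. The ratio can optionally be taken from raw
baseline-subtracted extrema instead of fitted amplitudes
(configuration flag); the fitted-amplitude form is the default since
the comparison is defined on the fitted, baseline-free model. Manual
bin exclusion for visible artifacts is supported through the fit's
mask argument.

**Field reconstruction and extent.** The scalp potential at a bin time
is interpolated from the live electrodes with Gaussian radial basis
functions, kernel exp(−r²/(2w²)) with w = 1 cm (the sensor spacing),
solved exactly (no smoothing) so the field passes through every
measured value; dead-channel positions simply receive the interpolated
field. The expansion is pure-kernel (no appended polynomial): with a
fitted constant term the far field rides on a plateau and half-max
areas become margin-dependent. The analysis grid covers the electrode
bounding box plus a 1-cm margin at 0.1-cm pitch by default (0.033 cm
available; the difference in half-max area on target-scale fields is
below 1%). The extent of an event is measured on the field built from
each live channel's measured value at the scalp peak bin minus its
fitted baseline: the 8-connected component of grid cells with
|v| ≥ 0.5·|peak| containing the peak cell, area = cell count × pitch²,
and the diameter of the equal-area circle, 2√(area/π). Magnitudes
(absolute voltage) are used throughout, consistent with "largest
deviation from zero".

A known, quantified limitation: the electrode rows span only ~3.5 cm
vertically while the half-max footprint of a typical event is ~4.9 cm
across, so part of the region lies outside the electrode hull where the
kernel expansion decays toward zero. On the noiseless default event the
reconstructed half-max area is ~16.5 cm² against the analytic
18.7 cm² (~12% low). The extent screening threshold (diameter
≥ 3.5 cm) is comfortably clear of this bias. Tests that validate the
area *measurement* therefore use fields evaluated from the generator's
analytic footprint; a separate regression test pins the
reconstruction-from-electrodes bias band.

**Screening.** An event is acceptable when (1) it appears in more than
one but not all live channels — membership is an in-window fitted-pulse
excursion of at least 30% of the peak channel's (the excursion, rather
than the raw A parameter, is immune to baseline-degenerate fits on
no-signal channels); (2) its peak amplitude lies in [−1200, −230] µV;
(3) its half-max equivalent diameter is ≥ 3.5 cm (the "~4 cm" extent
criterion with headroom for reconstruction bias); and (4), when prior
accepted events exist, it repeats within one electrode spacing of a
prior event's peak channel inside a 12-h look-back. Criteria 1–3 are
always required; criterion 4 never rescues a failure of 1–3. All
thresholds are configuration keys.

**Reporting.** Each metric over the accepted comparison records is
summarised as mean ± StD when Shapiro–Wilk does not reject normality at
α = 0.05, else median [IQR] (IQR as a single width). Constant data skip
the test with a note. Outliers are never excluded. Scalp vs ECoG FWHM
is additionally compared with a paired two-sided test — Student's t
when the paired differences pass Shapiro–Wilk, Wilcoxon signed-rank
otherwise. The peak-time difference is reported over all events; a
delayed-only variant simply excludes negative differences.

## Synthetic scenarios

The generator emulates the statistical structure the pipeline assumes,
with full ground truth returned alongside the recordings. Per event:
ECoG contact c receives `A·w_c` at the event pulse, with contact
weights (0, 0.2, 1, 1, 1, 0.2) placing the activity on the central
contacts; scalp electrode e receives
`A·ratio·exp(−d(e, centre)²/(2s²))` at a widened pulse delayed by a few
seconds. Population defaults: ECoG peak −3771 µV (StD 171), ECoG FWHM
63.2 s (3.65), ratio 0.121 (0.016), scalp FWHM 70.9 s (5.92), delay
2.89 s (normal-equivalent StD of the reported 2.32 IQR), half-max area
18.7 cm² (2.76), event centre at electrode C5 (right of the array
centre, matching the member-electrode pattern of the motivating
events), cluster interval 1344 s (22.4 min). Per-event jitter draws
each parameter from a normal at those dispersions. Channels carry
independent quadratic drift (offset ±100 µV, slope ±0.02 µV/s,
curvature ±10⁻⁵ µV/s²) and white noise with σ = 2% of the channel's
event peak (floor 1 µV) — calibrated so pulse-parameter fit errors stay
under the 11% ceiling; dead channels emit floor noise only. Artifact
injection (device-wide steps, single-channel bursts, flatline) closes
the loop with the readability rules. Generation is at the 0.125-Hz
binned rate by default, with sample i at the centre of bin i (a 256-Hz
raw mode exists; binning it is tested separately — averaging an
8-second bin across a ~30-s-σ Gaussian perturbs the peak by < 0.5%).
Everything is reproducible byte-for-byte from the scenario seed.

The 26-event fixture contains 24 faithful events plus two whose scalp
pulse is time-reversed about the event time and shifted 40 s later —
still a cleanly fittable pulse, but temporally mismatched with its
ECoG partner, driving the CoD far below the 0.80 threshold.

What the generator does **not** emulate: pulse asymmetry, propagation
across the array (the scalp footprint appears and dissipates in place),
EEG-band suppression, spatially correlated noise, electrode-gel drying
drift, or co-registration error between the scalp array and the ECoG
strip. Passing tests therefore demonstrate that the pipeline recovers
its own model family under realistic noise, drift and artifact
conditions — not that it would perform identically on patient data.

Two arithmetic wrinkles in the motivating study conditions are resolved
as follows: a 25-event cluster at a 22.4-min mean interval spans
~8.96 h (the interval is taken as primary); and per-event frequency is
defined as 1/FWHM (≈ 0.014 Hz for these durations) rather than
reproducing separately aggregated frequency figures.

## Numerical choices and degenerate inputs

- EDF encoding uses a symmetric 16-bit digital range (±32767) so 0 µV
  round-trips exactly; default physical range ±3200 µV (quantisation
  step ≈ 0.098 µV), configurable — ECoG-scale exports need a wider
  range, and out-of-range voltages raise a scaling error rather than
  clip. Sub-hertz rates map to one sample per EDF record.
- Fitting requires ≥ 12 unmasked bins; fewer raises. Optimizer failure
  is flagged on the result, never raised.
- CoD requires non-zero variance on both series; it is invariant to
  affine rescaling of either input, so the amplitude scaling affects
  plots and residuals, not the similarity call.
- A singular RBF system (duplicate electrode positions) falls back to a
  minutely regularised solve with a warning; a half-max region touching
  the grid edge is flagged as possibly clipped.
- Screening with no prior history reports the repetition criterion
  "not-applicable" rather than failing it.

## Problem sizes in tests

The test suite and the acceptance script run the full pipeline on
26-event (~9.7 h at 0.125 Hz) and 24-event scenarios — a few hundred
six-parameter fits — plus analytic-identity and property checks; the
whole suite completes in well under a minute on one CPU, the acceptance
script in ~20 s.
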