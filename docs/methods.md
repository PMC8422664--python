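# Methods

## Setting and signal model

Two 9-DoF IMU loggers record at a nominal 100 Hz: one strapped to a
bareback pad over the horse's lumbar spine, one on the rider's
head/helmet. The devices clock independently; a shared push-button sync
pulse, recorded as a binary channel on both, marks one common instant.
Alignment is therefore a single offset (rider clock − horse clock at the
first 0→1 pulse transition); multi-pulse clock-drift correction is out of
scope. Only the first 10 minutes of each session — continuous steady
walking — are analyzed; the analysis window defaults to
[pulse, pulse + 600 s] clipped to the recordings' common span, and a pair
must overlap by at least 60 s to be analyzable.

The analyzed channel is the vertical acceleration ACC_z. A horse walking
drives the rider with a near-periodic vertical impulse train at a cadence
of roughly 90–100 steps per minute, i.e. a fundamental near 1.5 Hz with
harmonics near 3.0 and 4.5 Hz. Content below 1 Hz is dominated by the
(orientation-dependent) gravity projection rather than gait, and is
removed.

## Preprocessing

1. **Resampling.** All channels are linearly interpolated onto a uniform
   grid (`floor((t_end − t_start)·rate) + 1` samples). Linear
   interpolation is robust to log jitter and cannot overshoot;
   quaternions are renormalized after interpolation (adequate at 100 Hz
   where successive orientations are nearly identical — no slerp).
   In the session pipeline both recordings are resampled onto the *same*
   grid anchored at the analysis-window start, after shifting rider
   timestamps by −sync_offset onto the horse clock, so correlation sees
   two series on identical time stamps.
2. **Vertical extraction.** Default `sensor_z`: the third accelerometer
   component, the convention used for this sensor placement. `world_z`
   rotates each sample into the world frame via the orientation
   quaternion (sensor→world, (w, x, y, z) order) — useful when a
   head-mounted sensor tilts, but it requires a logged orientation, which
   is optional in the format.
3. **Baseline removal.** A 4th-order zero-phase (forward–backward)
   Butterworth high-pass, default cutoff 1.0 Hz, then exact mean
   subtraction. Cutoff 0 means mean subtraction only. Removing the sub-1 Hz
   band in the time domain keeps the correlation and spectral metric
   families consistent: both see the same gait-band content. Note the
   forward–backward pass squares the magnitude response, so a 1.5 Hz tone
   retains ≈96% of its amplitude at the default cutoff.
4. **Cropping.** Windows are half-open [start, end) on absolute session
   time; cropping never re-zeroes phase between horse and rider. Cropping
   a baseline-removed signal re-subtracts the (tiny) window mean so the
   zero-mean contract survives; Pearson correlation demeans per overlap,
   so this is metrically neutral.

## Interaction metrics

**Lagged correlation.** r(τ) is the Pearson correlation of ref(t) with
target(t + τ) over the overlapping samples only, for every sample lag in
[−2 s, +2 s]. Overlap-only normalization (rather than zero padding) avoids
biasing |r| downward at large lags, which would distort the argmax. The
default ±2 s window is generous against sub-second physiological lags
while excluding whole-stride aliases. Two implementations — an
FFT/prefix-sum path and a direct sliced path — agree to machine precision
and are tested against a scalar double-loop oracle. Degenerate overlaps
(zero variance, e.g. constant segments) define r = 0, and values are
clipped to [−1, 1] against rounding. The maximum and its lag are reported;
exact ties break to the smallest |lag|, then negative before positive —
for periodic signals the argmax is ambiguous and the physical prior is
minimal transmission delay. Positive lag means the rider lags the horse.
Correlation uses the full 10-minute window rather than averaged
sub-windows: the session phase is stationary by design (steady
figure-of-eight walking), and one long window minimizes estimator
variance.

**Spectra.** Welch PSD with 20 s Hann windows, 50% overlap, per-segment
linear detrend: 0.05 Hz resolution, ample to separate 1.5/3.0/4.5 Hz
while averaging ≈59 segments per 10-minute session.

**Harmonic detection.** Peak candidates are interior local PSD maxima in
the search band (default 1–6 Hz, below which gravity artifacts live and
above which walk harmonics carry no power) that exceed a relative power
floor of 1e-3 of the in-band maximum. The floor exists because taper
sidelobes at ~1e-30 of a peak are still, numerically, local maxima; a
truly absent harmonic must be flagged missing rather than matched to a
sidelobe, while genuine noise peaks (orders of magnitude above the floor)
remain eligible. The fundamental is the highest-power candidate not
within ±30% of twice another candidate of higher-or-equal power — so a
strong second harmonic of a weaker fundamental is not mistaken for the
fundamental. The k-th harmonic is the highest local maximum within ±30%
of k × fundamental; empty windows are flagged missing. Frequencies are
reported at bin centers; a quadratic sub-bin refinement exists
(`refine=True`) but is off by default so reported values correspond
directly to spectral bins.

**Harmonic RMSE.** Root-mean-square difference of corresponding peak
frequencies (Hz), dropping missing pairs with a warning. The statistic is
symmetric and scale-covariant. A variant over peak powers is available
(`rmse_mode="power"`); frequencies are the default because the metric is
read as spatial frequency alignment of the two movement spectra.

## Functional mobility

Records are one timing per (participant, session ∈ {1, 4, 8},
phase ∈ {pre, post}, test ∈ {TUG, 10mWT}). Percent change is
100·(mean₁ − meanₛ)/mean₁ for time-like (decrease-phrased) quantities and
sign-flipped for increase-phrased ones (correlation); the default pools
pre and post within a session (one number per session), with a
`phase=` restriction available — the summary table reports the per-phase
variant alongside. Group variability is the sample (n−1) standard
deviation; it is omitted for single-participant groups. Summary rows are
fully determined by the distinct (test, phase, session) groups present.

## Synthetic generator

The generator defines the study conditions the tests run under:

* **Horse back:** gravity offset (9.81 m/s²) + Σₖ Aₖ sin(2π k f₀ t + φₖ)
  + white noise. Defaults: cadence 90 steps/min (f₀ = 1.5 Hz), three
  harmonics with amplitudes 1.0/0.5/0.25 m/s² (a decaying harmonic stack
  of the kind walk spectra show), noise sd 0.1 m/s², 600 s at 100 Hz,
  sync pulse rising at t = 1 s. Lateral channels carry low-amplitude
  noise only.
* **Rider head:** gain × (baseline-removed horse z delayed by lag) +
  intrinsic sway + white noise + gravity. Sway defaults to 0.2 m/s² at
  0.3 Hz: postural sway is slow, so it sits below the 1 Hz high-pass just
  like the gravity artifact — rider-generated motion that the analysis
  deliberately ignores. The linear gain + pure delay form is the simplest
  structure under which maximum correlation, lag and harmonic RMSE are
  all identifiable; it is a modeling choice, not a biomechanical trunk
  model.
* **Progression schedule** (sessions 1→8): coupling gain 0.4→0.9 and lag
  0.5→0.2 s linearly, rider noise 1.2→0.15 m/s² geometrically, sway
  0.3→0.1 m/s² — a monotone familiarization trend. Functional times are
  log-normal (positive, right-skewed), moment-matched to scheduled
  mean/sd per session: TUG 12.0/9.80/8.70 s (sd 3.5) and 10mWT
  30.0/19.02/18.87 s (sd 3.0) for sessions 1/4/8, declining in the same
  proportions as the real-data trends this structure emulates.
* All generators are pure functions of (config, seed); per-session and
  per-participant child seeds derive from one root seed via
  `SeedSequence` spawn keys.

What passing tests do and do not show: the generator produces stationary,
strictly periodic gait with additive Gaussian noise and a constant pure
delay. Real sessions have cadence drift, turns in the figure-of-eight
pattern, non-stationary rider behavior, sensor mounting wobble and
possible log corruption. Parameter-recovery results therefore validate
the *estimators* (unbiasedness, resolution, monotone trend recovery),
not robustness to every field artifact.

## Numerical and policy choices

* Sample-lag grid: lag resolution equals the sample period (0.01 s);
  recovered lags are quantized accordingly.
* Rows with non-numeric required fields are dropped and counted; logs of
  ≥20 rows error when more than 5% drop (silent tolerance for occasional
  corruption, loud failure for systematic loss). Fewer than two valid
  rows is always an error.
* Accelerometer units default to g (Razor-class loggers) with a
  `m/s2` option; conversion uses standard gravity 9.80665.
* Quaternion norms are validated to 1e-6; CSV round-trips write 10
  significant digits so channels survive to 1e-6.
* Welch requires at least two windows of signal; harmonic search
  requires the band's lower edge at or above the spectral resolution.
* Percent change is undefined for a zero baseline mean (the pipeline
  report skips such metrics with a warning — e.g. harmonic RMSE exactly 0
  across clean synthetic sessions).
* Test-suite simulations use 80–120 s sessions; the acceptance script
  runs the full 600 s default.

## Known limitations

* No orientation estimation from gyro+acc: `world_z` consumes a logged
  quaternion channel, it does not compute one.
* No time-varying synchronization measure (windowed correlation,
  coherence, phase locking) and no anterior-posterior / medio-lateral
  axes — the vertical axis only.
* Single-pulse sync cannot correct clock drift within a session.
* The walk-halt-walk second half of a session is not modeled or
  analyzed.
* Harmonic RMSE at bin resolution is exactly 0 whenever both spectra
  peak in the same 0.05 Hz bins, which clean synthetic data usually do;
  it becomes informative at low SNR or with `refine=True`.
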