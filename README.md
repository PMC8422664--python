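# equisync

Quantifying how a mounted rider's movement synchronizes to a horse's gait
from paired inertial sensors, for rehabilitation research in physical
therapy that incorporates equine movement (hippotherapy). The intended
users are movement scientists and therapists who record a horse-back and a
rider-head IMU during riding sessions and want per-session synchronization
metrics plus trends in functional-mobility tests (Timed Up and Go, 10 m
Walk Test) across a treatment series.

## What it computes

The analyzed channel is the vertical acceleration **ACC<sub>z</sub>** of
each sensor — acceleration is an interaction force normalized by body
mass, so ACC<sub>z</sub> carries the vertical impulse the horse imparts to
the rider. The horse-back signal *x(t)* is the reference; the rider-head
signal *y(t)* is modeled as responding to it. Per session, over the first
10 minutes of continuous riding:

* **Lagged cross-correlation.** For each lag τ on the sample grid in
  [−τ<sub>max</sub>, +τ<sub>max</sub>],

  r(τ) = corr( x(t), y(t + τ) ),

  a Pearson correlation over the overlapping samples only (no zero
  padding). Reported are max<sub>τ</sub> r(τ) and the lag
  τ* = argmax<sub>τ</sub> r(τ); positive τ* means the rider's head lags
  the horse's back. Higher maximum correlation and smaller lag read as
  *temporal* synchronization.

* **Gait harmonics and their RMSE.** Welch power spectral densities
  (20 s Hann windows, 50% overlap, per-segment linear detrend) of both
  signals; content below 1 Hz is excluded as a gravity artifact. At a walk
  the cadence is ≈90 steps/min, so dominant peaks sit near 1.5, 3.0 and
  4.5 Hz. The K = 3 dominant harmonic peak frequencies f<sub>k</sub> are
  detected in the 1–6 Hz band and compared:

  RMSE = √( (1/K) Σ<sub>k</sub> (f<sub>k</sub><sup>rider</sup> − f<sub>k</sub><sup>horse</sup>)² ).

  Smaller harmonic RMSE reads as *spatial* synchronization.

* **Functional mobility.** TUG / 10mWT times recorded pre and post
  session on test days 1, 4 and 8: group means, sample standard
  deviations, and percent change of sessions 4 and 8 against session 1.
  No hypothesis tests — these are small-sample descriptive trends.

A synthetic generator produces coupled horse–rider session pairs (harmonic
horse-back signal; rider = gain × delayed horse + postural sway + noise)
with known ground truth, so every metric is validated by parameter
recovery.

## Worked example

```python
import equisync as eq

cfg = eq.SimulateConfig(
    participants=(("P1", "TUG"),),
    progression=eq.ProgressionConfig(sessions=(1, 4, 8),
                                     horse=eq.HorseGaitConfig(duration_s=120.0)),
    seed=42)
eq.run_simulate(cfg, "demo_data")
res = eq.run_analyze("demo_data/manifest.yaml", "demo_data/functional.csv",
                     "demo_out", seed=42)
print(res.metrics[["participant", "session", "max_corr", "lag_s", "rmse_freq_hz"]]
      .to_string(index=False))
```

prints

```
participant  session  max_corr  lag_s  rmse_freq_hz
         P1        1  0.269626   0.50           0.0
         P1        4  0.715906   0.37           0.0
         P1        8  0.978480   0.20           0.0
```

The simulated participant follows the default familiarization schedule
(coupling gain 0.4 → 0.9, transmission lag 0.5 → 0.2 s, noise falling),
and the pipeline recovers it: maximum correlation rises from 0.27 to 0.98
while the estimated lag tracks the injected 0.50 / 0.37 / 0.20 s. The
harmonic RMSE is 0 Hz here because the clean coupled rider shares the
horse's peak frequencies exactly at this signal-to-noise ratio.
`res.report` adds the percent-change view, e.g. `max_corr … session 8:
+262.9%`, `lag_s … session 8: −60.0%`, mirroring how session trends are
reported for real data.

The same thing from a shell:

```bash
equisync simulate --config sim.yaml --out demo_data
equisync analyze --manifest demo_data/manifest.yaml \
                 --functional demo_data/functional.csv --out demo_out
```

Real datasets use the identical layout: one CSV per sensor (columns `t,
ax, ay, az[, gx, gy, gz, qw, qx, qy, qz, sync]`, accelerations in g by
default), a YAML manifest listing `{participant, session, horse_log,
rider_log}`, and a functional-test CSV.

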