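# gaitar

Autoregressive modelling of gait-pattern dynamics from vertical ground
reaction force (vGRF) recordings.

## The problem

Gait asymmetry — each leg loading the ground differently — is common in
people with impaired neuromuscular control, and a key question in gait
analysis is which metrics are sensitive enough to detect it. Comparing mean
vGRF peak magnitudes across walking conditions often shows nothing, because
asymmetry changes the *dynamics* of limb loading from step to step more than
its average. `gaitar` implements an analysis that captures those dynamics:

1. extract the impact (weight-acceptance) and propulsive stance peaks from
   each step of a walking vGRF signal (35 Hz zero-phase 4th-order
   Butterworth filter, body-weight normalization, 50 N heel-strike
   threshold) and interleave them into one peak time series per limb;
2. fit a second-order autoregressive model to the demeaned series,

   yₜ = δ + φ₁ yₜ₋₁ + φ₂ yₜ₋₂ + εₜ,

   by conditional least squares, with Box–Jenkins order identification
   (ACF/PACF) and Anderson–Darling residual-normality checks;
3. place (φ₁, φ₂) on the AR(2) **stationarity triangle** — the region with
   vertices (−2, −1), (2, −1), (0, 1) inside which both characteristic roots
   of m² − φ₁m − φ₂ = 0 have modulus < 1 — and quantify gait-pattern
   stability as the Euclidean **distance from the triangle centroid
   (0, −1/3)**: points near the edge are nearly non-stationary, i.e. less
   stable gait dynamics;
4. compare conditions (one-way ANOVA + Tukey HSD with compact letter
   displays) on two per-participant metrics: mean peak vGRF and the AR
   centroid distance.

A seeded synthetic split-belt treadmill generator (double-hump stance
templates, speed-dependent cadence and peak magnitudes, known AR(2)
step-to-step fluctuations, sensor noise, between-limb belt-speed asymmetry)
provides ground truth for every stage, so the whole pipeline is testable
without human data. It is aimed at biomechanics/rehabilitation researchers
who want a reproducible, scriptable implementation of the stationarity-
triangle gait analysis.

## Worked example

```python
import gaitar as g

# one limb, one minute of symmetric 1.0 m/s walking, 5 N sensor noise
cond = g.GaitCondition("sym_1.00", 1.0, 1.0, 60.0)
rec, truth = g.simulate_walking_trial(cond, g.SimulationParams(sensor_noise_sd=5.0),
                                      "left", seed=21)
series, qc = g.process_recording(rec, limb="left", condition="sym_1.00")
fit = g.fit_ar(series.values, order=2)
point = g.classify(fit.phi1, fit.phi2)
print(qc.as_dict())
print(round(fit.phi1, 3), round(fit.phi2, 3), round(point.distance, 3), point.inside)
```

prints

```
{'stances_detected': 108, 'peak_pairs_extracted': 108, 'stances_dropped': 0, 'lead_in_pairs_skipped': 10}
0.602 -0.203 0.616 True
```

108 stances detected in 60 s at cadence 1.8/s; after skipping the 10-stride
lead-in, the 196-value interleaved peak series yields AR(2) coefficients
(0.60, −0.20) — inside the triangle (stationary gait pattern) at distance
0.62 from the centroid, typical of stable symmetric walking. The
`examples/` directory has one short narrative script per capability
(simulation, peak extraction, AR fitting + triangle, group comparison, full
pipeline); each prints the numbers it computes and what they mean. A thin
CLI mirrors the pipeline stages: `gaitar run --config cfg.yaml`, plus
`simulate`, `extract-peaks`, `fit-ar`, `triangle`, `compare`.

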