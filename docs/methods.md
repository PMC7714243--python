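# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `gaitar`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The AR(2) stability analysis

The analysed series is the interleaved vGRF peak sequence of one limb in one
walking condition: two values per step (impact peak, then propulsive peak),
in body-weight (BW) units, in chronological order. The model is

y_t = δ + φ1 y_{t−1} + φ2 y_{t−2} + ε_t,  ε_t ~ WN(0, σ²).

The series is demeaned first, which makes δ = 0 by construction (δ is still
reported as μ(1 − φ1 − φ2)). Coefficients are estimated by **conditional
least squares**: regression of y_t on (y_{t−1}, y_{t−2}) without intercept,
minimising the conditional sum of squared one-step errors. CLS is the
canonical Box–Jenkins conditional method, reproducible without optimizer
choices; a Yule–Walker option (`method="yule_walker"`, via statsmodels) is
provided and agrees with CLS to ~0.01 at the series lengths used here.
σ² = RSS/(n_eff − p) with n_eff = n − p.

Order identification follows the PACF cut-off rule: the recommended order is
the largest lag whose sample PACF exceeds ±1.96/√n (order 0 for white
noise — when no lag exceeds the bound, the selection record notes it). The
ACF uses the biased (divide-by-n) estimator, the standard convention that
guarantees a positive semi-definite correlation sequence for the
Durbin–Levinson recursion used to compute the PACF.

Model adequacy is checked on the one-step residuals with the composite
Anderson–Darling normality test (mean and variance estimated): the raw A² is
adjusted by (1 + 4/n − 25/n²) and compared with the 0.752 critical value at
α = 0.05. R² is deliberately not computed: with serially correlated model
errors it is not an appropriate fit measure, so residual diagnostics are
used instead.

Stability is summarised geometrically. The characteristic polynomial
m² − φ1 m − φ2 has roots m = (φ1 ± √(φ1² + 4φ2))/2; the process is
stationary iff both moduli are < 1, equivalently iff (φ1, φ2) lies strictly
inside the triangle with vertices (−2, −1), (2, −1), (0, 1). The scalar
stability statistic is the Euclidean distance from the triangle centroid
(0, −1/3). Euclidean distance in the (φ1, φ2) plane is the natural reading
of "distance from the centroid" and is what this package implements.
Strict inequalities define membership (a unit root is not stationary);
points whose smallest edge margin is within 1e−9 are flagged `boundary` and
reported not-inside. The membership/root-modulus equivalence is verified on
a 101×101 grid over [−2.5, 2.5] × [−1.5, 1.5]; grid points that fall exactly
on an edge (the grid does contain some) carry a root of modulus exactly 1,
where floating-point root finding is not sign-stable, so the equivalence is
asserted strictly off the boundary band and edge points are asserted to be
boundary-flagged with |m|max ≈ 1.

## Group comparison

Per participant × limb × condition the two metrics are the mean of the
interleaved peak series (mean peak vGRF, BW) and the AR centroid distance.
Conditions are compared per limb within two families — the three symmetric
speeds, and symmetric 1.0 m/s versus the two asymmetric conditions — by
one-way fixed-effects ANOVA (F = MS_between/MS_within) and Tukey HSD
(Tukey–Kramer q with the studentized range distribution at (k, df_within)),
summarised with compact letter displays: letters are the maximal cliques of
the non-significant-pair graph, ordered by descending group mean, so groups
share a letter iff they are not significantly different. Display tables
round mean (sd) to one decimal.

Participants appear in every condition but are treated as independent
observations per condition (one-way layout). This ignores the
repeated-measures correlation; the comparison report carries a note to that
effect. For equal group means the positive between-participant correlation
makes the one-way F conservative, which the type-I calibration checks
reflect.

## The synthetic split-belt generator

The generator emulates an instrumented split-belt treadmill protocol: five
one-minute conditions — symmetric walking at 0.75, 1.0, 1.5 m/s, and two
asymmetric conditions with between-limb speed differences of 0.25 m/s
(L 0.75 / R 1.0) and 0.50 m/s (L 1.5 / R 1.0). Optional symmetric 0.75 m/s
de-adaptation segments can be inserted after each asymmetric condition; they
are simulated but excluded from analysis (their purpose is wash-out, not
measurement). Speed changes between segments are instantaneous.

Per limb the signal is a train of stance-phase templates:

* **Stance template** — a C¹ monotone piecewise-cubic (PCHIP) double hump
  through (0, 0) → (0.25, impact) → (0.5, valley) → (0.75, propulsive) →
  (1, 0) on normalized stance time. PCHIP makes the anchor points exact
  local extrema with nothing in between, so the template is brute-force
  verifiable. Anchor fractions are snapped to the sample grid, so true peak
  values appear exactly in the sampled noise-free signal.
* **Cadence** — `cadence_model(speed)` is the per-limb stance rate:
  1.6 / 1.8 / 2.0 stances per second at 0.75 / 1.0 / 1.5 m/s (piecewise
  linear, monotone). Stance occupies `duty_factor` = 0.62 of each stance
  interval; swing is exactly 0 N. These rates are configurable stand-ins —
  the generator's convention, not measured values.
* **Peak magnitudes** — `peak_model(speed)` gives mean (impact, propulsive)
  peaks of 1.0 / 1.1 / 1.2 BW at the three speeds, equal for the two peak
  types. Equal magnitudes make the interleaved multiplicative fluctuation
  series an exact scaled AR(2) process after demeaning, so parameter
  recovery through the full chain is well-posed. Group-mean calibration
  (~1.0 BW at 0.75 m/s, ~1.2 BW at 1.5 m/s) matches normalized walking
  vGRF magnitudes.
* **Step-to-step fluctuations** — one interleaved AR(2) multiplier series
  per limb (mean 1, innovation sd 0.02, burn-in ≥ 200 discarded,
  coefficients validated strictly inside the triangle at construction),
  applied multiplicatively to both peaks.
* **Sensor noise** — additive white Gaussian noise (default 2 N) on the full
  record, then clipping at 0 N (plates report non-negative vertical force).
* **Seeding** — a master `SeedSequence` spawns one child per condition, one
  grandchild per limb, then separate (fluctuation, noise) streams, so any
  sub-simulation is independently and bit-identically re-runnable.

Study-level simulation adds participant variation: body weight ~ N(71.6,
10.9) kg × g (clipped to 45–110 kg), a shared peak-magnitude scale
1 + |N(0, 0.04)| (keeping peaks ≥ 1 BW and monotone in speed), and
per-condition AR truth jittered per participant (sd 0.15 on φ1, 0.10 on φ2,
rejection-sampled to stay inside the triangle with margin 0.05). The default
condition truths put φ2 = −1/3 so centroid distance equals φ1: 0.60 / 0.65 /
0.70 for the symmetric speeds, 0.55 for the 0.25 m/s asymmetry (a slightly
more constrained, more stable pattern) and 0.85 for the destabilising
0.50 m/s asymmetry. With the fit noise at ~200-value series these choices
give fitted-distance spreads of ~0.2 and a between-condition contrast of
~0.3 — the magnitudes the analysis is designed to resolve. Because the held
(right) limb walks at 1.0 m/s in all three asymmetric-family conditions, its
mean peak is equal across that family by construction: the generator
reproduces the situation where the AR statistic discriminates and the mean
does not.

A **fast path** (`simulate_study_peak_table`) emits the same participant
draws and true peak series in the pipeline's output schema without
synthesising the 1200 Hz waveform; it shares seed substreams with the signal
path and agrees with it to the filter/extraction error (~5e−3 in fitted φ).
Replicate-level analyses (power, type-I calibration; 200 replicates) use the
fast path; the full signal chain is exercised end to end in the single-study
runs and the fidelity checks. Problem sizes throughout (60 s conditions,
17 participants, 200 replicates, n = 110 recovery studies) are the package's
chosen study scale.

### What the generator does not emulate

Real stance waveforms vary in shape within and between people; templates
here vary only in peak magnitude. There are no crossover steps, no gait
adaptation dynamics within a condition, no drift in cadence, no
anterior–posterior/medio-lateral forces, and the per-limb stance rate
convention (stances/s equal to `cadence_model`) is a simulation convention
rather than measured walking cadence. Passing tests therefore demonstrate
correctness of the *analysis chain* under known dynamics, not robustness to
every feature of real treadmill data.

## Signal processing choices

* **Filter** — 4th-order Butterworth low-pass at 35 Hz, applied zero-phase
  (forward–backward, `sosfiltfilt`), the biomechanics convention: no peak
  lag, effective attenuation is the squared single-pass response. The
  smooth stance template's content is almost entirely below ~15 Hz, so the
  filter's passband effect on true peaks is ~1e−4 BW; exact-fidelity checks
  against ground truth therefore run the chain with `cutoff=None`, and the
  filter's own contract is verified analytically from its designed response.
  The 50 N rule is applied to the filtered signal.
* **Stance detection** — heel strike = first sample at/above 50 N after a
  below-threshold gap; toe off = last sample at/above before the next gap.
  Intervals separated by gaps < 0.1 s are merged (debounce against
  noise-induced double crossings near threshold), intervals shorter than
  0.2 s or longer than 2 s are dropped, and stances touching the recording
  boundaries are incomplete and discarded. The threshold is specified in
  newtons and rescaled by body weight when the recording is already
  normalized, so detection is invariant to processing order.
* **Peak rule** — impact peak = highest interior local maximum in the first
  half of the stance; propulsive = highest in the second half. Halves are
  the simplest unambiguous split and are verifiable on templates; stances
  lacking an interior maximum in either half (e.g. monotone artefacts) are
  dropped and counted in the QC report, never silently.
* **Lead-in** — the first 10 strides of every condition are skipped in
  software (`skip_strides`), applying the same convention to synthetic and
  real recordings; at least 2 pairs must remain.
* **Interleaving** — one series per limb containing both peak types
  (strictly alternating, impact first). Separate impact-only/propulsive-only
  analyses are possible by filtering the peaks table on `peak_type` before
  fitting.

## Numerical details and degenerate inputs

Constant series are rejected wherever variance is required (ACF, AR fit,
Anderson–Darling). AR fitting needs n ≥ order + 10. Characteristic roots are
computed from the quadratic formula with an explicit complex branch; the
root–coefficient duality (m1 + m2 = φ1, −m1·m2 = φ2) holds to 1e−9 and the
characteristic-equation residual to 1e−10. The studentized range quantile
comes from `scipy.stats.studentized_range` (q(0.05; 3, 15) = 3.673 to 1e−3).
Triangle SVG rendering pins the matplotlib hash salt and suppresses date
metadata so identical input yields byte-identical output.

## Known limitations

* The one-way ANOVA ignores repeated measures (see above).
* The AR model is fit per condition-minute (~200 values); the method is
  designed for such short series, but estimates carry sampling noise of
  ~0.07–0.1 per coefficient at that length, which the group analysis
  absorbs into between-participant spread.
* The supplementary-workbook reader recognises peak-level and summary-level
  layouts by header sniffing; other layouts raise a schema error showing the
  detected headers rather than guessing.
* Only vertical forces are modelled and analysed.
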