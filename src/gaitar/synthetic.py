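"""Seeded synthetic split-belt walking generator with known ground truth.

Emulates an instrumented split-belt treadmill protocol: each limb produces a
train of double-hump stance-phase vertical-GRF waveforms at a speed-dependent
cadence, with step-to-step peak magnitudes fluctuating multiplicatively around
speed-dependent means according to a known stationary AR(2) process, plus
additive sensor noise. Because the true peak values, event times and AR
coefficients are returned alongside the signal, every downstream stage
(filtering, stance detection, peak extraction, AR fitting, triangle analysis)
can be validated against ground truth without any recorded human data.

Conventions
-----------
* ``cadence_model(speed)`` is the per-limb stance rate (stance phases per
  second for that limb); a 60 s condition at cadence 1.8 yields 108 stances.
* ``peak_model(speed)`` returns the mean (impact, propulsive) peak magnitudes
  in body weights (BW); both are >= 1 BW and strictly increasing in speed.
* Peak fluctuations are one interleaved AR(2) multiplier series per limb
  (impact, propulsive, impact, ...; mean 1), so the series a peak extractor
  reconstructs genuinely carries the AR(2) structure used to generate it.
* Swing-phase force is exactly 0 N before sensor noise; the noisy signal is
  clipped at 0 N (force plates report non-negative vertical force).
* Reproducibility: a master seed is expanded with numpy ``SeedSequence``
  spawning — one child per protocol condition, then one grandchild per limb,
  then (peak-fluctuation, sensor-noise) streams — so any sub-simulation can be
  re-run independently and bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import lfilter

from .recording import GRFRecording
from .triangle import StationarityError, is_stationary

PROTOCOL_SPEEDS = (0.75, 1.0, 1.5)


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _piecewise_linear(knots_x: Sequence[float], knots_y: Sequence[float]) -> Callable[[float], float]:
    """Monotone piecewise-linear map through knots, linearly extrapolated."""
    kx = np.asarray(knots_x, dtype=float)
    ky = np.asarray(knots_y, dtype=float)

    def f(v: float) -> float:
        if v <= kx[0]:
            slope = (ky[1] - ky[0]) / (kx[1] - kx[0])
            return float(ky[0] + slope * (v - kx[0]))
        if v >= kx[-1]:
            slope = (ky[-1] - ky[-2]) / (kx[-1] - kx[-2])
            return float(ky[-1] + slope * (v - kx[-1]))
        return float(np.interp(v, kx, ky))

    return f


#: Default per-limb stance rate (stances/s) at 0.75 / 1.0 / 1.5 m/s.
default_cadence = _piecewise_linear(PROTOCOL_SPEEDS, (1.6, 1.8, 2.0))

_default_peak = _piecewise_linear(PROTOCOL_SPEEDS, (1.0, 1.1, 1.2))


def default_peak_model(speed: float) -> tuple[float, float]:
    """Mean (impact, propulsive) stance peaks in BW; equal by default.

    Calibrated so group-mean peaks are ~1.0 BW at 0.75 m/s, ~1.1 at 1.0 and
    ~1.2 at 1.5 m/s, as observed for normalized walking vGRF. Equal impact and
    propulsive magnitudes make the interleaved fluctuation series an exact
    (scaled) AR(2) process, so AR parameter recovery is well-posed.
    """
    p = _default_peak(speed)
    return (p, p)


@dataclass
class SimulationParams:
    """Generator configuration for one simulated participant.

    Parameters
    ----------
    sampling_rate : Hz, treadmill force sampling (default 1200).
    body_weight : newtons.
    cadence_model : speed (m/s) -> per-limb stance rate (1/s), increasing.
    duty_factor : stance fraction of the step period, in (0, 1).
    peak_model : speed -> (mean impact, mean propulsive) peak, BW, increasing.
    ar_coeffs : (φ1, φ2) of the step-to-step peak fluctuation process; must
        lie strictly inside the stationarity triangle.
    fluctuation_sd : innovation SD of the AR(2) multiplier series
        (dimensionless, i.e. BW per BW of mean peak).
    sensor_noise_sd : additive white sensor noise, newtons.
    timing : (t_peak1, t_valley, t_peak2) as fractions of stance.
    valley_ratio : mid-stance valley as a fraction of the smaller peak.
    """

    sampling_rate: float = 1200.0
    body_weight: float = 702.4  # 71.6 kg * 9.81 m/s^2
    cadence_model: Callable[[float], float] = field(default=default_cadence)
    duty_factor: float = 0.62
    peak_model: Callable[[float], tuple[float, float]] = field(default=default_peak_model)
    ar_coeffs: tuple[float, float] = (0.6, -0.2)
    fluctuation_sd: float = 0.02
    sensor_noise_sd: float = 2.0
    timing: tuple[float, float, float] = (0.25, 0.5, 0.75)
    valley_ratio: float = 0.7

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * 35.0:
            raise ValueError("sampling_rate must exceed twice the 35 Hz filter cutoff")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")
        if not 0.0 < self.duty_factor < 1.0:
            raise ValueError("duty_factor must be in (0, 1)")
        if not 0.0 < self.valley_ratio < 1.0:
            raise ValueError("valley_ratio must be in (0, 1)")
        t1, tv, t2 = self.timing
        if not 0.0 < t1 < tv < t2 < 1.0:
            raise ValueError("timing fractions must satisfy 0 < t_peak1 < t_valley < t_peak2 < 1")
        if self.fluctuation_sd < 0 or self.sensor_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        member = is_stationary(*self.ar_coeffs)
        if not member.inside:
            raise StationarityError(
                f"ar_coeffs {self.ar_coeffs} lie outside the AR(2) stationarity triangle")
        peaks = [self.peak_model(v) for v in PROTOCOL_SPEEDS]
        means = [0.5 * (p[0] + p[1]) for p in peaks]
        if min(min(p) for p in peaks) < 1.0 - 1e-9:
            raise ValueError("peak_model must be >= 1.0 BW at all protocol speeds")
        if not all(b > a for a, b in zip(means, means[1:])):
            raise ValueError("peak_model must be strictly increasing in speed")
        cad = [self.cadence_model(v) for v in PROTOCOL_SPEEDS]
        if not all(b > a for a, b in zip(cad, cad[1:])):
            raise ValueError("cadence_model must be strictly increasing in speed")


@dataclass(frozen=True)
class GaitCondition:
    """One protocol segment: belt speeds per limb, duration and label."""

    label: str
    left_speed: float
    right_speed: float
    duration: float = 60.0
    analysis: bool = True  # de-adaptation segments are simulated but not analysed

    def __post_init__(self) -> None:
        if self.left_speed <= 0 or self.right_speed <= 0:
            raise ValueError("belt speeds must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def speed(self, limb: str) -> float:
        return self.left_speed if limb == "left" else self.right_speed


@dataclass(frozen=True)
class GaitProtocol:
    """Ordered list of uniquely labelled walking conditions."""

    conditions: tuple[GaitCondition, ...]

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        if not labels:
            raise ValueError("protocol must contain at least one condition")

    def __iter__(self):
        return iter(self.conditions)

    def __len__(self) -> int:
        return len(self.conditions)

    def analysis_labels(self) -> list[str]:
        return [c.label for c in self.conditions if c.analysis]


def default_protocol(duration: float = 60.0,
                     include_deadaptation: bool = False) -> GaitProtocol:
    """The five analysed walking conditions: three symmetric speeds plus
    between-limb differences of 0.25 m/s (L 0.75 / R 1.0) and 0.50 m/s
    (L 1.5 / R 1.0), one minute each.

    With ``include_deadaptation`` a symmetric 0.75 m/s wash-out segment is
    inserted after each asymmetric condition (simulated, excluded from
    analysis).
    """
    conds = [
        GaitCondition("sym_0.75", 0.75, 0.75, duration),
        GaitCondition("sym_1.00", 1.0, 1.0, duration),
        GaitCondition("sym_1.50", 1.5, 1.5, duration),
        GaitCondition("asym_0.25", 0.75, 1.0, duration),
        GaitCondition("asym_0.50", 1.5, 1.0, duration),
    ]
    if include_deadaptation:
        out = conds[:3]
        for i, c in enumerate(conds[3:], start=1):
            out.append(c)
            out.append(GaitCondition(f"deadapt_{i}", 0.75, 0.75, duration, analysis=False))
        conds = out
    return GaitProtocol(tuple(conds))


def simulate_ar2_series(phi1: float, phi2: float, n: int, noise_sd: float,
                        mean: float = 0.0, seed=None,
                        rng: np.random.Generator | None = None,
                        burn_in: int = 500) -> np.ndarray:
    """Simulate a stationary AR(2) series of length ``n`` with given mean.

    y_t = δ + φ1 y_{t−1} + φ2 y_{t−2} + ε_t with ε_t ~ N(0, noise_sd²) and
    δ = mean·(1 − φ1 − φ2) so the process mean equals ``mean``. The recursion
    starts from zeros and a burn-in (>= 200 samples) is discarded; identical
    seeds give identical output.
    """
    member = is_stationary(phi1, phi2)
    if not member.inside:
        raise StationarityError(
            f"(phi1, phi2) = ({phi1}, {phi2}) is outside the stationarity triangle")
    if n < 3:
        raise ValueError("n must be >= 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if burn_in < 200:
        raise ValueError("burn_in must be >= 200")
    if rng is None:
        rng = np.random.default_rng(_seedseq(seed))
    eps = rng.normal(0.0, noise_sd, size=n + burn_in) if noise_sd > 0 else np.zeros(n + burn_in)
    # AR recursion as an IIR filter with zero initial conditions
    x = lfilter([1.0], [1.0, -phi1, -phi2], eps)
    return x[burn_in:] + mean


def stance_waveform(t_norm, impact_peak: float, propulsive_peak: float,
                    valley: float,
                    timing: tuple[float, float, float] = (0.25, 0.5, 0.75)):
    """Smooth double-hump stance-phase vGRF template on normalized time [0, 1].

    A C¹ monotone piecewise-cubic (PCHIP) through the anchor points
    (0, 0) → (t_peak1, impact) → (t_valley, valley) → (t_peak2, propulsive)
    → (1, 0). The curve is zero at both stance boundaries, attains exactly the
    requested peak values at the requested fractions, and has exactly one
    local minimum between the two peaks.
    """
    t1, tv, t2 = timing
    if not 0.0 < t1 < tv < t2 < 1.0:
        raise ValueError("timing fractions must satisfy 0 < t_peak1 < t_valley < t_peak2 < 1")
    if not (impact_peak > valley and propulsive_peak > valley and valley > 0):
        raise ValueError("need peaks > valley > 0")
    interp = PchipInterpolator([0.0, t1, tv, t2, 1.0],
                               [0.0, impact_peak, valley, propulsive_peak, 0.0])
    t = np.asarray(t_norm, dtype=float)
    if np.any(t < 0.0) or np.any(t > 1.0):
        raise ValueError("t_norm must lie in [0, 1]")
    out = interp(t)
    return float(out) if np.isscalar(t_norm) else out


def _snap_timing(timing: tuple[float, float, float], n_st: int) -> tuple[int, int, int]:
    """Snap template anchor fractions to the stance sample grid."""
    idx = tuple(int(round(t * (n_st - 1))) for t in timing)
    if not 0 < idx[0] < idx[1] < idx[2] < n_st - 1:
        raise ValueError("stance too short to resolve the peak/valley anchors")
    return idx


def simulate_walking_trial(condition: GaitCondition, params: SimulationParams,
                           limb: str, seed=None) -> tuple[GRFRecording, pd.DataFrame]:
    """Simulate one limb's vGRF for one condition; return signal + ground truth.

    The waveform is a train of stance templates at the limb's cadence, each
    scaled by that step's AR(2) peak multipliers, with swing phases at 0 N,
    additive sensor noise, and clipping at 0 N. Peak anchor fractions are
    snapped to the sample grid so true peak values appear exactly in the
    sampled (noise-free) signal.

    Returns ``(recording, truth)`` where ``truth`` has columns
    ``limb, step_index, event_time, peak_type, peak_value_bw``.
    """
    if limb not in ("left", "right"):
        raise ValueError("limb must be 'left' or 'right'")
    speed = condition.speed(limb)
    cadence = params.cadence_model(speed)
    step_period = 1.0 / cadence
    n_steps = int(np.floor(condition.duration * cadence + 1e-9))
    if n_steps < 5:
        raise ValueError(
            f"condition duration {condition.duration}s gives only {n_steps} stances "
            f"at cadence {cadence:.2f}/s; need at least 5")
    fs = params.sampling_rate
    n_samples = int(round(condition.duration * fs))

    ss = _seedseq(seed)
    rng_peaks, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    phi1, phi2 = params.ar_coeffs
    mult = simulate_ar2_series(phi1, phi2, 2 * n_steps, params.fluctuation_sd,
                               mean=1.0, rng=rng_peaks)
    base_imp, base_prop = params.peak_model(speed)

    force = np.zeros(n_samples)
    rows = []
    for k in range(n_steps):
        start = int(round(k * step_period * fs))
        n_st = int(round(params.duty_factor * step_period * fs))
        i1, iv, i2 = _snap_timing(params.timing, n_st)
        imp = base_imp * mult[2 * k]
        prop = base_prop * mult[2 * k + 1]
        valley = params.valley_ratio * min(imp, prop)
        grid = np.arange(n_st) / (n_st - 1)
        knots = np.array([0, i1, iv, i2, n_st - 1]) / (n_st - 1)
        curve = PchipInterpolator(knots, [0.0, imp, valley, prop, 0.0])(grid)
        end = min(start + n_st, n_samples)
        force[start:end] = curve[: end - start] * params.body_weight
        rows.append((limb, k, (start + i1) / fs, "impact", imp))
        rows.append((limb, k, (start + i2) / fs, "propulsive", prop))

    if params.sensor_noise_sd > 0:
        force = force + rng_noise.normal(0.0, params.sensor_noise_sd, size=n_samples)
    np.clip(force, 0.0, None, out=force)

    rec = GRFRecording(
        time=np.arange(n_samples) / fs,
        force_left=force if limb == "left" else None,
        force_right=force if limb == "right" else None,
        sampling_rate=fs,
        body_weight=params.body_weight,
        units="N",
        metadata={"condition": condition.label, "limb": limb, "speed_mps": speed,
                  "cadence_hz": cadence, "n_steps": n_steps},
    )
    truth = pd.DataFrame(rows, columns=["limb", "step_index", "event_time",
                                        "peak_type", "peak_value_bw"])
    return rec, truth


def simulate_protocol(protocol: GaitProtocol, params: SimulationParams, seed=None,
                      condition_overrides: dict[str, dict] | None = None,
                      ) -> tuple[GRFRecording, pd.DataFrame]:
    """Simulate a full protocol for both limbs with independent noise streams.

    ``condition_overrides`` maps condition labels to ``SimulationParams`` field
    replacements (e.g. per-condition ``ar_coeffs``). Per-condition segment
    boundaries are recorded in the recording metadata; the returned truth
    table gains a ``condition`` column and absolute event times.
    """
    overrides = condition_overrides or {}
    unknown = set(overrides) - {c.label for c in protocol}
    if unknown:
        raise ValueError(f"condition_overrides for unknown labels: {sorted(unknown)}")
    ss = _seedseq(seed)
    cond_seeds = ss.spawn(len(protocol))

    forces = {"left": [], "right": []}
    truths = []
    segments = []
    t_offset = 0.0
    for cond, cseed in zip(protocol, cond_seeds):
        params_c = dataclasses.replace(params, **overrides.get(cond.label, {}))
        limb_seeds = cseed.spawn(2)
        n_cond = None
        for limb, lseed in zip(("left", "right"), limb_seeds):
            rec, truth = simulate_walking_trial(cond, params_c, limb, seed=lseed)
            forces[limb].append(rec.force(limb))
            n_cond = rec.n_samples
            truth = truth.assign(condition=cond.label,
                                 event_time=truth["event_time"] + t_offset)
            truths.append(truth)
        segments.append({"label": cond.label, "start_s": t_offset,
                         "end_s": t_offset + n_cond / params.sampling_rate,
                         "left_speed": cond.left_speed,
                         "right_speed": cond.right_speed,
                         "analysis": cond.analysis})
        t_offset += n_cond / params.sampling_rate

    force_left = np.concatenate(forces["left"])
    force_right = np.concatenate(forces["right"])
    rec = GRFRecording(
        time=np.arange(force_left.size) / params.sampling_rate,
        force_left=force_left,
        force_right=force_right,
        sampling_rate=params.sampling_rate,
        body_weight=params.body_weight,
        units="N",
        metadata={"segments": segments},
    )
    truth = pd.concat(truths, ignore_index=True)
    truth = truth[["limb", "condition", "step_index", "event_time",
                   "peak_type", "peak_value_bw"]]
    return rec, truth


# ---------------------------------------------------------------------------
# Study-level simulation (multiple participants, condition-dependent AR truth)
# ---------------------------------------------------------------------------

#: Per-condition AR truth for the default simulated study. φ2 = −1/3 puts the
#: centroid distance equal to φ1, calibrated to the observed group magnitudes:
#: ~0.6–0.7 for symmetric walking, smaller for the 0.25 m/s asymmetry (more
#: constrained gait) and ~0.85 for the destabilising 0.50 m/s asymmetry.
DEFAULT_CONDITION_COEFFS: dict[str, tuple[float, float]] = {
    "sym_0.75": (0.60, -1.0 / 3.0),
    "sym_1.00": (0.65, -1.0 / 3.0),
    "sym_1.50": (0.70, -1.0 / 3.0),
    "asym_0.25": (0.55, -1.0 / 3.0),
    "asym_0.50": (0.85, -1.0 / 3.0),
}


@dataclass
class StudyDesign:
    """Population-level description of a simulated split-belt study."""

    n_participants: int = 17
    protocol: GaitProtocol = field(default_factory=default_protocol)
    condition_coeffs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_COEFFS))
    coeff_jitter_sd: tuple[float, float] = (0.15, 0.10)
    peak_scale_sd: float = 0.04
    mass_mean_kg: float = 71.6
    mass_sd_kg: float = 10.9
    gravity: float = 9.81
    params: SimulationParams = field(default_factory=SimulationParams)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least 1 participant")
        missing = [c.label for c in self.protocol
                   if c.analysis and c.label not in self.condition_coeffs]
        if missing:
            raise ValueError(f"condition_coeffs missing for: {missing}")
        for label, (p1, p2) in self.condition_coeffs.items():
            if not is_stationary(p1, p2).inside:
                raise StationarityError(f"coefficients for {label!r} are non-stationary")


def _jittered_coeffs(base: tuple[float, float], jitter_sd: tuple[float, float],
                     rng: np.random.Generator, margin: float = 0.05,
                     max_tries: int = 200) -> tuple[float, float]:
    """Draw participant-level (φ1, φ2) around a condition truth, kept strictly
    inside the triangle with a safety margin (rejection sampling)."""
    for _ in range(max_tries):
        p1 = base[0] + rng.normal(0.0, jitter_sd[0])
        p2 = base[1] + rng.normal(0.0, jitter_sd[1])
        edge_margin = min(1 - (p2 + p1), 1 - (p2 - p1), 1 - abs(p2))
        if edge_margin > margin:
            return (p1, p2)
    return base


def _participant_draws(design: StudyDesign, rng: np.random.Generator):
    """Body weight, peak scale, and per-condition AR coefficients for one person."""
    mass = float(np.clip(rng.normal(design.mass_mean_kg, design.mass_sd_kg), 45.0, 110.0))
    scale = 1.0 + abs(rng.normal(0.0, design.peak_scale_sd))
    coeffs = {label: _jittered_coeffs(base, design.coeff_jitter_sd, rng)
              for label, base in design.condition_coeffs.items()}
    return mass * design.gravity, scale, coeffs


def _scaled_peak_model(base_model, scale: float):
    def model(speed: float) -> tuple[float, float]:
        imp, prop = base_model(speed)
        return (scale * imp, scale * prop)

    return model


def simulate_study_recordings(design: StudyDesign, seed=None):
    """Yield ``(participant_id, recording, truth)`` for each simulated participant.

    Participant-level variation: body weight ~ N(71.6, 10.9) kg (clipped to a
    physiological range), a shared multiplicative peak-magnitude scale
    ``1 + |N(0, peak_scale_sd)|`` applied at every speed, and per-condition
    AR coefficients jittered around the design truth inside the triangle.
    """
    ss = _seedseq(seed)
    part_seeds = ss.spawn(design.n_participants)
    for i, pseed in enumerate(part_seeds):
        draw_seed, sim_seed = pseed.spawn(2)
        bw, scale, coeffs = _participant_draws(design, np.random.default_rng(draw_seed))
        params = dataclasses.replace(
            design.params, body_weight=bw,
            peak_model=_scaled_peak_model(design.params.peak_model, scale))
        overrides = {label: {"ar_coeffs": c} for label, c in coeffs.items()
                     if label in {cc.label for cc in design.protocol}}
        rec, truth = simulate_protocol(design.protocol, params, seed=sim_seed,
                                       condition_overrides=overrides)
        truth = truth.assign(participant=f"P{i + 1:02d}")
        yield f"P{i + 1:02d}", rec, truth


def simulate_study_peak_table(design: StudyDesign, seed=None,
                              skip_strides: int = 10,
                              conditions: set[str] | None = None,
                              limbs: tuple[str, ...] = ("left", "right"),
                              ) -> pd.DataFrame:
    """Fast path: the study's true peak series without waveform synthesis.

    Produces the same table schema the signal-chain pipeline extracts
    (``participant, limb, condition, step_index, peak_type, event_time_s,
    value_bw``), with the first ``skip_strides`` stances of each series
    discarded, using identical participant-level draws to
    :func:`simulate_study_recordings`. Intended for replicate-level power
    studies where re-synthesising the 1200 Hz signal adds nothing.

    ``conditions``/``limbs`` restrict the generated cells without disturbing
    the seed substreams of the cells that are generated.
    """
    ss = _seedseq(seed)
    part_seeds = ss.spawn(design.n_participants)
    frames = []
    for i, pseed in enumerate(part_seeds):
        draw_seed, sim_seed = pseed.spawn(2)
        rng_draw = np.random.default_rng(draw_seed)
        bw, scale, coeffs = _participant_draws(design, rng_draw)
        cond_seeds = sim_seed.spawn(len(design.protocol))
        for cond, cseed in zip(design.protocol, cond_seeds):
            if conditions is not None and cond.label not in conditions:
                continue
            phi1, phi2 = coeffs.get(cond.label, design.params.ar_coeffs)
            limb_seeds = cseed.spawn(2)
            for limb, lseed in zip(("left", "right"), limb_seeds):
                if limb not in limbs:
                    continue
                speed = cond.speed(limb)
                cadence = design.params.cadence_model(speed)
                n_steps = int(np.floor(cond.duration * cadence + 1e-9))
                rng_peaks = np.random.default_rng(lseed.spawn(2)[0])
                mult = simulate_ar2_series(phi1, phi2, 2 * n_steps,
                                           design.params.fluctuation_sd,
                                           mean=1.0, rng=rng_peaks)
                imp, prop = _scaled_peak_model(design.params.peak_model, scale)(speed)
                base = np.tile([imp, prop], n_steps)
                values = base * mult
                t1, _, t2 = design.params.timing
                period = 1.0 / cadence
                times = np.repeat(np.arange(n_steps) * period, 2)
                times = times + np.tile([t1, t2], n_steps) * design.params.duty_factor * period
                keep = slice(2 * skip_strides, None)
                n_kept = n_steps - skip_strides
                frames.append(pd.DataFrame({
                    "participant": f"P{i + 1:02d}",
                    "limb": limb,
                    "condition": cond.label,
                    "step_index": np.repeat(np.arange(skip_strides, n_steps), 2),
                    "peak_type": np.tile(["impact", "propulsive"], n_kept),
                    "event_time_s": times[keep],
                    "value_bw": values[keep],
                }))
    return pd.concat(frames, ignore_index=True)


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    """Write a ground-truth peak table CSV."""
    truth.to_csv(path, index=False, float_format="%.9f")
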