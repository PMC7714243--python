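"""End-to-end orchestration: simulate → extract peaks → fit AR → triangle → compare.

Each stage reads and writes plain files (CSV/JSON/YAML/SVG) so stages are
independently re-runnable; a manifest records the configuration snapshot,
package version, output hashes and warnings so a run is reproducible from its
own paperwork. A reader for supplementary spreadsheet exports (peak-level or
summary-level layouts, schema-sniffed) lets the same analysis run on deposited
data when available.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import ar as _ar
from . import grf as _grf
from . import stats as _stats
from . import synthetic as _syn
from . import triangle as _tri
from .recording import GRFRecording, write_recording


class SchemaError(ValueError):
    """Raised when a supplementary workbook's layout is not recognised."""


_CONFIG_FIELDS = {
    "mode", "out_dir", "seed", "n_participants", "filter_cutoff_hz",
    "filter_order", "threshold_n", "skip_strides", "ar_order", "alpha",
    "write_recordings", "render_figure", "recording_paths", "workbook_path",
    "sampling_rate_hz", "log_level",
}


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run.

    ``mode`` is ``"simulate"`` (seeded synthetic study), ``"recordings"``
    (list of recording CSVs with sidecars) or ``"workbook"`` (supplementary
    spreadsheet).
    """

    mode: str = "simulate"
    out_dir: str = "gaitar_run"
    seed: int | None = None
    n_participants: int = 17
    sampling_rate_hz: float = 1200.0
    filter_cutoff_hz: float = 35.0
    filter_order: int = 4
    threshold_n: float = 50.0
    skip_strides: int = 10
    ar_order: int = 2
    alpha: float = 0.05
    write_recordings: bool = False
    render_figure: bool = True
    recording_paths: list = field(default_factory=list)
    workbook_path: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        errors = []
        if self.mode not in ("simulate", "recordings", "workbook"):
            errors.append(f"mode must be simulate/recordings/workbook, got {self.mode!r}")
        if self.mode == "simulate" and self.seed is None:
            errors.append("seed is mandatory in simulate mode")
        if self.mode == "recordings" and not self.recording_paths:
            errors.append("recordings mode requires recording_paths")
        if self.mode == "workbook" and not self.workbook_path:
            errors.append("workbook mode requires workbook_path")
        if self.n_participants < 2:
            errors.append("n_participants must be >= 2")
        if not 0 < self.filter_cutoff_hz < self.sampling_rate_hz / 2:
            errors.append(
                f"filter_cutoff_hz must lie in (0, Nyquist={self.sampling_rate_hz / 2} Hz)")
        if self.filter_order < 1:
            errors.append("filter_order must be >= 1")
        if self.threshold_n <= 0:
            errors.append("threshold_n must be positive")
        if self.skip_strides < 0:
            errors.append("skip_strides must be >= 0")
        if self.ar_order < 1:
            errors.append("ar_order must be >= 1")
        if not 0 < self.alpha < 1:
            errors.append("alpha must be in (0, 1)")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Stage functions on in-memory tables
# ---------------------------------------------------------------------------

def extract_study_peaks(recordings, config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Run the GRF processing chain over (participant, recording) pairs.

    Recordings must carry a ``segments`` metadata table (as written by the
    simulator); each analysis segment is processed per limb. Returns the long
    peak table and a QC summary dict.
    """
    frames = []
    qc_total = _grf.QCReport()
    warnings: list[str] = []
    for pid, rec in recordings:
        segments = rec.metadata.get("segments")
        if not segments:
            raise ValueError(f"recording for {pid} lacks a segments table")
        filtered = _grf.lowpass_filter(rec, cutoff=config.filter_cutoff_hz,
                                       order=config.filter_order)
        norm = _grf.normalize_bw(filtered)
        fs = rec.sampling_rate
        for seg in segments:
            if not seg.get("analysis", True):
                continue
            lo = int(round(seg["start_s"] * fs))
            hi = int(round(seg["end_s"] * fs))
            window = GRFRecording(
                time=norm.time[lo:hi], sampling_rate=fs,
                force_left=None if norm.force_left is None else norm.force_left[lo:hi],
                force_right=None if norm.force_right is None else norm.force_right[lo:hi],
                body_weight=norm.body_weight, units=norm.units,
                metadata=dict(norm.metadata))
            for limb in window.limbs():
                stances = _grf.detect_stances(window, limb,
                                              threshold_n=config.threshold_n)
                pairs, qc = _grf.extract_peaks(window, stances)
                if qc.n_dropped:
                    warnings.append(
                        f"{pid}/{seg['label']}/{limb}: {qc.n_dropped} stances dropped")
                qc_total.n_stances += qc.n_stances
                qc_total.n_dropped += qc.n_dropped
                series = _grf.build_peak_series(pairs, condition=seg["label"],
                                                limb=limb,
                                                skip_strides=config.skip_strides)
                qc_total.n_extracted += series.n // 2
                qc_total.n_skipped += config.skip_strides
                n_vals = series.n
                frames.append(pd.DataFrame({
                    "participant": pid, "limb": limb, "condition": seg["label"],
                    "step_index": np.repeat(
                        np.arange(config.skip_strides,
                                  config.skip_strides + n_vals // 2), 2),
                    "peak_type": list(series.peak_types),
                    "event_time_s": series.times,
                    "value_bw": series.values,
                }))
    peaks = pd.concat(frames, ignore_index=True)
    return peaks, {"qc": qc_total.as_dict(), "warnings": warnings}


def fit_study_ar(peaks: pd.DataFrame, order: int = 2) -> pd.DataFrame:
    """Fit one AR model per participant × limb × condition peak series.

    Returns a table with coefficients, innovation variance, root moduli,
    stationarity/centroid-distance statistics and the Anderson–Darling
    residual-normality decision.
    """
    rows = []
    for (pid, limb, cond), grp in peaks.groupby(["participant", "limb", "condition"],
                                                sort=True):
        grp = grp.sort_values("event_time_s")
        fit = _ar.fit_ar(grp["value_bw"].to_numpy(), order=order)
        diag = _ar.residual_diagnostics(fit)
        rec = _ar.fit_record(fit, diag, participant=pid, limb=limb, condition=cond)
        roots = rec.pop("roots")
        rec["root_modulus_max"] = roots[0]["modulus"]
        rows.append(rec)
    return pd.DataFrame(rows)


def triangle_points(fits: pd.DataFrame) -> list[_tri.TrianglePoint]:
    return [_tri.classify(row.phi1, row.phi2, participant=row.participant,
                          limb=row.limb, condition=row.condition)
            for row in fits.itertuples()]


def study_metrics(peaks: pd.DataFrame, fits: pd.DataFrame) -> pd.DataFrame:
    """Long metric table: per-cell mean peak vGRF (BW) and AR centroid distance."""
    mean_peak = (peaks.groupby(["participant", "limb", "condition"])["value_bw"]
                 .mean().reset_index(name="value"))
    mean_peak["metric"] = "mean_peak_vgrf_bw"
    dist = fits[["participant", "limb", "condition", "distance"]].rename(
        columns={"distance": "value"})
    dist["metric"] = "ar_distance"
    out = pd.concat([mean_peak, dist], ignore_index=True)
    return out[["participant", "limb", "condition", "metric", "value"]]


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    config: RunConfig
    peaks: pd.DataFrame
    fits: pd.DataFrame
    metrics: pd.DataFrame
    comparison: _stats.ConditionComparison | None
    manifest: dict


def run_pipeline(config: RunConfig, design: _syn.StudyDesign | None = None) -> RunResult:
    """Execute the configured pipeline end to end, writing all stage outputs.

    In simulate mode a seeded multi-participant study is generated (optionally
    overriding the :class:`~gaitar.synthetic.StudyDesign`); recordings mode
    reads recording CSVs; workbook mode ingests a supplementary spreadsheet.
    Outputs: peaks CSV + QC, AR-fit records (CSV + JSON), triangle points CSV
    and figure, comparison table (CSV + JSON), and a manifest with file
    hashes. Any stage failure aborts with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "gaitar",
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "config": dataclasses.asdict(config),
        "warnings": [],
        "outputs": {},
    }
    stage = "configure"
    try:
        if config.mode == "simulate":
            stage = "simulate"
            design = design or _syn.StudyDesign(n_participants=config.n_participants)
            recordings = []
            truths = []
            for pid, rec, truth in _syn.simulate_study_recordings(design, seed=config.seed):
                recordings.append((pid, rec))
                truths.append(truth)
                if config.write_recordings:
                    write_recording(rec, out / f"recording_{pid}.csv")
            truth = pd.concat(truths, ignore_index=True)
            _syn.write_ground_truth(truth, out / "ground_truth_peaks.csv")
            stage = "extract-peaks"
            peaks, qc = extract_study_peaks(recordings, config)
        elif config.mode == "recordings":
            stage = "extract-peaks"
            from .recording import read_recording

            recordings = [(Path(p).stem, read_recording(p)) for p in config.recording_paths]
            peaks, qc = extract_study_peaks(recordings, config)
        else:
            stage = "read-workbook"
            kind, table = read_supplementary_workbook(config.workbook_path)
            if kind == "metrics":
                manifest["warnings"].append(
                    "workbook holds summary metrics only; AR fitting skipped")
                comparison = _stats.compare_conditions(table, alpha=config.alpha)
                _write_comparison(comparison, out, manifest)
                _finalize_manifest(out, manifest)
                return RunResult(config=config, peaks=pd.DataFrame(),
                                 fits=pd.DataFrame(), metrics=table,
                                 comparison=comparison, manifest=manifest)
            peaks, qc = table, {"qc": {}, "warnings": []}

        manifest["qc"] = qc["qc"]
        manifest["warnings"].extend(qc["warnings"])
        peaks.to_csv(out / "peaks.csv", index=False, float_format="%.9f")

        stage = "fit-ar"
        fits = fit_study_ar(peaks, order=config.ar_order)
        fits.to_csv(out / "ar_fits.csv", index=False, float_format="%.9f")
        with open(out / "ar_fits.json", "w") as fh:
            json.dump(fits.to_dict(orient="records"), fh, indent=1, default=str)

        stage = "triangle"
        points = triangle_points(fits)
        _tri.points_table(points).to_csv(out / "triangle_points.csv", index=False,
                                         float_format="%.9f")
        if config.render_figure:
            _tri.render_triangle(points, out / "triangle.svg")

        stage = "compare"
        metrics = study_metrics(peaks, fits)
        metrics.to_csv(out / "metrics.csv", index=False, float_format="%.9f")
        comparison = _stats.compare_conditions(metrics, alpha=config.alpha)
        _write_comparison(comparison, out, manifest)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _finalize_manifest(out, manifest)
    return RunResult(config=config, peaks=peaks, fits=fits, metrics=metrics,
                     comparison=comparison, manifest=manifest)


def _write_comparison(comparison: _stats.ConditionComparison, out: Path,
                      manifest: dict) -> None:
    comparison.table().to_csv(out / "comparison.csv", index=False)
    with open(out / "comparison.json", "w") as fh:
        json.dump(comparison.records(), fh, indent=1)


def _finalize_manifest(out: Path, manifest: dict) -> None:
    for p in sorted(out.iterdir()):
        if p.name == "manifest.yaml" or not p.is_file():
            continue
        manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def replicate_family_pvalues(design: _syn.StudyDesign, conditions: list[str],
                             limb: str = "right", n_replicates: int = 200,
                             seed=None, ar_order: int = 2) -> pd.DataFrame:
    """ANOVA p-values over seeded replicate studies, for power/type-I studies.

    Each replicate simulates the study's true peak series (fast path, one limb,
    the given condition family), fits the AR models, and runs one-way ANOVAs
    on the AR centroid distance and on the per-participant mean peak vGRF.
    Returns one row per replicate with columns ``p_ar_distance, p_mean_peak``.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rows = []
    for rep, rseed in enumerate(ss.spawn(n_replicates)):
        tab = _syn.simulate_study_peak_table(design, seed=rseed,
                                             conditions=set(conditions),
                                             limbs=(limb,))
        fits = fit_study_ar(tab, order=ar_order)
        dist_groups = [fits.loc[fits["condition"] == c, "distance"].to_numpy()
                       for c in conditions]
        mp = (tab.groupby(["participant", "condition"])["value_bw"]
              .mean().reset_index())
        peak_groups = [mp.loc[mp["condition"] == c, "value_bw"].to_numpy()
                       for c in conditions]
        rows.append({"replicate": rep,
                     "p_ar_distance": _stats.one_way_anova(dist_groups).p,
                     "p_mean_peak": _stats.one_way_anova(peak_groups).p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Supplementary workbook ingestion
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = {"participant", "limb", "condition", "peak_type", "value"}
_METRIC_COLUMNS = {"participant", "limb", "condition", "metric", "value"}


def read_supplementary_workbook(path) -> tuple[str, pd.DataFrame]:
    """Schema-sniffing reader for supplementary spreadsheet exports.

    Recognises two layouts (case-insensitive headers, first sheet):

    * peak-level — columns {participant, limb, condition, [step], peak_type,
      value}: returned as ``("peaks", table)`` matching the pipeline's peak
      schema, suitable for AR fitting;
    * summary-level — columns {participant, limb, condition, metric, value}:
      returned as ``("metrics", table)``; AR fitting is not possible.

    Anything else raises :class:`SchemaError` showing the detected headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_excel(path)
    except Exception as exc:  # unreadable / not a spreadsheet
        raise SchemaError(f"could not read workbook {path}: {exc}") from exc
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    cols = set(df.columns)
    if df.empty or not cols:
        raise SchemaError(f"workbook {path} is empty")
    if "step" in cols and "step_index" not in cols:
        df = df.rename(columns={"step": "step_index"})
        cols = set(df.columns)
    if _PEAK_COLUMNS.issubset(cols):
        out = df.rename(columns={"value": "value_bw"})
        if "step_index" not in out.columns:
            out["step_index"] = out.groupby(
                ["participant", "limb", "condition", "peak_type"]).cumcount()
        if "event_time_s" not in out.columns:
            # synthesize strictly increasing within-cell event order
            out["event_time_s"] = out.groupby(
                ["participant", "limb", "condition"]).cumcount().astype(float)
        return "peaks", out[["participant", "limb", "condition", "step_index",
                             "peak_type", "event_time_s", "value_bw"]]
    if _METRIC_COLUMNS.issubset(cols):
        return "metrics", df[["participant", "limb", "condition", "metric", "value"]]
    raise SchemaError(
        f"unrecognised workbook layout; detected headers: {sorted(cols)}")
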