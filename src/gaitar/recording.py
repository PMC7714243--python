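"""Vertical ground reaction force recordings and their on-disk CSV format.

A recording holds one or both limbs' vertical force sampled on a uniform time
grid, with the participant's body weight carried as metadata so downstream
stages can normalise forces to body-weight (BW) units. On disk a recording is
a CSV with header ``time,fz_left,fz_right`` (seconds, newtons) plus a YAML
sidecar with body weight, sampling rate, segment table and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

LIMBS = ("left", "right")


@dataclass
class GRFRecording:
    """Uniformly sampled vertical GRF waveform(s) for one or both limbs.

    ``units`` is ``"N"`` (newtons) or ``"BW"`` (body weights); forces are
    non-negative by convention (force plates report vertical load only).
    """

    time: np.ndarray
    force_left: np.ndarray | None
    force_right: np.ndarray | None
    sampling_rate: float
    body_weight: float
    units: str = "N"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time must be a 1-D array with at least 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.sampling_rate)) > 1e-9:
            raise ValueError("time grid is not uniform at the stated sampling rate")
        if self.force_left is None and self.force_right is None:
            raise ValueError("at least one limb channel is required")
        for limb in LIMBS:
            f = getattr(self, f"force_{limb}")
            if f is None:
                continue
            f = np.asarray(f, dtype=float)
            if f.shape != self.time.shape:
                raise ValueError(f"force_{limb} length differs from time")
            setattr(self, f"force_{limb}", f)
        if self.units not in ("N", "BW"):
            raise ValueError("units must be 'N' or 'BW'")

    @property
    def n_samples(self) -> int:
        return self.time.size

    def limbs(self) -> tuple[str, ...]:
        return tuple(l for l in LIMBS if getattr(self, f"force_{l}") is not None)

    def force(self, limb: str) -> np.ndarray:
        if limb not in LIMBS:
            raise ValueError(f"unknown limb {limb!r}")
        f = getattr(self, f"force_{limb}")
        if f is None:
            raise ValueError(f"recording has no {limb}-limb channel")
        return f

    def with_forces(self, **channels: np.ndarray) -> "GRFRecording":
        """Copy of the recording with replaced force channels/units/metadata."""
        units = channels.pop("units", self.units)
        metadata = channels.pop("metadata", dict(self.metadata))
        kwargs = {f"force_{l}": channels.get(l, getattr(self, f"force_{l}"))
                  for l in LIMBS}
        return replace(self, units=units, metadata=metadata, **kwargs)


def write_recording(rec: GRFRecording, csv_path, meta_path=None) -> None:
    """Write ``time,fz_left,fz_right`` CSV plus a YAML metadata sidecar."""
    csv_path = Path(csv_path)
    cols = {"time": rec.time}
    for limb in LIMBS:
        f = getattr(rec, f"force_{limb}")
        cols[f"fz_{limb}"] = f if f is not None else np.full_like(rec.time, np.nan)
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.6f")
    meta = {
        "body_weight_N": float(rec.body_weight),
        "sampling_rate_hz": float(rec.sampling_rate),
        "units": rec.units,
        **{k: v for k, v in rec.metadata.items()},
    }
    if meta_path is None:
        meta_path = csv_path.with_suffix(".meta.yaml")
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_recording(csv_path, meta_path=None) -> GRFRecording:
    """Read a recording CSV and its YAML sidecar back into memory."""
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".meta.yaml")
    df = pd.read_csv(csv_path)
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    body_weight = float(meta.pop("body_weight_N"))
    fs = float(meta.pop("sampling_rate_hz"))
    units = meta.pop("units", "N")

    def channel(name: str):
        if name not in df.columns:
            return None
        vals = df[name].to_numpy(dtype=float)
        return None if np.all(np.isnan(vals)) else vals

    # rebuild the uniform grid exactly; CSV text rounds the time stamps
    t0 = float(df["time"].iloc[0])
    return GRFRecording(
        time=t0 + np.arange(len(df)) / fs,
        force_left=channel("fz_left"),
        force_right=channel("fz_right"),
        sampling_rate=fs,
        body_weight=body_weight,
        units=units,
        metadata=meta,
    )
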