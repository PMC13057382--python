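"""Waveform data model and delimited-text I/O.

A :class:`WaveformRecord` holds uniformly sampled multichannel traces from
one ventilation session: airway pressure (cmH2O), flow (L/min, inspiratory
positive), volume (mL), and optionally esophageal pressure (cmH2O),
end-tidal CO2 (mmHg) and SpO2 (%).  The on-disk format is a UTF-8 CSV with
header ``time_s,paw_cmh2o,flow_lpm,vol_ml,pes_cmh2o,etco2_mmhg,spo2_pct``
(optional columns may be absent) and ``# key: value`` comment lines
carrying metadata.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .config import ClassifierConfig, DEFAULT_CONFIG


class WaveformFormatError(ValueError):
    """Raised for malformed or non-uniform waveform files."""


_COLUMNS = {
    "paw": "paw_cmh2o",
    "flow": "flow_lpm",
    "volume": "vol_ml",
    "pes": "pes_cmh2o",
    "etco2": "etco2_mmhg",
    "spo2": "spo2_pct",
}


@dataclass
class WaveformRecord:
    """One uniformly sampled ventilation session."""

    sample_rate_hz: float
    paw: np.ndarray
    flow: np.ndarray
    volume: Optional[np.ndarray] = None
    pes: Optional[np.ndarray] = None
    etco2: Optional[np.ndarray] = None
    spo2: Optional[np.ndarray] = None
    artifact_mask: Optional[np.ndarray] = None
    t0_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.paw = np.asarray(self.paw, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        for name in ("volume", "pes", "etco2", "spo2"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.paw.shape, dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.sample_rate_hz <= 0:
            raise WaveformFormatError("sample_rate_hz must be positive")
        n = len(self.paw)
        if n < 2:
            raise WaveformFormatError("channels need at least 2 samples")
        for name in ("flow", "volume", "pes", "etco2", "spo2"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise WaveformFormatError(f"channel {name!r} length mismatch")
        if len(self.artifact_mask) != n:
            raise WaveformFormatError("artifact_mask length mismatch")
        if not np.all(np.isfinite(self.paw)):
            raise WaveformFormatError("paw contains non-finite samples")
        if not np.all(np.isfinite(self.flow)):
            raise WaveformFormatError("flow contains non-finite samples")

    # -- conveniences ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.paw)

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.sample_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sample_rate_hz

    def index_at(self, time_s: float) -> int:
        """Nearest sample index for a time in seconds (clipped in range)."""
        i = int(round((time_s - self.t0_s) * self.sample_rate_hz))
        return min(max(i, 0), self.n_samples - 1)

    def copy(self) -> "WaveformRecord":
        rec = replace(self)
        for name in ("paw", "flow", "volume", "pes", "etco2", "spo2",
                     "artifact_mask"):
            v = getattr(rec, name)
            if v is not None:
                setattr(rec, name, v.copy())
        rec.meta = dict(self.meta)
        return rec


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_waveform(source: Union[str, Path, io.TextIOBase],
                  strict: bool = True) -> WaveformRecord:
    """Read the delimited waveform format into a validated record.

    The sample rate is inferred from the median time step; in strict mode
    any step deviating by more than 10% of the median is a format error.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_waveform(fh, strict=strict)

    meta: dict = {}
    body_lines = []
    for line in source:
        if line.startswith("#"):
            stripped = line[1:].strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                meta[key.strip()] = value.strip()
            continue
        if line.strip():
            body_lines.append(line)
    if not body_lines:
        raise WaveformFormatError("empty waveform file")

    df = pd.read_csv(io.StringIO("".join(body_lines)),
                     float_precision="round_trip")
    for required in ("time_s", "paw_cmh2o", "flow_lpm"):
        if required not in df.columns:
            raise WaveformFormatError(f"missing mandatory column {required!r}")
    if len(df) < 2:
        raise WaveformFormatError("waveform needs at least 2 rows")

    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0:
        raise WaveformFormatError("time column is not increasing")
    if strict and np.max(np.abs(dt - step)) >= 0.1 * step:
        raise WaveformFormatError("non-uniform time base beyond 10% tolerance")

    kwargs = {}
    for attr, col in _COLUMNS.items():
        if col in df.columns:
            kwargs[attr] = df[col].to_numpy(dtype=float)
    return WaveformRecord(sample_rate_hz=1.0 / step, t0_s=float(t[0]),
                          meta=meta, **kwargs)


def write_waveform(record: WaveformRecord,
                   target: Union[str, Path, io.TextIOBase]) -> None:
    """Write a record to the delimited format at full float precision."""
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as fh:
            write_waveform(record, fh)
        return

    for key, value in record.meta.items():
        target.write(f"# {key}: {value}\n")
    cols = {"time_s": record.time_s}
    for attr, col in _COLUMNS.items():
        v = getattr(record, attr)
        if v is not None:
            cols[col] = v
    pd.DataFrame(cols).to_csv(target, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def integrate_volume(flow_lpm: np.ndarray, sample_rate_hz: float,
                     start_index: int, end_index: int) -> float:
    """Trapezoidal integral of flow over [start_index, end_index], in mL.

    Flow is L/min; the integral over seconds is converted via 1000/60.
    """
    flow_lpm = np.asarray(flow_lpm, dtype=float)
    n = len(flow_lpm)
    if not (0 <= start_index <= end_index < n):
        raise IndexError("integration window out of range")
    if start_index == end_index:
        return 0.0
    window = flow_lpm[start_index:end_index + 1]
    return float(np.trapezoid(window, dx=1.0 / sample_rate_hz) * 1000.0 / 60.0)


def compute_breath_leak(v_insp_ml: float, v_exp_ml: float) -> float:
    """Breath leak percentage: 100*(Vinsp - Vexp)/Vinsp, clamped to [0, 100]."""
    if v_insp_ml <= 0:
        raise ValueError("inspired volume must be positive")
    if v_exp_ml < 0:
        raise ValueError("expired volume must be nonnegative")
    return float(np.clip(100.0 * (v_insp_ml - v_exp_ml) / v_insp_ml, 0.0, 100.0))


# ---------------------------------------------------------------------------
# Artifact masking
# ---------------------------------------------------------------------------

def _label_regions(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) half-open index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def mask_artifacts(record: WaveformRecord,
                   cfg: ClassifierConfig = DEFAULT_CONFIG) -> WaveformRecord:
    """Mask cough and active-expiration artifacts.

    Cough: a brief positive flow transient rising above the local flow
    baseline by more than ``cough_flow_spike_lpm`` while the surrounding
    context is expiratory.  Active expiration: a positive Pes transient
    exceeding ``active_exp_pes_cmh2o`` above the rolling Pes baseline.
    Masked windows are excluded downstream from numerator and denominator.
    Idempotent: the mask depends only on the channels, and is OR-ed in.
    """
    rec = record.copy()
    fs = rec.sample_rate_hz
    mask = rec.artifact_mask.copy()
    pad = max(1, int(round(cfg.artifact_pad_s * fs)))

    # Flow-spike route.
    win = max(3, int(round(0.7 * fs)) | 1)
    baseline = median_filter(rec.flow, size=win, mode="nearest")
    dev = rec.flow - baseline
    candidates = dev > cfg.cough_flow_spike_lpm
    ctx = max(1, int(round(0.30 * fs)))
    n = rec.n_samples
    dpaw = np.diff(rec.paw) * fs
    for start, stop in _label_regions(candidates):
        if (stop - start) / fs > 0.45:
            continue  # sustained rise: an inspiration, not a cough
        if rec.flow[start:stop].max() <= 0:
            continue  # a rebound within expiratory flow (effort), not a cough
        if np.any(dpaw[max(0, start - 5):stop]
                  >= cfg.paw_trigger_slope_cmh2o_per_s):
            continue  # ventilator pressurization: a (short) machine breath
        before = rec.flow[max(0, start - ctx):start]
        after = rec.flow[stop:min(n, stop + ctx)]
        if len(before) and len(after) and before.mean() < 0 and after.mean() < 0:
            mask[max(0, start - pad):min(n, stop + pad)] = True

    # Pes route (active expiratory effort raises Pes above baseline).
    if rec.pes is not None:
        pwin = max(3, int(round(cfg.pes_baseline_win_s * fs)) | 1)
        pes_base = median_filter(rec.pes, size=pwin, mode="nearest")
        high = (rec.pes - pes_base) > cfg.active_exp_pes_cmh2o
        for start, stop in _label_regions(high):
            mask[max(0, start - pad):min(n, stop + pad)] = True

    rec.artifact_mask = mask
    return rec
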