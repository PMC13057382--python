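"""Outcome indices for one measurement period.

The Asynchrony Index (AI) is the percentage of asynchronous events over
the number of machine breaths plus ineffective efforts:

    AI       = 100 * (major + minor events) / (machine breaths + IE)
    Major AI = 100 * (AT + DB + IE)         / (machine breaths + IE)
    Minor AI = 100 * (TD + EC + LC)         / (machine breaths + IE)

so AI = Major AI + Minor AI exactly (shared denominator).  Secondary
outcomes are channel means over unmasked samples, the mean per-breath
leak fraction, and the Comfort-B behavioral score with its published
bands (<10 possible over-sedation, 12-17 adequate, >17 agitation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .classifier import AsynchronyEvent
from .segmentation import BreathSegment
from .waveforms import WaveformRecord, compute_breath_leak


@dataclass
class AIResult:
    n_machine_breaths: int
    n_ie: int
    n_at: int
    n_db: int
    n_td: int
    n_ec: int
    n_lc: int
    ai_pct: float
    major_ai_pct: float
    minor_ai_pct: float

    @property
    def denominator(self) -> int:
        return self.n_machine_breaths + self.n_ie


@dataclass
class PeriodSummary:
    ai: AIResult
    mean_spo2_pct: Optional[float]
    mean_etco2_mmhg: Optional[float]
    mean_leak_pct: Optional[float]
    comfort_b: Optional[int]
    duration_s: float


def compute_ai(events: list[AsynchronyEvent], n_machine_breaths: int) -> AIResult:
    """Tally events by type and compute AI / Major AI / Minor AI."""
    counts = {t: 0 for t in ("AT", "DB", "IE", "TD", "EC", "LC")}
    for ev in events:
        counts[ev.type] += 1
    denom = n_machine_breaths + counts["IE"]
    if denom <= 0:
        raise ValueError("AI denominator (machine breaths + IE) must be positive")
    major = counts["AT"] + counts["DB"] + counts["IE"]
    minor = counts["TD"] + counts["EC"] + counts["LC"]
    major_pct = 100.0 * major / denom
    minor_pct = 100.0 * minor / denom
    res = AIResult(
        n_machine_breaths=n_machine_breaths, n_ie=counts["IE"],
        n_at=counts["AT"], n_db=counts["DB"], n_td=counts["TD"],
        n_ec=counts["EC"], n_lc=counts["LC"],
        # Summed, not recomputed: AI = Major + Minor holds bit-exactly.
        ai_pct=major_pct + minor_pct,
        major_ai_pct=major_pct, minor_ai_pct=minor_pct)
    if not (0.0 <= res.minor_ai_pct <= 200.0):
        raise AssertionError("minor AI out of the bound implied by precedence")
    return res


def comfort_band(score: int) -> str:
    """Comfort-B band: <10 over-sedation, 12-17 adequate, >17 agitation;
    10-11 falls in the unnamed gap between the published bands."""
    if not (6 <= score <= 30):
        raise ValueError("Comfort-B score must be within 6-30")
    if score < 10:
        return "over_sedation"
    if score <= 11:
        return "indeterminate"
    if score <= 17:
        return "adequate"
    return "agitation"


def _masked_mean(channel: Optional[np.ndarray],
                 mask: np.ndarray) -> Optional[float]:
    if channel is None:
        return None
    keep = ~mask
    if not keep.any():
        return None
    return float(np.mean(channel[keep]))


def _breath_unmasked(record: WaveformRecord, breath: BreathSegment) -> bool:
    i0 = record.index_at(breath.onset_time_s)
    i1 = record.index_at(breath.end_time_s)
    return not record.artifact_mask[i0:i1 + 1].any()


def summarize_period(record: WaveformRecord, events: list[AsynchronyEvent],
                     breaths: list[BreathSegment],
                     comfort_b: Optional[int] = None) -> PeriodSummary:
    """Summarize one measurement period.

    Breaths overlapping artifact-masked windows are excluded from the AI
    denominator (events inside masked windows were already dropped by the
    classifier); channel means are over unmasked samples only.
    """
    clean_breaths = [b for b in breaths if _breath_unmasked(record, b)]
    ai = compute_ai(events, len(clean_breaths))

    leaks = []
    for b in clean_breaths:
        if b.v_insp_ml > 0:
            leaks.append(compute_breath_leak(b.v_insp_ml, b.v_exp_ml))
    mean_leak = float(np.mean(leaks)) if leaks else None

    return PeriodSummary(
        ai=ai,
        mean_spo2_pct=_masked_mean(record.spo2, record.artifact_mask),
        mean_etco2_mmhg=_masked_mean(record.etco2, record.artifact_mask),
        mean_leak_pct=mean_leak,
        comfort_b=comfort_b,
        duration_s=record.duration_s)
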