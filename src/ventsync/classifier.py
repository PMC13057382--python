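"""Breath-by-breath asynchrony classification.

Labels each machine breath / patient effort with one of six asynchrony
types under explicit precedence rules:

* AT (auto-trigger), DB (double breath), IE (ineffective effort) — major;
* TD (trigger delay), EC (early cycling), LC (late cycling) — minor.

Trigger timing bins on ventilator response time: (0, 117] ms normal,
(117, 234] ms trigger delay, > 234 ms ineffective effort.  Early/late
cycling is diagnosed when the ventilator cycles >= 100 ms before/after
the patient's inspiratory termination (Pes midpoint rule).  A double
breath is two consecutive ventilator cycles separated by an expiratory
time no longer than half the first cycle's inspiratory time.

Precedence (documented order, applied by :func:`classify_session`):
per machine breath at most one trigger-phase label (AT or TD) and at
most one cycling-phase label (EC or LC); DB attaches to the second cycle
of its pair, suppresses EC on the first cycle and any trigger-phase
label on the second; IE events live on effort cycles (at most one per
effort) and are never double-counted with TD for the same effort.  When
Pes is present the Pes-based rules take priority over the flow-only
morphological fallbacks.  Events inside artifact-masked windows are
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import ClassifierConfig, DEFAULT_CONFIG
from .segmentation import (BreathSegment, EffortEvent, MatchResult,
                           fit_passive_decay)
from .waveforms import WaveformRecord

MAJOR_TYPES = ("AT", "DB", "IE")
MINOR_TYPES = ("TD", "EC", "LC")
EVENT_TYPES = MAJOR_TYPES + MINOR_TYPES


def severity_of(event_type: str) -> str:
    if event_type in MAJOR_TYPES:
        return "major"
    if event_type in MINOR_TYPES:
        return "minor"
    raise ValueError(f"unknown asynchrony type {event_type!r}")


@dataclass
class AsynchronyEvent:
    type: str
    time_s: float
    breath_index: Optional[int]
    metric_value: Optional[float]
    metric_units: Optional[str]

    @property
    def severity(self) -> str:
        return severity_of(self.type)


# ---------------------------------------------------------------------------
# Individual rules
# ---------------------------------------------------------------------------

def classify_trigger_timing(response_time_ms: float,
                            cfg: ClassifierConfig = DEFAULT_CONFIG) -> str:
    """Bin a ventilator response time: 'normal', 'TD' or 'IE'."""
    if response_time_ms < 0:
        raise ValueError("response time must be nonnegative")
    if response_time_ms <= cfg.normal_trigger_max_ms:
        return "normal"
    if response_time_ms <= cfg.td_max_ms:
        return "TD"
    return "IE"


def detect_double_breath(first: BreathSegment, second: BreathSegment,
                         cfg: ClassifierConfig = DEFAULT_CONFIG
                         ) -> Optional[AsynchronyEvent]:
    """DB when the interposed expiratory time <= ratio * first Ti.

    The event attaches to the second cycle; it is DB even when the second
    cycle follows an auto-trigger or mandatory breath.
    """
    te = second.onset_time_s - first.cycle_time_s
    if te < 0 or first.ti_s <= 0:
        return None
    ratio = te / first.ti_s
    if ratio <= cfg.db_te_ti_ratio:
        return AsynchronyEvent("DB", second.onset_time_s, None,
                               ratio, "te_ti_ratio")
    return None


def detect_cycling(breath: BreathSegment, effort: EffortEvent,
                   cfg: ClassifierConfig = DEFAULT_CONFIG
                   ) -> tuple[Optional[str], float]:
    """Cycling offset for a matched breath/effort pair.

    offset = effort termination - ventilator cycle (ms).  Positive beyond
    the threshold means the ventilator cycled early (EC); negative beyond
    the symmetric threshold means late cycling (LC).
    """
    offset_ms = 1000.0 * (effort.termination_time_s - breath.cycle_time_s)
    if offset_ms >= cfg.ec_lc_offset_ms:
        return "EC", offset_ms
    if offset_ms <= -cfg.ec_lc_offset_ms:
        return "LC", offset_ms
    return None, offset_ms


def detect_ie_pes(match: MatchResult, efforts: list[EffortEvent],
                  cfg: ClassifierConfig = DEFAULT_CONFIG
                  ) -> list[AsynchronyEvent]:
    """Pes-route ineffective efforts: unmatched efforts, plus matched
    efforts whose response time exceeds the IE boundary.  At most one IE
    per effort cycle."""
    events = []
    for ei in match.unmatched_efforts:
        eff = efforts[ei]
        events.append(AsynchronyEvent("IE", eff.onset_time_s, None,
                                      None, None))
    for link in match.links:
        rt = max(link["response_time_ms"], 0.0)
        if rt > cfg.td_max_ms:
            eff = efforts[link["effort_index"]]
            events.append(AsynchronyEvent("IE", eff.onset_time_s,
                                          link["breath_index"], rt, "ms"))
    return events


def _expiration_deviations(record: WaveformRecord, breath: BreathSegment,
                           cfg: ClassifierConfig) -> list[tuple[float, float]]:
    """Flow deviations toward zero during expiration: (time_s, magnitude).

    If a passive-decay fit of the early expiration succeeds, deviations
    are residuals above the fitted envelope; otherwise a monotone envelope
    (expiratory flow should rise monotonically toward zero when passive)
    is used.
    """
    fs = record.sample_rate_hz
    i0 = record.index_at(breath.cycle_time_s + cfg.decay_fit_delay_s)
    i1 = record.index_at(breath.end_time_s - 0.02)
    if i1 - i0 < 8:
        return []
    flow = record.flow[i0:i1 + 1]
    if np.any(flow >= 0):  # keep strictly expiratory tail
        pos = np.flatnonzero(flow >= 0)
        first_pos = pos[0]
        if first_pos < 8:
            return []
        flow = flow[:first_pos]
        i1 = i0 + first_pos - 1

    nfit = min(len(flow), int(round(cfg.decay_fit_window_s * fs)))
    fit = fit_passive_decay(flow[:nfit], fs, cfg)
    if fit.is_passive and fit.tau_s:
        t_rel = np.arange(len(flow)) / fs
        envelope = flow[0] * np.exp(-t_rel / fit.tau_s)
        resid_scale = np.std(flow[:nfit] - envelope[:nfit])
        thr = max(1.0, 3.0 * resid_scale)
        resid = flow - envelope
    else:
        # Monotone envelope: flow closer to zero than any later sample.
        later_min = np.minimum.accumulate(flow[::-1])[::-1]
        resid = flow - later_min
        thr = cfg.ec_flow_bump_lpm

    above = resid > thr
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    out = []
    for start, stop in zip(edges[::2], edges[1::2]):
        peak = start + int(np.argmax(resid[start:stop]))
        t = record.t0_s + (i0 + peak) / fs
        if out and t - out[-1][0] < 0.3:  # merge near-duplicates
            continue
        out.append((t, float(resid[peak])))
    return out


def detect_ie_flow(record: WaveformRecord, breath: BreathSegment,
                   cfg: ClassifierConfig = DEFAULT_CONFIG
                   ) -> list[AsynchronyEvent]:
    """Flow-only ineffective efforts during one breath's expiration.

    An IE is a flow deviation toward zero breaking the passive envelope,
    combined with an abrupt airway-pressure drop of at least
    ``ie_paw_drop_cmh2o`` within +/-150 ms of the deviation.
    """
    if breath.te_s < 0.2:
        return []
    events = []
    fs = record.sample_rate_hz
    for t_dev, _mag in _expiration_deviations(record, breath, cfg):
        j0 = record.index_at(t_dev - 0.15)
        j1 = record.index_at(t_dev + 0.15)
        paw_win = record.paw[j0:j1 + 1]
        if len(paw_win) < 2:
            continue
        drop = float(np.max(paw_win) - np.min(paw_win))
        imax = int(np.argmax(paw_win))
        imin = int(np.argmin(paw_win))
        if imin > imax and drop >= cfg.ie_paw_drop_cmh2o:
            events.append(AsynchronyEvent("IE", t_dev, None, drop, "cmH2O"))
    return events


def detect_auto_trigger(breath: BreathSegment, breath_index: int,
                        match: MatchResult, record: WaveformRecord,
                        cfg: ClassifierConfig = DEFAULT_CONFIG
                        ) -> Optional[AsynchronyEvent]:
    """AT for an unmatched breath with no pre-onset effort signature.

    Requires the absence of a negative airway-pressure deflection above
    the noise floor in the pre-trigger window and, when Pes is present,
    the absence of a negative Pes deflection there (a positive Pes
    deflection is consistent with AT and does not veto it).
    """
    if breath_index not in match.unmatched_breaths:
        return None
    fs = record.sample_rate_hz
    i1 = record.index_at(breath.onset_time_s - 0.01)
    i0 = record.index_at(breath.onset_time_s - 0.01 - cfg.at_preonset_win_s)
    if i1 - i0 < 3:
        return None
    k = np.ones(3) / 3.0
    paw = np.convolve(record.paw[i0:i1 + 1], k, mode="valid")
    paw_dip = float(np.median(paw) - np.min(paw))
    if paw_dip >= cfg.at_paw_dip_cmh2o:
        return None
    if record.pes is not None:
        pes = np.convolve(record.pes[i0:i1 + 1], k, mode="valid")
        pes_dip = float(np.median(pes) - np.min(pes))
        if pes_dip >= cfg.at_pes_dip_cmh2o:
            return None
    return AsynchronyEvent("AT", breath.onset_time_s, breath_index,
                           paw_dip, "cmH2O")


def _detect_lc_flow(record: WaveformRecord, breath: BreathSegment,
                    cfg: ClassifierConfig) -> bool:
    """Flow-only LC fallback: airway-pressure spike just before cycling."""
    i1 = record.index_at(breath.cycle_time_s)
    i0 = record.index_at(breath.cycle_time_s - cfg.lc_window_before_cycle_s)
    m0 = record.index_at(breath.onset_time_s + 0.5 * breath.ti_s)
    if i1 - i0 < 2 or i0 - m0 < 2:
        return False
    plateau = float(np.median(record.paw[m0:i0]))
    spike = float(np.max(record.paw[i0:i1 + 1]))
    return spike - plateau >= cfg.lc_paw_spike_cmh2o


# ---------------------------------------------------------------------------
# Whole-session classification
# ---------------------------------------------------------------------------

def classify_session(record: WaveformRecord, breaths: list[BreathSegment],
                     efforts: Optional[list[EffortEvent]],
                     match: Optional[MatchResult],
                     cfg: ClassifierConfig = DEFAULT_CONFIG
                     ) -> list[AsynchronyEvent]:
    """Apply all rules with the documented precedence; returns events
    sorted by time, with events in artifact-masked windows dropped."""
    if efforts is not None and match is None:
        raise ValueError("match must be provided when efforts are provided")
    if match is not None:
        for link in match.links:
            if link["breath_index"] >= len(breaths):
                raise ValueError("match refers to unknown breath index")

    events: list[AsynchronyEvent] = []

    # 1. Double breaths on consecutive pairs.
    db_first: set[int] = set()
    db_second: set[int] = set()
    for k in range(len(breaths) - 1):
        ev = detect_double_breath(breaths[k], breaths[k + 1], cfg)
        if ev is not None:
            ev.breath_index = k + 1
            events.append(ev)
            db_first.add(k)
            db_second.add(k + 1)

    link_by_breath = {}
    if match is not None:
        link_by_breath = {l["breath_index"]: l for l in match.links}

    # 2. Trigger phase per machine breath (skipped on DB second cycles).
    for bi, br in enumerate(breaths):
        if bi in db_second:
            continue
        link = link_by_breath.get(bi)
        if link is not None:
            rt = max(link["response_time_ms"], 0.0)
            label = classify_trigger_timing(rt, cfg)
            if label == "TD":
                events.append(AsynchronyEvent("TD", br.onset_time_s, bi,
                                              rt, "ms"))
            # label == "IE" handled by the Pes IE route below.
        elif match is not None or efforts is None:
            ev = detect_auto_trigger(br, bi, match, record, cfg) \
                if match is not None else None
            if ev is not None:
                events.append(ev)

    # 3. Ineffective efforts.
    if efforts is not None:
        events.extend(detect_ie_pes(match, efforts, cfg))
    else:
        for br in breaths:
            events.extend(detect_ie_flow(record, br, cfg))

    # 4. Cycling phase per breath.
    if efforts is not None:
        for link in match.links:
            bi = link["breath_index"]
            br = breaths[bi]
            label, offset = detect_cycling(br, efforts[link["effort_index"]],
                                           cfg)
            if label == "EC" and bi in db_first:
                continue  # the early cycle is the DB mechanism
            if label is not None:
                events.append(AsynchronyEvent(label, br.cycle_time_s, bi,
                                              offset, "ms"))
    else:
        for bi, br in enumerate(breaths):
            if bi in db_first:
                continue
            ec_candidates = [
                (t, m) for t, m in _expiration_deviations(record, br, cfg)
                if t - br.cycle_time_s <= cfg.ec_window_after_cycle_s]
            is_ie_like = any(
                ev.type == "IE" and abs(ev.time_s - t) < 0.2
                for ev in events for t, _ in ec_candidates)
            if ec_candidates and not is_ie_like:
                t, m = ec_candidates[0]
                events.append(AsynchronyEvent("EC", br.cycle_time_s, bi,
                                              m, "lpm"))
            elif _detect_lc_flow(record, br, cfg):
                events.append(AsynchronyEvent("LC", br.cycle_time_s, bi,
                                              None, None))

    # 5. Drop events in masked windows; sort.
    if record.artifact_mask.any():
        events = [ev for ev in events
                  if not record.artifact_mask[record.index_at(ev.time_s)]]
    events.sort(key=lambda ev: ev.time_s)
    return events


def analyze_record(record: WaveformRecord,
                   cfg: ClassifierConfig = DEFAULT_CONFIG):
    """Full single-session chain: mask artifacts, segment, match, classify.

    Returns (masked_record, breaths, efforts, match, events); efforts and
    match are None when the record has no Pes channel.
    """
    from .waveforms import mask_artifacts
    from .segmentation import detect_breaths, detect_efforts, match_efforts

    rec = mask_artifacts(record, cfg)
    breaths = detect_breaths(rec, cfg)
    if rec.pes is not None:
        efforts = detect_efforts(rec, cfg)
        match = match_efforts(breaths, efforts, cfg)
    else:
        efforts, match = None, None
    events = classify_session(rec, breaths, efforts, match, cfg)
    return rec, breaths, efforts, match, events
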