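"""Breath and effort segmentation primitives.

Machine breaths are located on the flow channel: inspiration onset at the
interpolated upward crossing of a flow-deflection threshold (validated by
a concurrent airway-pressure rise), and the inspiration-to-expiration
transition at the interpolated downward zero-crossing of flow after peak
inspiratory flow — the instant the exhalation valve opens in pressure
support.  Expiratory passivity is assessed by a least-squares exponential
fit of the decaying flow; deviations from log-linearity flag residual
patient activity.  Patient efforts are read from the esophageal-pressure
channel as negative deflections from an upper-quantile rolling baseline,
with the effort termination at the midpoint of the rapid post-nadir
pressure rise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import percentile_filter

from .config import ClassifierConfig, DEFAULT_CONFIG
from .waveforms import WaveformRecord, integrate_volume


@dataclass
class DecayFit:
    tau_s: Optional[float]
    r_squared: float
    window_start_s: float
    window_end_s: float
    is_passive: bool


@dataclass
class BreathSegment:
    onset_time_s: float
    cycle_time_s: float
    end_time_s: float
    peak_insp_flow_lpm: float
    v_insp_ml: float
    v_exp_ml: float
    passive_insp: bool = False
    passive_exp: bool = True

    @property
    def ti_s(self) -> float:
        return self.cycle_time_s - self.onset_time_s

    @property
    def te_s(self) -> float:
        return self.end_time_s - self.cycle_time_s


@dataclass
class EffortEvent:
    onset_time_s: float
    nadir_time_s: float
    termination_time_s: float
    amplitude_cmh2o: float


@dataclass
class MatchResult:
    links: list[dict]              # {effort_index, breath_index, response_time_ms}
    unmatched_breaths: list[int]   # machine-initiated / auto-trigger candidates
    unmatched_efforts: list[int]   # ineffective-effort candidates

    def breath_link(self, breath_index: int) -> Optional[dict]:
        for link in self.links:
            if link["breath_index"] == breath_index:
                return link
        return None


# ---------------------------------------------------------------------------
# Passive decay
# ---------------------------------------------------------------------------

def fit_passive_decay(flow_window: np.ndarray, sample_rate_hz: float,
                      cfg: ClassifierConfig = DEFAULT_CONFIG,
                      t_start_s: float = 0.0) -> DecayFit:
    """Least-squares exponential fit of |flow| over the window.

    Samples below ``decay_floor_lpm`` in magnitude are excluded.  The fit
    is passive when r^2 >= ``passive_r2_min`` and the time constant lies in
    [``tau_min_s``, ``tau_max_s``].
    """
    flow = np.asarray(flow_window, dtype=float)
    t_end = t_start_s + (len(flow) - 1) / sample_rate_hz if len(flow) else t_start_s
    usable = np.abs(flow) >= cfg.decay_floor_lpm
    if usable.sum() < 8:
        return DecayFit(None, 0.0, t_start_s, t_end, False)
    idx = np.flatnonzero(usable)
    t = idx / sample_rate_hz
    y = np.log(np.abs(flow[idx]))
    tc = t - t.mean()
    yc = y - y.mean()
    stt = float(tc @ tc)
    syy = float(yc @ yc)
    if syy < 1e-12:  # flat on log scale: no decay present
        return DecayFit(None, 0.0, t_start_s, t_end, False)
    sty = float(tc @ yc)
    slope = sty / stt
    r2 = (sty * sty) / (stt * syy)
    if slope >= 0:
        return DecayFit(None, r2, t_start_s, t_end, False)
    tau = -1.0 / slope
    passive = (r2 >= cfg.passive_r2_min) and (cfg.tau_min_s <= tau <= cfg.tau_max_s)
    return DecayFit(tau, r2, t_start_s, t_end, passive)


# ---------------------------------------------------------------------------
# Breath detection
# ---------------------------------------------------------------------------

def _interp_crossing(t0: float, t1: float, y0: float, y1: float,
                     level: float) -> float:
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def detect_breaths(record: WaveformRecord,
                   cfg: ClassifierConfig = DEFAULT_CONFIG) -> list[BreathSegment]:
    """Segment machine breaths from the flow (and airway pressure) channels."""
    flow = record.flow
    paw = record.paw
    fs = record.sample_rate_hz
    n = record.n_samples
    thr = cfg.breath_flow_onset_lpm

    below = flow[:-1] < thr
    above = flow[1:] >= thr
    crossings = np.flatnonzero(below & above)

    # Second candidate source: ventilator pressurization upswings on Paw.
    # A double-triggered second cycle starts with the lung still inflated,
    # so its flow may never reach the absolute threshold even though the
    # positive flow deflection and pressure rise are unmistakable.
    rise_win = max(1, int(round(cfg.paw_rise_win_s * fs)))
    dpaw = np.diff(paw) * fs
    slope_thr = cfg.paw_trigger_slope_cmh2o_per_s
    steep_idx = np.flatnonzero(dpaw >= slope_thr)
    paw_cands = []
    prev = -10
    for j in steep_idx:
        if j - prev > 2:  # first sample of each upswing only
            hi = min(n, j + rise_win + 1)
            if (paw[j:hi].max() - paw[j] >= cfg.paw_rise_min_cmh2o
                    and flow[j:hi].max() - flow[j] >= thr):
                paw_cands.append(j)
        prev = j
    candidates = sorted(set(crossings) | set(paw_cands))

    # Validate each candidate by a concurrent airway-pressure rise and
    # enforce a refractory interval between onsets.
    onsets: list[tuple[float, int]] = []
    last_t = -np.inf
    for i in candidates:
        if i + 1 < n and flow[i] < thr <= flow[i + 1]:
            t_on = record.t0_s + _interp_crossing(i / fs, (i + 1) / fs,
                                                  flow[i], flow[i + 1], thr)
        else:
            t_on = record.t0_s + i / fs
        if t_on - last_t < cfg.min_breath_interval_s:
            continue
        seg = paw[i:min(n, i + rise_win + 1)]
        if seg.max() - paw[i] < cfg.paw_rise_min_cmh2o:
            continue
        # Refine the onset to the ventilator trigger: a patient effort can
        # pull flow through the threshold before the machine pressurizes,
        # so locate the pressurization upswing on Paw and interpolate the
        # 25%-of-rise crossing.
        j0 = max(0, i - 5)
        j1 = min(n - 2, i + int(round(0.35 * fs)))
        steep = np.flatnonzero(dpaw[j0:j1 + 1] >= slope_thr)
        if len(steep):
            j = j0 + int(steep[0])
            base = float(np.median(paw[max(0, j - int(0.3 * fs)):j + 1]))
            plateau = float(np.max(paw[j:min(n, j + int(0.3 * fs) + 1)]))
            level = base + 0.25 * (plateau - base)
            jj = max(0, j - 1)
            while jj < j1 and not (paw[jj] < level <= paw[jj + 1]):
                jj += 1
            if paw[jj] < level <= paw[jj + 1]:
                t_ref = record.t0_s + _interp_crossing(
                    jj / fs, (jj + 1) / fs, paw[jj], paw[jj + 1], level)
                if t_ref - last_t >= cfg.min_breath_interval_s:
                    t_on = t_ref
                    i = jj
        onsets.append((t_on, i))
        last_t = t_on

    if not onsets:
        return []

    # Prefix integrals of the signed flow parts for per-phase volumes (mL).
    dt = 1.0 / fs
    pos = np.maximum(flow, 0.0)
    cum_pos = np.concatenate(([0.0],
                              np.cumsum((pos[:-1] + pos[1:]) * 0.5 * dt))) * 1000.0 / 60.0
    neg = np.minimum(flow, 0.0)
    cum_neg = np.concatenate(([0.0],
                              np.cumsum((neg[:-1] + neg[1:]) * 0.5 * dt))) * 1000.0 / 60.0

    segments: list[BreathSegment] = []
    prev_cycle_idx = 0
    for k, (t_on, i_on) in enumerate(onsets):
        i_next = onsets[k + 1][1] if k + 1 < len(onsets) else n - 1
        t_next = onsets[k + 1][0] if k + 1 < len(onsets) else record.t0_s + (n - 1) / fs
        if i_next <= i_on + 1:
            continue
        region = flow[i_on:i_next + 1]
        i_peak = i_on + int(np.argmax(region))
        peak = float(flow[i_peak])

        # Cycle: the ventilator's cycling instant.  The exhalation-valve
        # opening shows as a steep Paw downswing; prefer it, because under
        # late cycling the flow can cross zero long before the ventilator
        # cycles (the inflated lung's recoil exceeds the support level).
        # Fall back to the flow zero-crossing when Paw shows no valve edge.
        d0 = i_on + max(3, int(round(0.15 * fs)))
        down = np.flatnonzero(dpaw[d0:i_next] <= -slope_thr)
        t_cycle = None
        if len(down):
            j = d0 + int(down[0])
            top = float(paw[j])
            floor = float(np.min(paw[j:min(n, j + int(0.3 * fs) + 1)]))
            level = top - 0.25 * (top - floor)
            jj = max(i_on, j - 1)
            while jj < i_next and not (paw[jj] >= level > paw[jj + 1]):
                jj += 1
            if paw[jj] >= level > paw[jj + 1]:
                t_cycle = record.t0_s + _interp_crossing(
                    jj / fs, (jj + 1) / fs, paw[jj], paw[jj + 1], level)
                i_cycle = jj
        if t_cycle is None:
            seg = flow[i_peak:i_next + 1]
            strong = np.flatnonzero(seg < -2.0)
            if len(strong):
                j = i_peak + int(strong[0])
                while j > i_peak and flow[j - 1] < 0:
                    j -= 1
                j = max(i_peak, j - 1)
            else:
                negs = np.flatnonzero((seg[:-1] >= 0) & (seg[1:] < 0))
                if not len(negs):
                    # No expiration captured (record truncated mid-insp).
                    continue
                j = i_peak + int(negs[0])
            t_cycle = record.t0_s + _interp_crossing(j / fs, (j + 1) / fs,
                                                     flow[j], flow[j + 1], 0.0)
            i_cycle = j
        if not (t_on < t_cycle < t_next):
            continue

        # Inspired volume includes pre-trigger patient inflow: integrate
        # the positive flow part back to the previous cycle (bounded).
        i_start = max(prev_cycle_idx, i_on - int(fs))
        v_insp = float(cum_pos[i_cycle] - cum_pos[i_start])
        v_exp = float(-(cum_neg[i_next] - cum_neg[i_cycle]))
        prev_cycle_idx = i_cycle

        # Expiratory passivity over a window shortly after cycling.
        f0 = min(n - 1, i_cycle + 1 + int(round(cfg.decay_fit_delay_s * fs)))
        f1 = min(i_next, f0 + int(round(cfg.decay_fit_window_s * fs)))
        exp_fit = fit_passive_decay(flow[f0:f1 + 1], fs, cfg, t_start_s=f0 / fs)

        insp_fit = fit_passive_decay(flow[i_peak:i_cycle + 1], fs, cfg,
                                     t_start_s=i_peak / fs)

        segments.append(BreathSegment(
            onset_time_s=t_on, cycle_time_s=t_cycle, end_time_s=t_next,
            peak_insp_flow_lpm=peak, v_insp_ml=max(v_insp, 0.0),
            v_exp_ml=max(v_exp, 0.0),
            passive_insp=insp_fit.is_passive, passive_exp=exp_fit.is_passive))
    return segments


# ---------------------------------------------------------------------------
# Effort detection (esophageal pressure)
# ---------------------------------------------------------------------------

class PesUnavailableError(RuntimeError):
    """Raised when a Pes-based path is requested without a Pes channel."""


def detect_efforts(record: WaveformRecord,
                   cfg: ClassifierConfig = DEFAULT_CONFIG) -> list[EffortEvent]:
    """Detect inspiratory efforts as negative Pes deflections.

    Baseline is a centered rolling median; an effort is a contiguous
    negative deflection with amplitude >= ``pes_effort_min_cmh2o``.  Onset
    is the interpolated crossing of baseline - ``pes_onset_frac``*amplitude
    on the descending limb; termination is the interpolated midpoint
    crossing of the post-nadir rise.
    """
    if record.pes is None:
        raise PesUnavailableError("record has no esophageal-pressure channel")
    fs = record.sample_rate_hz
    n = record.n_samples
    # Light centered smoothing to stabilize threshold crossings.
    k = max(1, int(round(0.05 * fs)) | 1)
    kernel = np.ones(k) / k
    pes = np.convolve(record.pes, kernel, mode="same")
    # Upper-quantile rolling baseline: inspiratory efforts can occupy
    # close to half of a window, which would drag a rolling median inside
    # the effort envelope and hide weak efforts.
    win = max(3, int(round(cfg.pes_baseline_win_s * fs)) | 1)
    baseline = percentile_filter(pes, 70, size=win, mode="nearest")
    dev = baseline - pes  # positive during inspiratory effort

    seed_thr = 0.3 * cfg.pes_effort_min_cmh2o
    active = dev > seed_thr
    if not active.any():
        return []
    padded = np.concatenate(([False], active, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    regions = list(zip(edges[::2], edges[1::2]))

    max_scan = int(round(2.0 * fs))
    efforts: list[EffortEvent] = []
    for r, (start, stop) in enumerate(regions):
        seg = dev[start:stop]
        amp = float(seg.max())
        if amp < cfg.pes_effort_min_cmh2o:
            continue
        i_nadir = start + int(np.argmax(seg))
        t_nadir = record.t0_s + i_nadir / fs

        # Onset: walk left until dev falls below the onset fraction.  The
        # walk may not run into the preceding effort's region: for a weak
        # effort the onset threshold can be lower than the inter-effort
        # trough, which would swallow the neighbor.  The threshold is also
        # floored above the local quiet-expiration pedestal (chest-wall
        # recoil keeps Pes slightly below the upper-quantile baseline).
        i = i_nadir
        lo = max(0, i_nadir - max_scan,
                 regions[r - 1][1] if r > 0 else 0)
        pre = dev[max(lo, start - int(0.5 * fs)):max(start, lo + 1)]
        pedestal = float(np.median(pre)) if len(pre) else 0.0
        thr_on = max(cfg.pes_onset_frac * amp, pedestal + 0.2)
        while i > lo and dev[i - 1] > thr_on:
            i -= 1
        if i > 0 and dev[i - 1] <= thr_on <= dev[i]:
            t_onset = record.t0_s + _interp_crossing(
                (i - 1) / fs, i / fs, dev[i - 1], dev[i], thr_on)
        else:
            t_onset = record.t0_s + i / fs

        # Termination: walk right until dev falls below half amplitude,
        # bounded by the next effort's region.
        thr_term = 0.5 * amp
        j = i_nadir
        hi = min(n - 1, i_nadir + max_scan,
                 regions[r + 1][0] - 1 if r + 1 < len(regions) else n - 1)
        while j < hi and dev[j + 1] > thr_term:
            j += 1
        if j >= n - 1:
            continue  # effort truncated by record end
        t_term = record.t0_s + _interp_crossing(
            j / fs, (j + 1) / fs, dev[j], dev[j + 1], thr_term)

        if not (t_onset < t_nadir < t_term):
            continue
        efforts.append(EffortEvent(onset_time_s=t_onset, nadir_time_s=t_nadir,
                                   termination_time_s=t_term,
                                   amplitude_cmh2o=amp))
    efforts.sort(key=lambda e: e.onset_time_s)
    return efforts


# ---------------------------------------------------------------------------
# Effort-to-breath matching
# ---------------------------------------------------------------------------

def match_efforts(breaths: list[BreathSegment], efforts: list[EffortEvent],
                  cfg: ClassifierConfig = DEFAULT_CONFIG) -> MatchResult:
    """Greedy chronological one-to-one matching of efforts to breaths.

    Each effort links to the earliest unmatched breath whose onset lies in
    [effort.onset - pre_trigger_tol, effort.onset + match_window].
    """
    pre = cfg.pre_trigger_tol_ms / 1000.0
    win = cfg.match_window_ms / 1000.0
    taken = [False] * len(breaths)
    links: list[dict] = []
    unmatched_efforts: list[int] = []
    for ei, eff in enumerate(efforts):
        found = None
        for bi, br in enumerate(breaths):
            if taken[bi]:
                continue
            if br.onset_time_s < eff.onset_time_s - pre:
                continue
            if br.onset_time_s > eff.onset_time_s + win:
                break
            found = bi
            break
        if found is None:
            unmatched_efforts.append(ei)
        else:
            taken[found] = True
            links.append({
                "effort_index": ei,
                "breath_index": found,
                "response_time_ms":
                    1000.0 * (breaths[found].onset_time_s - eff.onset_time_s),
            })
    unmatched_breaths = [bi for bi, t in enumerate(taken) if not t]
    return MatchResult(links=links, unmatched_breaths=unmatched_breaths,
                       unmatched_efforts=unmatched_efforts)
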