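"""Random micro-session generator for classifier oracle checks.

Builds small abstract sessions (a handful of breaths, efforts with
assorted response times and cycling offsets, occasional unmatched
breaths with or without effort signatures, optional artifact windows)
together with the minimal waveforms the auto-trigger rule inspects.
"""

import numpy as np

from ventsync.segmentation import BreathSegment, EffortEvent, match_efforts
from ventsync.waveforms import WaveformRecord


def make_micro_session(rng, cfg, fs=50.0, max_breaths=12):
    n_breaths = int(rng.integers(3, max_breaths + 1))
    raw = []
    t = 2.0 + rng.uniform(0.0, 1.0)
    for _ in range(n_breaths):
        ti = rng.uniform(0.35, 0.9)
        cycle = t + ti
        if rng.random() < 0.2:  # occasionally a short interposed expiration
            gap = rng.uniform(0.05, 0.8) * ti
        else:
            gap = rng.uniform(0.8, 2.2)
        raw.append((t, cycle, cycle + gap))
        t = cycle + gap
    duration = t + 2.0

    n = int(duration * fs) + 1
    paw = np.full(n, 5.0) + rng.normal(0.0, 0.03, n)
    pes = np.full(n, 5.0) + rng.normal(0.0, 0.03, n)
    flow = np.zeros(n)

    breaths = []
    efforts = []
    for onset, cycle, end in raw:
        breaths.append(BreathSegment(onset, cycle, end, 15.0, 80.0, 75.0))
        if rng.random() < 0.75:
            # Patient-triggered: an effort somewhere around the onset, with
            # a cycling offset spanning early/acceptable/late.
            e_on = onset - rng.uniform(-0.05, 0.45)
            nadir = e_on + rng.uniform(0.10, 0.30)
            term = max(cycle + rng.uniform(-0.35, 0.35), nadir + 0.05)
            efforts.append(EffortEvent(e_on, nadir, term,
                                       rng.uniform(2.0, 10.0)))
        elif rng.random() < 0.5:
            # Machine cycle preceded by an effort signature the effort
            # detector "missed": not an auto-trigger.
            i1 = int((onset - 0.02) * fs)
            i0 = int((onset - 0.18) * fs)
            channel = paw if rng.random() < 0.5 else pes
            channel[i0:i1] -= 1.2
        # else: a clean unmatched breath, i.e. an auto-trigger.

    if rng.random() < 0.4:  # a stray unsupported effort mid-record
        e_on = rng.uniform(2.0, duration - 2.0)
        efforts.append(EffortEvent(e_on, e_on + 0.2, e_on + 0.45,
                                   rng.uniform(2.0, 6.0)))

    efforts.sort(key=lambda e: e.onset_time_s)
    mask = np.zeros(n, dtype=bool)
    if rng.random() < 0.3:
        j0 = int(rng.uniform(2.0, duration - 3.0) * fs)
        mask[j0:j0 + int(0.6 * fs)] = True

    record = WaveformRecord(sample_rate_hz=fs, paw=paw, flow=flow, pes=pes,
                            artifact_mask=mask)
    match = match_efforts(breaths, efforts, cfg)
    return record, breaths, efforts, match
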