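"""Independent brute-force reference for whole-session classification.

Re-implements each labeling rule directly from its published definition
with plain Python loops, then resolves precedence in the documented
order.  Deliberately shares no code with the package's classifier so the
two can disagree.
"""

import statistics


def _moving_avg3(values):
    return [sum(values[i:i + 3]) / 3.0 for i in range(len(values) - 2)]


def _window(record, t_lo, t_hi):
    i0 = record.index_at(t_lo)
    i1 = record.index_at(t_hi)
    return i0, i1


def _effort_signature(record, breath, cfg):
    """True when the pre-onset window shows a Paw or Pes deflection."""
    t1 = breath.onset_time_s - 0.01
    i0, i1 = _window(record, t1 - cfg.at_preonset_win_s, t1)
    if i1 - i0 < 3:
        return True  # cannot rule an effort out
    paw = _moving_avg3(list(record.paw[i0:i1 + 1]))
    if statistics.median(paw) - min(paw) >= cfg.at_paw_dip_cmh2o:
        return True
    if record.pes is not None:
        pes = _moving_avg3(list(record.pes[i0:i1 + 1]))
        if statistics.median(pes) - min(pes) >= cfg.at_pes_dip_cmh2o:
            return True
    return False


def reference_classify(record, breaths, efforts, match, cfg):
    """Return the event multiset as sorted (type, time, breath_index)."""
    events = []

    # Double breaths: Te between consecutive cycles <= ratio * Ti(first).
    db_first, db_second = set(), set()
    for k in range(len(breaths) - 1):
        first, second = breaths[k], breaths[k + 1]
        ti = first.cycle_time_s - first.onset_time_s
        te = second.onset_time_s - first.cycle_time_s
        if ti > 0 and 0 <= te <= cfg.db_te_ti_ratio * ti:
            events.append(("DB", second.onset_time_s, k + 1))
            db_first.add(k)
            db_second.add(k + 1)

    links = {l["breath_index"]: l for l in match.links}

    # Trigger phase: TD on matched breaths in the delay band; AT on
    # unmatched breaths without an effort signature.  DB second cycles
    # carry no trigger-phase label.
    for bi, breath in enumerate(breaths):
        if bi in db_second:
            continue
        if bi in links:
            rt = max(links[bi]["response_time_ms"], 0.0)
            if cfg.normal_trigger_max_ms < rt <= cfg.td_max_ms:
                events.append(("TD", breath.onset_time_s, bi))
        elif not _effort_signature(record, breath, cfg):
            events.append(("AT", breath.onset_time_s, bi))

    # Ineffective efforts: unmatched efforts, plus matched ones whose
    # response time exceeds the IE boundary (one per effort cycle).
    for ei in match.unmatched_efforts:
        events.append(("IE", efforts[ei].onset_time_s, None))
    for link in match.links:
        if max(link["response_time_ms"], 0.0) > cfg.td_max_ms:
            events.append(("IE", efforts[link["effort_index"]].onset_time_s,
                           link["breath_index"]))

    # Cycling phase on matched breaths; EC suppressed on DB first cycles.
    for link in match.links:
        bi = link["breath_index"]
        breath = breaths[bi]
        eff = efforts[link["effort_index"]]
        offset = 1000.0 * (eff.termination_time_s - breath.cycle_time_s)
        if offset >= cfg.ec_lc_offset_ms:
            if bi not in db_first:
                events.append(("EC", breath.cycle_time_s, bi))
        elif offset <= -cfg.ec_lc_offset_ms:
            events.append(("LC", breath.cycle_time_s, bi))

    kept = []
    for etype, t, bi in events:
        if record.artifact_mask[record.index_at(t)]:
            continue
        kept.append((etype, round(t, 6), bi))
    return sorted(kept)
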