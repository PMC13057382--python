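import numpy as np
import pytest

from ventsync.classifier import (analyze_record, classify_session,
                                 classify_trigger_timing, detect_cycling,
                                 detect_double_breath, detect_ie_flow,
                                 detect_ie_pes, severity_of)
from ventsync.segmentation import (BreathSegment, EffortEvent, MatchResult)
from ventsync.waveforms import WaveformRecord

from micro_sessions import make_micro_session
from reference_oracle import reference_classify

FS = 50.0


class TestTriggerTiming:
    @pytest.mark.parametrize("rt,expected", [
        (60.0, "normal"),
        (117.0, "normal"),   # boundary: (0, 117] is normal
        (117.5, "TD"),
        (150.0, "TD"),
        (234.0, "TD"),
        (235.0, "IE"),
    ])
    def test_bins(self, rt, expected, cfg):
        assert classify_trigger_timing(rt, cfg) == expected

    def test_negative_response_time_rejected(self, cfg):
        with pytest.raises(ValueError):
            classify_trigger_timing(-1.0, cfg)


def _breath(onset, ti, end=None):
    cycle = onset + ti
    return BreathSegment(onset, cycle, end if end is not None else cycle + 1.2,
                         15.0, 80.0, 75.0)


class TestDoubleBreath:
    @pytest.mark.parametrize("te,expect_db", [
        (0.3, True),    # 0.3 <= 0.4
        (0.4, True),    # equal to half of Ti counts
        (0.5, False),   # 0.5 > 0.4
    ])
    def test_te_ti_rule(self, te, expect_db, cfg):
        first = _breath(10.0, 0.8, end=10.8 + te)
        second = _breath(10.8 + te, 0.7)
        ev = detect_double_breath(first, second, cfg)
        assert (ev is not None) == expect_db
        if ev:
            assert severity_of(ev.type) == "major"


class TestCycling:
    @pytest.mark.parametrize("offset_ms,expected", [
        (150.0, "EC"), (-150.0, "LC"), (50.0, None),
        (101.0, "EC"), (-101.0, "LC"), (-50.0, None),
    ])
    def test_offset_thresholds(self, offset_ms, expected, cfg):
        breath = _breath(10.0, 0.6)
        term = breath.cycle_time_s + offset_ms / 1000.0
        effort = EffortEvent(10.0, 10.25, term, 6.0)
        label, measured = detect_cycling(breath, effort, cfg)
        assert label == expected
        assert measured == pytest.approx(offset_ms)


class TestIEPes:
    def test_unmatched_efforts_each_count_once(self, cfg):
        efforts = [EffortEvent(t, t + 0.2, t + 0.5, 4.0)
                   for t in (10.0, 14.0, 18.0)]
        match = MatchResult(links=[], unmatched_breaths=[],
                            unmatched_efforts=[0, 1, 2])
        events = detect_ie_pes(match, efforts, cfg)
        assert [ev.type for ev in events] == ["IE", "IE", "IE"]

    @pytest.mark.parametrize("rt,n_ie", [(300.0, 1), (90.0, 0)])
    def test_matched_effort_by_response_time(self, rt, n_ie, cfg):
        efforts = [EffortEvent(10.0, 10.2, 10.5, 6.0)]
        match = MatchResult(links=[{"effort_index": 0, "breath_index": 0,
                                    "response_time_ms": rt}],
                            unmatched_breaths=[], unmatched_efforts=[])
        assert len(detect_ie_pes(match, efforts, cfg)) == n_ie


class TestIEFlow:
    def _expiration_record(self, paw_drop, duration=12.0):
        """One breath then passive expiration with a notch + Paw dip."""
        n = int(duration * FS) + 1
        t = np.arange(n) / FS
        flow = np.zeros(n)
        paw = np.full(n, 5.0)
        i0, i1 = int(5.0 * FS), int(5.8 * FS)
        flow[i0:i1] = 14.0
        paw[i0:i1] = 13.5
        te = t[i1:] - t[i1]
        flow[i1:] = -28.0 * np.exp(-te / 0.35)
        # Notch toward zero at 1.0 s into expiration, with a Paw dip.
        j0 = i1 + int(1.0 * FS)
        bump = 6.0 * np.sin(np.pi * np.arange(0, 15) / 15)
        flow[j0:j0 + 15] += bump
        paw[j0:j0 + 15] -= paw_drop * np.sin(np.pi * np.arange(0, 15) / 15)
        return WaveformRecord(sample_rate_hz=FS, paw=paw, flow=flow)

    def test_notch_with_sufficient_paw_drop_is_ie(self, cfg):
        rec = self._expiration_record(paw_drop=0.7)
        breaths = [_breath(5.0, 0.8, end=11.5)]
        events = detect_ie_flow(rec, breaths[0], cfg)
        assert [ev.type for ev in events] == ["IE"]
        assert events[0].time_s == pytest.approx(5.8 + 1.0, abs=0.2)

    def test_same_notch_below_half_cmh2o_is_not_ie(self, cfg):
        rec = self._expiration_record(paw_drop=0.3)
        assert detect_ie_flow(rec, _breath(5.0, 0.8, end=11.5), cfg) == []

    def test_clean_passive_expiration_has_no_ie(self, cfg):
        n = int(12.0 * FS) + 1
        t = np.arange(n) / FS
        flow = np.zeros(n)
        paw = np.full(n, 5.0)
        i0, i1 = int(5.0 * FS), int(5.8 * FS)
        flow[i0:i1] = 14.0
        paw[i0:i1] = 13.5
        flow[i1:] = -28.0 * np.exp(-(t[i1:] - t[i1]) / 0.35)
        rec = WaveformRecord(sample_rate_hz=FS, paw=paw, flow=flow)
        assert detect_ie_flow(rec, _breath(5.0, 0.8, end=11.5), cfg) == []


class TestSessionClassification:
    def test_zero_injection_session_yields_no_events(self, clean_session, cfg):
        _, _, _, _, events = analyze_record(clean_session.record, cfg)
        assert events == []

    def test_events_in_masked_windows_dropped(self, cfg):
        rng = np.random.default_rng(1)
        record, breaths, efforts, match = make_micro_session(rng, cfg)
        events = classify_session(record, breaths, efforts, match, cfg)
        if not events:
            pytest.skip("fixture produced no events")
        # Mask a window around the first event and reclassify.
        t0 = events[0].time_s
        masked = record.copy()
        i = masked.index_at(t0)
        masked.artifact_mask[max(0, i - 5):i + 5] = True
        again = classify_session(masked, breaths, efforts, match, cfg)
        assert all(abs(ev.time_s - t0) > 1e-9 for ev in again)

    def test_ie_paw_drop_threshold_monotonicity(self, cfg):
        fixture = TestIEFlow()._expiration_record(paw_drop=0.7)
        breath = _breath(5.0, 0.8, end=11.5)
        counts = [len(detect_ie_flow(fixture, breath,
                                     cfg.with_overrides(ie_paw_drop_cmh2o=thr)))
                  for thr in (0.2, 0.5, 0.9, 2.0)]
        assert counts == sorted(counts, reverse=True)

    def test_ec_lc_offset_threshold_monotonicity(self, cfg):
        breath = _breath(10.0, 0.6)
        offsets = [-220.0, -130.0, -60.0, 40.0, 90.0, 150.0, 260.0]
        efforts = [EffortEvent(10.0, 10.2, breath.cycle_time_s + o / 1000.0, 5.0)
                   for o in offsets]

        def n_cycling(thr_ms):
            c = cfg.with_overrides(ec_lc_offset_ms=thr_ms)
            return sum(detect_cycling(breath, e, c)[0] is not None
                       for e in efforts)

        counts = [n_cycling(t) for t in (250.0, 150.0, 100.0, 50.0)]
        assert counts == sorted(counts)

    def test_matches_reference_on_micro_sessions(self, cfg):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            record, breaths, efforts, match = make_micro_session(rng, cfg)
            got = sorted((ev.type, round(ev.time_s, 6), ev.breath_index)
                         for ev in classify_session(record, breaths, efforts,
                                                    match, cfg))
            expected = reference_classify(record, breaths, efforts, match, cfg)
            assert got == expected

    def test_recovers_injected_events_with_high_fidelity(self, cfg):
        from ventsync.pipeline import _confusion_for, evaluate_session
        from ventsync.simulator import (AsynchronyProfile, PatientModel,
                                        VentSettings, simulate_session)
        tot = {t: {"tp": 0, "fn": 0, "fp": 0}
               for t in ("AT", "DB", "IE", "TD", "EC", "LC")}
        for seed in range(3):
            s = simulate_session(PatientModel(), VentSettings(),
                                 AsynchronyProfile(), 600.0, seed=seed)
            res = evaluate_session(s, cfg)
            for t, c in _confusion_for(res["truth"], res["events"]).items():
                for k in c:
                    tot[t][k] += c[k]
        for t, c in tot.items():
            n_truth = c["tp"] + c["fn"]
            if n_truth:
                assert c["tp"] / n_truth >= 0.9, f"{t} sensitivity low: {c}"
            if c["tp"] + c["fp"]:
                assert c["tp"] / (c["tp"] + c["fp"]) >= 0.9, f"{t}: {c}"
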