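import numpy as np
import pytest

from ventsync.segmentation import (BreathSegment, EffortEvent,
                                   PesUnavailableError, detect_breaths,
                                   detect_efforts, fit_passive_decay,
                                   match_efforts)
from ventsync.simulator import _pmus_profile
from ventsync.waveforms import WaveformRecord

FS = 50.0


def _record(paw, flow, pes=None):
    return WaveformRecord(sample_rate_hz=FS, paw=np.asarray(paw, float),
                          flow=np.asarray(flow, float), pes=pes)


class TestPassiveDecay:
    def test_exact_exponential_recovered(self, cfg):
        t = np.arange(0, 0.5, 1 / FS)
        fit = fit_passive_decay(-30.0 * np.exp(-t / 0.3), FS, cfg)
        assert fit.is_passive
        assert fit.tau_s == pytest.approx(0.3, rel=0.01)
        assert fit.r_squared >= 0.999

    def test_constant_flow_is_not_passive(self, cfg):
        fit = fit_passive_decay(np.full(30, 8.0), FS, cfg)
        assert not fit.is_passive
        assert fit.r_squared == pytest.approx(0.0, abs=1e-6)

    def test_notch_breaks_log_linearity(self, cfg):
        t = np.arange(0, 0.6, 1 / FS)
        flow = -30.0 * np.exp(-t / 0.3)
        flow[12:18] *= 0.3  # mid-window deviation toward zero
        fit = fit_passive_decay(flow, FS, cfg)
        assert not fit.is_passive

    def test_too_few_usable_samples_fails(self, cfg):
        fit = fit_passive_decay(np.array([-5.0, -4.0, -3.0]), FS, cfg)
        assert not fit.is_passive
        assert fit.tau_s is None

    def test_tau_outside_bounds_not_passive(self, cfg):
        t = np.arange(0, 1.0, 1 / FS)
        fit = fit_passive_decay(-30.0 * np.exp(-t / 3.0), FS, cfg)
        assert fit.tau_s is not None and fit.tau_s > cfg.tau_max_s
        assert not fit.is_passive


def _square_breath_record(onset=5.0, ti=1.0, duration=12.0):
    n = int(duration * FS) + 1
    t = np.arange(n) / FS
    flow = np.zeros(n)
    paw = np.full(n, 5.0)
    i0, i1 = int(onset * FS), int((onset + ti) * FS)
    flow[i0:i1] = 12.0
    flow[i1:] = -25.0 * np.exp(-(t[i1:] - (onset + ti)) / 0.3)
    paw[i0:i1] = 14.0
    return _record(paw, flow)


class TestBreathDetection:
    def test_single_square_breath_ti(self, cfg):
        segs = detect_breaths(_square_breath_record(), cfg)
        assert len(segs) == 1
        assert segs[0].ti_s == pytest.approx(1.0, abs=0.04)

    def test_all_zero_flow_yields_no_breaths(self, cfg):
        segs = detect_breaths(_record(np.full(600, 5.0), np.zeros(600)), cfg)
        assert segs == []

    def test_simulated_onsets_near_ground_truth(self, clean_session, cfg):
        segs = detect_breaths(clean_session.record, cfg)
        truth = np.array(clean_session.machine_breath_times)
        onsets = np.array([s.onset_time_s for s in segs])
        assert abs(len(segs) - len(truth)) <= 1
        matched = [np.min(np.abs(onsets - t)) for t in truth
                   if truth[0] <= t <= onsets[-1]]
        assert np.max(matched) < 0.04

    def test_breath_count_matches_truth_across_seeds(self, cfg):
        from ventsync.simulator import (AsynchronyProfile, PatientModel,
                                        VentSettings, simulate_session)
        profile = AsynchronyProfile(rates_per_min={
            k: 0.0 for k in ("IE", "AT", "DB", "TD", "EC", "LC")})
        exact = 0
        n_seeds = 10
        for seed in range(n_seeds):
            s = simulate_session(PatientModel(), VentSettings(), profile,
                                 duration_s=120.0, seed=seed)
            segs = detect_breaths(s.record, cfg)
            exact += int(len(segs) == s.n_machine_breaths)
        assert exact >= int(0.95 * n_seeds)

    def test_translation_invariance(self, cfg):
        rec = _square_breath_record()
        k = 40  # shift by 0.8 s
        shifted = _record(np.concatenate((np.full(k, 5.0), rec.paw)),
                          np.concatenate((np.zeros(k), rec.flow)))
        a = detect_breaths(rec, cfg)
        b = detect_breaths(shifted, cfg)
        assert len(a) == len(b) == 1
        assert b[0].onset_time_s - a[0].onset_time_s == pytest.approx(
            k / FS, abs=1e-9)
        assert b[0].cycle_time_s - a[0].cycle_time_s == pytest.approx(
            k / FS, abs=1e-9)


class TestEffortDetection:
    def _pes_record(self, bursts, duration=10.0, noise=0.0, seed=0):
        n = int(duration * FS) + 1
        t = np.arange(n) / FS
        pes = np.full(n, 5.0)
        for onset, rise, plateau, fall, amp in bursts:
            pes -= _pmus_profile(t, onset, rise, plateau, fall, amp)
        if noise:
            pes = pes + np.random.default_rng(seed).normal(0, noise, n)
        return _record(np.full(n, 5.0), np.zeros(n), pes=pes)

    def test_single_burst_termination_at_relaxation_midpoint(self, cfg):
        # Midpoint of the relaxation: onset + rise + plateau + fall/2.
        rec = self._pes_record([(4.0, 0.2, 0.25, 0.35, 8.0)])
        efforts = detect_efforts(rec, cfg)
        assert len(efforts) == 1
        assert efforts[0].termination_time_s == pytest.approx(4.625, abs=0.04)
        assert efforts[0].amplitude_cmh2o == pytest.approx(8.0, abs=0.3)

    def test_flat_pes_with_noise_yields_no_efforts(self, cfg):
        rec = self._pes_record([], noise=0.1)
        assert detect_efforts(rec, cfg) == []

    def test_two_efforts_stay_separate(self, cfg):
        rec = self._pes_record([(3.0, 0.2, 0.2, 0.3, 6.0),
                                (5.0, 0.2, 0.2, 0.3, 6.0)])
        efforts = detect_efforts(rec, cfg)
        assert len(efforts) == 2
        assert efforts[0].onset_time_s < efforts[1].onset_time_s
        assert efforts[1].onset_time_s == pytest.approx(
            efforts[0].onset_time_s + 2.0, abs=0.08)

    def test_missing_pes_channel_raises(self, cfg):
        rec = _record(np.full(600, 5.0), np.zeros(600))
        with pytest.raises(PesUnavailableError):
            detect_efforts(rec, cfg)


def _breath(onset, ti=0.6):
    return BreathSegment(onset, onset + ti, onset + ti + 1.0, 15.0, 80.0, 75.0)


def _effort(onset):
    return EffortEvent(onset, onset + 0.2, onset + 0.5, 6.0)


class TestMatching:
    def test_simple_link_response_time(self, cfg):
        match = match_efforts([_breath(10.050)], [_effort(10.000)], cfg)
        assert len(match.links) == 1
        assert match.links[0]["response_time_ms"] == pytest.approx(50.0)

    def test_effort_without_breath_in_window_unmatched(self, cfg):
        match = match_efforts([_breath(11.0)], [_effort(10.0)], cfg)
        assert match.unmatched_efforts == [0]
        assert match.unmatched_breaths == [0]

    def test_two_efforts_one_breath(self, cfg):
        match = match_efforts([_breath(10.1)],
                              [_effort(10.0), _effort(10.4)], cfg)
        assert len(match.links) == 1
        assert match.links[0]["effort_index"] == 0
        assert match.unmatched_efforts == [1]

    def test_greedy_matches_as_many_pairs_as_exhaustive_search(self, cfg):
        rng = np.random.default_rng(42)
        pre = cfg.pre_trigger_tol_ms / 1000.0
        win = cfg.match_window_ms / 1000.0
        for _ in range(60):
            nb, ne = rng.integers(1, 7), rng.integers(1, 7)
            breaths = sorted(rng.uniform(0, 8, nb))
            efforts = sorted(rng.uniform(0, 8, ne))
            b_objs = [_breath(t) for t in breaths]
            e_objs = [_effort(t) for t in efforts]
            got = len(match_efforts(b_objs, e_objs, cfg).links)

            # Exhaustive maximum one-to-one assignment.
            def best_from(ei, used):
                if ei == ne:
                    return 0
                best = best_from(ei + 1, used)
                for bi in range(nb):
                    if bi not in used and \
                            efforts[ei] - pre <= breaths[bi] <= efforts[ei] + win:
                        best = max(best,
                                   1 + best_from(ei + 1, used | {bi}))
                return best

            assert got == best_from(0, frozenset())
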