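"""Synthetic pediatric pressure-support ventilation sessions.

The simulator emulates a spontaneously breathing pediatric patient on
pressure support through a single-compartment equation of motion,

    flow = (Paw - PEEP + Pmus - V/C) / R,
    Pes  = Pes_baseline + Ecw * V - Pmus,

with inspiratory muscle pressure Pmus modeled as a smooth burst: a
short half-cosine activation ramp, a sustained plateau, and a brisk
half-cosine relaxation (muscle relaxation is fast relative to the
activation, and the ramp is short regardless of Ti).  The ventilator is
a state machine: it triggers a fixed latency after the neural onset
(short in the closed-loop emulation, longer and more variable in the
conventional arm), pressurizes exponentially toward PEEP+PS with a time
constant set by the pressure ramp, and cycles into expiration around the
patient's neural inspiratory termination — the conventional arm emulates
a physician-tailored expiratory trigger whose realized cycling instant
scatters around the neural termination, while the closed-loop arm cycles
on the simulated neural termination itself and is synchronous by
construction.

Asynchronies are injected per breath by Bernoulli thinning against
per-minute target rates, at most one anomaly per breath, and every
realized event is written to a ground-truth log with its realized metric:

* TD — trigger latency drawn inside the trigger-delay band;
* EC/LC — the machine cycle forced early/late relative to the neural
  termination by a drawn offset;
* DB — a rapid second machine cycle with a brief interposed expiration;
* AT — an extra machine cycle with no underlying effort;
* IE — an additional weak, unsupported effort during expiration;
* cough — a brief positive flow/Pes transient (artifact, not an
  asynchrony).

The closed-loop arm is an idealized, oracle-synchronized emulation of a
waveform-driven synchronization controller; it does not reproduce any
proprietary algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .waveforms import WaveformRecord


class ProfileError(ValueError):
    """Infeasible asynchrony-injection configuration."""


# Documented per-profile mechanics ranges (R in cmH2O.s/L, C in mL/cmH2O),
# centered on plausible infant/toddler values.
PROFILE_RANGES = {
    "normal":      {"R": (20.0, 30.0), "C": (10.0, 16.0)},
    "obstructive": {"R": (40.0, 60.0), "C": (10.0, 16.0)},
    "restrictive": {"R": (20.0, 30.0), "C": (5.0, 8.0)},
    "mixed":       {"R": (32.0, 48.0), "C": (6.0, 10.0)},
}

@dataclass(frozen=True)
class PatientModel:
    resistance_cmh2o_s_per_l: float = 38.0
    compliance_ml_per_cmh2o: float = 8.0
    chest_wall_elastance_cmh2o_per_ml: float = 0.004
    pmus_max_cmh2o: float = 8.0
    neural_rate_bpm: float = 28.0
    neural_ti_s: float = 0.60
    rate_variability_cv: float = 0.08
    pes_baseline_cmh2o: float = 5.0
    leak_frac: float = 0.06
    noise_sd: dict = field(default_factory=lambda: {
        "paw": 0.15, "flow": 0.4, "pes": 0.12, "etco2": 0.3, "spo2": 0.15})
    physiology_profile: str = "mixed"

    def __post_init__(self) -> None:
        if self.resistance_cmh2o_s_per_l <= 0 or self.compliance_ml_per_cmh2o <= 0:
            raise ValueError("R and C must be positive")
        if self.neural_ti_s >= 60.0 / self.neural_rate_bpm:
            raise ValueError("neural_ti_s must be shorter than the breath period")
        if self.physiology_profile not in PROFILE_RANGES:
            raise ValueError(f"unknown physiology profile {self.physiology_profile!r}")


@dataclass(frozen=True)
class VentSettings:
    ps_cmh2o: float = 8.5
    peep_cmh2o: float = 5.0
    fio2_pct: float = 30.0
    p_ramp_ms: float = 50.0
    flow_trigger_lpm: float = 0.75
    ets_pct: float = 30.0
    sync_mode: str = "conventional"
    max_ti_s: float = 1.3

    def __post_init__(self) -> None:
        if self.sync_mode not in ("conventional", "closed_loop_emulated"):
            raise ValueError(f"unknown sync_mode {self.sync_mode!r}")
        if not (0 < self.ets_pct < 100):
            raise ValueError("ets_pct must be in (0, 100)")
        for name in ("p_ramp_ms", "flow_trigger_lpm", "max_ti_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_RATES = {"IE": 0.7, "AT": 0.45, "DB": 0.3,
                 "TD": 1.25, "EC": 1.0, "LC": 0.25}

# Closed-loop arm: large reductions in AT/DB/TD/EC, no change in IE, and a
# slight increase in LC, mirroring the directionality observed in the trial.
DEFAULT_ARM_EFFECT = {"IE": 1.0, "AT": 0.33, "DB": 0.125,
                      "TD": 0.15, "EC": 0.07, "LC": 1.8}


@dataclass(frozen=True)
class AsynchronyProfile:
    rates_per_min: dict = field(default_factory=lambda: dict(DEFAULT_RATES))
    ie_effort_frac: float = 0.35
    td_latency_range_ms: tuple = (165.0, 220.0)
    ec_offset_range_ms: tuple = (200.0, 400.0)
    lc_offset_range_ms: tuple = (200.0, 400.0)
    db_gap_ti_frac_range: tuple = (0.20, 0.45)
    cough_rate_per_min: float = 0.0

    def __post_init__(self) -> None:
        for k, v in self.rates_per_min.items():
            if k not in DEFAULT_RATES:
                raise ProfileError(f"unknown asynchrony type {k!r}")
            if not np.isfinite(v) or v < 0:
                raise ProfileError(f"rate for {k} must be finite and nonnegative")
        lo, hi = self.td_latency_range_ms
        if not (117.0 < lo <= hi <= 234.0):
            raise ProfileError("TD latency injection must lie in (117, 234] ms")
        if self.ec_offset_range_ms[0] < 100.0 or self.lc_offset_range_ms[0] < 100.0:
            raise ProfileError("EC/LC offset injection must be >= 100 ms")

    def scaled(self, factors: dict) -> "AsynchronyProfile":
        rates = {k: v * factors.get(k, 1.0) for k, v in self.rates_per_min.items()}
        return replace(self, rates_per_min=rates)


@dataclass
class GroundTruthEntry:
    time_s: float
    kind: str            # IE, AT, DB, TD, EC, LC or cough
    true_metric: Optional[float] = None


@dataclass
class SimSession:
    record: WaveformRecord
    truth: list
    n_machine_breaths: int
    machine_breath_times: list
    comfort_b: int
    settings: VentSettings
    patient: PatientModel
    seed: int


@dataclass
class PatientPair:
    patient_id: str
    order: str           # 'conventional_first' or 'closed_loop_first'
    conventional: SimSession
    closed_loop: SimSession
    patient: PatientModel


@dataclass
class CrossoverDataset:
    patients: list
    seed: int


def truth_counts(truth: list) -> dict:
    counts = {t: 0 for t in ("IE", "AT", "DB", "TD", "EC", "LC", "cough")}
    for entry in truth:
        counts[entry.kind] += 1
    return counts


def truth_ai_pct(session: SimSession) -> float:
    """Ground-truth Asynchrony Index from the injection log."""
    c = truth_counts(session.truth)
    denom = session.n_machine_breaths + c["IE"]
    events = c["IE"] + c["AT"] + c["DB"] + c["TD"] + c["EC"] + c["LC"]
    return 100.0 * events / denom


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------

def _pmus_profile(t: np.ndarray, onset: float, rise_s: float,
                  plateau_s: float, fall_s: float,
                  amplitude: float) -> np.ndarray:
    """Smooth muscle-pressure burst: a short half-cosine activation ramp,
    a sustained plateau, and a brisk half-cosine relaxation.  The ramp is
    short and roughly constant across patients (neural drive recruits
    quickly), so effort-onset timing is uniform regardless of Ti."""
    tau = t - onset
    out = np.zeros_like(t)
    m1 = (tau >= 0) & (tau < rise_s)
    out[m1] = amplitude * 0.5 * (1.0 - np.cos(np.pi * tau[m1] / rise_s))
    m2 = (tau >= rise_s) & (tau < rise_s + plateau_s)
    out[m2] = amplitude
    t3 = rise_s + plateau_s
    m3 = (tau >= t3) & (tau <= t3 + fall_s)
    out[m3] = amplitude * 0.5 * (1.0 + np.cos(np.pi * (tau[m3] - t3)
                                              / fall_s))
    return out


def _burst_timing(ti_n: float) -> tuple[float, float, float]:
    """(rise, plateau, fall) such that onset-to-relaxation-midpoint equals
    roughly ti_n, with a short fixed-scale activation ramp."""
    fall = min(0.35, 0.7 * ti_n)
    rise = min(0.20, 0.40 * ti_n)
    plateau = max(0.0, ti_n - rise - 0.5 * fall)
    return rise, plateau, fall


def simulate_session(patient: PatientModel, vent: VentSettings,
                     profile: AsynchronyProfile, duration_s: float,
                     seed: int, sample_rate_hz: float = 50.0,
                     etco2_mean_mmhg: float = 43.0,
                     spo2_mean_pct: float = 96.0,
                     comfort_b_median: int = 14,
                     meta: Optional[dict] = None) -> SimSession:
    """Simulate one session; identical inputs and seed give bit-identical
    output.  Raises :class:`ProfileError` if the per-breath injection
    probabilities sum beyond one."""
    if duration_s < 60:
        raise ValueError("duration_s must be at least 60 s")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fs = sample_rate_hz
    ttot_nom = 60.0 / patient.neural_rate_bpm
    p_inject = {k: v * ttot_nom / 60.0
                for k, v in profile.rates_per_min.items()}
    p_inject["cough"] = profile.cough_rate_per_min * ttot_nom / 60.0
    if sum(p_inject.values()) > 1.0:
        raise ProfileError("per-breath injection probabilities sum beyond 1; "
                           "lower the rates or the respiratory rate")
    kinds = list(p_inject)
    probs = np.array([p_inject[k] for k in kinds])
    probs = np.concatenate((probs, [1.0 - probs.sum()]))
    kinds.append("none")

    closed_loop = vent.sync_mode == "closed_loop_emulated"

    # ----- neural rhythm -------------------------------------------------
    onsets = []
    t = 2.0 + rng.uniform(0.0, ttot_nom)
    while t < duration_s - 3.0:
        onsets.append(t)
        t += ttot_nom * np.exp(rng.normal(0.0, patient.rate_variability_cv))

    # ----- breath-by-breath plan ----------------------------------------
    efforts = []          # (onset, rise, plateau, fall, amplitude)
    machine = []          # (trigger, cycle)
    truth: list = []
    coughs = []

    for k, o in enumerate(onsets):
        nxt = onsets[k + 1] if k + 1 < len(onsets) else duration_s - 1.0
        amp = patient.pmus_max_cmh2o * np.exp(rng.normal(0.0, 0.15))
        ti_n = patient.neural_ti_s * np.exp(rng.normal(0.0, 0.05))
        # Neural Ti runs from the onset to the midpoint of the relaxation
        # (the Pes termination landmark): ti_n = rise + plateau + fall/2.
        rise, plateau, fall = _burst_timing(ti_n)
        t_act = rise + plateau + fall
        cap = 0.55 * (nxt - o)
        if t_act > cap:
            k_sc = cap / t_act
            rise, plateau, fall = rise * k_sc, plateau * k_sc, fall * k_sc
            t_act = cap
        ti_n = rise + plateau + 0.5 * fall
        term = o + ti_n

        anomaly = kinds[rng.choice(len(kinds), p=probs)]

        if closed_loop:
            latency = rng.uniform(0.015, 0.035)
        else:
            latency = rng.uniform(0.040, 0.070)
        if anomaly == "TD":
            lo, hi = profile.td_latency_range_ms
            latency = rng.uniform(lo, hi) / 1000.0
        trig = o + latency

        if closed_loop:
            cycle = term + rng.uniform(0.010, 0.040)
        else:
            cycle = term + rng.normal(0.0, 0.020)
        if anomaly == "EC":
            cycle = term - rng.uniform(*profile.ec_offset_range_ms) / 1000.0
        elif anomaly == "LC":
            cycle = term + rng.uniform(*profile.lc_offset_range_ms) / 1000.0
        cycle = min(cycle, trig + vent.max_ti_s, nxt - 0.35)
        cycle = max(cycle, trig + 0.20)

        efforts.append((o, rise, plateau, fall, amp))
        machine.append((trig, cycle))

        if anomaly == "TD":
            truth.append(GroundTruthEntry(trig, "TD", latency * 1000.0))
        elif anomaly in ("EC", "LC"):
            truth.append(GroundTruthEntry(cycle, anomaly,
                                          (term - cycle) * 1000.0))
        elif anomaly == "DB":
            ti1 = cycle - trig
            gap = rng.uniform(*profile.db_gap_ti_frac_range) * ti1
            trig2 = cycle + gap
            cyc2 = trig2 + rng.uniform(0.5, 0.8) * ti1
            if cyc2 < nxt - 0.30:
                machine.append((trig2, cyc2))
                truth.append(GroundTruthEntry(trig2, "DB", gap / ti1))
        elif anomaly == "AT":
            ti_at = rng.uniform(0.5, 0.8) * (cycle - trig)
            # Place the spurious cycle in quiet expiration, clear of the
            # preceding effort's relaxation tail.
            lo_t = max(cycle + 0.30, o + t_act + 0.25)
            hi_t = nxt - 0.30 - ti_at
            if lo_t < hi_t:
                t_at = rng.uniform(lo_t, hi_t)
                machine.append((t_at, t_at + ti_at))
                truth.append(GroundTruthEntry(t_at, "AT"))
        elif anomaly == "IE":
            rise_ie, plat_ie, fall_ie = _burst_timing(0.55 * ti_n)
            t_act_ie = rise_ie + plat_ie + fall_ie
            # A distinct unsupported effort: strictly after the main
            # effort's activation has relaxed, with room before the next.
            lo_t = max(cycle + 0.20 * (nxt - cycle), o + t_act + 0.15)
            hi_t = nxt - max(t_act_ie + 0.15, 0.70)
            if lo_t < hi_t:
                e_o = rng.uniform(lo_t, hi_t)
                a_ie = (patient.pmus_max_cmh2o * profile.ie_effort_frac
                        * np.exp(rng.normal(0.0, 0.10)))
                efforts.append((e_o, rise_ie, plat_ie, fall_ie, a_ie))
                truth.append(GroundTruthEntry(e_o, "IE"))
        elif anomaly == "cough":
            t_c = cycle + rng.uniform(0.25, 0.50) * (nxt - cycle)
            if t_c + 0.40 < nxt:
                coughs.append(t_c)
                truth.append(GroundTruthEntry(t_c, "cough"))

    machine.sort()
    truth.sort(key=lambda e: e.time_s)

    # ----- waveform synthesis -------------------------------------------
    # The mechanics are integrated on an oversampled internal grid (the
    # ventilator samples far faster internally than it streams): trigger
    # and valve transitions are near-discontinuous, and integrating flow
    # at the output rate alone would violate volume conservation by a few
    # percent per breath.
    oversample = 4
    fs_i = fs * oversample
    n = int(round(duration_s * fs)) + 1
    n_i = (n - 1) * oversample + 1
    tgrid = np.arange(n_i) / fs_i
    dt_i = 1.0 / fs_i

    pmus = np.zeros(n_i)
    for o, rise, plateau, fall, amp in efforts:
        i0 = max(0, int(o * fs_i) - 1)
        i1 = min(n_i, int((o + rise + plateau + fall) * fs_i) + 2)
        pmus[i0:i1] += _pmus_profile(tgrid[i0:i1], o, rise, plateau, fall, amp)

    peep, ps = vent.peep_cmh2o, vent.ps_cmh2o
    tau_ramp = max(vent.p_ramp_ms, 10.0) / 1000.0 / 3.0
    tau_valve = 0.04
    paw = np.full(n_i, peep)
    insp_mask = np.zeros(n_i, dtype=bool)
    for bi, (trig, cyc) in enumerate(machine):
        i0, i1 = int(np.ceil(trig * fs_i)), int(np.floor(cyc * fs_i))
        nxt_trig = machine[bi + 1][0] if bi + 1 < len(machine) else duration_s
        i2 = min(n_i - 1, int(np.floor(nxt_trig * fs_i)))
        if i1 <= i0 or i1 >= n_i:
            continue
        seg = tgrid[i0:i1 + 1] - trig
        paw[i0:i1 + 1] = peep + ps * (1.0 - np.exp(-seg / tau_ramp))
        insp_mask[i0:i1 + 1] = True
        p_cyc = paw[i1] - peep
        seg2 = tgrid[i1 + 1:i2 + 1] - cyc
        paw[i1 + 1:i2 + 1] = peep + p_cyc * np.exp(-seg2 / tau_valve)

    # Demand-valve dip: effort against the circuit outside machine insp.
    dip = 0.3 * pmus * (~insp_mask)
    paw = paw - dip

    # Equation of motion, solved with an exact one-step exponential
    # integrator expressed as a first-order IIR filter.
    R = patient.resistance_cmh2o_s_per_l
    C = patient.compliance_ml_per_cmh2o
    tau_rc = R * C / 1000.0
    alpha = np.exp(-dt_i / tau_rc)
    u = (paw - peep) + pmus
    vol_true = lfilter([(1.0 - alpha) * C], [1.0, -alpha], u)
    flow_lpm = (u - vol_true / C) / R * 60.0

    pes = (patient.pes_baseline_cmh2o
           + patient.chest_wall_elastance_cmh2o_per_ml * vol_true - pmus)

    # Leak: a constant fraction of inspired volume never returns through
    # the expiratory limb; the recorded expiratory flow is scaled down.
    flow_rec = flow_lpm.copy()
    flow_rec[flow_rec < 0] *= (1.0 - patient.leak_frac)

    for t_c in coughs:
        i0 = int(t_c * fs_i)
        i1 = min(n_i, i0 + int(0.20 * fs_i))
        burst = np.sin(np.pi * np.arange(i1 - i0) / (i1 - i0))
        flow_rec[i0:i1] += 25.0 * burst
        pes[i0:i1] += 6.0 * burst

    # Ventilator volume display: internal-rate integral of the recorded
    # flow, reset at each machine trigger.
    cum = np.concatenate(([0.0], np.cumsum(
        (flow_rec[:-1] + flow_rec[1:]) * 0.5 * dt_i))) * 1000.0 / 60.0
    vol = cum.copy()
    trig_idx = [min(n_i - 1, int(np.ceil(tr * fs_i))) for tr, _ in machine]
    bounds = trig_idx + [n_i]
    prev = 0
    offset = 0.0
    for b in bounds:
        vol[prev:b] = cum[prev:b] - offset
        if b < n_i:
            offset = cum[b]
        prev = b

    # Decimate to the streamed output rate; sensor noise applies to the
    # recorded samples.
    paw = paw[::oversample]
    flow_rec = flow_rec[::oversample]
    pes = pes[::oversample]
    vol = vol[::oversample]

    sd = patient.noise_sd
    paw = paw + rng.normal(0.0, sd.get("paw", 0.0), n)
    flow_rec = flow_rec + rng.normal(0.0, sd.get("flow", 0.0), n)
    pes = pes + rng.normal(0.0, sd.get("pes", 0.0), n)

    # Gas-exchange channels: slow AR(1) drift around configured means.
    dt = 1.0 / fs
    phi = np.exp(-dt / 30.0)
    innov = rng.normal(0.0, 1.0, n)
    drift = lfilter([np.sqrt(1.0 - phi ** 2)], [1.0, -phi], innov)
    etco2 = etco2_mean_mmhg + 1.0 * drift + rng.normal(0.0, sd.get("etco2", 0.0), n)
    drift2 = lfilter([np.sqrt(1.0 - phi ** 2)], [1.0, -phi],
                     rng.normal(0.0, 1.0, n))
    spo2 = np.clip(spo2_mean_pct + 0.5 * drift2
                   + rng.normal(0.0, sd.get("spo2", 0.0), n), 0.0, 100.0)

    comfort_b = int(np.clip(
        comfort_b_median + rng.choice([-2, -1, 0, 1, 2],
                                      p=[0.1, 0.25, 0.3, 0.25, 0.1]),
        6, 30))

    record = WaveformRecord(
        sample_rate_hz=fs, paw=paw, flow=flow_rec, volume=vol, pes=pes,
        etco2=etco2, spo2=spo2,
        meta={"sync_mode": vent.sync_mode, "seed": str(seed),
              **(meta or {})})
    return SimSession(record=record, truth=truth,
                      n_machine_breaths=len(machine),
                      machine_breath_times=[tr for tr, _ in machine],
                      comfort_b=comfort_b,
                      settings=vent, patient=patient, seed=seed)


# ---------------------------------------------------------------------------
# Crossover cohorts
# ---------------------------------------------------------------------------

_PROFILE_WEIGHTS = (("mixed", 0.44), ("restrictive", 0.28),
                    ("obstructive", 0.16), ("normal", 0.12))


def draw_patient(rng: np.random.Generator) -> PatientModel:
    """Draw a pediatric patient from documented ranges (settings centered
    on PEEP 5, PS 8.5, RR 28)."""
    names, weights = zip(*_PROFILE_WEIGHTS)
    prof = names[rng.choice(len(names), p=np.array(weights))]
    rr = float(np.clip(rng.normal(28.0, 5.0), 18.0, 42.0))
    ti = min(rng.uniform(0.55, 0.80), 0.30 * 60.0 / rr)
    return PatientModel(
        resistance_cmh2o_s_per_l=rng.uniform(*PROFILE_RANGES[prof]["R"]),
        compliance_ml_per_cmh2o=rng.uniform(*PROFILE_RANGES[prof]["C"]),
        pmus_max_cmh2o=rng.uniform(6.0, 10.0),
        neural_rate_bpm=rr,
        neural_ti_s=ti,
        pes_baseline_cmh2o=rng.uniform(3.0, 7.0),
        physiology_profile=prof)


def _block_orders(n_patients: int, rng: np.random.Generator) -> list:
    """Randomized sequence assignment in blocks of four (2+2 per block)."""
    orders = []
    block = ["conventional_first"] * 2 + ["closed_loop_first"] * 2
    while len(orders) < n_patients:
        perm = [block[i] for i in rng.permutation(4)]
        orders.extend(perm)
    return orders[:n_patients]


def generate_crossover_cohort(n_patients: int,
                              arm_effect: Optional[dict] = None,
                              base_profile: Optional[AsynchronyProfile] = None,
                              seed: int = 0,
                              duration_s: float = 600.0,
                              rate_multiplier_sigma: float = 0.25
                              ) -> CrossoverDataset:
    """Simulate a paired two-arm crossover cohort.

    Each patient gets one conventional and one closed-loop session sharing
    the same PatientModel; the closed-loop profile is the conventional
    profile scaled by ``arm_effect``.  Per-patient substreams are spawned
    from the root seed so earlier patients are unchanged when the cohort
    grows.
    """
    if n_patients < 2:
        raise ValueError("a crossover cohort needs at least 2 patients")
    arm_effect = dict(DEFAULT_ARM_EFFECT) if arm_effect is None else arm_effect
    base_profile = base_profile if base_profile is not None else AsynchronyProfile()

    root = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(root.spawn(1)[0])
    orders = _block_orders(n_patients, order_rng)
    children = root.spawn(n_patients + 1)[1:]

    vent_conv = VentSettings(sync_mode="conventional")
    vent_cl = VentSettings(sync_mode="closed_loop_emulated")

    patients = []
    for i in range(n_patients):
        ss = children[i]
        prng = np.random.default_rng(ss)
        pat = draw_patient(prng)
        mult = float(np.exp(prng.normal(0.0, rate_multiplier_sigma)))
        conv_profile = base_profile.scaled({k: mult for k in DEFAULT_RATES})
        cl_profile = conv_profile.scaled(arm_effect)
        seed_conv, seed_cl = (int(s) % (2 ** 31)
                              for s in ss.generate_state(2))
        pid = f"P{i + 1:03d}"
        conv = simulate_session(pat, vent_conv, conv_profile, duration_s,
                                seed_conv, etco2_mean_mmhg=43.0,
                                spo2_mean_pct=96.0, comfort_b_median=14,
                                meta={"patient_id": pid, "arm": "conventional"})
        cl = simulate_session(pat, vent_cl, cl_profile, duration_s,
                              seed_cl, etco2_mean_mmhg=42.0,
                              spo2_mean_pct=96.0, comfort_b_median=13,
                              meta={"patient_id": pid, "arm": "closed_loop"})
        patients.append(PatientPair(patient_id=pid, order=orders[i],
                                    conventional=conv, closed_loop=cl,
                                    patient=pat))
    return CrossoverDataset(patients=patients, seed=seed)
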