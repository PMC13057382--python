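"""Thresholds and tuning knobs for waveform analysis.

The timing bins (117/234 ms), the 0.5 cmH2O airway-pressure drop for
flow-only ineffective efforts, the ≥100 ms early-cycling offset and the
Te ≤ Ti/2 double-breath rule are the published waveform-analysis
criteria for pressure-support ventilation.  Everything else (decay-fit
acceptance, esophageal-pressure effort detection, matching windows,
artifact thresholds) is a tunable detail of this implementation with
defaults chosen for pediatric time constants; all are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Any


@dataclass(frozen=True)
class ClassifierConfig:
    # Trigger-timing bins (ms).  Realized on continuous time as
    # (-inf, normal] / (normal, td] / (td, inf).
    normal_trigger_max_ms: float = 117.0
    td_max_ms: float = 234.0

    # Flow-only ineffective-effort rule: expiratory flow deviation toward
    # zero combined with an abrupt airway-pressure drop of at least this.
    ie_paw_drop_cmh2o: float = 0.5

    # Cycling offset (ms) separating early/late cycling from acceptable
    # cycling.  Early cycling is published at >=100 ms; late cycling uses
    # the symmetric threshold.
    ec_lc_offset_ms: float = 100.0

    # Double breath: interposed expiratory time <= ratio * inspiratory time.
    db_te_ti_ratio: float = 0.5

    # Delay after effort onset beyond which a Pes effort with no
    # ventilator breath is an ineffective effort.
    pes_ie_delay_ms: float = 234.0

    # Passive expiratory decay acceptance.
    passive_r2_min: float = 0.95
    tau_min_s: float = 0.05
    tau_max_s: float = 1.5
    decay_floor_lpm: float = 2.0

    # Esophageal-pressure effort detection.
    pes_effort_min_cmh2o: float = 1.0
    pes_onset_frac: float = 0.05
    pes_baseline_win_s: float = 2.5

    # Effort-to-breath matching.
    match_window_ms: float = 600.0
    pre_trigger_tol_ms: float = 60.0

    # Artifact masking.
    cough_flow_spike_lpm: float = 10.0
    active_exp_pes_cmh2o: float = 3.0
    artifact_pad_s: float = 0.10

    # Breath detection.  A flow-deflection crossing proposes the breath;
    # the onset is refined to the ventilator pressurization upswing when
    # the airway pressure shows a slope above paw_trigger_slope.
    breath_flow_onset_lpm: float = 2.0
    paw_trigger_slope_cmh2o_per_s: float = 75.0
    paw_rise_min_cmh2o: float = 1.0
    paw_rise_win_s: float = 0.15
    min_breath_interval_s: float = 0.25
    decay_fit_window_s: float = 0.35
    decay_fit_delay_s: float = 0.04

    # Auto-trigger pre-onset scan: effort evidence thresholds.
    at_paw_dip_cmh2o: float = 0.3
    at_pes_dip_cmh2o: float = 0.8
    at_preonset_win_s: float = 0.20

    # Flow-only cycling fallbacks (used when Pes is absent).
    ec_flow_bump_lpm: float = 2.0
    ec_window_after_cycle_s: float = 0.30
    lc_paw_spike_cmh2o: float = 1.0
    lc_window_before_cycle_s: float = 0.15

    def __post_init__(self) -> None:
        if not (0 < self.normal_trigger_max_ms < self.td_max_ms):
            raise ValueError("require 0 < normal_trigger_max_ms < td_max_ms")
        if not (0 < self.db_te_ti_ratio <= 1):
            raise ValueError("db_te_ti_ratio must be in (0, 1]")
        for name in ("ie_paw_drop_cmh2o", "ec_lc_offset_ms", "pes_ie_delay_ms",
                     "tau_min_s", "tau_max_s", "decay_floor_lpm",
                     "pes_effort_min_cmh2o", "pes_baseline_win_s",
                     "match_window_ms", "cough_flow_spike_lpm",
                     "active_exp_pes_cmh2o", "breath_flow_onset_lpm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.passive_r2_min <= 1):
            raise ValueError("passive_r2_min must be in [0, 1]")
        if self.tau_min_s >= self.tau_max_s:
            raise ValueError("tau_min_s must be < tau_max_s")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def with_overrides(self, **kwargs: Any) -> "ClassifierConfig":
        """Return a copy with the given fields replaced (unknown names raise)."""
        known = set(self.__dataclass_fields__)
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown ClassifierConfig fields: {sorted(unknown)}")
        return replace(self, **kwargs)


DEFAULT_CONFIG = ClassifierConfig()
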