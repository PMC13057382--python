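"""End-to-end orchestration: simulate -> segment -> classify -> summarize
-> analyze, with ground-truth-vs-detected bookkeeping.

A run simulates a two-arm crossover cohort, discards a leading run-in
fraction of each session (mirroring a stabilization phase before the
measurement period), classifies every session, summarizes outcomes per
session, and produces the paired crossover analysis table plus a
per-type confusion table of injected versus detected events.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .classifier import EVENT_TYPES, analyze_record
from .config import ClassifierConfig, DEFAULT_CONFIG
from .indices import PeriodSummary, summarize_period
from .simulator import (AsynchronyProfile, CrossoverDataset, SimSession,
                        generate_crossover_cohort, truth_counts)
from .stats import analyze_crossover
from .waveforms import WaveformRecord, write_waveform


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    seed: int = 0
    n_patients: int = 8
    duration_s: float = 900.0
    run_in_frac: float = 1.0 / 3.0
    arm_effect: Optional[dict] = None
    rates_per_min: Optional[dict] = None
    classifier: dict = field(default_factory=dict)
    out_dir: Optional[str] = None
    verbosity: int = 1
    report_format: str = "csv"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.n_patients < 2:
            raise ConfigError("n_patients must be at least 2")
        if not (0.0 <= cfg.run_in_frac < 1.0):
            raise ConfigError("run_in_frac must be in [0, 1)")
        if cfg.duration_s * (1.0 - cfg.run_in_frac) < 60.0:
            raise ConfigError("measurement period must be at least 60 s")
        if cfg.report_format != "csv":
            raise ConfigError("report_format must be 'csv'")
        return cfg

    def classifier_config(self) -> ClassifierConfig:
        return DEFAULT_CONFIG.with_overrides(**self.classifier)


@dataclass
class RunReport:
    summaries: pd.DataFrame
    crossover: pd.DataFrame
    confusion: pd.DataFrame
    recovery: pd.DataFrame
    seed: int
    config: dict
    version: str = __version__


# ---------------------------------------------------------------------------
# Session-level helpers
# ---------------------------------------------------------------------------

def crop_record(record: WaveformRecord, start_s: float) -> WaveformRecord:
    """Drop everything before ``start_s`` (run-in exclusion)."""
    i0 = record.index_at(record.t0_s + start_s)
    kwargs = {}
    for name in ("paw", "flow", "volume", "pes", "etco2", "spo2",
                 "artifact_mask"):
        v = getattr(record, name)
        kwargs[name] = v[i0:] if v is not None else None
    return WaveformRecord(sample_rate_hz=record.sample_rate_hz,
                          t0_s=0.0, meta=dict(record.meta), **kwargs)


def evaluate_session(session: SimSession,
                     cfg: ClassifierConfig = DEFAULT_CONFIG,
                     run_in_s: float = 0.0) -> dict:
    """Classify one simulated session and compare against its injection log.

    Returns the period summary, the detected events, and ground-truth
    counts/AI restricted to the analyzed window.
    """
    record = (crop_record(session.record, run_in_s)
              if run_in_s > 0 else session.record)
    rec, breaths, efforts, match, events = analyze_record(record, cfg)
    summary = summarize_period(rec, events, breaths,
                               comfort_b=session.comfort_b)

    window_truth = [e for e in session.truth if e.time_s >= run_in_s]
    tc = truth_counts(window_truth)
    truth_events = sum(tc[t] for t in EVENT_TYPES)
    truth_breaths = sum(1 for t in session.machine_breath_times
                        if t >= run_in_s)
    truth_denom = truth_breaths + tc["IE"]
    truth_ai = 100.0 * truth_events / truth_denom if truth_denom else float("nan")
    return {
        "summary": summary,
        "events": events,
        "truth": window_truth,
        "truth_counts": tc,
        "truth_ai_pct": truth_ai,
        "breaths": breaths,
    }


def _confusion_for(truth, events, tol_s: float = 0.30) -> dict:
    """Greedy per-type time matching of injected vs detected events."""
    out = {}
    for t in EVENT_TYPES:
        t_times = sorted(e.time_s for e in truth if e.kind == t)
        d_times = sorted(ev.time_s for ev in events if ev.type == t)
        used = [False] * len(d_times)
        tp = 0
        for tt in t_times:
            for j, dt_ in enumerate(d_times):
                if not used[j] and abs(dt_ - tt) <= tol_s:
                    used[j] = True
                    tp += 1
                    break
        out[t] = {"tp": tp, "fn": len(t_times) - tp,
                  "fp": len(d_times) - tp}
    return out


def _summary_row(pid: str, arm: str, summary: PeriodSummary) -> dict:
    ai = summary.ai
    denom = ai.denominator
    row = {
        "patient_id": pid, "arm": arm,
        "ai_pct": ai.ai_pct, "major_ai_pct": ai.major_ai_pct,
        "minor_ai_pct": ai.minor_ai_pct,
        "comfort_b": summary.comfort_b,
        "etco2_mmhg": summary.mean_etco2_mmhg,
        "spo2_pct": summary.mean_spo2_pct,
        "leak_pct": summary.mean_leak_pct,
        "n_machine_breaths": ai.n_machine_breaths,
    }
    for t, cnt in (("at", ai.n_at), ("db", ai.n_db), ("ie", ai.n_ie),
                   ("td", ai.n_td), ("ec", ai.n_ec), ("lc", ai.n_lc)):
        row[f"{t}_pct"] = 100.0 * cnt / denom
    return row


# ---------------------------------------------------------------------------
# Cohort-level analysis
# ---------------------------------------------------------------------------

def analyze_cohort(dataset: CrossoverDataset,
                   cfg: ClassifierConfig = DEFAULT_CONFIG,
                   run_in_s: float = 0.0
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Classify every session of a cohort.

    Returns (summaries, recovery, confusion): per-session outcome rows,
    per-session ground-truth-vs-detected AI, and per-type event-matching
    counts aggregated over the cohort.
    """
    rows, recovery_rows = [], []
    agg = {t: {"tp": 0, "fn": 0, "fp": 0} for t in EVENT_TYPES}
    for pair in dataset.patients:
        for arm, session in (("conventional", pair.conventional),
                             ("closed_loop", pair.closed_loop)):
            res = evaluate_session(session, cfg, run_in_s=run_in_s)
            rows.append(_summary_row(pair.patient_id, arm, res["summary"]))
            recovery_rows.append({
                "patient_id": pair.patient_id, "arm": arm,
                "truth_ai_pct": res["truth_ai_pct"],
                "detected_ai_pct": res["summary"].ai.ai_pct,
            })
            for t, c in _confusion_for(res["truth"], res["events"]).items():
                for k in ("tp", "fn", "fp"):
                    agg[t][k] += c[k]
    confusion = pd.DataFrame(
        [{"type": t, **c,
          "sensitivity": c["tp"] / (c["tp"] + c["fn"])
          if c["tp"] + c["fn"] else float("nan"),
          "precision": c["tp"] / (c["tp"] + c["fp"])
          if c["tp"] + c["fp"] else float("nan")}
         for t, c in agg.items()])
    return pd.DataFrame(rows), pd.DataFrame(recovery_rows), confusion


OUTCOME_COLUMNS = ["ai_pct", "major_ai_pct", "minor_ai_pct",
                   "db_pct", "at_pct", "ie_pct", "td_pct", "ec_pct",
                   "lc_pct", "comfort_b", "etco2_mmhg", "spo2_pct",
                   "leak_pct"]


def run_pipeline(config: RunConfig) -> RunReport:
    """Deterministic end-to-end run; writes intermediates when an output
    directory is configured."""
    cfg = config.classifier_config()
    profile = (AsynchronyProfile(rates_per_min=config.rates_per_min)
               if config.rates_per_min else None)
    dataset = generate_crossover_cohort(
        config.n_patients, arm_effect=config.arm_effect,
        base_profile=profile, seed=config.seed,
        duration_s=config.duration_s)
    run_in_s = config.run_in_frac * config.duration_s
    summaries, recovery, confusion = analyze_cohort(dataset, cfg,
                                                    run_in_s=run_in_s)
    crossover = analyze_crossover(summaries, OUTCOME_COLUMNS)
    report = RunReport(summaries=summaries, crossover=crossover,
                       confusion=confusion, recovery=recovery,
                       seed=config.seed,
                       config=dataclasses.asdict(config))

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pair in dataset.patients:
            for arm, session in (("conventional", pair.conventional),
                                 ("closed_loop", pair.closed_loop)):
                stem = f"{pair.patient_id}_{arm}"
                write_waveform(session.record, out / f"{stem}_waveform.csv")
                pd.DataFrame(
                    [{"time_s": e.time_s, "kind": e.kind,
                      "true_metric": e.true_metric} for e in session.truth]
                ).to_csv(out / f"{stem}_truth.csv", index=False)
        summaries.to_csv(out / "summaries.csv", index=False)
        recovery.to_csv(out / "recovery.csv", index=False)
        confusion.to_csv(out / "confusion.csv", index=False)
        crossover.to_csv(out / "crossover.csv", index=False)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump({"version": report.version, "seed": report.seed,
                       "config": report.config}, fh, indent=2, sort_keys=True)
    return report


def write_events_csv(events, path) -> None:
    """Event CSV dialect: time_s,breath_index,type,severity,metric_value,
    metric_units."""
    pd.DataFrame(
        [{"time_s": ev.time_s, "breath_index": ev.breath_index,
          "type": ev.type, "severity": ev.severity,
          "metric_value": ev.metric_value,
          "metric_units": ev.metric_units} for ev in events]
    ).to_csv(path, index=False)
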