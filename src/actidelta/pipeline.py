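"""End-to-end orchestration: wear masking -> AI -> eligibility -> statistics.

The pipeline mirrors the analysis order of the study it reproduces: off-body
periods are excluded first, then per-second/per-minute AI is computed, then
each registered attack is pushed through the eligibility funnel

    nighttime -> data-ratio -> matched-interval -> pooled-volume -> eligible

with one terminal status per attack (the per-attack ledger reproduces the
funnel structure of a per-participant attack-count table).  Eligible attacks
enter the whole-attack percentile-delta analysis and the onset-relative bin
analysis.  Everything is deterministic given the inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import AIParams, AISeries, compute_ai
from .intervals import (
    CalendarConfig,
    analysis_cumsum,
    data_ratio,
    find_non_ch_intervals,
    is_daytime,
    onset_relative_bins,
    pool_non_ch,
)
from .recording import AccRecording, EventLog
from .stats import AttackComparison, analyze_onset_relative, analyze_whole_attacks
from .wear import WearParams, detect_offbody

log = logging.getLogger(__name__)

#: Terminal eligibility statuses, in funnel order.
STATUSES = ("nighttime", "low_data_ratio", "no_match", "insufficient_pool", "eligible")


@dataclass
class RunConfig:
    """Switches and parameters for one pipeline run (single participant)."""

    ai_params: AIParams = field(default_factory=AIParams)
    wear_params: WearParams = field(default_factory=WearParams)
    calendar: CalendarConfig = field(default_factory=CalendarConfig)
    min_data_ratio: float = 0.75
    strict_bin_daytime: bool = True
    family_m_whole: int = 4
    family_m_bins: int | None = None  # None = number of tests performed
    zero_method: str = "wilcox"
    quantile_method: str = "median_unbiased"  # see stats.ANALYSIS_QUANTILE_METHOD
    treatment_stratify: str | None = None
    run_wear_detection: bool = True
    seed: int | None = None  # recorded for provenance when inputs were simulated


@dataclass
class RunResult:
    ledger: pd.DataFrame
    whole_delta: pd.DataFrame
    whole_stats: pd.DataFrame
    bin_delta: pd.DataFrame
    bin_stats: pd.DataFrame
    skipped_bins: pd.DataFrame
    params: dict
    ai: AISeries = None
    stratified_stats: pd.DataFrame = None


def classify_attacks(
    event_log: EventLog,
    recording: AccRecording,
    ai: AISeries,
    config: RunConfig,
) -> tuple:
    """Walk every attack through the eligibility funnel.

    Returns ``(ledger_df, comparisons)`` where the ledger has one row per
    attack with its terminal status and the reason metrics, and
    ``comparisons`` maps attack index -> :class:`AttackComparison` for
    eligible attacks.
    """
    cum = analysis_cumsum(recording)
    rows = []
    comparisons = {}
    for i, ev in enumerate(event_log):
        row = {
            "attack_id": i,
            "onset": ev.onset.isoformat(),
            "end": ev.end.isoformat(),
            "duration_min": ev.duration_minutes,
            "intensity": ev.intensity,
            "treatment": ev.treatment_label,
            "data_ratio": np.nan,
            "n_candidates": 0,
            "pooled_minutes": 0,
        }
        if not is_daytime(ev, config.calendar):
            row["status"] = "nighttime"
            rows.append(row)
            continue
        ratio = data_ratio(ev.onset, ev.end, recording, cum)
        row["data_ratio"] = ratio
        if ratio < config.min_data_ratio:
            row["status"] = "low_data_ratio"
            rows.append(row)
            continue
        candidates = find_non_ch_intervals(
            ev, event_log, recording, config.calendar, config.min_data_ratio, cum, i
        )
        row["n_candidates"] = len(candidates)
        if not candidates:
            row["status"] = "no_match"
            rows.append(row)
            continue
        pooled = pool_non_ch(candidates, ai)
        row["pooled_minutes"] = int(pooled.size)
        ch_vals = ai.valid_minutes_in(ev.onset, ev.end)
        if pooled.size < ev.duration_minutes or ch_vals.size == 0:
            row["status"] = "insufficient_pool"
            rows.append(row)
            continue
        row["status"] = "eligible"
        rows.append(row)
        comparisons[i] = AttackComparison(
            attack_id=i,
            treatment=ev.treatment_label,
            ch_values=ch_vals,
            non_ch_values=pooled,
        )
    ledger = pd.DataFrame(
        rows,
        columns=[
            "attack_id", "onset", "end", "duration_min", "intensity", "treatment",
            "data_ratio", "n_candidates", "pooled_minutes", "status",
        ],
    )
    return ledger, comparisons


def collect_bin_comparisons(
    event_log: EventLog,
    recording: AccRecording,
    ai: AISeries,
    config: RunConfig,
    eligible_ids,
) -> tuple:
    """Onset-relative bin pairs for the attacks that passed the funnel."""
    cum = analysis_cumsum(recording)
    pairs, skipped = [], []
    for i in eligible_ids:
        ev = event_log[i]
        kept, skip = onset_relative_bins(
            ev, event_log, recording, config.calendar, config.min_data_ratio,
            config.strict_bin_daytime, cum, i,
        )
        for bin_id, reason in skip:
            skipped.append({"attack_id": i, "bin_id": bin_id, "reason": reason})
        for bin_iv, matches in kept:
            ch_vals = ai.valid_minutes_in(bin_iv.start, bin_iv.end)
            non_ch = pool_non_ch(matches, ai)
            if ch_vals.size == 0 or non_ch.size == 0:
                skipped.append({"attack_id": i, "bin_id": bin_iv.bin_id, "reason": "no_valid_minutes"})
                continue
            pairs.append(
                AttackComparison(i, ev.treatment_label, ch_vals, non_ch, bin_id=bin_iv.bin_id)
            )
    skipped_df = pd.DataFrame(skipped, columns=["attack_id", "bin_id", "reason"])
    return pairs, skipped_df


def run(
    recording: AccRecording,
    event_log: EventLog,
    config: RunConfig = None,
    out_dir=None,
    ai: AISeries = None,
) -> RunResult:
    """Run the full analysis; optionally write the report bundle to ``out_dir``.

    Passing a precomputed ``ai`` series (with the same parameters) reproduces
    the end-to-end result exactly — the pipeline is checkpointable.
    """
    config = config or RunConfig()
    if config.run_wear_detection:
        recording = recording.with_on_body(detect_offbody(recording, config.wear_params))
    if ai is None:
        ai = compute_ai(recording, config.ai_params)

    ledger, comparisons = classify_attacks(event_log, recording, ai, config)
    pairs = [comparisons[i] for i in sorted(comparisons)]
    whole_delta, whole_stats = analyze_whole_attacks(
        pairs, config.family_m_whole, zero_method=config.zero_method,
        quantile_method=config.quantile_method,
    )
    stratified_stats = None
    if config.treatment_stratify:
        _, stratified_stats = analyze_whole_attacks(
            pairs, config.family_m_whole, treatment_filter=config.treatment_stratify,
            zero_method=config.zero_method, quantile_method=config.quantile_method,
        )
    bin_pairs, skipped_bins = collect_bin_comparisons(
        event_log, recording, ai, config, sorted(comparisons)
    )
    bin_delta, bin_stats = analyze_onset_relative(
        bin_pairs, config.family_m_bins, zero_method=config.zero_method,
        quantile_method=config.quantile_method,
    )
    if len(ledger) and not (ledger["status"] == "eligible").any():
        log.info("no eligible attacks: statistics are empty, see the eligibility ledger")

    params = {
        "ai_params": asdict(config.ai_params),
        "wear_params": asdict(config.wear_params),
        "calendar": {
            "nighttime_start": config.calendar.nighttime_start.isoformat(),
            "nighttime_end": config.calendar.nighttime_end.isoformat(),
            "holiday_dates": sorted(str(d) for d in config.calendar.holiday_dates),
            "weekend_days": sorted(config.calendar.weekend_days),
        },
        "min_data_ratio": config.min_data_ratio,
        "strict_bin_daytime": config.strict_bin_daytime,
        "family_m_whole": config.family_m_whole,
        "family_m_bins": config.family_m_bins,
        "zero_method": config.zero_method,
        "quantile_method": config.quantile_method,
        "treatment_stratify": config.treatment_stratify,
        "seed": config.seed,
    }
    result = RunResult(
        ledger=ledger,
        whole_delta=whole_delta,
        whole_stats=whole_stats,
        bin_delta=bin_delta,
        bin_stats=bin_stats,
        skipped_bins=skipped_bins,
        params=params,
        ai=ai,
        stratified_stats=stratified_stats,
    )
    if out_dir is not None:
        write_report_bundle(result, out_dir)
    return result


def write_report_bundle(result: RunResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.ledger.to_csv(out / "eligibility_ledger.csv", index=False)
    result.whole_delta.to_csv(out / "whole_attack_deltas.csv", index=False)
    result.whole_stats.to_csv(out / "whole_attack_stats.csv", index=False)
    result.bin_delta.to_csv(out / "onset_relative_deltas.csv", index=False)
    result.bin_stats.to_csv(out / "onset_relative_stats.csv", index=False)
    result.skipped_bins.to_csv(out / "skipped_bins.csv", index=False)
    if result.stratified_stats is not None:
        result.stratified_stats.to_csv(out / "stratified_stats.csv", index=False)
    with open(out / "run_log.json", "w") as fh:
        json.dump(result.params, fh, indent=1, default=str)


def funnel_counts(ledger: pd.DataFrame) -> dict:
    """Attack-count funnel: total / daytime / +data-ratio / +matched-eligible."""
    status = ledger["status"]
    total = int(len(ledger))
    daytime = int((status != "nighttime").sum())
    with_ratio = int((~status.isin(["nighttime", "low_data_ratio"])).sum())
    eligible = int((status == "eligible").sum())
    return {"total": total, "daytime": daytime, "daytime_75pct": with_ratio, "eligible": eligible}
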