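"""Eligibility rules for attack intervals and matched non-attack intervals.

An attack qualifies for analysis when (1) it is a daytime attack — its interval
does not overlap the nightly 23:00–07:30 window — and (2) at least 75% of the
expected samples in the interval are present and on-body (the data ratio).

Its comparison data come from matched non-attack windows: the same wall-clock
range on every other day of the study with the same day-type (weekday vs
weekend), excluding holidays, requiring the window to be at least 24 h away
from the start and end of *every* registered attack and to meet the same 75%
data ratio.  All matches are pooled into a single comparison distribution.

Onset-relative bins (−3 h .. +3 h around onset) reuse the same construction
with the bin's clock range.

All boundary comparisons are inclusive (a ratio of exactly 0.75 passes; a
distance of exactly 24 h passes).  Wall-clock rules use the local timezone of
the timestamps; windows crossing midnight inherit the onset date's day-type.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta

import numpy as np

from .activity import AISeries
from .recording import AccRecording, AttackEvent, EventLog

#: Onset-relative bins as (bin_id, start_offset_min, end_offset_min).
ONSET_BINS = (
    ("-3h..-1h", -180, -60),
    ("-1h..-30m", -60, -30),
    ("-30m..0", -30, 0),
    ("0..+30m", 0, 30),
    ("+30m..+1h", 30, 60),
    ("+1h..+2h", 60, 120),
    ("+2h..+3h", 120, 180),
)


@dataclass
class CalendarConfig:
    """Wall-clock calendar rules: nighttime window, weekends, holidays."""

    nighttime_start: time = time(23, 0)
    nighttime_end: time = time(7, 30)
    holiday_dates: frozenset = frozenset()
    weekend_days: frozenset = frozenset({5, 6})  # Monday=0

    def day_type(self, d: date) -> str:
        return "weekend" if d.weekday() in self.weekend_days else "weekday"


@dataclass
class EligibleInterval:
    """A labelled analysis interval with its measured data ratio."""

    start: datetime
    end: datetime
    label: str  # attack | onset_rel_bin | non_ch_match
    source_attack: int | None = None
    bin_id: str | None = None
    data_ratio: float = float("nan")

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"interval end must be after start ({self.start}..{self.end})")


class EligibilityError(ValueError):
    """An interval cannot enter the analysis (e.g. no matched data)."""


# ---------------------------------------------------------------------------
# data ratio
# ---------------------------------------------------------------------------

def analysis_cumsum(recording: AccRecording) -> np.ndarray:
    """Prefix sums of the present-and-on-body mask for O(1) ratio queries."""
    return np.concatenate([[0], np.cumsum(recording.analysis_mask, dtype=np.int64)])


def data_ratio(
    start: datetime,
    end: datetime,
    recording: AccRecording,
    cumsum: np.ndarray = None,
) -> float:
    """Fraction of grid samples in ``[start, end)`` that are present and on-body."""
    i0 = recording.index_at(start)
    i1 = recording.index_at(end)
    if i0 < 0 or i1 > recording.n_samples or i1 <= i0:
        raise ValueError(
            f"interval {start}..{end} outside recording span "
            f"{recording.start_time}..{recording.end_time}"
        )
    if cumsum is not None:
        good = int(cumsum[i1] - cumsum[i0])
    else:
        good = int(np.count_nonzero(recording.analysis_mask[i0:i1]))
    return good / (i1 - i0)


# ---------------------------------------------------------------------------
# daytime rule
# ---------------------------------------------------------------------------

def _overlaps_nighttime(start: datetime, end: datetime, cal: CalendarConfig) -> bool:
    """Does ``[start, end)`` intersect any nightly [night_start, next-day night_end)?"""
    tz = start.tzinfo
    d = start.date() - timedelta(days=1)
    while True:
        night_start = datetime.combine(d, cal.nighttime_start, tzinfo=tz)
        night_end = datetime.combine(d + timedelta(days=1), cal.nighttime_end, tzinfo=tz)
        if night_start >= end:
            return False
        if max(start, night_start) < min(end, night_end):
            return True
        d += timedelta(days=1)


def is_daytime_interval(start: datetime, end: datetime, cal: CalendarConfig = None) -> bool:
    return not _overlaps_nighttime(start, end, cal or CalendarConfig())


def is_daytime(attack: AttackEvent, cal: CalendarConfig = None) -> bool:
    """True iff the attack interval has no overlap with the nighttime window."""
    return is_daytime_interval(attack.onset, attack.end, cal)


# ---------------------------------------------------------------------------
# matched non-attack intervals
# ---------------------------------------------------------------------------

def _far_from_all_attacks(start: datetime, end: datetime, event_log: EventLog) -> bool:
    """Every point of ``[start, end)`` at least 24 h from every attack boundary."""
    h24 = timedelta(hours=24)
    for ev in event_log:
        if not (end + h24 <= ev.onset or start >= ev.end + h24):
            return False
    return True


def candidate_days(recording: AccRecording) -> list:
    """Local calendar dates fully or partly covered by the recording."""
    tz = recording.start_time.tzinfo
    d0 = recording.start_time.astimezone(tz).date()
    d1 = (recording.end_time.astimezone(tz) - timedelta(microseconds=1)).date()
    out = []
    d = d0
    while d <= d1:
        out.append(d)
        d += timedelta(days=1)
    return out


def matched_intervals(
    start: datetime,
    end: datetime,
    source_attack: int,
    event_log: EventLog,
    recording: AccRecording,
    cal: CalendarConfig = None,
    min_ratio: float = 0.75,
    cumsum: np.ndarray = None,
    bin_id: str = None,
) -> list:
    """Matched same-clock windows for an arbitrary reference window.

    Candidates are the same wall-clock range on every other study day with the
    reference window's onset-date day-type, skipping holidays, windows within
    24 h of any attack boundary, windows leaving the recording span, and
    windows below the data-ratio floor.
    """
    cal = cal or CalendarConfig()
    tz = start.tzinfo
    ref_date = start.astimezone(tz).date()
    ref_type = cal.day_type(ref_date)
    duration = end - start
    clock = start.astimezone(tz).time()
    out = []
    for d in candidate_days(recording):
        if d == ref_date:
            continue
        if cal.day_type(d) != ref_type:
            continue
        if d in cal.holiday_dates:
            continue
        c_start = datetime.combine(d, clock, tzinfo=tz)
        c_end = c_start + duration
        if c_start < recording.start_time or c_end > recording.end_time:
            continue
        if not _far_from_all_attacks(c_start, c_end, event_log):
            continue
        ratio = data_ratio(c_start, c_end, recording, cumsum)
        if ratio < min_ratio:
            continue
        out.append(
            EligibleInterval(c_start, c_end, "non_ch_match", source_attack, bin_id, ratio)
        )
    return out


def find_non_ch_intervals(
    attack: AttackEvent,
    event_log: EventLog,
    recording: AccRecording,
    cal: CalendarConfig = None,
    min_ratio: float = 0.75,
    cumsum: np.ndarray = None,
    attack_index: int = 0,
) -> list:
    """Matched non-attack windows for one attack (sorted by date)."""
    return matched_intervals(
        attack.onset, attack.end, attack_index, event_log, recording, cal, min_ratio, cumsum
    )


def pool_non_ch(candidates: list, ai: AISeries) -> np.ndarray:
    """Concatenated valid per-minute AI values over all matched windows.

    Raises :class:`EligibilityError` when there are no candidates — the
    corresponding attack is then excluded downstream.
    """
    if not candidates:
        raise EligibilityError("no eligible matched non-attack intervals")
    chunks = [ai.valid_minutes_in(c.start, c.end) for c in candidates]
    return np.concatenate(chunks) if chunks else np.empty(0)


# ---------------------------------------------------------------------------
# onset-relative bins
# ---------------------------------------------------------------------------

def onset_relative_bins(
    attack: AttackEvent,
    event_log: EventLog,
    recording: AccRecording,
    cal: CalendarConfig = None,
    min_ratio: float = 0.75,
    strict_daytime: bool = True,
    cumsum: np.ndarray = None,
    attack_index: int = 0,
) -> tuple:
    """Onset-anchored bins with their matched windows, plus skip reasons.

    Returns ``(kept, skipped)`` where ``kept`` is a list of
    ``(EligibleInterval bin, [matched EligibleInterval, ...])`` and ``skipped``
    is a list of ``(bin_id, reason)``.  With ``strict_daytime`` (default) a bin
    overlapping the nighttime window is dropped; the lenient setting keeps it.
    """
    cal = cal or CalendarConfig()
    kept, skipped = [], []
    for bin_id, lo, hi in ONSET_BINS:
        b_start = attack.onset + timedelta(minutes=lo)
        b_end = attack.onset + timedelta(minutes=hi)
        if b_start < recording.start_time or b_end > recording.end_time:
            skipped.append((bin_id, "outside_recording"))
            continue
        if strict_daytime and not is_daytime_interval(b_start, b_end, cal):
            skipped.append((bin_id, "nighttime_overlap"))
            continue
        # a bin containing a different registered attack is not a clean
        # onset-relative window for this attack
        contaminated = any(
            ev is not attack and max(b_start, ev.onset) < min(b_end, ev.end)
            for ev in event_log
        )
        if contaminated:
            skipped.append((bin_id, "overlaps_other_attack"))
            continue
        ratio = data_ratio(b_start, b_end, recording, cumsum)
        if ratio < min_ratio:
            skipped.append((bin_id, "low_data_ratio"))
            continue
        matches = matched_intervals(
            b_start, b_end, attack_index, event_log, recording, cal, min_ratio, cumsum, bin_id
        )
        if not matches:
            skipped.append((bin_id, "no_match"))
            continue
        kept.append(
            (EligibleInterval(b_start, b_end, "onset_rel_bin", attack_index, bin_id, ratio), matches)
        )
    return kept, skipped
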