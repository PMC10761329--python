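"""Eligibility rules: data ratio, daytime filter, matched-interval calendar."""

from datetime import date, datetime, time, timedelta
from zoneinfo import ZoneInfo

import numpy as np
import pytest

from actidelta import (
    AttackEvent,
    CalendarConfig,
    EligibilityError,
    EventLog,
    SynthConfig,
    compute_ai,
    data_ratio,
    find_non_ch_intervals,
    generate_recording,
    is_daytime,
    onset_relative_bins,
    pool_non_ch,
)
from actidelta.intervals import analysis_cumsum, matched_intervals
from _oracles import brute_candidates, brute_classify, brute_is_daytime

TZ = ZoneInfo("Europe/Brussels")
MONDAY = datetime(2022, 1, 10, tzinfo=TZ)  # study start, midnight local


def _dt(day, hour, minute=0):
    return MONDAY + timedelta(days=day, hours=hour, minutes=minute)


def _attack(day, hour, minute, dur_min, intensity=3):
    onset = _dt(day, hour, minute)
    return AttackEvent(onset, onset + timedelta(minutes=dur_min), intensity, ("oxygen",), True)


def _recording(days=21, rate=2, seed=0, **kw):
    cfg = SynthConfig(study_days=days, sample_rate_hz=rate, n_attacks=0,
                      gap_rate=0.0, offbody_segments=[], seed=seed, **kw)
    rec, _, _ = generate_recording(cfg)
    return rec


class TestDataRatio:
    def test_complete_interval_is_one(self):
        rec = _recording(days=1)
        assert data_ratio(_dt(0, 10), _dt(0, 11), rec) == 1.0

    def test_boundary_quarter_masked_passes_inclusive(self):
        rec = _recording(days=1)
        i0, i1 = rec.index_at(_dt(0, 10)), rec.index_at(_dt(0, 11))
        n = i1 - i0
        rec.valid_mask[i0 : i0 + n // 4] = False
        assert data_ratio(_dt(0, 10), _dt(0, 11), rec) == pytest.approx(0.75)
        assert data_ratio(_dt(0, 10), _dt(0, 11), rec) >= 0.75

    def test_fully_offbody_is_zero(self):
        rec = _recording(days=1)
        rec.on_body_mask[:] = False
        assert data_ratio(_dt(0, 10), _dt(0, 11), rec) == 0.0

    def test_outside_recording_rejected(self):
        rec = _recording(days=1)
        with pytest.raises(ValueError, match="outside"):
            data_ratio(_dt(0, 23), _dt(1, 1), rec)

    def test_cumsum_cache_agrees(self, rng):
        rec = _recording(days=2, seed=4)
        rec.valid_mask &= rng.random(rec.n_samples) > 0.3
        cum = analysis_cumsum(rec)
        for _ in range(10):
            h = int(rng.integers(0, 40))
            a, b = _dt(0, h), _dt(0, h + 2)
            assert data_ratio(a, b, rec, cum) == data_ratio(a, b, rec)


class TestDaytime:
    @pytest.mark.parametrize(
        "hour,minute,dur,expected",
        [
            (10, 0, 40, True),    # mid-morning
            (7, 0, 45, False),    # overlaps 07:00-07:30
            (22, 30, 40, False),  # runs into 23:00
            (7, 30, 30, True),    # starts exactly at nighttime end
            (22, 0, 60, True),    # ends exactly at nighttime start
        ],
    )
    def test_nighttime_overlap_rule(self, hour, minute, dur, expected):
        attack = _attack(1, hour, minute, dur)
        assert is_daytime(attack) is expected
        assert brute_is_daytime(attack, CalendarConfig()) is expected


class TestMatchedIntervals:
    def test_single_tuesday_attack_calendar_enumeration(self):
        """Candidates = same-clock weekday windows >= 24 h away; count matches
        an independent brute-force enumeration."""
        rec = _recording()
        attack = _attack(1, 14, 0, 40)  # Tuesday 14:00-14:40
        log = EventLog([attack])
        got = find_non_ch_intervals(attack, log, rec)
        expect = brute_candidates(attack, log, rec, CalendarConfig())
        assert [(c.start, c.end) for c in got] == expect
        # Mon/Tue/Wed of week 1 are within 24 h; all other weekdays qualify
        assert len(got) == 12
        assert all(c.start.weekday() < 5 for c in got)

    def test_saturday_attack_matches_weekends_only(self):
        rec = _recording()
        attack = _attack(5, 11, 0, 30)  # Saturday
        got = find_non_ch_intervals(attack, EventLog([attack]), rec)
        assert got and all(c.start.weekday() >= 5 for c in got)

    def test_holiday_candidate_excluded(self):
        rec = _recording()
        attack = _attack(1, 14, 0, 40)
        cal = CalendarConfig(holiday_dates=frozenset({date(2022, 1, 20)}))
        got = find_non_ch_intervals(attack, EventLog([attack]), rec, cal)
        assert date(2022, 1, 20) not in {c.start.date() for c in got}
        assert len(got) == 11

    def test_low_ratio_candidate_excluded(self):
        rec = _recording()
        attack = _attack(1, 14, 0, 40)
        sl = rec.sample_slice(_dt(7, 14), _dt(7, 15))  # ruin Mon Jan 17
        rec.valid_mask[sl] = False
        got = find_non_ch_intervals(attack, EventLog([attack]), rec)
        assert date(2022, 1, 17) not in {c.start.date() for c in got}

    def test_24h_exclusion_is_symmetric(self):
        """No accepted candidate lies within 24 h of any attack boundary."""
        rec = _recording()
        events = [_attack(1, 14, 0, 40), _attack(2, 9, 30, 60), _attack(8, 16, 0, 90)]
        log = EventLog(events)
        h24 = timedelta(hours=24)
        for ev in events:
            for c in find_non_ch_intervals(ev, log, rec):
                for other in events:
                    for bound in (other.onset, other.end):
                        # distance from the nearest point of the window
                        dist = max(bound - c.end, c.start - bound, timedelta(0))
                        assert dist >= h24

    def test_pool_concatenates_valid_minutes(self):
        rec = _recording(rate=4)
        ai = compute_ai(rec)
        attack = _attack(1, 14, 0, 40)
        cands = find_non_ch_intervals(attack, EventLog([attack]), rec)
        pooled = pool_non_ch(cands, ai)
        assert pooled.size == sum(
            ai.valid_minutes_in(c.start, c.end).size for c in cands
        )
        assert pooled.size >= attack.duration_minutes

    def test_empty_candidates_signal_ineligibility(self):
        rec = _recording(rate=4)
        ai = compute_ai(rec)
        with pytest.raises(EligibilityError):
            pool_non_ch([], ai)


class TestOnsetBins:
    def test_bin_arithmetic_for_noon_onset(self):
        rec = _recording()
        attack = _attack(8, 12, 0, 40)
        kept, skipped = onset_relative_bins(attack, EventLog([attack]), rec)
        spans = {b.bin_id: (b.start, b.end) for b, _ in kept}
        assert spans["-3h..-1h"] == (_dt(8, 9), _dt(8, 11))
        assert spans["-1h..-30m"] == (_dt(8, 11), _dt(8, 11, 30))
        assert spans["-30m..0"] == (_dt(8, 11, 30), _dt(8, 12))
        assert spans["0..+30m"] == (_dt(8, 12), _dt(8, 12, 30))
        assert spans["+2h..+3h"] == (_dt(8, 14), _dt(8, 15))
        assert not skipped

    def test_early_onset_drops_night_overlapping_bin_when_strict(self):
        rec = _recording()
        attack = _attack(8, 8, 10, 30)  # -3h..-1h bin = [05:10, 07:10) in night
        kept, skipped = onset_relative_bins(attack, EventLog([attack]), rec, strict_daytime=True)
        assert ("-3h..-1h", "nighttime_overlap") in skipped
        lenient, _ = onset_relative_bins(attack, EventLog([attack]), rec, strict_daytime=False)
        assert "-3h..-1h" in {b.bin_id for b, _ in lenient}

    def test_gap_spanning_bin_excludes_it(self):
        rec = _recording()
        attack = _attack(8, 12, 0, 40)
        sl = rec.sample_slice(_dt(8, 12), _dt(8, 12, 30))
        rec.valid_mask[sl] = False
        _, skipped = onset_relative_bins(attack, EventLog([attack]), rec)
        assert ("0..+30m", "low_data_ratio") in skipped

    def test_bin_overlapping_other_attack_excluded(self):
        rec = _recording()
        a = _attack(8, 12, 0, 40)
        b = _attack(8, 10, 0, 30)  # sits inside a's -3h..-1h bin
        kept, skipped = onset_relative_bins(a, EventLog([a, b]), rec)
        assert ("-3h..-1h", "overlaps_other_attack") in skipped


class TestEligibilityOracle:
    def test_monotone_in_data(self):
        """Filling gaps never removes an eligible attack."""
        cfg = SynthConfig(study_days=21, sample_rate_hz=2, n_attacks=8,
                          gap_rate=0.2, seed=6)
        rec, log, _ = generate_recording(cfg)
        cal = CalendarConfig()
        before = {i for i, (s, _) in brute_classify(log, rec, cal).items() if s == "eligible"}
        rec.valid_mask[:] = True
        after = {i for i, (s, _) in brute_classify(log, rec, cal).items() if s == "eligible"}
        assert before <= after

    def test_matched_intervals_shared_construction_for_bins(self):
        rec = _recording()
        attack = _attack(8, 12, 0, 40)
        log = EventLog([attack])
        m = matched_intervals(_dt(8, 11), _dt(8, 11, 30), 0, log, rec, bin_id="-1h..-30m")
        assert m and all(c.bin_id == "-1h..-30m" for c in m)
        assert all((c.end - c.start) == timedelta(minutes=30) for c in m)
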