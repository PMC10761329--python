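"""Synthetic-recording generator: determinism, structure, effect direction."""

from dataclasses import replace
from datetime import datetime, timedelta
from zoneinfo import ZoneInfo

import numpy as np
import pytest
from scipy.stats import ks_2samp

from actidelta import SynthConfig, compute_ai, generate_recording, inject_missingness

TZ = ZoneInfo("Europe/Brussels")


def small_config(**kw):
    base = dict(study_days=2, sample_rate_hz=4, n_attacks=3, attacks_per_day=2.0,
                gap_rate=0.0, offbody_segments=[], seed=7)
    base.update(kw)
    return SynthConfig(**base)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = small_config(gap_rate=0.1, offbody_segments=None)
        r1, e1, g1 = generate_recording(cfg)
        r2, e2, g2 = generate_recording(cfg)
        assert np.array_equal(r1.samples, r2.samples)
        assert np.array_equal(r1.valid_mask, r2.valid_mask)
        assert [(a.onset, a.end, a.intensity, a.treatments) for a in e1] == \
               [(a.onset, a.end, a.intensity, a.treatments) for a in e2]
        assert np.array_equal(g1.state_per_minute, g2.state_per_minute)

    def test_different_seeds_differ(self):
        r1, _, _ = generate_recording(small_config(seed=1))
        r2, _, _ = generate_recording(small_config(seed=2))
        assert not np.array_equal(r1.samples, r2.samples)


class TestStructure:
    def test_degenerate_config_all_valid_no_events(self):
        cfg = small_config(n_attacks=0)
        rec, events, truth = generate_recording(cfg)
        assert rec.n_samples == cfg.n_samples
        assert rec.valid_mask.all()
        assert rec.on_body_mask.all()
        assert len(events) == 0
        assert not truth.gap_mask.any()

    def test_attacks_inside_study_and_disjoint(self):
        cfg = small_config(study_days=5, n_attacks=8, seed=3)
        _, events, truth = generate_recording(cfg)
        assert len(events) == 8
        for ev in events:
            assert cfg.study_start <= ev.onset < ev.end <= cfg.study_end
            assert 15 <= ev.duration_minutes <= 180
            assert ev.intensity in (2, 3, 4, 5)
        wins = sorted(truth.attack_windows)
        for (_, e1), (o2, _) in zip(wins, wins[1:]):
            assert o2 >= e1

    def test_explicit_overlapping_windows_rejected(self):
        t0 = datetime(2022, 1, 10, 10, 0, tzinfo=TZ)
        cfg = small_config(attack_windows=[
            (t0, t0 + timedelta(minutes=60)),
            (t0 + timedelta(minutes=30), t0 + timedelta(minutes=90)),
        ])
        with pytest.raises(ValueError, match="overlap"):
            generate_recording(cfg)

    def test_nighttime_fraction_forces_night_onsets(self):
        cfg = small_config(nighttime_attack_fraction=1.0, seed=5)
        _, events, _ = generate_recording(cfg)
        for ev in events:
            t = ev.onset.astimezone(TZ).time()
            assert t.hour >= 23 or (t.hour, t.minute) < (7, 30)

    def test_offbody_segment_has_frozen_gravity_and_low_variance(self):
        start = datetime(2022, 1, 10, 12, 0, tzinfo=TZ)
        cfg = small_config(offbody_segments=[(start, 60.0)], n_attacks=0, seed=9)
        rec, _, truth = generate_recording(cfg)
        seg = rec.samples[truth.offbody_mask]
        assert seg.std(axis=0, dtype=np.float64).max() < 0.004
        worn = rec.samples[~truth.offbody_mask]
        assert worn.std(axis=0, dtype=np.float64).min() > 0.004

    def test_masks_consistent_with_recording(self):
        cfg = small_config(gap_rate=0.1, seed=11)
        rec, _, truth = generate_recording(cfg)
        assert np.array_equal(rec.valid_mask, ~truth.gap_mask)
        assert rec.on_body_mask.all()  # wear detection has not run yet

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            small_config(gap_rate=1.0).validate()
        with pytest.raises(ValueError):
            small_config(state_sds={"rest": 0.0, "low": 0.03, "moderate": 0.1, "high": 0.3}).validate()
        bad_prof = SynthConfig().diurnal_profile
        bad_prof[3] = {"rest": 0.5, "low": 0.5, "moderate": 0.5, "high": 0.5}
        with pytest.raises(ValueError, match="sum to 1"):
            small_config(diurnal_profile=bad_prof).validate()


class TestInjectMissingness:
    def test_zero_rate_unchanged(self):
        rec, _, _ = generate_recording(small_config())
        assert inject_missingness(rec, 0.0, seed=1) is rec

    def test_gap_fraction_concentrates(self):
        rec, _, _ = generate_recording(SynthConfig(
            study_days=3, sample_rate_hz=2, n_attacks=0, gap_rate=0.0,
            offbody_segments=[], seed=0))
        n = rec.n_samples
        assert n > 500_000
        out = inject_missingness(rec, 0.25, seed=42)
        frac = 1.0 - out.valid_mask.mean()
        assert abs(frac - 0.25) < 0.01

    def test_deterministic_given_seed(self):
        rec, _, _ = generate_recording(small_config())
        a = inject_missingness(rec, 0.2, seed=5)
        b = inject_missingness(rec, 0.2, seed=5)
        assert np.array_equal(a.valid_mask, b.valid_mask)

    def test_rate_one_rejected(self):
        rec, _, _ = generate_recording(small_config())
        with pytest.raises(ValueError):
            inject_missingness(rec, 1.0, seed=1)

    def test_gaps_come_in_bursts(self):
        rec, _, _ = generate_recording(small_config(study_days=1))
        out = inject_missingness(rec, 0.2, seed=3)
        gaps = ~out.valid_mask
        runs = np.diff(np.flatnonzero(np.diff(gaps.astype(np.int8))))
        # mean gap burst should be on the order of a second of samples
        assert gaps.mean() > 0.1
        assert runs.size > 0


class TestEffectDirection:
    def _mean_ai_in_out(self, seed):
        cfg = small_config(attack_effect=0.2, seed=seed, n_attacks=3)
        rec, events, truth = generate_recording(cfg)
        ai = compute_ai(rec)
        inside, outside = [], []
        for ev in events:
            inside.extend(ai.valid_minutes_in(ev.onset, ev.end))
        for d in range(cfg.study_days):
            day0 = cfg.study_start + timedelta(days=d, hours=9)
            vals = ai.minutes_in(day0, day0 + timedelta(hours=12))
            outside.extend(vals[~np.isnan(vals)])
        att_min = np.zeros(cfg.n_minutes, bool)
        for o, e in truth.attack_windows:
            i0 = int((o - cfg.study_start).total_seconds() // 60)
            i1 = int((e - cfg.study_start).total_seconds() // 60)
            att_min[i0:i1] = True
        return float(np.mean(inside)), float(np.mean(outside))

    def test_suppression_lowers_mean_ai_in_every_seed(self):
        """attack_effect = 0.2 pushes within-attack AI below daytime baseline."""
        for seed in range(20):
            inside, outside = self._mean_ai_in_out(seed)
            assert inside < outside, f"seed {seed}: {inside} !< {outside}"

    def test_null_effect_matches_matched_windows_ks(self):
        """attack_effect = 1: within-attack and next-day same-clock AI are
        indistinguishable; a 5% KS test rejects in about 5% of seeds.

        Per-minute AI values are serially correlated through activity bouts,
        so minutes are thinned to every 10th before the KS test (which assumes
        independent samples)."""
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = small_config(attack_effect=1.0, seed=1000 + seed, n_attacks=2,
                               study_days=2, attacks_per_day=2.0,
                               attack_duration_bounds_min=(120.0, 180.0),
                               attack_duration_mean_min=150.0)
            rec, events, _ = generate_recording(cfg)
            ai = compute_ai(rec)
            inside, matched = [], []
            for ev in events:
                inside.extend(ai.valid_minutes_in(ev.onset, ev.end)[::10])
                shift = timedelta(days=1 if ev.onset.day == 10 else -1)
                matched.extend(ai.valid_minutes_in(ev.onset + shift, ev.end + shift)[::10])
            if len(inside) > 5 and len(matched) > 5:
                if ks_2samp(inside, matched).pvalue < 0.05:
                    rejections += 1
        assert 1 <= rejections <= 12  # central 98% band of Binomial(100, 0.05)
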