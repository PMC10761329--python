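"""Synthetic multi-day wrist-accelerometer recordings with embedded attacks.

The generator emulates the data structure the analysis assumes: a 21-day
continuous tri-axial recording at 32 Hz and ±2 g with

* a latent activity process — a first-order semi-Markov chain over
  {rest, low, moderate, high} with hour-of-day state weights (night dominated
  by rest) and geometric bout durations, giving bout-like per-minute AI
  distributions;
* per-sample acceleration = slowly drifting unit-norm gravity vector
  (constant within a minute) + zero-mean Gaussian noise with the latent
  state's SD, clipped to the device range;
* attack windows whose probability of the "high" state is multiplied by
  ``attack_effect`` (< 1 suppression, > 1 agitation, 1 null) from
  ``preictal_effect_minutes`` before onset through attack end;
* streaming gaps injected as short bursts, and daily off-body "charging"
  segments with frozen gravity orientation and near-zero noise.

Attacks are placed on a contiguous "bout" block of days (chronic cluster
headache presents with several attacks per day during active periods), with
onsets uniform over 08:00–22:00 by default; a configurable fraction can be
forced into the nighttime window to exercise the eligibility filters.

Everything is driven by one seed: same seed + same config gives byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from zoneinfo import ZoneInfo

import numpy as np

from .recording import AccRecording, AttackEvent, EventLog

STATES = ("rest", "low", "moderate", "high")

NIGHT_MINUTES = tuple(range(1380, 1440)) + tuple(range(0, 450))  # 23:00-07:30


def default_study_start() -> datetime:
    return datetime(2022, 1, 10, 0, 0, tzinfo=ZoneInfo("Europe/Brussels"))


def default_state_sds() -> dict:
    return {"rest": 0.005, "low": 0.03, "moderate": 0.10, "high": 0.30}


def default_state_dwell_minutes() -> dict:
    return {"rest": 8.0, "low": 4.0, "moderate": 2.0, "high": 1.0}


def default_diurnal_profile() -> dict:
    """Per-hour state occupancy weights (rows sum to 1).

    Weights are target fractions of time in each state; the latent-state
    sampler converts them to bout entry probabilities using the mean dwell
    times, so that the realized per-minute occupancy matches the profile.
    """
    night = {"rest": 0.95, "low": 0.04, "moderate": 0.008, "high": 0.002}
    shoulder = {"rest": 0.40, "low": 0.28, "moderate": 0.18, "high": 0.14}
    day = {"rest": 0.15, "low": 0.25, "moderate": 0.25, "high": 0.35}
    prof = {}
    for h in range(24):
        if h >= 23 or h < 8:
            prof[h] = dict(night)
        elif h in (8, 21, 22):
            prof[h] = dict(shoulder)
        else:
            prof[h] = dict(day)
    return prof


def default_treatment_probs() -> dict:
    return {"oxygen": 0.60, "combination_analgesic": 0.13, "unspecified": 0.13, "none": 0.14}


@dataclass
class SynthConfig:
    """Study conditions for one simulated participant."""

    study_start: datetime = field(default_factory=default_study_start)
    study_days: int = 21
    sample_rate_hz: int = 32
    state_sds: dict = field(default_factory=default_state_sds)
    state_dwell_minutes: dict = field(default_factory=default_state_dwell_minutes)
    diurnal_profile: dict = field(default_factory=default_diurnal_profile)
    n_attacks: int = 15
    attack_duration_mean_min: float = 37.0
    attack_duration_sd_min: float = 25.0
    attack_duration_bounds_min: tuple = (15.0, 180.0)
    attack_effect: float = 1.0
    preictal_effect_minutes: float = 30.0
    attacks_per_day: float = 2.5
    nighttime_attack_fraction: float = 0.0
    attack_windows: list | None = None  # explicit (onset, end) datetimes
    treatment_effect_map: dict | None = None  # label -> effect override (coupling knob)
    gap_rate: float = 0.02
    gap_burst_mean_s: float = 1.0
    offbody_segments: list | None = None  # None = daily charging; [] = none
    offbody_noise_sd: float = 0.001
    holiday_dates: frozenset = frozenset()
    intensity_probs: tuple = (0.30, 0.50, 0.15, 0.05)  # levels 2..5
    treatment_probs: dict = field(default_factory=default_treatment_probs)
    effectiveness_prob: float = 0.92
    gravity_drift: float = 0.05
    state_sd_jitter_halfwidth: float = 0.5  # per-minute intensity jitter, uniform 1±halfwidth
    range_g: float = 2.0
    seed: int = 0

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.study_start.tzinfo is None:
            raise ValueError("study_start must be timezone-aware")
        if self.study_days <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("study_days and sample_rate_hz must be positive")
        for s in STATES:
            if self.state_sds.get(s, 0) <= 0:
                raise ValueError(f"state SD for {s!r} must be positive")
            if self.state_dwell_minutes.get(s, 0) <= 0:
                raise ValueError(f"dwell time for {s!r} must be positive")
        for h in range(24):
            w = self.diurnal_profile[h]
            probs = [w[s] for s in STATES]
            if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1) > 1e-9:
                raise ValueError(f"hour {h}: state weights must be in [0,1] and sum to 1")
        if not (0 <= self.gap_rate < 1):
            raise ValueError(f"gap_rate must be in [0, 1), got {self.gap_rate}")
        if not (0 <= self.nighttime_attack_fraction <= 1):
            raise ValueError("nighttime_attack_fraction must be in [0, 1]")
        if not (0 <= self.state_sd_jitter_halfwidth < 1):
            raise ValueError("state_sd_jitter_halfwidth must be in [0, 1)")
        if self.attack_effect < 0:
            raise ValueError("attack_effect must be >= 0")
        lo, hi = self.attack_duration_bounds_min
        if not (0 < lo <= hi):
            raise ValueError("attack duration bounds must satisfy 0 < lo <= hi")

    @property
    def n_minutes(self) -> int:
        return self.study_days * 1440

    @property
    def n_samples(self) -> int:
        return self.n_minutes * 60 * self.sample_rate_hz

    @property
    def study_end(self) -> datetime:
        return self.study_start + timedelta(days=self.study_days)


@dataclass
class GroundTruth:
    """Latent quantities behind one generated recording (for recovery tests)."""

    attack_windows: list  # (onset, end) datetimes
    state_per_minute: np.ndarray  # int8 index into STATES
    gap_mask: np.ndarray  # per sample, True = lost to streaming gap
    offbody_mask: np.ndarray  # per sample, True = device off body
    effect_windows: list  # (start, end) datetimes where the attack effect applied
    sample_rate_hz: int = 32

    @property
    def state_per_sample(self) -> np.ndarray:
        return np.repeat(self.state_per_minute, 60 * self.sample_rate_hz)


# ---------------------------------------------------------------------------
# attack placement
# ---------------------------------------------------------------------------

def _minutes_from_start(config: SynthConfig, when: datetime) -> int:
    return int(round((when - config.study_start).total_seconds() / 60.0))


def _place_attacks(config: SynthConfig, rng: np.random.Generator) -> list:
    """Attack windows in whole minutes from study start: [(onset_min, end_min), ...]."""
    if config.attack_windows is not None:
        wins = []
        for onset, end in config.attack_windows:
            o, e = _minutes_from_start(config, onset), _minutes_from_start(config, end)
            if o < 0 or e > config.n_minutes or e <= o:
                raise ValueError(f"attack window {onset}..{end} outside study period")
            wins.append((o, e))
        wins.sort()
        for (o1, e1), (o2, e2) in zip(wins, wins[1:]):
            if o2 < e1:
                raise ValueError(
                    f"overlapping attack windows: minutes [{o1}, {e1}) and [{o2}, {e2})"
                )
        return wins

    if config.n_attacks == 0:
        return []
    lo, hi = config.attack_duration_bounds_min
    durations = np.clip(
        rng.normal(config.attack_duration_mean_min, config.attack_duration_sd_min,
                   config.n_attacks),
        lo, hi,
    )
    durations = np.maximum(1, np.rint(durations).astype(int))
    n_bout = min(config.study_days, max(1, math.ceil(config.n_attacks / config.attacks_per_day)))
    bout0 = int(rng.integers(0, config.study_days - n_bout + 1))
    placed = []
    for dur in durations:
        for _ in range(5000):
            day = bout0 + int(rng.integers(0, n_bout))
            if rng.random() < config.nighttime_attack_fraction:
                onset_mod = int(NIGHT_MINUTES[int(rng.integers(0, len(NIGHT_MINUTES)))])
            else:
                onset_mod = int(rng.integers(480, 1320))  # 08:00 - 22:00
            onset = day * 1440 + onset_mod
            end = onset + int(dur)
            if end > config.n_minutes:
                continue
            if all(end + 1 <= o or onset >= e + 1 for o, e in placed):
                placed.append((onset, end))
                break
        else:
            raise RuntimeError(
                f"could not place {config.n_attacks} non-overlapping attacks; "
                "reduce n_attacks or lengthen the study"
            )
    placed.sort()
    return placed


# ---------------------------------------------------------------------------
# latent state process
# ---------------------------------------------------------------------------

def _effect_weights(base: np.ndarray, eff: float) -> np.ndarray:
    """Multiply the high-state probability by ``eff`` and renormalize the rest."""
    w = base.copy()
    ph = min(0.95, w[3] * eff)
    if w[3] < 1.0:
        w[:3] *= (1.0 - ph) / (1.0 - w[3])
    w[3] = ph
    return w / w.sum()


def _latent_states(
    config: SynthConfig, rng: np.random.Generator, effect_min: np.ndarray
) -> np.ndarray:
    # profile weights are target occupancies; entry probabilities divide out the
    # mean bout length so that occupancy matches the profile
    prof = np.array([[config.diurnal_profile[h][s] for s in STATES] for h in range(24)])
    dwell = np.array([config.state_dwell_minutes[s] for s in STATES])
    prof = prof / dwell
    prof /= prof.sum(axis=1, keepdims=True)
    n_min = config.n_minutes
    # force a state redraw wherever the effect multiplier changes
    boundaries = list(np.flatnonzero(np.diff(effect_min)) + 1) + [n_min]
    states = np.empty(n_min, dtype=np.int8)
    m, bi = 0, 0
    start_hour = config.study_start.hour  # study_start is normally midnight-aligned
    while m < n_min:
        while boundaries[bi] <= m:
            bi += 1
        hour = (start_hour + m // 60) % 24
        w = prof[hour]
        eff = effect_min[m]
        if eff != 1.0:
            w = _effect_weights(w, eff)
        s = int(rng.choice(4, p=w))
        run = max(1, int(rng.geometric(1.0 / dwell[s])))
        end = min(m + run, boundaries[bi])
        states[m:end] = s
        m = end
    return states


# ---------------------------------------------------------------------------
# gaps and off-body segments
# ---------------------------------------------------------------------------

def _gap_mask(
    n: int, rate: int, gap_rate: float, burst_mean_s: float, rng: np.random.Generator
) -> np.ndarray:
    if gap_rate == 0 or n == 0:
        return np.zeros(n, dtype=bool)
    mean_off = max(1.0, burst_mean_s * rate)
    mean_on = mean_off * (1.0 - gap_rate) / gap_rate
    p_off = 1.0 / mean_off
    p_on = min(1.0, 1.0 / mean_on)
    k = int(n / (mean_on + mean_off) * 1.6) + 16
    while True:
        on_runs = rng.geometric(p_on, k)
        off_runs = rng.geometric(p_off, k)
        lens = np.empty(2 * k, dtype=np.int64)
        lens[0::2] = on_runs
        lens[1::2] = off_runs
        if lens.sum() >= n:
            break
        k *= 2
    flags = np.zeros(2 * k, dtype=bool)
    flags[1::2] = True
    return np.repeat(flags, lens)[:n]


def inject_missingness(
    recording: AccRecording, gap_rate: float, seed: int, burst_mean_s: float = 1.0
) -> AccRecording:
    """Mask a ``gap_rate`` fraction of samples in geometric-length bursts.

    Deterministic given ``seed``; a ``gap_rate`` of 0 returns the recording
    unchanged.
    """
    if not (0 <= gap_rate < 1):
        raise ValueError(f"gap_rate must be in [0, 1), got {gap_rate}")
    if gap_rate == 0:
        return recording
    rng = np.random.default_rng(seed)
    gaps = _gap_mask(recording.n_samples, recording.sample_rate_hz, gap_rate, burst_mean_s, rng)
    return replace(recording, valid_mask=recording.valid_mask & ~gaps)


def _offbody_minutes(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros(config.n_minutes, dtype=bool)
    if config.offbody_segments is None:
        # daily charging in the late evening, ~40 min with jitter
        for day in range(config.study_days):
            start = day * 1440 + 1330 + int(rng.integers(-20, 21))
            dur = 40 + int(rng.integers(-10, 11))
            mask[max(0, start): min(config.n_minutes, start + dur)] = True
    else:
        for start_dt, dur_min in config.offbody_segments:
            start = _minutes_from_start(config, start_dt)
            mask[max(0, start): min(config.n_minutes, start + int(round(dur_min)))] = True
    return mask


def _gravity(
    config: SynthConfig, rng: np.random.Generator, offbody_min: np.ndarray
) -> np.ndarray:
    """Per-minute unit gravity vector with slow orientation drift; frozen off-body."""
    n_min = config.n_minutes
    g0 = rng.standard_normal(3)
    g0 = 5.0 * g0 / np.linalg.norm(g0)
    raw = g0 + np.cumsum(config.gravity_drift * rng.standard_normal((n_min, 3)), axis=0)
    grav = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    # freeze orientation within each off-body run
    d = np.diff(offbody_min.astype(np.int8))
    run_starts = list(np.flatnonzero(d == 1) + 1)
    if offbody_min.size and offbody_min[0]:
        run_starts = [0] + run_starts
    run_ends = list(np.flatnonzero(d == -1) + 1)
    if offbody_min.size and offbody_min[-1]:
        run_ends = run_ends + [n_min]
    for s, e in zip(run_starts, run_ends):
        grav[s:e] = grav[s]
    return grav


# ---------------------------------------------------------------------------
# top-level generation
# ---------------------------------------------------------------------------

def _draw_events(
    config: SynthConfig, rng: np.random.Generator, windows_min: list
) -> EventLog:
    labels = sorted(config.treatment_probs)
    probs = np.array([config.treatment_probs[k] for k in labels])
    probs = probs / probs.sum()
    events = []
    for onset_m, end_m in windows_min:
        onset = config.study_start + timedelta(minutes=onset_m)
        end = config.study_start + timedelta(minutes=end_m)
        intensity = int(rng.choice([2, 3, 4, 5], p=config.intensity_probs))
        label = str(labels[int(rng.choice(len(labels), p=probs))])
        treatments = () if label == "none" else (label,)
        effective = None if label == "none" else bool(rng.random() < config.effectiveness_prob)
        events.append(AttackEvent(onset, end, intensity, treatments, effective))
    return EventLog(events, study_start=config.study_start, study_end=config.study_end)


def _attack_effect_for(config: SynthConfig, event: AttackEvent) -> float:
    if config.treatment_effect_map:
        return float(config.treatment_effect_map.get(event.treatment_label, config.attack_effect))
    return config.attack_effect


def generate_recording(config: SynthConfig) -> tuple:
    """Generate one participant's recording, event log, and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rate = config.sample_rate_hz
    spm = 60 * rate

    windows_min = _place_attacks(config, rng)
    event_log = _draw_events(config, rng, windows_min)

    # per-minute effect multiplier on the high-state probability
    effect_min = np.ones(config.n_minutes)
    effect_windows = []
    pre = int(round(config.preictal_effect_minutes))
    for (onset_m, end_m), ev in zip(windows_min, event_log):
        eff = _attack_effect_for(config, ev)
        if eff == 1.0:
            continue
        lo = max(0, onset_m - pre)
        effect_min[lo:end_m] = eff
        effect_windows.append(
            (config.study_start + timedelta(minutes=lo),
             config.study_start + timedelta(minutes=end_m))
        )

    states = _latent_states(config, rng, effect_min)
    offbody_min = _offbody_minutes(config, rng)
    sd_lookup = np.array([config.state_sds[s] for s in STATES])
    sd_min = sd_lookup[states]
    # movement intensity varies continuously within a state: mean-one uniform
    # per-minute multiplier on the movement states (rest stays at the device
    # noise floor), giving a piecewise-flat per-minute AI distribution
    if config.state_sd_jitter_halfwidth > 0:
        a = config.state_sd_jitter_halfwidth
        jitter = rng.uniform(1.0 - a, 1.0 + a, size=config.n_minutes)
        sd_min = np.where(states > 0, sd_min * jitter, sd_min)
    sd_min = np.where(offbody_min, config.offbody_noise_sd, sd_min)
    grav_min = _gravity(config, rng, offbody_min)

    # float32 throughout the hot path; per-minute quantities broadcast in place
    samples = rng.standard_normal((config.n_samples, 3), dtype=np.float32)
    by_minute = samples.reshape(config.n_minutes, spm, 3)
    by_minute *= sd_min.astype(np.float32)[:, None, None]
    by_minute += grav_min.astype(np.float32)[:, None, :]
    np.clip(samples, -config.range_g, config.range_g, out=samples)

    gaps = _gap_mask(config.n_samples, rate, config.gap_rate, config.gap_burst_mean_s, rng)
    recording = AccRecording(
        start_time=config.study_start,
        sample_rate_hz=rate,
        samples=samples,
        valid_mask=~gaps,
        range_g=config.range_g,
    )
    truth = GroundTruth(
        attack_windows=[
            (config.study_start + timedelta(minutes=o), config.study_start + timedelta(minutes=e))
            for o, e in windows_min
        ],
        state_per_minute=states,
        gap_mask=gaps,
        offbody_mask=np.repeat(offbody_min, spm),
        effect_windows=effect_windows,
        sample_rate_hz=rate,
    )
    return recording, event_log, truth
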