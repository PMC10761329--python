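"""Independent brute-force reference implementations used as test oracles.

These deliberately re-derive each rule from first principles (minute loops,
per-point distance checks, exhaustive enumeration) rather than reusing the
package's vectorized or interval-based logic.
"""

from datetime import datetime, time, timedelta
from itertools import product

import numpy as np
from scipy.stats import rankdata


def naive_ai_series(recording, params):
    """Per-second and per-minute AI via an explicit per-window loop."""
    rate = recording.sample_rate_hz
    spw = int(round(params.window_seconds * rate))
    n_sec = recording.n_samples // spw
    mask = recording.valid_mask & recording.on_body_mask
    need = int(np.ceil(params.min_valid_fraction_per_window * spw))
    ddof = 1 if params.variance_estimator == "sample_n_minus_1" else 0
    per_second = np.full(n_sec, np.nan)
    for s in range(n_sec):
        w = recording.samples[s * spw : (s + 1) * spw].astype(np.float64)
        m = mask[s * spw : (s + 1) * spw]
        k = int(m.sum())
        if k < need or k <= ddof:
            continue
        var = np.var(w[m], axis=0, ddof=ddof)
        excess = np.mean(var - params.systematic_noise_sd**2)
        per_second[s] = np.sqrt(max(0.0, excess))
    sec_per_min = int(round(60 / params.window_seconds))
    n_min = n_sec // sec_per_min
    per_minute = np.full(n_min, np.nan)
    for m in range(n_min):
        vals = per_second[m * sec_per_min : (m + 1) * sec_per_min]
        ok = vals[~np.isnan(vals)]
        if len(ok) >= params.min_valid_seconds_per_minute:
            per_minute[m] = ok.mean()
    return per_second, per_minute


def exact_wilcoxon_p(deltas):
    """Two-tailed signed-rank p by exhaustive enumeration of sign patterns."""
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_low = np.mean(ws <= w_obs + 1e-12)
    p_high = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_low, p_high))


def _minute_in_night(t: time, night_start: time, night_end: time) -> bool:
    return t >= night_start or t < night_end


def brute_is_daytime(attack, cal) -> bool:
    """Minute-by-minute nighttime check (boundaries are minute-aligned)."""
    m = attack.onset
    while m < attack.end:
        if _minute_in_night(m.astimezone(m.tzinfo).time(), cal.nighttime_start, cal.nighttime_end):
            return False
        m += timedelta(minutes=1)
    return True


def brute_data_ratio(start, end, recording) -> float:
    i0 = int(round((start - recording.start_time).total_seconds() * recording.sample_rate_hz))
    i1 = int(round((end - recording.start_time).total_seconds() * recording.sample_rate_hz))
    good = recording.valid_mask[i0:i1] & recording.on_body_mask[i0:i1]
    return float(np.count_nonzero(good)) / (i1 - i0)


def brute_valid_minutes(start, end, recording, min_seconds=30) -> int:
    """Number of whole minutes in [start, end) with >= min_seconds fully valid seconds."""
    rate = recording.sample_rate_hz
    count = 0
    m = start
    while m + timedelta(minutes=1) <= end:
        i0 = int(round((m - recording.start_time).total_seconds() * rate))
        ok_seconds = 0
        for s in range(60):
            sl = recording.valid_mask[i0 + s * rate : i0 + (s + 1) * rate] & \
                recording.on_body_mask[i0 + s * rate : i0 + (s + 1) * rate]
            if len(sl) == rate and sl.all():
                ok_seconds += 1
        if ok_seconds >= min_seconds:
            count += 1
        m += timedelta(minutes=1)
    return count


def brute_candidates(attack, event_log, recording, cal, min_ratio=0.75):
    """Independent calendar enumeration of matched non-attack windows."""
    tz = attack.onset.tzinfo
    h24 = timedelta(hours=24)
    onset_local = attack.onset.astimezone(tz)
    dur = attack.end - attack.onset
    ref_weekend = onset_local.date().weekday() in cal.weekend_days
    out = []
    d = recording.start_time.astimezone(tz).date()
    last = (recording.end_time.astimezone(tz) - timedelta(microseconds=1)).date()
    while d <= last:
        if d != onset_local.date():
            cs = datetime.combine(d, onset_local.timetz())
            ce = cs + dur
            ok = (d.weekday() in cal.weekend_days) == ref_weekend
            ok = ok and d not in cal.holiday_dates
            ok = ok and cs >= recording.start_time and ce <= recording.end_time
            if ok:
                for ev in event_log:
                    # every point of [cs, ce) at least 24 h from both boundaries
                    far_onset = ce <= ev.onset - h24 or cs >= ev.onset + h24
                    far_end = ce <= ev.end - h24 or cs >= ev.end + h24
                    if not (far_onset and far_end):
                        ok = False
                        break
            if ok and brute_data_ratio(cs, ce, recording) >= min_ratio:
                out.append((cs, ce))
        d += timedelta(days=1)
    return out


def brute_classify(event_log, recording, cal, min_ratio=0.75):
    """Independent eligibility funnel: attack index -> (status, candidates)."""
    out = {}
    for i, ev in enumerate(event_log):
        if not brute_is_daytime(ev, cal):
            out[i] = ("nighttime", [])
            continue
        if brute_data_ratio(ev.onset, ev.end, recording) < min_ratio:
            out[i] = ("low_data_ratio", [])
            continue
        cands = brute_candidates(ev, event_log, recording, cal, min_ratio)
        if not cands:
            out[i] = ("no_match", [])
            continue
        pooled = sum(brute_valid_minutes(cs, ce, recording) for cs, ce in cands)
        ch_minutes = brute_valid_minutes(ev.onset, ev.end, recording)
        if pooled < ev.duration_minutes or ch_minutes == 0:
            out[i] = ("insufficient_pool", cands)
            continue
        out[i] = ("eligible", cands)
    return out
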