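"""Activity index (AI^ABS) from raw tri-axial acceleration.

The absolute activity index over a window of duration H is

    AI = sqrt( max(0, (1/3) * sum_m (sigma_m^2 - sigma_i^2)) ),   m in {x, y, z}

where ``sigma_m^2`` is the signal variance of axis ``m`` over the window and
``sigma_i^2`` a systematic device-noise variance (0 for the Empatica E4 class
of devices, which makes the guard inert).  With the default H = 1 s at 32 Hz a
window is 32 samples.  Second-level values are averaged into per-minute values
when enough valid seconds are available.

The statistic is location-invariant (gravity and any constant offset cancel),
non-negative, and |c|-homogeneous when ``sigma_i`` is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from .recording import AccRecording

_ESTIMATOR_DDOF = {"sample_n_minus_1": 1, "population_n": 0}


@dataclass
class AIParams:
    """Tunables for AI computation.

    ``window_seconds`` is H.  A window contributes only when at least
    ``min_valid_fraction_per_window`` of its samples are present and on-body
    (default: all of them); a minute contributes only when at least
    ``min_valid_seconds_per_minute`` of its seconds are valid.
    """

    window_seconds: float = 1.0
    systematic_noise_sd: float = 0.0
    variance_estimator: str = "sample_n_minus_1"
    min_valid_fraction_per_window: float = 1.0
    min_valid_seconds_per_minute: int = 30

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if self.systematic_noise_sd < 0:
            raise ValueError("systematic_noise_sd must be >= 0")
        if self.variance_estimator not in _ESTIMATOR_DDOF:
            raise ValueError(f"unknown variance estimator {self.variance_estimator!r}")
        if not (0 < self.min_valid_fraction_per_window <= 1):
            raise ValueError("min_valid_fraction_per_window must be in (0, 1]")

    @property
    def ddof(self) -> int:
        return _ESTIMATOR_DDOF[self.variance_estimator]


def ai_second(window: np.ndarray, params: AIParams = None, valid: np.ndarray = None) -> float:
    """AI over one window of shape ``(n, 3)`` in g; NaN when too few samples are valid."""
    params = params or AIParams()
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != 3:
        raise ValueError(f"window must have shape (n, 3), got {window.shape}")
    n = window.shape[0]
    if valid is None:
        valid = np.ones(n, dtype=bool)
    k = int(np.count_nonzero(valid))
    if k < math.ceil(params.min_valid_fraction_per_window * n) or k <= params.ddof:
        return float("nan")
    var = np.var(window[valid], axis=0, ddof=params.ddof)
    mean_excess = np.mean(var - params.systematic_noise_sd**2)
    return math.sqrt(max(0.0, mean_excess))


def ai_minute(per_second: np.ndarray, params: AIParams = None) -> float:
    """Mean of valid (non-NaN) per-second values; NaN below the valid-seconds floor."""
    params = params or AIParams()
    vals = np.asarray(per_second, dtype=float)
    ok = ~np.isnan(vals)
    if np.count_nonzero(ok) < params.min_valid_seconds_per_minute:
        return float("nan")
    return float(vals[ok].mean())


@dataclass
class AISeries:
    """Per-second and per-minute AI values on the recording's clock grid.

    Invalid epochs are NaN.  ``start_time`` is the recording start; second s
    covers ``[start + s*H, start + (s+1)*H)`` and minute m covers the m-th
    whole minute from the start.
    """

    start_time: datetime
    window_seconds: float
    per_second: np.ndarray
    per_minute: np.ndarray
    params: AIParams = field(default_factory=AIParams)

    def minute_index(self, when: datetime) -> int:
        return int(round((when - self.start_time).total_seconds() / 60.0))

    def minutes_in(self, start: datetime, end: datetime) -> np.ndarray:
        """Per-minute values (incl. NaN) for whole minutes inside ``[start, end)``."""
        m0 = max(0, self.minute_index(start))
        m1 = min(len(self.per_minute), self.minute_index(end))
        return self.per_minute[m0:max(m0, m1)]

    def valid_minutes_in(self, start: datetime, end: datetime) -> np.ndarray:
        vals = self.minutes_in(start, end)
        return vals[~np.isnan(vals)]

    @property
    def minute_times(self) -> list:
        return [self.start_time + timedelta(minutes=m) for m in range(len(self.per_minute))]


def compute_ai(recording: AccRecording, params: AIParams = None, chunk_windows: int = 2_000_000) -> AISeries:
    """Compute per-second and per-minute AI for a whole recording.

    Samples that are gapped or off-body are excluded from their windows; the
    wear-detection stage must therefore run first so that ``on_body_mask``
    reflects actual wear.  Windows tile the recording (non-overlapping,
    clock-aligned); a trailing partial window is dropped.
    """
    params = params or AIParams()
    rate = recording.sample_rate_hz
    spw = int(round(params.window_seconds * rate))
    if spw < 1:
        raise ValueError("window shorter than one sample period")
    n_sec = recording.n_samples // spw
    per_second = np.full(n_sec, np.nan)
    mask = recording.analysis_mask
    need = math.ceil(params.min_valid_fraction_per_window * spw)
    sigma_i2 = params.systematic_noise_sd**2
    ddof = params.ddof

    for lo in range(0, n_sec, chunk_windows):
        hi = min(n_sec, lo + chunk_windows)
        s = slice(lo * spw, hi * spw)
        x = recording.samples[s].reshape(hi - lo, spw, 3)
        m = mask[s].reshape(hi - lo, spw)
        counts = m.sum(axis=1)
        # two-pass masked variance with float64 accumulation (stable when the
        # gravity offset dominates the within-window noise); when every window
        # must be complete anyway (the default), skip the masking entirely —
        # windows with missing samples are discarded below
        needs_masking = need < spw and not bool(m.all())
        xm = np.where(m[:, :, None], x, x.dtype.type(0)) if needs_masking else x
        mean = xm.sum(axis=1, dtype=np.float64) / np.maximum(counts, 1)[:, None]
        d = xm - mean[:, None, :].astype(x.dtype)
        if needs_masking:
            d *= m[:, :, None]
        ss = (d * d).sum(axis=1, dtype=np.float64)  # (k, 3)
        var = ss / np.maximum(counts - ddof, 1)[:, None]
        mean_excess = np.mean(var - sigma_i2, axis=1)
        vals = np.sqrt(np.maximum(0.0, mean_excess))
        ok = (counts >= need) & (counts > ddof)
        per_second[lo:hi] = np.where(ok, vals, np.nan)

    sec_per_min = int(round(60.0 / params.window_seconds))
    n_min = n_sec // sec_per_min
    mins = per_second[: n_min * sec_per_min].reshape(n_min, sec_per_min)
    ok_sec = ~np.isnan(mins)
    n_ok = ok_sec.sum(axis=1)
    with np.errstate(invalid="ignore"):
        sums = np.nansum(mins, axis=1)
        per_minute = np.where(n_ok >= params.min_valid_seconds_per_minute, sums / np.maximum(n_ok, 1), np.nan)

    return AISeries(
        start_time=recording.start_time,
        window_seconds=params.window_seconds,
        per_second=per_second,
        per_minute=per_minute,
        params=params,
    )
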