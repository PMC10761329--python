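"""Off-body (non-wear) detection from the accelerometer stream alone.

A worn wrist device shows per-axis variability well above the noise floor even
during sleep (posture shifts move the gravity vector across axes); a device
left on a table shows a frozen orientation and near-zero variance.  Detection
is a variance-floor rule: a 5-min window is a candidate when the per-axis
sample SD is below ``sd_threshold`` on all three axes; candidate runs shorter
than ``min_offbody_minutes`` are discarded and runs separated by less than
``merge_gap_minutes`` are merged.

Gapped (invalid) samples carry no wear information: windows without enough
present samples are never candidates, so an all-gap stretch keeps its current
wear status.  Detection reads only the raw samples and the gap mask, which
makes it idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import AccRecording


@dataclass
class WearParams:
    sd_threshold: float = 0.004  # g; between the off-body and worn-rest noise floors
    window_minutes: float = 5.0
    min_offbody_minutes: float = 15.0
    merge_gap_minutes: float = 2.0

    def __post_init__(self) -> None:
        for name in ("sd_threshold", "window_minutes", "min_offbody_minutes", "merge_gap_minutes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs."""
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    bounds = [0] + list(edges + 1) + [mask.size]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1) if mask[bounds[i]]]


def detect_offbody(recording: AccRecording, params: WearParams = None) -> np.ndarray:
    """Return a fresh on-body mask (False on detected off-body periods).

    Windows of ``window_minutes`` slide at a one-minute hop; a minute is
    off-body when it is covered by any window whose per-axis SD is below the
    threshold on all three axes, so segment edges are recovered to minute
    resolution.
    """
    params = params or WearParams()
    rate = recording.sample_rate_hz
    spm = 60 * rate
    n = recording.n_samples
    n_min = n // spm
    w = max(1, int(round(params.window_minutes)))
    on_body = np.ones(n, dtype=bool)
    if n_min < w:
        return on_body

    # per-minute masked first/second moments (float64; per-minute centering
    # keeps the window variance numerically stable under the ~1 g offset)
    x = recording.samples[: n_min * spm].reshape(n_min, spm, 3)
    m = recording.valid_mask[: n_min * spm].reshape(n_min, spm)
    cnt = m.sum(axis=1).astype(np.float64)
    xm = np.where(m[:, :, None], x, x.dtype.type(0))
    s1 = xm.sum(axis=1, dtype=np.float64)  # (n_min, 3)
    mu = s1 / np.maximum(cnt, 1)[:, None]
    d = xm - mu[:, None, :].astype(x.dtype)
    d *= m[:, :, None]
    ss = (d * d).sum(axis=1, dtype=np.float64)  # within-minute SS

    def rolling(a):
        c = np.cumsum(a, axis=0, dtype=np.float64)
        pad = np.zeros((1,) + a.shape[1:])
        c = np.concatenate([pad, c], axis=0)
        return c[w:] - c[:-w]

    N = rolling(cnt[:, None])[:, 0]
    S1 = rolling(s1)
    Q = rolling(cnt[:, None] * mu**2)
    SS = rolling(ss) + Q - S1**2 / np.maximum(N, 1)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        var = SS / np.maximum(N - 1, 1)[:, None]
        sd = np.sqrt(np.maximum(var, 0.0))
    enough = N >= max(2, (w * spm) // 2)  # too little data: no wear decision
    cand_start = enough & (sd < params.sd_threshold).all(axis=1)

    covered = np.zeros(n_min, dtype=bool)
    for j in np.flatnonzero(cand_start):
        covered[j : j + w] = True

    # merge runs separated by short gaps, then drop short runs
    runs = _runs(covered)
    merged = []
    for start, stop in runs:
        if merged and (start - merged[-1][1]) < params.merge_gap_minutes:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    for start, stop in merged:
        if (stop - start) >= params.min_offbody_minutes:
            on_body[start * spm : stop * spm] = False
    return on_body


def apply_wear_detection(recording: AccRecording, params: WearParams = None) -> AccRecording:
    """Convenience: return the recording with its on-body mask set by detection."""
    return recording.with_on_body(detect_offbody(recording, params))
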