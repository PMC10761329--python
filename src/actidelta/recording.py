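"""Core in-memory containers for wrist-accelerometer recordings and attack logs.

A recording is a uniformly sampled tri-axial acceleration series in g units on a
fixed grid anchored at ``start_time``: sample ``i`` is implicitly timestamped at
``start_time + i / sample_rate_hz`` seconds.  Streaming gaps are represented by
masking on this grid (``valid_mask``), never by deleting samples, so windowed
variance and data-ratio computations stay simple array operations.  Off-body
wear is a separate mask (``on_body_mask``) populated by the wear-detection
stage; on construction it is all-true.

All datetimes are timezone-aware.  Intervals are half-open ``[start, end)``
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np

#: Acute-treatment vocabulary used in attack logs.
TREATMENT_LABELS = frozenset(
    {
        "oxygen",
        "sumatriptan_sc",
        "zolmitriptan_nasal",
        "combination_analgesic",
        "unspecified",
        "none",
    }
)


def _require_aware(dt: datetime, name: str) -> None:
    if dt.tzinfo is None or dt.utcoffset() is None:
        raise ValueError(f"{name} must be timezone-aware, got naive {dt!r}")


@dataclass
class AccRecording:
    """Uniformly sampled tri-axial acceleration in g with validity masks.

    Parameters
    ----------
    start_time
        Timezone-aware timestamp of sample 0.
    sample_rate_hz
        Samples per second (uniform grid).
    samples
        ``(n, 3)`` float array of x/y/z acceleration in g.
    valid_mask
        Per-sample boolean; ``False`` marks a streaming gap (sample absent).
    on_body_mask
        Per-sample boolean; ``False`` marks a detected off-body period.
    range_g
        Dynamic range of the device; samples must lie within ``±range_g``.
    """

    start_time: datetime
    sample_rate_hz: int
    samples: np.ndarray
    valid_mask: np.ndarray = None  # type: ignore[assignment]
    on_body_mask: np.ndarray = None  # type: ignore[assignment]
    range_g: float = 2.0

    def __post_init__(self) -> None:
        _require_aware(self.start_time, "start_time")
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        self.samples = np.asarray(self.samples)
        if self.samples.dtype not in (np.float32, np.float64):
            self.samples = self.samples.astype(np.float64)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(f"samples must have shape (n, 3), got {self.samples.shape}")
        n = self.samples.shape[0]
        if self.valid_mask is None:
            self.valid_mask = np.ones(n, dtype=bool)
        if self.on_body_mask is None:
            self.on_body_mask = np.ones(n, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        self.on_body_mask = np.asarray(self.on_body_mask, dtype=bool)
        if len(self.valid_mask) != n or len(self.on_body_mask) != n:
            raise ValueError("samples, valid_mask and on_body_mask must have equal length")
        if n and self.valid_mask.any():
            # cheap whole-array bound first; only index by mask if it trips
            amax = max(float(self.samples.max()), -float(self.samples.min()))
            if amax > self.range_g + 1e-9:
                vmax = np.nanmax(np.abs(self.samples[self.valid_mask]))
                if vmax > self.range_g + 1e-9:
                    raise ValueError(
                        f"valid samples exceed device range ±{self.range_g} g "
                        f"(max |a| = {vmax:.4f})"
                    )

    # -- grid arithmetic ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def end_time(self) -> datetime:
        return self.start_time + timedelta(seconds=self.n_samples / self.sample_rate_hz)

    def index_at(self, when: datetime) -> int:
        """Grid index of the sample nearest to ``when`` (may be out of range)."""
        off = (when - self.start_time).total_seconds()
        return int(round(off * self.sample_rate_hz))

    def sample_slice(self, start: datetime, end: datetime) -> slice:
        """Index slice covering ``[start, end)``, clipped to the recording."""
        i0 = max(0, self.index_at(start))
        i1 = min(self.n_samples, self.index_at(end))
        return slice(i0, max(i0, i1))

    @property
    def analysis_mask(self) -> np.ndarray:
        """Samples that are both present and on-body."""
        return self.valid_mask & self.on_body_mask

    def with_on_body(self, mask: np.ndarray) -> "AccRecording":
        return replace(self, on_body_mask=np.asarray(mask, dtype=bool))


@dataclass(frozen=True)
class AttackEvent:
    """One registered headache attack (minute-precision onset/end)."""

    onset: datetime
    end: datetime
    intensity: int
    treatments: tuple = ()
    effective: bool | None = None

    def __post_init__(self) -> None:
        _require_aware(self.onset, "onset")
        _require_aware(self.end, "end")
        if self.end <= self.onset:
            raise ValueError(f"attack end must be after onset ({self.onset} .. {self.end})")
        if self.intensity not in (1, 2, 3, 4, 5):
            raise ValueError(f"intensity must be in 1..5, got {self.intensity}")
        object.__setattr__(self, "treatments", tuple(self.treatments))
        unknown = set(self.treatments) - TREATMENT_LABELS
        if unknown:
            raise ValueError(f"unknown treatment labels: {sorted(unknown)}")

    @property
    def duration_minutes(self) -> float:
        return (self.end - self.onset).total_seconds() / 60.0

    @property
    def treatment_label(self) -> str:
        """Single summary label for stratified analyses/plots."""
        return self.treatments[0] if self.treatments else "none"


@dataclass
class EventLog:
    """Ordered attack log for one participant over a study period."""

    events: list = field(default_factory=list)
    study_start: datetime | None = None
    study_end: datetime | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset)
        if self.study_start is not None and self.study_end is not None:
            for i, ev in enumerate(self.events):
                if ev.onset < self.study_start or ev.end > self.study_end:
                    raise ValueError(
                        f"event {i} ({ev.onset}..{ev.end}) outside study period "
                        f"{self.study_start}..{self.study_end}"
                    )

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __getitem__(self, i):
        return self.events[i]
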