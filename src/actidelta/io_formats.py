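"""Readers and writers for the accelerometer and event-log dialects.

Two recording dialects are supported:

* the Empatica-E4 ``ACC.csv`` dialect — header line 1 is the UNIX start epoch,
  line 2 the sample rate, and every following row holds integer counts where
  64 counts = 1 g;
* a generic timestamped CSV with ISO-8601 timestamps and x/y/z columns in
  either g or counts, resampled onto the uniform grid by nearest-sample
  snapping.

Event logs round-trip through CSV or JSON.  The E4 dialect quantizes to its
native 1/64 g resolution on write; the generic dialect is lossless to <1e-9 g.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .recording import AccRecording, AttackEvent, EventLog

log = logging.getLogger(__name__)

E4_COUNTS_PER_G = 64.0


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# E4 ACC dialect
# ---------------------------------------------------------------------------

def _header_value(row, path, lineno, what) -> float:
    vals = {v.strip() for v in row if v.strip() != ""}
    if not vals:
        raise ParseError(f"{path}:{lineno}: empty {what} header row")
    if len(vals) > 1:
        raise ParseError(f"{path}:{lineno}: inconsistent {what} header values {sorted(vals)}")
    try:
        return float(vals.pop())
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-numeric {what} header") from exc


def read_e4_acc_csv(path, tz=timezone.utc) -> AccRecording:
    """Read an E4-dialect ACC CSV (counts at 64/g) into an :class:`AccRecording`.

    Non-numeric body rows are kept on the grid but masked invalid (with a
    logged warning), mirroring how streaming gaps are represented internally.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    if len(rows) < 2:
        raise ParseError(f"{path}: missing E4 header (need epoch and sample-rate rows)")
    epoch = _header_value(rows[0], path, 1, "start-epoch")
    rate = _header_value(rows[1], path, 2, "sample-rate")
    if rate <= 0 or rate != int(rate):
        raise ParseError(f"{path}:2: sample rate must be a positive integer, got {rate}")
    start = datetime.fromtimestamp(epoch, tz=tz)

    body = rows[2:]
    n = len(body)
    samples = np.zeros((n, 3), dtype=float)
    valid = np.ones(n, dtype=bool)
    n_bad = 0
    for k, row in enumerate(body):
        try:
            if len(row) != 3:
                raise ValueError
            vals = [float(v) for v in row]
            if not all(math.isfinite(v) for v in vals):
                raise ValueError
            samples[k] = vals
        except ValueError:
            valid[k] = False
            n_bad += 1
    if n_bad:
        log.warning("%s: %d non-numeric row(s) masked invalid", path, n_bad)
    samples[valid] /= E4_COUNTS_PER_G
    return AccRecording(
        start_time=start, sample_rate_hz=int(rate), samples=samples, valid_mask=valid
    )


def write_e4_acc_csv(recording: AccRecording, path) -> None:
    """Write the E4 dialect: values quantized to integer counts (64/g);
    invalid samples are written as non-numeric rows so the mask round-trips."""
    counts = np.rint(recording.samples * E4_COUNTS_PER_G).astype(int)
    epoch = recording.start_time.timestamp()
    epoch_s = f"{epoch:.6f}".rstrip("0").rstrip(".")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([epoch_s] * 3)
        w.writerow([f"{recording.sample_rate_hz:.6f}"] * 3)
        for k in range(recording.n_samples):
            if recording.valid_mask[k]:
                w.writerow(list(counts[k]))
            else:
                w.writerow(["", "", ""])


# ---------------------------------------------------------------------------
# Generic timestamped CSV
# ---------------------------------------------------------------------------

@dataclass
class GenericSchema:
    """Column/unit conventions for the generic dialect."""

    timestamp_col: str = "timestamp"
    x_col: str = "x"
    y_col: str = "y"
    z_col: str = "z"
    units: str = "g"  # "g" or "counts"
    sample_rate_hz: int = 32


def read_generic_csv(path, schema: GenericSchema = None) -> AccRecording:
    """Read a generic timestamped CSV, snapping rows to the uniform grid.

    The grid is anchored at the first timestamp; grid slots with no row within
    half a sample period are masked invalid.  Duplicate timestamps are an
    error.
    """
    schema = schema or GenericSchema()
    df = pd.read_csv(path)
    for col in (schema.timestamp_col, schema.x_col, schema.y_col, schema.z_col):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    ts = pd.to_datetime(df[schema.timestamp_col], utc=True)
    if ts.duplicated().any():
        dups = ts[ts.duplicated()].unique()
        raise ParseError(f"{path}: duplicate timestamps: {list(dups[:5])}")
    if len(df) == 0:
        start = datetime.fromtimestamp(0, tz=timezone.utc)
        return AccRecording(start, schema.sample_rate_hz, np.empty((0, 3)))

    rate = schema.sample_rate_hz
    t0 = ts.iloc[0]
    off = (ts - t0).dt.total_seconds().to_numpy()
    idx = np.rint(off * rate).astype(int)
    resid = np.abs(off - idx / rate)
    snapped = resid <= (0.5 / rate) + 1e-12
    if np.unique(idx[snapped]).size != snapped.sum():
        raise ParseError(f"{path}: multiple rows snap to the same grid sample")

    n = int(idx[snapped].max()) + 1 if snapped.any() else 0
    samples = np.zeros((n, 3), dtype=float)
    valid = np.zeros(n, dtype=bool)
    vals = df[[schema.x_col, schema.y_col, schema.z_col]].to_numpy(dtype=float)
    if schema.units == "counts":
        vals = vals / E4_COUNTS_PER_G
    elif schema.units != "g":
        raise ParseError(f"unknown units {schema.units!r} (expected 'g' or 'counts')")
    keep = snapped & ~np.isnan(vals).any(axis=1)
    samples[idx[keep]] = vals[keep]
    valid[idx[keep]] = True
    start = t0.to_pydatetime()
    return AccRecording(start, rate, samples, valid_mask=valid)


def write_generic_csv(recording: AccRecording, path) -> None:
    """Write the generic dialect in g with full-precision ISO timestamps;
    invalid samples are written as NaN so the mask round-trips."""
    n = recording.n_samples
    step_ns = int(round(1e9 / recording.sample_rate_hz))
    t0 = pd.Timestamp(recording.start_time)
    ts = t0 + pd.to_timedelta(np.arange(n) * step_ns, unit="ns")
    vals = recording.samples.copy()
    vals[~recording.valid_mask] = np.nan
    df = pd.DataFrame(
        {"timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S.%f%z"),
         "x": vals[:, 0], "y": vals[:, 1], "z": vals[:, 2]}
    )
    df.to_csv(path, index=False, float_format="%.10f")


# ---------------------------------------------------------------------------
# Event logs
# ---------------------------------------------------------------------------

def _parse_dt(value, where: str) -> datetime:
    dt = datetime.fromisoformat(str(value))
    if dt.tzinfo is None:
        raise ParseError(f"{where}: timestamp {value!r} lacks a timezone offset")
    return dt


def _event_from_record(rec: dict, idx: int) -> AttackEvent:
    where = f"event record {idx}"
    onset = _parse_dt(rec["onset"], where)
    end = _parse_dt(rec["end"], where)
    if end <= onset:
        raise ParseError(f"{where}: end {end} is not after onset {onset}")
    intensity = int(rec["intensity"])
    if intensity not in (1, 2, 3, 4, 5):
        raise ParseError(f"{where}: intensity {intensity} outside 1..5")
    treatments = rec.get("treatments", [])
    if isinstance(treatments, str):
        treatments = [t for t in treatments.split(";") if t]
    elif treatments is None or (isinstance(treatments, float) and math.isnan(treatments)):
        treatments = []
    effective = rec.get("effective")
    if effective in ("", None) or (isinstance(effective, float) and math.isnan(effective)):
        effective = None
    elif isinstance(effective, str):
        effective = effective.strip().lower() in ("1", "true", "yes")
    else:
        effective = bool(effective)
    return AttackEvent(onset, end, intensity, tuple(treatments), effective)


def read_event_log(path) -> EventLog:
    """Read an attack log from CSV or JSON (ISO-8601 timestamps with zone).

    Overlapping attacks are accepted with a warning; records with end <= onset
    or intensity outside 1..5 are rejected naming the record index.
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        records = payload["events"] if isinstance(payload, dict) else payload
        study_start = study_end = None
        if isinstance(payload, dict):
            if payload.get("study_start"):
                study_start = _parse_dt(payload["study_start"], "study_start")
            if payload.get("study_end"):
                study_end = _parse_dt(payload["study_end"], "study_end")
    else:
        records = pd.read_csv(path).to_dict("records")
        study_start = study_end = None
    events = [_event_from_record(r, i) for i, r in enumerate(records)]
    events.sort(key=lambda e: e.onset)
    for a, b in zip(events, events[1:]):
        if b.onset < a.end:
            log.warning("overlapping attacks: %s..%s and %s..%s", a.onset, a.end, b.onset, b.end)
    return EventLog(events, study_start=study_start, study_end=study_end)


def _event_to_record(ev: AttackEvent) -> dict:
    return {
        "onset": ev.onset.isoformat(),
        "end": ev.end.isoformat(),
        "intensity": ev.intensity,
        "treatments": ";".join(ev.treatments),
        "effective": "" if ev.effective is None else ev.effective,
    }


def write_event_log(event_log: EventLog, path) -> None:
    path = str(path)
    records = [_event_to_record(ev) for ev in event_log]
    if path.endswith(".json"):
        for r in records:
            r["treatments"] = [t for t in r["treatments"].split(";") if t]
            if r["effective"] == "":
                r["effective"] = None
        payload = {
            "study_start": event_log.study_start.isoformat() if event_log.study_start else None,
            "study_end": event_log.study_end.isoformat() if event_log.study_end else None,
            "events": records,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        pd.DataFrame(records, columns=["onset", "end", "intensity", "treatments", "effective"]).to_csv(
            path, index=False
        )
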