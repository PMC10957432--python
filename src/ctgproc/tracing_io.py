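"""Ingestion of tall per-sample tracing CSVs.

A tracing file holds one row per sample with seven fields: tracing GUID,
trace time and recorded time (both in *milliseconds before birth*, i.e.
non-negative integers), measurement name (HR1/HR2/MHR/UP), sensor, monitor
and the reading.  On read, times are converted to the canonical signed
seconds-relative-to-birth axis and the rows are grouped into one
:class:`~ctgproc.segsig.SegmentedSignal` per unique
(measurement, sensor, monitor) combination — the *signal identity*.

Two data-quality rules from the upstream acquisition are applied here:

* several rows may share one (signal, timestamp) — resent packets; the
  rule keeps the valid reading, and among several differing valid readings
  the one written last (greatest row index), as it is likely a correction;
* maternal medical record numbers come in 7-, 8- or 12-digit forms and are
  normalized to 12 digits ("1100" prefix + zero-padded 8-digit id).

Samples earlier than 72 hours before birth are never analyzed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segsig import DELTA, EFMRecord, SegmentedSignal, build_segmented, restrict

__all__ = [
    "TALL_COLUMNS",
    "MRNResult",
    "normalize_mrn",
    "reading_is_valid",
    "resolve_duplicate_timestamps",
    "apply_birth_window",
    "parse_tracing_csv",
    "ParseReport",
]

#: header of the tall per-sample format
TALL_COLUMNS = [
    "tracing_guid",
    "trace_dt",
    "recorded_dt",
    "measurement",
    "sensor",
    "monitor",
    "reading",
]

#: accepted aliases (lower-cased, punctuation-stripped) per canonical column
COLUMN_ALIASES = {
    "tracing_guid": {"tracingguid", "traceidentifier", "tracing_guid", "guid"},
    "trace_dt": {"tracedt", "trace_dt"},
    "recorded_dt": {"recordeddt", "recorded_dt"},
    "measurement": {"measurement"},
    "sensor": {"sensor"},
    "monitor": {"monitor"},
    "reading": {"reading", "samplevalue"},
}

BIRTH_WINDOW_H = 72.0

#: physical validity ranges per measurement (0 bpm FHR is a dropout marker,
#: stored and therefore valid here; it is handled in repair)
VALID_RANGES = {
    "HR1": (0.0, 300.0),
    "HR2": (0.0, 300.0),
    "MHR": (0.0, 300.0),
    "UP": (0.0, 100.0),
}


# ---------------------------------------------------------------------------
# MRN normalization


@dataclass
class MRNResult:
    ok: bool
    value: str | None = None
    reason: str | None = None


def normalize_mrn(raw: str) -> MRNResult:
    """Normalize a maternal MRN to the canonical 12-digit form.

    7-digit ids are zero-padded to 8; 8-digit ids get the "1100" prefix;
    12-digit ids pass through.  Non-numeric content or any other length is
    rejected.
    """
    s = str(raw).strip()
    if not re.fullmatch(r"\d+", s):
        return MRNResult(False, reason="nonnumeric")
    if len(s) == 7:
        s = s.zfill(8)
    if len(s) == 8:
        s = "1100" + s
    if len(s) != 12:
        return MRNResult(False, reason="length")
    return MRNResult(True, value=s)


# ---------------------------------------------------------------------------
# duplicate-timestamp resolution


def reading_is_valid(measurement: str, reading) -> bool:
    """A reading is valid if non-empty, numeric and physically plausible."""
    if reading is None:
        return False
    try:
        v = float(reading)
    except (TypeError, ValueError):
        return False
    if np.isnan(v):
        return False
    lo, hi = VALID_RANGES.get(measurement, (-np.inf, np.inf))
    return lo <= v <= hi


def resolve_duplicate_timestamps(rows: pd.DataFrame) -> float | None:
    """Resolve rows sharing one (signal, trace_dt) to at most one reading.

    All-invalid -> None (dropped); one valid -> that reading; several valid
    -> the reading with the greatest row index (latest written).
    """
    meas = rows["measurement"].iloc[0]
    valid = rows[
        [reading_is_valid(meas, r) for r in rows["reading"]]
    ]
    if valid.empty:
        return None
    winner = valid.loc[valid["row_index"].idxmax()]
    return float(winner["reading"])


# ---------------------------------------------------------------------------
# birth window


def apply_birth_window(
    sig: SegmentedSignal, window_h: float = BIRTH_WINDOW_H
) -> tuple[SegmentedSignal, str]:
    """Drop samples earlier than ``window_h`` hours before birth.

    Returns the (possibly truncated) signal and a status: ``"matched"`` when
    anything survives, ``"outside_window_prior"`` when nothing does.
    """
    lo = -window_h * 3600.0
    if sig.is_empty:
        return sig, "outside_window_prior"
    hi = sig.segments[-1].end_time(sig.delta)
    out = restrict(sig, [(lo, max(hi, lo + sig.delta))])
    status = "matched" if not out.is_empty else "outside_window_prior"
    return out, status


# ---------------------------------------------------------------------------
# CSV parsing


@dataclass
class ParseReport:
    """Row/tracing disposition accounting (one report per file)."""

    status: str = "matched"
    n_rows: int = 0
    n_kept: int = 0
    n_dropped_duplicate: int = 0
    n_dropped_invalid: int = 0
    n_skipped_malformed: int = 0
    n_dropped_window: int = 0
    detail: str = ""
    counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "status": self.status,
            "n_rows": self.n_rows,
            "n_kept": self.n_kept,
            "n_dropped_duplicate": self.n_dropped_duplicate,
            "n_dropped_invalid": self.n_dropped_invalid,
            "n_skipped_malformed": self.n_skipped_malformed,
            "n_dropped_window": self.n_dropped_window,
            "detail": self.detail,
        }


def _canon(name: str) -> str:
    return re.sub(r"[^a-z0-9_]", "", name.strip().lower().replace(" ", ""))


def _map_columns(columns) -> dict:
    mapping = {}
    for col in columns:
        c = _canon(col)
        for canonical, aliases in COLUMN_ALIASES.items():
            if c in aliases:
                mapping[col] = canonical
    return mapping


def parse_tracing_csv(
    path,
    delta: float = DELTA,
    apply_window: bool = True,
) -> tuple[EFMRecord, ParseReport]:
    """Parse a tall tracing CSV into a raw-stage :class:`EFMRecord`.

    Times are given as milliseconds before birth and converted to negative
    seconds.  One signal is built per (measurement, sensor, monitor); rows
    with malformed timestamps are skipped and counted; duplicate timestamps
    are resolved by the highest-row rule.
    """
    df = pd.read_csv(path, dtype={"Reading": str, "reading": str})
    mapping = _map_columns(df.columns)
    missing = set(TALL_COLUMNS) - set(mapping.values())
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    df = df.rename(columns=mapping)[TALL_COLUMNS].copy()
    report = ParseReport(n_rows=len(df))
    guid = str(df["tracing_guid"].iloc[0]) if len(df) else ""
    if df.empty:
        report.status = "empty_file"
        return EFMRecord(guid=guid, stage="raw", provenance=str(path)), report
    df["row_index"] = np.arange(len(df))

    # timestamps: non-negative ms before birth -> signed seconds
    t_ms = pd.to_numeric(df["trace_dt"], errors="coerce")
    bad_ts = t_ms.isna() | (t_ms < 0)
    report.n_skipped_malformed = int(bad_ts.sum())
    df = df[~bad_ts].copy()
    if df.empty:
        report.status = "error"
        report.detail = "all timestamps malformed"
        return EFMRecord(guid=guid, stage="raw", provenance=str(path)), report
    df["time_s"] = -t_ms[~bad_ts].astype(float) / 1000.0

    signals: dict = {}
    for (meas, sensor, monitor), grp in df.groupby(
        ["measurement", "sensor", "monitor"], sort=True
    ):
        grp = grp.sort_values(["time_s", "row_index"])
        vals = pd.to_numeric(grp["reading"], errors="coerce")
        lo, hi = VALID_RANGES.get(meas, (-np.inf, np.inf))
        valid = vals.notna() & (vals >= lo) & (vals <= hi)
        dup = grp["time_s"].duplicated(keep=False)

        samples: list[tuple[float, float]] = []
        # common path: unique timestamps, vectorized
        uni = grp[~dup]
        report.n_dropped_invalid += int((~valid[~dup]).sum())
        samples.extend(
            zip(uni.loc[valid[~dup], "time_s"], vals[~dup][valid[~dup]])
        )
        # rare path: resent packets sharing a timestamp
        for t, sub in grp[dup].groupby("time_s", sort=True):
            v = resolve_duplicate_timestamps(sub)
            if v is None:
                report.n_dropped_invalid += len(sub)
            else:
                samples.append((t, v))
                report.n_dropped_duplicate += len(sub) - 1
        samples.sort(key=lambda p: p[0])
        if not samples:
            continue
        units = "0-100" if meas == "UP" else "BPM"
        sig = build_segmented(
            samples,
            delta=delta,
            measurement=meas,
            units=units,
            sensor=str(sensor),
            monitor=str(monitor),
        )
        if apply_window:
            n_before = sig.n_samples
            sig, status = apply_birth_window(sig)
            report.n_dropped_window += n_before - sig.n_samples
            if sig.is_empty:
                continue
        signals[(meas, str(sensor), str(monitor))] = sig

    report.n_kept = int(sum(s.n_samples for s in signals.values()))
    if not signals:
        report.status = (
            "outside_window_prior" if report.n_dropped_window else "empty_file"
        )
    record = EFMRecord(
        guid=guid, stage="raw", signals=signals, provenance=str(path)
    )
    return record, report


def write_tracing_csv(record: EFMRecord, path) -> None:
    """Write a raw-stage record back to the tall CSV format (round trip)."""
    rows = []
    for (meas, sensor, monitor), sig in record.signals.items():
        times = sig.sample_times()
        for t, v in zip(times, sig.data):
            rows.append(
                {
                    "tracing_guid": record.guid,
                    "trace_dt": int(round(-t * 1000.0)),
                    "recorded_dt": int(round(-t * 1000.0)),
                    "measurement": meas,
                    "sensor": sensor,
                    "monitor": monitor,
                    "reading": v,
                }
            )
    pd.DataFrame(rows, columns=TALL_COLUMNS).to_csv(path, index=False)
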