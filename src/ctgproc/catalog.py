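"""Relational persistence and coverage statistics.

A single-file SQLite store mirrors the processing-tracking and pattern
schemas: per-tracing status, per-signal and per-segment statistics,
events, per-epoch features and processing provenance.  Every table can
also be exported to CSV.  Re-running a processing step upserts status
rows instead of duplicating them.
"""

from __future__ import annotations

import json
import sqlite3
from pathlib import Path

import numpy as np
import pandas as pd

from .segsig import EFMRecord, find_gaps
from .patterns import Event
from .features import EpochFeatures

__all__ = [
    "CatalogDB",
    "write_catalog",
    "coverage_curve",
    "signal_coverage_epochs",
]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS CTG_Status (
    tracing_guid TEXT PRIMARY KEY,
    stage TEXT NOT NULL,
    source_file TEXT,
    updated TEXT DEFAULT CURRENT_TIMESTAMP
);
CREATE TABLE IF NOT EXISTS Processing (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    tracing_guid TEXT NOT NULL,
    step TEXT NOT NULL,
    completed TEXT DEFAULT CURRENT_TIMESTAMP,
    UNIQUE (tracing_guid, step)
);
CREATE TABLE IF NOT EXISTS Tracing (
    tracing_id INTEGER PRIMARY KEY AUTOINCREMENT,
    tracing_guid TEXT UNIQUE NOT NULL
);
CREATE TABLE IF NOT EXISTS DomainStart (
    tracing_guid TEXT PRIMARY KEY,
    start_s REAL NOT NULL
);
CREATE TABLE IF NOT EXISTS signalStats (
    tracing_guid TEXT NOT NULL,
    signal TEXT NOT NULL,
    sensor TEXT,
    monitor TEXT,
    n_segments INTEGER,
    n_samples INTEGER,
    start_s REAL,
    end_s REAL,
    coverage REAL,
    PRIMARY KEY (tracing_guid, signal)
);
CREATE TABLE IF NOT EXISTS segmentStats (
    tracing_guid TEXT NOT NULL,
    signal TEXT NOT NULL,
    segment_index INTEGER NOT NULL,
    start_s REAL,
    n_samples INTEGER,
    sensor TEXT,
    monitor TEXT,
    PRIMARY KEY (tracing_guid, signal, segment_index)
);
CREATE TABLE IF NOT EXISTS guidStats (
    tracing_guid TEXT PRIMARY KEY,
    n_signals INTEGER,
    total_samples INTEGER,
    start_s REAL,
    end_s REAL
);
CREATE TABLE IF NOT EXISTS Event_Type (
    event_type_id INTEGER PRIMARY KEY,
    name TEXT UNIQUE NOT NULL
);
CREATE TABLE IF NOT EXISTS Event (
    event_id INTEGER PRIMARY KEY AUTOINCREMENT,
    tracing_guid TEXT NOT NULL,
    event_type_id INTEGER NOT NULL,
    start_s REAL NOT NULL,
    end_s REAL NOT NULL,
    subtype TEXT,
    attrs TEXT
);
CREATE TABLE IF NOT EXISTS features4epoch (
    tracing_guid TEXT NOT NULL,
    epoch_index INTEGER NOT NULL,
    start_s REAL,
    end_s REAL,
    payload TEXT,
    PRIMARY KEY (tracing_guid, epoch_index)
);
CREATE TABLE IF NOT EXISTS Tracing_Epoch_EventCount (
    tracing_guid TEXT NOT NULL,
    epoch_index INTEGER NOT NULL,
    event_type TEXT NOT NULL,
    n_events INTEGER,
    PRIMARY KEY (tracing_guid, epoch_index, event_type)
);
CREATE TABLE IF NOT EXISTS InfantRecord (
    infant_id TEXT PRIMARY KEY,
    study_group TEXT,
    severity TEXT,
    evidence TEXT
);
"""

_EVENT_TYPES = ["BAS", "ACC", "DEC", "CON", "NOI", "RIN"]


class CatalogDB:
    """Thin wrapper over the SQLite store."""

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.executescript(_SCHEMA)
        for i, name in enumerate(_EVENT_TYPES, start=1):
            self.conn.execute(
                "INSERT OR IGNORE INTO Event_Type (event_type_id, name) VALUES (?, ?)",
                (i, name),
            )
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    # -- writers ----------------------------------------------------------

    def upsert_status(self, guid: str, stage: str, source_file: str = "") -> None:
        self.conn.execute(
            "INSERT INTO CTG_Status (tracing_guid, stage, source_file) VALUES (?,?,?) "
            "ON CONFLICT(tracing_guid) DO UPDATE SET stage=excluded.stage, "
            "source_file=excluded.source_file, updated=CURRENT_TIMESTAMP",
            (guid, stage, source_file),
        )
        self.conn.execute(
            "INSERT OR IGNORE INTO Processing (tracing_guid, step) VALUES (?,?)",
            (guid, stage),
        )
        self.conn.execute(
            "INSERT OR IGNORE INTO Tracing (tracing_guid) VALUES (?)", (guid,)
        )
        self.conn.commit()

    def write_record_stats(self, record: EFMRecord) -> None:
        total = 0
        lo, hi = np.inf, -np.inf
        for key, sig in record.signals.items():
            name = key if isinstance(key, str) else "/".join(key)
            if sig.is_empty:
                continue
            s0 = sig.segments[0].start_time
            s1 = sig.segments[-1].end_time(sig.delta)
            span = s1 - s0
            cov = sig.n_samples * sig.delta / span if span > 0 else 0.0
            self.conn.execute(
                "INSERT OR REPLACE INTO signalStats VALUES (?,?,?,?,?,?,?,?,?)",
                (
                    record.guid, name,
                    sig.segments[0].sensor, sig.segments[0].monitor,
                    sig.n_segments, sig.n_samples, s0, s1, cov,
                ),
            )
            for k, seg in enumerate(sig.segments):
                self.conn.execute(
                    "INSERT OR REPLACE INTO segmentStats VALUES (?,?,?,?,?,?,?)",
                    (record.guid, name, k, seg.start_time, seg.n_samples,
                     seg.sensor, seg.monitor),
                )
            total += sig.n_samples
            lo, hi = min(lo, s0), max(hi, s1)
        if np.isfinite(lo):
            self.conn.execute(
                "INSERT OR REPLACE INTO guidStats VALUES (?,?,?,?,?)",
                (record.guid, len(record.signals), total, lo, hi),
            )
            self.conn.execute(
                "INSERT OR REPLACE INTO DomainStart VALUES (?,?)",
                (record.guid, lo),
            )
        self.conn.commit()

    def write_events(self, guid: str, events: list[Event]) -> None:
        type_id = {
            name: i for name, i in self.conn.execute(
                "SELECT name, event_type_id FROM Event_Type"
            )
        }
        self.conn.execute("DELETE FROM Event WHERE tracing_guid = ?", (guid,))
        for ev in events:
            self.conn.execute(
                "INSERT INTO Event (tracing_guid, event_type_id, start_s, end_s,"
                " subtype, attrs) VALUES (?,?,?,?,?,?)",
                (guid, type_id[ev.type], ev.start_s, ev.end_s, ev.subtype,
                 json.dumps(ev.attrs)),
            )
        self.conn.commit()

    def read_events(self, guid: str) -> list[Event]:
        name_of = {
            i: name for i, name in self.conn.execute(
                "SELECT event_type_id, name FROM Event_Type"
            )
        }
        out = []
        for tid, start, end, subtype, attrs in self.conn.execute(
            "SELECT event_type_id, start_s, end_s, subtype, attrs FROM Event "
            "WHERE tracing_guid = ? ORDER BY start_s", (guid,)
        ):
            out.append(
                Event(guid, name_of[tid], start, end, json.loads(attrs),
                      subtype=subtype)
            )
        return out

    def write_features(self, feats: list[EpochFeatures]) -> None:
        for f in feats:
            self.conn.execute(
                "INSERT OR REPLACE INTO features4epoch VALUES (?,?,?,?,?)",
                (
                    f.guid, f.epoch_index, f.start_s, f.end_s,
                    json.dumps({str(k): v for k, v in f.to_row().items()}),
                ),
            )
        self.conn.commit()

    def write_epoch_event_counts(
        self, guid: str, events: list[Event], epoch_s: float = 1200.0
    ) -> None:
        for ev in events:
            k = int(np.floor(-ev.start_s / epoch_s))
            self.conn.execute(
                "INSERT INTO Tracing_Epoch_EventCount VALUES (?,?,?,1) "
                "ON CONFLICT(tracing_guid, epoch_index, event_type) "
                "DO UPDATE SET n_events = n_events + 1",
                (guid, k, ev.type),
            )
        self.conn.commit()

    def write_infant(self, infant_id: str, group: str, severity: str | None,
                     evidence: str) -> None:
        self.conn.execute(
            "INSERT OR REPLACE INTO InfantRecord VALUES (?,?,?,?)",
            (infant_id, group, severity, evidence),
        )
        self.conn.commit()

    def export_csv(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        tables = [
            r[0] for r in self.conn.execute(
                "SELECT name FROM sqlite_master WHERE type='table'"
            )
        ]
        for tb in tables:
            df = pd.read_sql_query(f"SELECT * FROM {tb}", self.conn)
            p = out_dir / f"{tb}.csv"
            df.to_csv(p, index=False)
            paths.append(p)
        return paths


def write_catalog(
    records: list[EFMRecord],
    events_by_guid: dict[str, list[Event]] | None = None,
    features_by_guid: dict[str, list[EpochFeatures]] | None = None,
    db_path: str | Path = "ctg.sqlite",
) -> CatalogDB:
    """Populate the relational store from pipeline outputs."""
    db = CatalogDB(db_path)
    for rec in records:
        db.upsert_status(rec.guid, rec.stage, rec.provenance)
        db.write_record_stats(rec)
        if events_by_guid and rec.guid in events_by_guid:
            db.write_events(rec.guid, events_by_guid[rec.guid])
            db.write_epoch_event_counts(rec.guid, events_by_guid[rec.guid])
        if features_by_guid and rec.guid in features_by_guid:
            db.write_features(features_by_guid[rec.guid])
    return db


# ---------------------------------------------------------------------------
# coverage statistics


def signal_coverage_epochs(
    record: EFMRecord, epoch_s: float = 1200.0
) -> pd.DataFrame:
    """Per-signal fraction of each 20-minute epoch covered by samples."""
    rows = []
    for key, sig in record.signals.items():
        name = key if isinstance(key, str) else "/".join(key)
        if sig.is_empty:
            continue
        times = sig.sample_times()
        first_epoch = int(np.floor(-times.max() / epoch_s))
        last_epoch = int(np.floor((-times.min() - 1e-9) / epoch_s))
        epoch_n = int(round(epoch_s / sig.delta))
        for k in range(first_epoch, last_epoch + 1):
            lo, hi = -(k + 1) * epoch_s, -k * epoch_s
            n = int(((times >= lo) & (times < hi)).sum())
            rows.append(
                {
                    "tracing_guid": record.guid,
                    "signal": name,
                    "epoch_index": k,
                    "coverage": n / epoch_n,
                }
            )
    return pd.DataFrame(rows, columns=["tracing_guid", "signal", "epoch_index", "coverage"])


def coverage_curve(
    records: list[EFMRecord],
    groups: dict[str, str],
    window_h: float = 72.0,
) -> pd.DataFrame:
    """Per-hour fraction of records with both FHR and UA data, per group.

    For each hour bin in [-window_h, 0), a record counts as covered when
    it has at least one FHR and one UA sample in the bin.  Groups with no
    records are omitted.
    """
    edges = np.arange(-window_h, 0.0 + 1e-9, 1.0) * 3600.0
    per_group: dict[str, list[np.ndarray]] = {}
    for rec in records:
        grp = groups.get(rec.guid)
        if grp is None:
            continue
        cov = np.zeros(edges.size - 1, dtype=bool)
        fhr = rec.signals.get("FHR")
        ua = rec.signals.get("UA")
        if fhr is not None and ua is not None and not fhr.is_empty and not ua.is_empty:
            tf = fhr.sample_times()
            tu = ua.sample_times()
            hf, _ = np.histogram(tf, bins=edges)
            hu, _ = np.histogram(tu, bins=edges)
            cov = (hf > 0) & (hu > 0)
        per_group.setdefault(grp, []).append(cov)
    rows = []
    for grp, covs in per_group.items():
        frac = np.mean(np.vstack(covs), axis=0)
        for i, f in enumerate(frac):
            rows.append(
                {
                    "group": grp,
                    "hour_bin_start_h": edges[i] / 3600.0,
                    "fraction_covered": float(f),
                }
            )
    return pd.DataFrame(rows, columns=["group", "hour_bin_start_h", "fraction_covered"])
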