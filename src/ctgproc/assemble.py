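"""Combining per-sensor channels into per-measurement signals.

During labor the same physiological quantity is often recorded through
different sensors at different times: fetal heart rate starts on an
external ultrasound transducer and switches to a scalp-electrode ECG
(FECG) near birth; uterine activity starts on an external
tocodynamometer (TOCO) and may switch to an intrauterine pressure
catheter.  This module merges those channels into a single FHR, UA and
MHR signal per tracing, giving the more accurate sensor precedence
wherever channels overlap, while retaining sample-by-sample sensor
provenance in the segment table.

It also implements the file-level bookkeeping for infants linked to more
than one tracing: exact-content duplicates, overlapping "SPECIAL" files,
and concatenated multi-pregnancy files that must be split at birth times.
"""

from __future__ import annotations

import numpy as np

from .segsig import (
    DELTA,
    EFMRecord,
    Segment,
    SegmentedSignal,
    build_segmented,
    time_to_index,
)

__all__ = [
    "combine_sensors",
    "detect_duplicate_tracings",
    "split_concatenated_pregnancies",
]

# higher rank wins where channels overlap in time
_FHR_SENSOR_RANK = {"FECG": 2, "external": 1}
_UA_SENSOR_RANK = {"Internal": 2, "TOCO": 1}
_RECEPTACLE_RANK = {"HR2": 1, "HR1": 0}  # HR2 was the usual receptacle


def _merge_channels(
    channels: list[SegmentedSignal],
    precedence_key,
    measurement: str,
    units: str,
) -> SegmentedSignal | None:
    """Pointwise merge: write channels in ascending precedence on a common
    grid so higher-precedence samples overwrite lower ones, then rebuild
    segments, splitting wherever the winning (sensor, monitor) changes."""
    channels = [c for c in channels if not c.is_empty]
    if not channels:
        return None
    delta = channels[0].delta
    i0 = min(int(time_to_index(c.segments[0].start_time, delta)) for c in channels)
    i1 = max(
        int(time_to_index(c.segments[-1].start_time, delta))
        + c.segments[-1].n_samples
        for c in channels
    )
    n = i1 - i0
    vals = np.full(n, np.nan)
    prov = np.full(n, -1, dtype=np.int64)  # index into provenance table
    prov_table: list[tuple[str, str]] = []

    for ch in sorted(channels, key=precedence_key):
        for seg, off in zip(ch.segments, ch.onset_offsets):
            pid = len(prov_table)
            prov_table.append((seg.sensor, seg.monitor))
            j = int(time_to_index(seg.start_time, delta)) - i0
            vals[j : j + seg.n_samples] = ch.data[off : off + seg.n_samples]
            prov[j : j + seg.n_samples] = pid

    present = ~np.isnan(vals)
    if not present.any():
        return None
    # segment boundaries: gaps or provenance changes
    idx = np.flatnonzero(present)
    brk = np.flatnonzero(
        (np.diff(idx) > 1) | (prov[idx][1:] != prov[idx][:-1])
    ) + 1
    bounds = np.concatenate([[0], brk, [idx.size]])
    segments = []
    chunks = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        sl = idx[a:b]
        sensor, monitor = prov_table[prov[sl[0]]]
        segments.append(
            Segment(
                start_time=(i0 + sl[0]) * delta,
                n_samples=int(sl.size),
                sensor=sensor,
                monitor=monitor,
            )
        )
        chunks.append(vals[sl])
    return SegmentedSignal(
        measurement, np.concatenate(chunks), segments, delta, units
    )


def combine_sensors(raw: EFMRecord) -> EFMRecord:
    """Merge raw channels into one FHR, one UA and one MHR signal.

    FHR merges the HR1/HR2 channels with FECG taking precedence over the
    external ultrasound sensor (and HR2 over HR1 among equal sensors);
    UA merges UP channels with the internal pressure catheter over TOCO;
    MHR passes through.  Combining an already-combined record is a no-op.
    """
    if raw.stage != "raw":
        return EFMRecord(
            guid=raw.guid,
            stage="combined",
            signals={k: v.copy() for k, v in raw.signals.items()},
            provenance=raw.provenance,
        )
    fhr_ch, ua_ch, mhr_ch = [], [], []
    for key, sig in raw.signals.items():
        meas = key[0] if isinstance(key, tuple) else sig.measurement
        if meas in ("HR1", "HR2"):
            fhr_ch.append((meas, sig))
        elif meas == "UP":
            ua_ch.append(sig)
        elif meas == "MHR":
            mhr_ch.append(sig)

    signals = {}
    fhr = _merge_channels(
        [s for _, s in fhr_ch],
        precedence_key=lambda c: (
            _FHR_SENSOR_RANK.get(c.segments[0].sensor, 0),
            _RECEPTACLE_RANK.get(c.measurement, 0),
        ),
        measurement="FHR",
        units="BPM",
    )
    if fhr is not None:
        signals["FHR"] = fhr
    ua = _merge_channels(
        ua_ch,
        precedence_key=lambda c: _UA_SENSOR_RANK.get(c.segments[0].sensor, 0),
        measurement="UA",
        units="0-100",
    )
    if ua is not None:
        signals["UA"] = ua
    mhr = _merge_channels(
        mhr_ch,
        precedence_key=lambda c: 0,
        measurement="MHR",
        units="BPM",
    )
    if mhr is not None:
        signals["MHR"] = mhr

    prov = raw.provenance
    if "FHR" not in signals:
        prov = (prov + "; " if prov else "") + "flag:no-FHR-channel"
    return EFMRecord(guid=raw.guid, stage="combined", signals=signals, provenance=prov)


def detect_duplicate_tracings(candidates: list[EFMRecord]) -> dict:
    """Sort multiple tracings linked to one infant into dispositions.

    Exact-content duplicates keep one representative (lowest GUID);
    distinct files overlapping in time are all "special"; more than one
    distinct non-overlapping file excludes them all.
    """
    if not candidates:
        raise ValueError("no candidates")
    ordered = sorted(candidates, key=lambda r: r.guid)
    reps: list[EFMRecord] = []
    duplicates: list[EFMRecord] = []
    for rec in ordered:
        for rep in reps:
            if rec.content_equal(rep):
                duplicates.append(rec)
                break
        else:
            reps.append(rec)

    out = {"retained": [], "duplicates": duplicates, "special": [], "excluded": []}
    if len(reps) == 1:
        out["retained"] = reps
        return out
    ranges = [r.time_range() for r in reps]
    overlap = False
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            a, b = ranges[i], ranges[j]
            if a is not None and b is not None and a[0] < b[1] and b[0] < a[1]:
                overlap = True
    if overlap:
        out["special"] = reps
    else:
        out["excluded"] = reps
    return out


def split_concatenated_pregnancies(
    sig: SegmentedSignal,
    birth_times: list[float],
    window_h: float = 72.0,
) -> list[SegmentedSignal]:
    """Split a multi-pregnancy signal into one rebased signal per birth.

    ``sig`` carries times on a single maternal clock; each sample is
    assigned to the nearest following birth provided it lies within
    ``window_h`` hours before it, and the output signals are rebased so
    each birth is time 0.  Samples matching no birth are discarded.
    """
    if not birth_times:
        raise ValueError("empty birth list")
    births = np.sort(np.asarray(birth_times, dtype=float))
    times = sig.sample_times()
    out: list[SegmentedSignal] = []
    if times.size == 0:
        return out
    idx = np.searchsorted(births, times, side="left")
    for k, b in enumerate(births):
        mask = (idx == k) & (b - times <= window_h * 3600.0)
        if not mask.any():
            continue
        out.append(
            build_segmented(
                zip(times[mask] - b, sig.data[mask]),
                delta=sig.delta,
                measurement=sig.measurement,
                units=sig.units,
            )
        )
    return out
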