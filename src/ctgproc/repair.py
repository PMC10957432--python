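"""FHR repair: dropout removal, short-gap interpolation, artifact flagging.

Fetal monitors store a heart-rate value of 0 bpm when they cannot estimate
the rate (a *dropout*); these are converted to true gaps first.  Gaps
strictly shorter than 15 s are then bridged by linear interpolation between
the flanking samples.  Finally, spans that are uninterpretable — maternal
heart rate captured by the fetal sensor, recurrent impulse noise, or
physiologically impossible values — are flagged as NOI intervals.  NOI
spans are recorded, not deleted, so feature extraction can exclude them.

Only the FHR signal is repaired; uterine activity passes through
unchanged.  The uninterpretability heuristics (coincidence tolerance,
jump threshold, physiologic range) are this module's own documented,
configurable choices; only the <15 s interpolation bound is inherited
from the upstream processing convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .segsig import (
    EFMRecord,
    Segment,
    SegmentedSignal,
    find_gaps,
    intersect,
)

__all__ = [
    "RepairConfig",
    "dropouts_to_gaps",
    "interpolate_short_gaps",
    "flag_uninterpretable",
    "repair_record",
]


@dataclass
class RepairConfig:
    max_interp_gap: float = 15.0  # s, strict upper bound for bridging
    dropout_value: float = 0.0  # bpm
    min_dropout_run: int = 1  # samples
    mhr_coincidence_tol: float = 5.0  # bpm
    mhr_coincidence_min: float = 60.0  # s
    noise_jump: float = 25.0  # bpm per sample
    physiologic_range: tuple[float, float] = (50.0, 240.0)  # bpm

    def __post_init__(self) -> None:
        if (
            self.max_interp_gap <= 0
            or self.min_dropout_run <= 0
            or self.mhr_coincidence_tol <= 0
            or self.mhr_coincidence_min <= 0
            or self.noise_jump <= 0
        ):
            raise ValueError("repair thresholds must be positive")


def dropouts_to_gaps(
    fhr: SegmentedSignal, cfg: RepairConfig | None = None
) -> SegmentedSignal:
    """Remove runs of dropout samples (0 bpm), opening gaps in their place."""
    cfg = cfg or RepairConfig()
    segments: list[Segment] = []
    chunks: list[np.ndarray] = []
    for seg, off in zip(fhr.segments, fhr.onset_offsets):
        vals = fhr.data[off : off + seg.n_samples]
        drop = vals == cfg.dropout_value
        if cfg.min_dropout_run > 1:
            drop = _suppress_short_runs(drop, cfg.min_dropout_run)
        keep_idx = np.flatnonzero(~drop)
        if keep_idx.size == 0:
            continue
        brk = np.flatnonzero(np.diff(keep_idx) > 1) + 1
        bounds = np.concatenate([[0], brk, [keep_idx.size]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            sl = keep_idx[a:b]
            segments.append(
                replace(
                    seg,
                    start_time=seg.start_time + sl[0] * fhr.delta,
                    n_samples=int(sl.size),
                )
            )
            chunks.append(vals[sl])
    data = np.concatenate(chunks) if chunks else np.empty(0)
    return SegmentedSignal(fhr.measurement, data, segments, fhr.delta, fhr.units)


def _suppress_short_runs(mask: np.ndarray, min_run: int) -> np.ndarray:
    """Keep only True-runs of length >= min_run."""
    out = mask.copy()
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i < min_run:
                out[i:j] = False
            i = j
        else:
            i += 1
    return out


def interpolate_short_gaps(
    fhr: SegmentedSignal, cfg: RepairConfig | None = None
) -> SegmentedSignal:
    """Bridge every gap strictly shorter than ``max_interp_gap`` seconds.

    Inserted samples lie on the straight line between the last sample
    before and the first sample after the gap; flanking segments fuse.
    Original sample values are never modified, and boundary gaps (no
    flanking sample on one side) are never interpolated.
    """
    cfg = cfg or RepairConfig()
    if fhr.n_segments <= 1:
        return fhr.copy()
    delta = fhr.delta
    segments: list[Segment] = []
    chunks: list[np.ndarray] = []
    offsets = fhr.onset_offsets
    for k, seg in enumerate(fhr.segments):
        vals = fhr.data[offsets[k] : offsets[k] + seg.n_samples]
        if not segments:
            segments.append(replace(seg))
            chunks.append(vals)
            continue
        prev = segments[-1]
        gap = seg.start_time - prev.end_time(delta)
        if 0 < gap < cfg.max_interp_gap - delta / 100.0:
            n_missing = int(round(gap / delta))  # gap covers exactly these slots
            v0 = chunks[-1][-1]
            v1 = vals[0]
            fill = v0 + (v1 - v0) * np.arange(1, n_missing + 1) / (n_missing + 1)
            segments[-1] = replace(
                prev, n_samples=prev.n_samples + n_missing + seg.n_samples
            )
            chunks.append(fill)
            chunks.append(vals)
        else:
            segments.append(replace(seg))
            chunks.append(vals)
    return SegmentedSignal(
        fhr.measurement, np.concatenate(chunks), segments, delta, fhr.units
    )


def _runs_to_intervals(
    mask: np.ndarray, times: np.ndarray, delta: float
) -> list[tuple[float, float]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    brk = np.flatnonzero(np.diff(idx) > 1) + 1
    bounds = np.concatenate([[0], brk, [idx.size]])
    return [
        (times[idx[a]], times[idx[b - 1]] + delta)
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def merge_intervals(
    intervals: list[tuple[float, float]], slack: float = 0.0
) -> list[tuple[float, float]]:
    """Union of intervals, merging any that overlap or abut within slack."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for lo, hi in ivs[1:]:
        if lo <= out[-1][1] + slack:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return [(a, b) for a, b in out]


def flag_uninterpretable(
    fhr: SegmentedSignal,
    mhr: SegmentedSignal | None = None,
    cfg: RepairConfig | None = None,
) -> list[tuple[float, float, str]]:
    """Flag NOI intervals: (start_s, end_s, reason) triples.

    Reasons: ``mhr_capture`` — FHR tracks the maternal heart rate within
    ``mhr_coincidence_tol`` bpm continuously for at least
    ``mhr_coincidence_min`` s; ``impulse_noise`` — at least 3
    sample-to-sample jumps above ``noise_jump`` bpm within 10 s;
    ``out_of_range`` — values outside the physiologic range.
    """
    cfg = cfg or RepairConfig()
    flagged: list[tuple[float, float, str]] = []
    delta = fhr.delta
    times = fhr.sample_times()
    vals = fhr.data

    # (c) physiologically impossible values
    lo, hi = cfg.physiologic_range
    oor = (vals < lo) | (vals > hi)
    for a, b in _runs_to_intervals(oor, times, delta):
        flagged.append((a, b, "out_of_range"))

    # (b) recurrent impulse noise: >=3 big jumps within a 10 s window
    for seg, off in zip(fhr.segments, fhr.onset_offsets):
        v = fhr.data[off : off + seg.n_samples]
        if v.size < 2:
            continue
        jump = np.abs(np.diff(v)) > cfg.noise_jump
        w = int(round(10.0 / delta))
        jpos = np.flatnonzero(jump)
        for i in jpos:
            near = jpos[(jpos >= i) & (jpos < i + w)]
            if near.size >= 3:
                a = seg.start_time + near[0] * delta
                b = seg.start_time + (near[-1] + 2) * delta
                flagged.append((a, b, "impulse_noise"))

    # (a) maternal heart rate capture
    if mhr is not None and not mhr.is_empty and not fhr.is_empty:
        f2, m2 = intersect(fhr, mhr)
        if not f2.is_empty:
            t2 = f2.sample_times()
            close = np.abs(f2.data - m2.data) < cfg.mhr_coincidence_tol
            min_n = int(round(cfg.mhr_coincidence_min / delta))
            for a, b in _runs_to_intervals(close, t2, delta):
                if b - a >= cfg.mhr_coincidence_min - delta / 100.0 and min_n > 0:
                    flagged.append((a, b, "mhr_capture"))

    merged: list[tuple[float, float, str]] = []
    by_reason: dict[str, list[tuple[float, float]]] = {}
    for a, b, r in flagged:
        by_reason.setdefault(r, []).append((a, b))
    for r, ivs in by_reason.items():
        for a, b in merge_intervals(ivs, slack=delta):
            merged.append((a, b, r))
    merged.sort()
    return merged


def repair_record(
    combined: EFMRecord, cfg: RepairConfig | None = None
) -> tuple[EFMRecord, list[tuple[float, float, str]]]:
    """Run the full repair on a combined record.

    Returns the repaired record (FHR dropouts removed and short gaps
    bridged; UA and MHR untouched) plus the NOI interval table.
    """
    cfg = cfg or RepairConfig()
    signals = {k: v.copy() for k, v in combined.signals.items()}
    noi: list[tuple[float, float, str]] = []
    if "FHR" in signals:
        fhr = dropouts_to_gaps(signals["FHR"], cfg)
        if not fhr.is_empty:
            fhr = interpolate_short_gaps(fhr, cfg)
            noi = flag_uninterpretable(fhr, signals.get("MHR"), cfg)
            signals["FHR"] = fhr
        else:
            del signals["FHR"]
    return (
        EFMRecord(
            guid=combined.guid,
            stage="repaired",
            signals=signals,
            provenance=combined.provenance,
        ),
        noi,
    )
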