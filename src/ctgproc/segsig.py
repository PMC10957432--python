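"""Segmented-signal container and algebra.

Electronic fetal monitoring (EFM) signals are rarely contiguous: sensor
disconnects and transmission problems leave gaps, so each signal is a
sequence of contiguous *segments* of 4 Hz samples separated by gaps of
arbitrary length.  :class:`SegmentedSignal` stores the concatenated sample
values once, together with per-segment start times and lengths, and this
module supplies the algebra the rest of the pipeline needs: building from
timestamped samples, gap listing, dense (NaN-filled) round trips,
intersection of supports and concatenation.

Time convention
---------------
The canonical time axis is *signed seconds relative to birth*: birth is 0
and everything before birth is negative.  All sample times lie on the grid
``k * delta`` (``delta`` = 0.25 s at 4 Hz); comparisons use an absolute
tolerance of ``delta / 100``.

Segment pointers into the concatenated data array are exposed both 1-based
(``onset_pointers``, matching the field's MATLAB heritage) and 0-based
(``onset_offsets``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Segment",
    "SegmentedSignal",
    "EFMRecord",
    "build_segmented",
    "find_gaps",
    "to_dense",
    "from_dense",
    "intersect",
    "concatenate",
]

#: default sampling increment, seconds (4 Hz)
DELTA = 0.25

SENSORS = {"external", "FECG", "TOCO", "Internal", "ECG", "unknown"}
MONITORS = {"120series", "170series", "Coro250", "HP135X", "unknown"}
MEASUREMENTS = {"HR1", "HR2", "MHR", "UP", "FHR", "UA"}


def _tol(delta: float) -> float:
    return delta / 100.0


def time_to_index(t: float | np.ndarray, delta: float) -> np.ndarray:
    """Snap time(s) to the integer sample grid; raise if off-grid."""
    ratio = np.asarray(t, dtype=float) / delta
    idx = np.round(ratio)
    if np.any(np.abs(ratio - idx) * delta > _tol(delta)):
        raise ValueError("off-grid sample")
    return idx.astype(np.int64)


@dataclass
class Segment:
    """One maximal contiguous run of samples.

    ``start_time`` is in seconds relative to birth (negative before birth);
    the segment covers the half-open interval
    ``[start_time, start_time + n_samples * delta)``.
    """

    start_time: float
    n_samples: int
    sensor: str = "unknown"
    monitor: str = "unknown"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("segment must hold at least one sample")

    def end_time(self, delta: float) -> float:
        return self.start_time + self.n_samples * delta


@dataclass
class SegmentedSignal:
    """A gappy sampled signal stored as concatenated segments."""

    measurement: str
    data: np.ndarray
    segments: list[Segment]
    delta: float = DELTA
    units: str = "BPM"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.validate()

    # -- derived views ----------------------------------------------------

    @property
    def seg_lengths(self) -> np.ndarray:
        return np.array([s.n_samples for s in self.segments], dtype=np.int64)

    @property
    def onset_offsets(self) -> np.ndarray:
        """0-based index of the first sample of each segment in ``data``."""
        lens = self.seg_lengths
        return np.concatenate([[0], np.cumsum(lens)[:-1]]).astype(np.int64)

    @property
    def onset_pointers(self) -> np.ndarray:
        """1-based segment onset pointers."""
        return self.onset_offsets + 1

    @property
    def start_times(self) -> np.ndarray:
        return np.array([s.start_time for s in self.segments], dtype=float)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_samples(self) -> int:
        return int(self.data.size)

    @property
    def is_empty(self) -> bool:
        return self.n_samples == 0

    def sample_times(self) -> np.ndarray:
        """Time of every stored sample, concatenated in segment order."""
        if self.is_empty:
            return np.empty(0, dtype=float)
        parts = [
            s.start_time + np.arange(s.n_samples) * self.delta
            for s in self.segments
        ]
        return np.concatenate(parts)

    def support(self) -> list[tuple[float, float]]:
        """Half-open time intervals covered by samples."""
        return [(s.start_time, s.end_time(self.delta)) for s in self.segments]

    def segment_values(self, k: int) -> np.ndarray:
        off = self.onset_offsets
        return self.data[off[k] : off[k] + self.segments[k].n_samples]

    # -- integrity --------------------------------------------------------

    def validate(self) -> None:
        lens = self.seg_lengths
        if self.data.size != int(lens.sum()):
            raise ValueError("data length does not match segment lengths")
        tol = _tol(self.delta)
        for prev, nxt in zip(self.segments, self.segments[1:]):
            end = prev.end_time(self.delta)
            if nxt.start_time < end - tol:
                raise ValueError("segments overlap")
            # abutting segments are only allowed at a provenance change
            # (sensor switch in a combined signal); otherwise a gap of at
            # least one sample must separate segments
            if nxt.start_time < end + self.delta - tol and (
                nxt.sensor == prev.sensor and nxt.monitor == prev.monitor
            ):
                raise ValueError("segments abut without a provenance change")

    def copy(self) -> "SegmentedSignal":
        return SegmentedSignal(
            measurement=self.measurement,
            data=self.data.copy(),
            segments=[replace(s) for s in self.segments],
            delta=self.delta,
            units=self.units,
        )

    def content_equal(self, other: "SegmentedSignal") -> bool:
        return (
            self.measurement == other.measurement
            and self.delta == other.delta
            and self.n_segments == other.n_segments
            and np.allclose(self.start_times, other.start_times, atol=_tol(self.delta))
            and np.array_equal(self.seg_lengths, other.seg_lengths)
            and np.array_equal(self.data, other.data)
        )


@dataclass
class EFMRecord:
    """All signals of one tracing at one processing stage.

    ``signals`` is keyed by ``(measurement, sensor, monitor)`` at the raw
    stage and by measurement name (``FHR`` / ``UA`` / ``MHR``) once
    sensors have been combined.
    """

    guid: str
    stage: str  # raw | combined | repaired
    signals: dict = field(default_factory=dict)
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.stage not in {"raw", "combined", "repaired"}:
            raise ValueError(f"unknown stage {self.stage!r}")
        deltas = {s.delta for s in self.signals.values()}
        if len(deltas) > 1:
            raise ValueError("all signals in a record must share delta")

    def content_equal(self, other: "EFMRecord") -> bool:
        if set(self.signals) != set(other.signals):
            return False
        return all(
            self.signals[k].content_equal(other.signals[k]) for k in self.signals
        )

    def time_range(self) -> tuple[float, float] | None:
        """(min, max) sample time over all signals, or None if empty."""
        lo, hi = np.inf, -np.inf
        for sig in self.signals.values():
            if sig.is_empty:
                continue
            lo = min(lo, sig.segments[0].start_time)
            hi = max(hi, sig.segments[-1].end_time(sig.delta))
        if lo is np.inf or not np.isfinite(lo):
            return None
        return lo, hi


# ---------------------------------------------------------------------------
# construction


def build_segmented(
    samples: Iterable[tuple[float, float]],
    delta: float = DELTA,
    measurement: str = "FHR",
    units: str = "BPM",
    sensor: str = "unknown",
    monitor: str = "unknown",
) -> SegmentedSignal:
    """Build a segmented signal from (time, value) pairs.

    Times must be strictly increasing and lie on the ``delta`` grid.
    Consecutive samples exactly one ``delta`` apart share a segment; any
    larger step opens a new segment.
    """
    pairs = list(samples)
    if not pairs:
        return SegmentedSignal(measurement, np.empty(0), [], delta, units)
    times = np.array([p[0] for p in pairs], dtype=float)
    values = np.array([p[1] for p in pairs], dtype=float)
    idx = time_to_index(times, delta)
    steps = np.diff(idx)
    if np.any(steps <= 0):
        raise ValueError("unsorted input")
    breaks = np.flatnonzero(steps > 1) + 1
    bounds = np.concatenate([[0], breaks, [len(idx)]])
    segments = [
        Segment(
            start_time=idx[a] * delta,
            n_samples=int(b - a),
            sensor=sensor,
            monitor=monitor,
        )
        for a, b in zip(bounds[:-1], bounds[1:])
    ]
    return SegmentedSignal(measurement, values, segments, delta, units)


def from_seg_lengths(
    seg_lengths: Sequence[int],
    start_times: Sequence[float],
    data: np.ndarray | None = None,
    delta: float = DELTA,
    measurement: str = "FHR",
    units: str = "BPM",
) -> SegmentedSignal:
    """Build directly from per-segment lengths and start times."""
    if data is None:
        data = np.zeros(int(np.sum(seg_lengths)))
    segments = [
        Segment(start_time=float(t), n_samples=int(n))
        for t, n in zip(start_times, seg_lengths)
    ]
    return SegmentedSignal(measurement, np.asarray(data, float), segments, delta, units)


# ---------------------------------------------------------------------------
# algebra


def find_gaps(sig: SegmentedSignal) -> list[tuple[float, float]]:
    """Half-open ``[gap_start, gap_end)`` intervals between segments."""
    gaps = []
    for prev, nxt in zip(sig.segments, sig.segments[1:]):
        end = prev.end_time(sig.delta)
        if nxt.start_time - end > _tol(sig.delta):  # abutting pairs: no gap
            gaps.append((end, nxt.start_time))
    return gaps


def to_dense(sig: SegmentedSignal) -> tuple[np.ndarray, np.ndarray]:
    """Dense time axis and values with NaN in gaps.

    The axis spans the first to the last sample on the ``delta`` grid.
    """
    if sig.is_empty:
        return np.empty(0), np.empty(0)
    i0 = int(time_to_index(sig.segments[0].start_time, sig.delta))
    i1 = int(time_to_index(sig.segments[-1].start_time, sig.delta)) + sig.segments[
        -1
    ].n_samples
    n = i1 - i0
    times = (i0 + np.arange(n)) * sig.delta
    values = np.full(n, np.nan)
    for seg, off in zip(sig.segments, sig.onset_offsets):
        j = int(time_to_index(seg.start_time, sig.delta)) - i0
        values[j : j + seg.n_samples] = sig.data[off : off + seg.n_samples]
    return times, values


def from_dense(
    times: np.ndarray,
    values: np.ndarray,
    delta: float = DELTA,
    measurement: str = "FHR",
    units: str = "BPM",
) -> SegmentedSignal:
    """Inverse of :func:`to_dense`: NaN runs become gaps."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size:
        raise ValueError("times and values must have equal length")
    if times.size == 0:
        return SegmentedSignal(measurement, np.empty(0), [], delta, units)
    idx = time_to_index(times, delta)
    if np.any(np.diff(idx) != 1):
        raise ValueError("dense time axis must be contiguous on the grid")
    keep = ~np.isnan(values)
    return build_segmented(
        zip(times[keep], values[keep]),
        delta=delta,
        measurement=measurement,
        units=units,
    )


def intersect(
    a: SegmentedSignal, b: SegmentedSignal
) -> tuple[SegmentedSignal, SegmentedSignal]:
    """Restrict both signals to their common time support.

    Values are unchanged; both outputs have identical segment boundaries
    equal to the interval-intersection of the two supports.
    """
    if abs(a.delta - b.delta) > _tol(a.delta):
        raise ValueError("delta mismatch")
    common: list[tuple[float, float]] = []
    for sa, ea in a.support():
        for sb, eb in b.support():
            lo, hi = max(sa, sb), min(ea, eb)
            if hi - lo > _tol(a.delta):
                common.append((lo, hi))
    common.sort()
    return _restrict(a, common), _restrict(b, common)


def _restrict(
    sig: SegmentedSignal, intervals: list[tuple[float, float]]
) -> SegmentedSignal:
    """Keep only samples whose time falls in the given half-open intervals."""
    if sig.is_empty or not intervals:
        return SegmentedSignal(
            sig.measurement, np.empty(0), [], sig.delta, sig.units
        )
    tol = _tol(sig.delta)
    segments: list[Segment] = []
    chunks: list[np.ndarray] = []
    for seg, off in zip(sig.segments, sig.onset_offsets):
        t = seg.start_time + np.arange(seg.n_samples) * sig.delta
        v = sig.data[off : off + seg.n_samples]
        mask = np.zeros(seg.n_samples, dtype=bool)
        for lo, hi in intervals:
            mask |= (t >= lo - tol) & (t < hi - tol)
        keep = np.flatnonzero(mask)
        if keep.size == 0:
            continue
        brk = np.flatnonzero(np.diff(keep) > 1) + 1
        bounds = np.concatenate([[0], brk, [keep.size]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            sl = keep[a:b]
            segments.append(
                Segment(
                    start_time=float(t[sl[0]]),
                    n_samples=int(sl.size),
                    sensor=seg.sensor,
                    monitor=seg.monitor,
                )
            )
            chunks.append(v[sl])
    data = np.concatenate(chunks) if chunks else np.empty(0)
    return SegmentedSignal(sig.measurement, data, segments, sig.delta, sig.units)


def restrict(sig: SegmentedSignal, intervals: list[tuple[float, float]]) -> SegmentedSignal:
    """Public alias for interval restriction (used by windowing stages)."""
    return _restrict(sig, sorted(intervals))


def concatenate(parts: Sequence[SegmentedSignal]) -> SegmentedSignal:
    """Merge disjoint signals into one; abutting parts fuse into one segment."""
    parts = [p for p in parts if not p.is_empty]
    if not parts:
        raise ValueError("nothing to concatenate")
    delta = parts[0].delta
    for p in parts[1:]:
        if abs(p.delta - delta) > _tol(delta):
            raise ValueError("delta mismatch")
    ordered = sorted(parts, key=lambda p: p.segments[0].start_time)
    tol = _tol(delta)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.segments[0].start_time < prev.segments[-1].end_time(delta) - tol:
            raise ValueError("overlap; use combine_sensors")
    segments: list[Segment] = []
    chunks: list[np.ndarray] = []
    for p in ordered:
        for seg, off in zip(p.segments, p.onset_offsets):
            vals = p.data[off : off + seg.n_samples]
            if segments and abs(
                seg.start_time - segments[-1].end_time(delta)
            ) <= tol:
                # abutting: fuse
                segments[-1] = replace(
                    segments[-1], n_samples=segments[-1].n_samples + seg.n_samples
                )
            else:
                segments.append(replace(seg))
            chunks.append(vals)
    data = np.concatenate(chunks)
    first = ordered[0]
    return SegmentedSignal(first.measurement, data, segments, delta, first.units)
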