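"""Rule-based detection of clinically relevant CTG patterns.

Detects the standard cardiotocography events on the repaired record:

* **BAS** — fetal heart rate baseline: spans where the FHR stays within
  ±10 bpm of a running baseline estimate;
* **ACC / DEC** — accelerations / decelerations: excursions of more than
  15 bpm from baseline lasting more than 15 s that return to baseline
  (both thresholds strict);
* **CON** — uterine contractions: uterine-activity spans rising at least
  15 units above the resting tone for at least 30 s;
* **RIN** — interpretable FHR time assigned to none of the above;
* **NOI** — uninterpretable spans (produced by the repair stage and
  consumed here).

Decelerations are subtyped as variable (abrupt onset), early or late
(gradual, timed against the paired contraction) or prolonged (≥ 2 min).

The running baseline is a 10-minute windowed trimmed mean that excludes
excursion candidates and is iterated to a fixpoint, so isolated
accelerations or decelerations do not drag the baseline.  All numeric
rule parameters live in :class:`PatternConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .segsig import SegmentedSignal, EFMRecord
from .repair import merge_intervals

__all__ = [
    "PatternConfig",
    "Event",
    "estimate_baseline",
    "detect_acc_dec",
    "detect_contractions",
    "classify_deceleration",
    "detect_patterns",
]

_EPS = 1e-9


@dataclass
class PatternConfig:
    # baseline
    baseline_window_s: float = 600.0
    baseline_trim: float = 0.25  # proportion cut from each tail
    baseline_band_bpm: float = 10.0  # BAS band half-width
    baseline_max_iter: int = 5
    baseline_stride_s: float = 2.5  # baseline evaluated on this grid
    min_baseline_span_s: float = 120.0  # shorter chunks get no baseline
    # accelerations / decelerations (strict thresholds)
    excursion_bpm: float = 15.0
    min_event_s: float = 15.0
    prolonged_s: float = 120.0
    abrupt_onset_s: float = 30.0  # onset-to-nadir bound for "abrupt"
    return_band_s: float = 5.0  # min in-band time to count as "returned"
    dec_coincidence_tol_s: float = 15.0  # early-vs-late nadir tolerance
    # contractions
    con_rise: float = 15.0  # units above resting tone
    con_min_s: float = 30.0
    con_tone_window_s: float = 600.0
    con_tone_pct: float = 10.0  # resting tone percentile
    con_smooth_s: float = 30.0


@dataclass
class Event:
    """A detected pattern with time extent and type-specific attributes."""

    guid: str
    type: str  # BAS | ACC | DEC | CON | NOI | RIN
    start_s: float
    end_s: float
    attrs: dict = field(default_factory=dict)
    subtype: str | None = None  # DEC only: variable | early | late | prolonged

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("event must have positive duration")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# chunking helpers


def _interpretable_chunks(
    fhr: SegmentedSignal, noi: list[tuple[float, float]] | None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Maximal contiguous (times, values) runs after removing NOI spans."""
    times = fhr.sample_times()
    vals = fhr.data
    if times.size == 0:
        return []
    keep = np.ones(times.size, dtype=bool)
    for lo, hi in noi or []:
        keep &= ~((times >= lo - _EPS) & (times < hi - _EPS))
    times, vals = times[keep], vals[keep]
    if times.size == 0:
        return []
    brk = np.flatnonzero(np.diff(times) > fhr.delta * 1.5) + 1
    bounds = np.concatenate([[0], brk, [times.size]])
    return [
        (times[a:b], vals[a:b]) for a, b in zip(bounds[:-1], bounds[1:])
    ]


def _rolling_trimmed_mean(
    x: np.ndarray,
    include: np.ndarray,
    window: int,
    stride: int,
    trim: float,
) -> np.ndarray:
    """Centered rolling trimmed mean over included samples, evaluated on a
    stride grid and linearly interpolated back to the full grid."""
    n = x.size
    centers = np.arange(0, n, stride)
    est = np.empty(centers.size)
    half = window // 2
    fallback = np.nan
    for i, c in enumerate(centers):
        a, b = max(0, c - half), min(n, c + half)
        w = x[a:b][include[a:b]]
        if w.size >= 8:
            est[i] = stats.trim_mean(w, trim)
        else:
            est[i] = fallback
        if not np.isnan(est[i]):
            fallback = est[i]
    # fill leading NaNs from the first finite estimate
    if np.isnan(est).any():
        finite = np.flatnonzero(~np.isnan(est))
        if finite.size == 0:
            est[:] = np.nanmedian(x[include]) if include.any() else np.nanmedian(x)
        else:
            est[: finite[0]] = est[finite[0]]
    return np.interp(np.arange(n), centers, est)


# ---------------------------------------------------------------------------
# baseline


def estimate_baseline(
    fhr: SegmentedSignal,
    noi: list[tuple[float, float]] | None = None,
    cfg: PatternConfig | None = None,
    guid: str = "",
) -> tuple[list[Event], list[tuple[np.ndarray, np.ndarray, np.ndarray]]]:
    """Estimate the running baseline and emit BAS events.

    Returns the BAS events plus, for each interpretable chunk, the
    ``(times, values, baseline)`` arrays used downstream.  Chunks shorter
    than 2 minutes get no baseline (their whole span is RIN).
    """
    cfg = cfg or PatternConfig()
    delta = fhr.delta
    window = int(round(cfg.baseline_window_s / delta))
    stride = max(1, int(round(cfg.baseline_stride_s / delta)))
    events: list[Event] = []
    chunks: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for t, x in _interpretable_chunks(fhr, noi):
        if t.size * delta < cfg.min_baseline_span_s:
            chunks.append((t, x, np.full(t.size, np.nan)))
            continue
        include = np.ones(t.size, dtype=bool)
        b = _rolling_trimmed_mean(x, include, window, stride, cfg.baseline_trim)
        for _ in range(cfg.baseline_max_iter):
            new_include = np.abs(x - b) <= cfg.baseline_band_bpm + _EPS
            if new_include.sum() < 8:  # degenerate: keep all
                new_include = np.ones(t.size, dtype=bool)
            if np.array_equal(new_include, include):
                break
            include = new_include
            b = _rolling_trimmed_mean(x, include, window, stride, cfg.baseline_trim)
        chunks.append((t, x, b))
    # BAS events come from the partition labeling (shared with ACC/DEC)
    for t, x, b in chunks:
        labels = _label_chunk(t, x, b, fhr.delta, cfg)
        events.extend(_label_runs_to_events(t, x, b, labels, "BAS", fhr.delta, cfg, guid))
    return events, chunks


# ---------------------------------------------------------------------------
# sample labeling: BAS / excursion-event / RIN partition


def _label_chunk(
    t: np.ndarray,
    x: np.ndarray,
    b: np.ndarray,
    delta: float,
    cfg: PatternConfig,
) -> np.ndarray:
    """Label every sample: 0 = BAS, 1 = ACC, 2 = DEC, 3 = RIN."""
    n = t.size
    labels = np.full(n, 3, dtype=np.int8)  # default RIN
    if np.isnan(b).all():
        return labels
    dev = x - b
    out = np.abs(dev) > cfg.baseline_band_bpm + _EPS

    # an excursion only ends once the signal is back in band >= return_band_s:
    # absorb in-band runs shorter than that between two out-of-band runs
    min_in = int(round(cfg.return_band_s / delta))
    out = _absorb_short_inband(out, min_in)

    idx = np.flatnonzero(out)
    if idx.size:
        brk = np.flatnonzero(np.diff(idx) > 1) + 1
        bounds = np.concatenate([[0], brk, [idx.size]])
        for a, bb in zip(bounds[:-1], bounds[1:]):
            sl = idx[a:bb]
            d = dev[sl]
            peak = np.max(np.abs(d))
            dur = sl.size * delta
            sign = np.sign(d[np.argmax(np.abs(d))])
            qualifies = peak > cfg.excursion_bpm + _EPS and (
                dur > cfg.min_event_s + _EPS
            )
            if qualifies:
                labels[sl] = 1 if sign > 0 else 2
            # else stays RIN
    labels[(~out) & ~np.isnan(b)] = np.where(
        labels[(~out) & ~np.isnan(b)] == 3, 0, labels[(~out) & ~np.isnan(b)]
    )
    return labels


def _absorb_short_inband(out: np.ndarray, min_in: int) -> np.ndarray:
    """In-band runs shorter than min_in between two excursion runs are
    counted as part of the excursion ("has not yet returned to baseline")."""
    res = out.copy()
    n = out.size
    i = 0
    while i < n:
        if not res[i]:
            j = i
            while j < n and not res[j]:
                j += 1
            if 0 < i and j < n and (j - i) < min_in:
                res[i:j] = True
            i = j
        else:
            i += 1
    return res


def _label_runs_to_events(
    t: np.ndarray,
    x: np.ndarray,
    b: np.ndarray,
    labels: np.ndarray,
    which: str,
    delta: float,
    cfg: PatternConfig,
    guid: str,
) -> list[Event]:
    """Convert constant-label runs into events with their attributes."""
    code = {"BAS": 0, "ACC": 1, "DEC": 2, "RIN": 3}[which]
    events: list[Event] = []
    idx = np.flatnonzero(labels == code)
    if idx.size == 0:
        return events
    brk = np.flatnonzero(np.diff(idx) > 1) + 1
    bounds = np.concatenate([[0], brk, [idx.size]])
    for a, bb in zip(bounds[:-1], bounds[1:]):
        sl = idx[a:bb]
        start, end = t[sl[0]], t[sl[-1]] + delta
        attrs: dict = {}
        if which == "BAS":
            # level and slope by linear regression; variability peak-to-peak
            tt = t[sl] - t[sl[0]]
            if sl.size >= 2:
                slope, level0 = np.polyfit(tt, x[sl], 1)
            else:
                slope, level0 = 0.0, x[sl[0]]
            attrs = {
                "level": float(np.mean(x[sl])),
                "variability": float(np.ptp(x[sl])),
                "slope_bpm_per_min": float(slope * 60.0),
            }
        elif which in ("ACC", "DEC"):
            dev = x[sl] - b[sl]
            attrs = {
                "height": float(np.max(np.abs(dev))),
                "area_beats": float(np.sum(np.abs(dev)) * delta / 60.0),
            }
            if which == "DEC":
                nadir_i = sl[np.argmax(np.abs(dev))]
                attrs["nadir_s"] = float(t[nadir_i])
                attrs["onset_to_nadir_s"] = float(t[nadir_i] - start)
        events.append(Event(guid, which, float(start), float(end), attrs))
    return events


def detect_acc_dec(
    fhr: SegmentedSignal,
    noi: list[tuple[float, float]] | None = None,
    cfg: PatternConfig | None = None,
    guid: str = "",
    baseline_chunks: list | None = None,
) -> list[Event]:
    """Detect accelerations and decelerations against the running baseline."""
    cfg = cfg or PatternConfig()
    if baseline_chunks is None:
        _, baseline_chunks = estimate_baseline(fhr, noi, cfg, guid)
    events: list[Event] = []
    for t, x, b in baseline_chunks:
        labels = _label_chunk(t, x, b, fhr.delta, cfg)
        events.extend(
            _label_runs_to_events(t, x, b, labels, "ACC", fhr.delta, cfg, guid)
        )
        events.extend(
            _label_runs_to_events(t, x, b, labels, "DEC", fhr.delta, cfg, guid)
        )
    return sorted(events, key=lambda e: e.start_s)


# ---------------------------------------------------------------------------
# contractions


def detect_contractions(
    ua: SegmentedSignal,
    cfg: PatternConfig | None = None,
    guid: str = "",
) -> list[Event]:
    """Detect uterine contractions against a running resting tone.

    Resting tone is a rolling 10-minute 10th percentile; a contraction is
    a span where the 30 s-smoothed activity rises at least ``con_rise``
    units above the tone for at least ``con_min_s`` seconds.  Height and
    area are measured on the unsmoothed signal.
    """
    cfg = cfg or PatternConfig()
    delta = ua.delta
    events: list[Event] = []
    window = int(round(cfg.con_tone_window_s / delta))
    stride = max(1, int(round(2.5 / delta)))
    smooth_n = max(1, int(round(cfg.con_smooth_s / delta)))
    for t, x in _interpretable_chunks(ua, None):
        if t.size < smooth_n:
            continue
        n = t.size
        centers = np.arange(0, n, stride)
        half = window // 2
        tone_c = np.array(
            [
                np.percentile(x[max(0, c - half) : min(n, c + half)], cfg.con_tone_pct)
                for c in centers
            ]
        )
        tone = np.interp(np.arange(n), centers, tone_c)
        kernel = np.ones(smooth_n) / smooth_n
        smoothed = np.convolve(x, kernel, mode="same")
        above = smoothed - tone >= cfg.con_rise - _EPS
        idx = np.flatnonzero(above)
        if idx.size == 0:
            continue
        brk = np.flatnonzero(np.diff(idx) > 1) + 1
        bounds = np.concatenate([[0], brk, [idx.size]])
        for a, bb in zip(bounds[:-1], bounds[1:]):
            sl = idx[a:bb]
            if sl.size * delta < cfg.con_min_s - _EPS:
                continue
            peak_i = sl[np.argmax(x[sl])]
            height = float(x[peak_i] - tone[peak_i])
            area = float(np.sum(np.clip(x[sl] - tone[sl], 0, None)) * delta)
            events.append(
                Event(
                    guid,
                    "CON",
                    float(t[sl[0]]),
                    float(t[sl[-1]] + delta),
                    {"height": height, "area": area, "peak_s": float(t[peak_i])},
                )
            )
    return events


# ---------------------------------------------------------------------------
# deceleration subtyping


def classify_deceleration(
    dec: Event,
    contractions: list[Event],
    cfg: PatternConfig | None = None,
) -> str:
    """Subtype a deceleration: prolonged / variable / early / late.

    Prolonged: duration >= 2 min.  Abrupt onset (onset-to-nadir < 30 s):
    variable.  Gradual decelerations are timed against the nearest
    overlapping contraction: nadir within ``dec_coincidence_tol_s`` of the
    contraction peak is early, nadir later than that is late; a gradual
    deceleration with no paired contraction is variable.
    """
    cfg = cfg or PatternConfig()
    if dec.duration >= cfg.prolonged_s - _EPS:
        return "prolonged"
    onset_to_nadir = dec.attrs.get("onset_to_nadir_s")
    if onset_to_nadir is not None and onset_to_nadir < cfg.abrupt_onset_s:
        return "variable"
    # gradual: pair with nearest overlapping contraction
    nadir = dec.attrs.get("nadir_s", (dec.start_s + dec.end_s) / 2.0)
    paired = None
    best = np.inf
    for con in contractions:
        if con.type != "CON":
            continue
        if con.start_s < dec.end_s and dec.start_s < con.end_s:
            peak = con.attrs.get("peak_s", (con.start_s + con.end_s) / 2.0)
            if abs(nadir - peak) < best:
                best = abs(nadir - peak)
                paired = peak
    if paired is None:
        return "variable"
    if abs(nadir - paired) <= cfg.dec_coincidence_tol_s:
        return "early"
    if nadir > paired + cfg.dec_coincidence_tol_s:
        return "late"
    # nadir well before the contraction peak: no printed category fits;
    # treat as early-type coincidence failure -> variable
    return "variable"


# ---------------------------------------------------------------------------
# driver


def detect_patterns(
    record: EFMRecord,
    noi: list[tuple[float, float, str]] | None = None,
    cfg: PatternConfig | None = None,
) -> list[Event]:
    """Detect all events on a repaired record.

    Returns BAS, ACC, DEC (subtyped), CON, RIN and NOI events; BAS, ACC,
    DEC and RIN partition the interpretable FHR timeline.
    """
    cfg = cfg or PatternConfig()
    guid = record.guid
    noi_iv = [(a, b) for a, b, *_ in (noi or [])]
    noi_iv = merge_intervals(noi_iv)
    events: list[Event] = [
        Event(guid, "NOI", a, b, {"reason": r})
        for a, b, r in (noi or [])
    ]
    fhr = record.signals.get("FHR")
    if fhr is not None and not fhr.is_empty:
        bas_events, chunks = estimate_baseline(fhr, noi_iv, cfg, guid)
        events.extend(bas_events)
        for t, x, b in chunks:
            labels = _label_chunk(t, x, b, fhr.delta, cfg)
            for which in ("ACC", "DEC", "RIN"):
                events.extend(
                    _label_runs_to_events(
                        t, x, b, labels, which, fhr.delta, cfg, guid
                    )
                )
    ua = record.signals.get("UA")
    cons: list[Event] = []
    if ua is not None and not ua.is_empty:
        cons = detect_contractions(ua, cfg, guid)
        events.extend(cons)
    for ev in events:
        if ev.type == "DEC":
            ev.subtype = classify_deceleration(ev, cons, cfg)
    return sorted(events, key=lambda e: (e.start_s, e.type))
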