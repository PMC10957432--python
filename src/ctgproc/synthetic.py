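"""Ground-truth synthetic tracings and clinical cohorts.

The real monitoring data lives behind a hospital firewall, so the test
bed is a generator that emulates the phenomena the pipeline must handle:
4 Hz sampling, sensor switches (external ultrasound -> fetal scalp ECG,
TOCO -> intrauterine catheter), transmission gaps, zero-valued dropouts,
resent packets with duplicate timestamps, maternal-heart-rate capture
episodes, and planted baseline / acceleration / deceleration /
contraction morphology with known extents and attributes.  Everything is
deterministic given the seed.

FHR variability is AR(1)-filtered Gaussian noise — rich enough to
exercise the entropy / Hurst orderings, with no claim of physiological
realism beyond morphology.  Planted accelerations and decelerations use
trapezoidal ramps so their true height and duration are exact.

A cohort generator produces infant records drawn to satisfy each study
group's definition with margins away from the decision boundaries, plus
an optional boundary-stress mode that plants exactly-at-threshold cases
flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .outcome import BloodGas, InfantRecord, StudyGroup
from .tracing_io import TALL_COLUMNS

__all__ = [
    "PlannedEvent",
    "SimConfig",
    "simulate_tracing",
    "simulate_cohort",
    "write_wide_csv",
    "wide_to_tall",
    "WIDE_SAMPLES_PER_ROW",
]

#: samples per one-minute legacy wide-format record (4 Hz x 60 s)
WIDE_SAMPLES_PER_ROW = 240

DELTA = 0.25


@dataclass
class PlannedEvent:
    """A planted ACC/DEC/CON with exact ground-truth extent."""

    type: str  # ACC | DEC | CON
    onset_s: float  # seconds relative to birth (negative)
    duration_s: float
    height: float
    onset_to_nadir_s: float | None = None  # DEC only
    ramp_s: float = 5.0  # ACC/CON rise/fall ramp

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class SimConfig:
    seed: int = 0
    duration_h: float = 4.0
    baseline_bpm: float = 140.0
    baseline_drift_bpm: float = 0.0  # total drift over the tracing
    variability_bpm: float = 5.0  # SD of the AR(1) noise
    ar_coeff: float = 0.95
    accels: list[PlannedEvent] = field(default_factory=list)
    decels: list[PlannedEvent] = field(default_factory=list)
    contractions: list[PlannedEvent] = field(default_factory=list)
    gap_schedule: list[tuple[float, float]] = field(default_factory=list)
    ua_gap_schedule: list[tuple[float, float]] = field(default_factory=list)
    dropout_rate: float = 0.0  # fraction of FHR samples zeroed
    dropout_mean_run: int = 4  # samples
    duplicate_rate: float = 0.0  # fraction of rows duplicated (resent)
    sensor_switch_s: float | None = None  # external->FECG, TOCO->Internal
    mhr_capture: list[tuple[float, float]] = field(default_factory=list)
    mhr_bpm: float = 80.0
    ua_tone: float = 10.0
    ua_noise: float = 1.0
    monitor: str = "Coro250"
    guid: str = "SYNTH0001"

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        for evs in (self.accels, self.decels, self.contractions):
            evs_sorted = sorted(evs, key=lambda e: e.onset_s)
            for a, b in zip(evs_sorted, evs_sorted[1:]):
                if b.onset_s < a.end_s:
                    raise ValueError(
                        f"infeasible schedule: overlapping {a.type} events"
                    )


def standard_config(seed: int = 0, duration_h: float = 4.0) -> SimConfig:
    """A realistic default stated world: 4 h of labor monitoring with
    contractions every 3 minutes in the second half, a handful of
    accelerations and decelerations, a sensor switch 30 min before birth,
    a few transmission gaps and 1 % dropouts."""
    dur = duration_h * 3600.0
    contractions = [
        PlannedEvent("CON", -t, 70.0, 40.0)
        for t in np.arange(180.0, dur / 2, 180.0)
    ]
    accels = [
        PlannedEvent("ACC", -t, 30.0, 20.0)
        for t in np.arange(1500.0, dur, 2400.0)
    ]
    decels = [
        PlannedEvent("DEC", -t, 60.0, 25.0, onset_to_nadir_s=10.0)
        for t in np.arange(600.0, dur / 2, 1800.0)
    ]
    gaps = [(-dur * 0.6, -dur * 0.6 + 120.0), (-dur * 0.3, -dur * 0.3 + 30.0)]
    return SimConfig(
        seed=seed,
        duration_h=duration_h,
        accels=accels,
        decels=decels,
        contractions=contractions,
        gap_schedule=gaps,
        dropout_rate=0.01,
        duplicate_rate=0.001,
        sensor_switch_s=-1800.0,
    )


def _ar1_noise(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    w = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = w[0]
    for i in range(1, n):
        x[i] = phi * x[i - 1] + w[i]
    # scale to the requested stationary SD
    x *= sd * np.sqrt(1 - phi**2)
    return x


def _bump(t: np.ndarray, ev: PlannedEvent) -> np.ndarray:
    """Trapezoidal ACC/CON bump (exact height on the plateau)."""
    y = np.zeros_like(t)
    r = min(ev.ramp_s, ev.duration_s / 2)
    rel = t - ev.onset_s
    m = (rel >= 0) & (rel < ev.duration_s)
    up = np.clip(rel / r, 0, 1)
    down = np.clip((ev.duration_s - rel) / r, 0, 1)
    y[m] = ev.height * np.minimum(up[m], down[m])
    return y


def _decel_shape(t: np.ndarray, ev: PlannedEvent) -> np.ndarray:
    """Piecewise-linear deceleration: onset -> nadir -> recovery."""
    y = np.zeros_like(t)
    otn = ev.onset_to_nadir_s or ev.duration_s / 2
    otn = min(otn, ev.duration_s)
    rel = t - ev.onset_s
    m = (rel >= 0) & (rel < ev.duration_s)
    down = np.where(rel < otn, rel / max(otn, 1e-9), 1.0)
    rec_len = max(ev.duration_s - otn, 1e-9)
    up = np.where(rel >= otn, 1.0 - (rel - otn) / rec_len, 1.0)
    y[m] = -ev.height * np.minimum(down[m], up[m])
    return y


def simulate_tracing(
    cfg: SimConfig, out_path=None
) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate one tracing; returns (tall-format DataFrame, truth log).

    When ``out_path`` is given the tall CSV is also written there.  The
    truth log lists every planted ACC/DEC/CON and every planted
    maternal-capture (NOI) episode with exact extents and attributes.
    """
    rng = np.random.default_rng(cfg.seed)
    dur = cfg.duration_h * 3600.0
    n = int(round(dur / DELTA))
    t = -dur + np.arange(n) * DELTA  # [-dur, 0)

    drift = cfg.baseline_drift_bpm * (t - t[0]) / dur
    fhr = cfg.baseline_bpm + drift + _ar1_noise(rng, n, cfg.ar_coeff, cfg.variability_bpm)
    truth: list[dict] = []
    for ev in cfg.accels:
        fhr += _bump(t, ev)
        truth.append(
            {"type": "ACC", "start_s": ev.onset_s, "end_s": ev.end_s,
             "height": ev.height}
        )
    for ev in cfg.decels:
        fhr += _decel_shape(t, ev)
        truth.append(
            {"type": "DEC", "start_s": ev.onset_s, "end_s": ev.end_s,
             "height": ev.height, "onset_to_nadir_s": ev.onset_to_nadir_s}
        )

    mhr = cfg.mhr_bpm + _ar1_noise(rng, n, cfg.ar_coeff, 2.0)
    for lo, hi in cfg.mhr_capture:
        m = (t >= lo) & (t < hi)
        fhr[m] = mhr[m]
        truth.append({"type": "NOI", "start_s": lo, "end_s": hi,
                      "reason": "mhr_capture"})

    ua = cfg.ua_tone + np.abs(_ar1_noise(rng, n, 0.9, cfg.ua_noise))
    for ev in cfg.contractions:
        ua += _bump(t, ev)
        truth.append(
            {"type": "CON", "start_s": ev.onset_s, "end_s": ev.end_s,
             "height": ev.height}
        )
    ua = np.clip(ua, 0.0, 100.0)
    fhr = np.clip(fhr, 0.0, 300.0)

    # dropouts: zero-valued FHR runs
    if cfg.dropout_rate > 0:
        n_drop = int(cfg.dropout_rate * n)
        dropped = 0
        while dropped < n_drop:
            start = int(rng.integers(0, n))
            run = 1 + int(rng.geometric(1.0 / cfg.dropout_mean_run))
            fhr[start : start + run] = 0.0
            dropped += run

    # gap schedules: remove samples entirely
    fhr_keep = np.ones(n, dtype=bool)
    for lo, hi in cfg.gap_schedule:
        fhr_keep &= ~((t >= lo) & (t < hi))
    ua_keep = np.ones(n, dtype=bool)
    for lo, hi in cfg.ua_gap_schedule:
        ua_keep &= ~((t >= lo) & (t < hi))

    switch = cfg.sensor_switch_s
    rows: list[dict] = []

    def emit(meas: str, sensor_fn, times: np.ndarray, values: np.ndarray) -> None:
        ms = np.round(-times * 1000.0).astype(np.int64)
        for tt, msi, v in zip(times, ms, values):
            rows.append(
                {
                    "tracing_guid": cfg.guid,
                    "trace_dt": int(msi),
                    "recorded_dt": int(msi),
                    "measurement": meas,
                    "sensor": sensor_fn(tt),
                    "monitor": cfg.monitor,
                    "reading": float(np.round(v, 3)),
                }
            )

    fhr_sensor = (
        (lambda tt: "FECG" if switch is not None and tt >= switch else "external")
    )
    ua_sensor = (
        (lambda tt: "Internal" if switch is not None and tt >= switch else "TOCO")
    )
    emit("HR2", fhr_sensor, t[fhr_keep], fhr[fhr_keep])
    emit("UP", ua_sensor, t[ua_keep], ua[ua_keep])
    emit("MHR", lambda tt: "ECG", t, mhr)

    # resent packets: duplicate a fraction of rows with a corrupted value
    # written *earlier* in the file, so the highest-row rule recovers truth
    if cfg.duplicate_rate > 0 and rows:
        k = max(1, int(cfg.duplicate_rate * len(rows)))
        pick = rng.choice(len(rows), size=k, replace=False)
        extra = []
        for i in sorted(pick):
            bad = dict(rows[i])
            bad["reading"] = float(np.round(bad["reading"] + 7.0, 3))
            extra.append((i, bad))
        out_rows: list[dict] = []
        j = 0
        for i, r in enumerate(rows):
            while j < len(extra) and extra[j][0] == i:
                out_rows.append(extra[j][1])  # corrupted copy first
                j += 1
            out_rows.append(r)
        rows = out_rows

    df = pd.DataFrame(rows, columns=TALL_COLUMNS)
    if out_path is not None:
        df.to_csv(out_path, index=False)
    truth.sort(key=lambda d: d["start_s"])
    return df, truth


# ---------------------------------------------------------------------------
# legacy wide format (one-minute records, 240 sample fields)


def write_wide_csv(tall: pd.DataFrame, path) -> None:
    """Write a tall-format frame in the legacy one-minute wide format.

    Each row holds the identifier, the timestamp of its first sample and
    240 sample fields (one minute at 4 Hz); missing samples are empty.
    """
    cols = [
        "tracing_guid", "trace_dt", "recorded_dt",
        "measurement", "monitor", "sensor",
    ] + [f"s{i}" for i in range(WIDE_SAMPLES_PER_ROW)]
    out_rows = []
    for (meas, sensor, monitor), grp in tall.groupby(
        ["measurement", "sensor", "monitor"], sort=True
    ):
        grp = grp.sort_values("trace_dt", ascending=False)  # oldest first
        ms = grp["trace_dt"].to_numpy(dtype=np.int64)
        vals = grp["reading"].to_numpy(dtype=float)
        guid = grp["tracing_guid"].iloc[0]
        minute = ms // 60000
        for mnt in np.unique(minute):
            m = minute == mnt
            row = {
                "tracing_guid": guid,
                "trace_dt": int(ms[m].max()),
                "recorded_dt": int(ms[m].max()),
                "measurement": meas,
                "monitor": monitor,
                "sensor": sensor,
            }
            row_ms0 = (mnt + 1) * 60000 - 250  # newest slot in this minute
            for msi, v in zip(ms[m], vals[m]):
                slot = int((row_ms0 - msi) // 250)
                if 0 <= slot < WIDE_SAMPLES_PER_ROW:
                    row[f"s{slot}"] = v
            out_rows.append(row)
    pd.DataFrame(out_rows, columns=cols).to_csv(path, index=False)


def wide_to_tall(wide_path, tall_path=None) -> pd.DataFrame:
    """Convert a legacy wide file back to the tall one-sample-per-row form."""
    wide = pd.read_csv(wide_path)
    sample_cols = [c for c in wide.columns if c.startswith("s") and c[1:].isdigit()]
    if len(sample_cols) != WIDE_SAMPLES_PER_ROW:
        raise ValueError(
            f"expected {WIDE_SAMPLES_PER_ROW} sample fields, got {len(sample_cols)}"
        )
    rows = []
    for _, r in wide.iterrows():
        base_minute = int(r["trace_dt"]) // 60000
        row_ms0 = (base_minute + 1) * 60000 - 250
        for i in range(WIDE_SAMPLES_PER_ROW):
            v = r[f"s{i}"]
            if pd.isna(v):
                continue
            rows.append(
                {
                    "tracing_guid": r["tracing_guid"],
                    "trace_dt": int(row_ms0 - i * 250),
                    "recorded_dt": int(row_ms0 - i * 250),
                    "measurement": r["measurement"],
                    "sensor": r["sensor"],
                    "monitor": r["monitor"],
                    "reading": float(v),
                }
            )
    df = pd.DataFrame(rows, columns=TALL_COLUMNS)
    if tall_path is not None:
        df.to_csv(tall_path, index=False)
    return df


# ---------------------------------------------------------------------------
# clinical cohort


def _make_record(rng: np.random.Generator, infant_id: str, group: StudyGroup,
                 boundary: bool = False) -> InfantRecord:
    g = group
    if g is StudyGroup.PERINATAL_HIE:
        ph = 7.00 if boundary else float(rng.uniform(6.7, 6.9))
        return InfantRecord(
            infant_id,
            cord_gases=[BloodGas("arterial", ph=ph, base_deficit=float(rng.uniform(12, 18)))],
            ene_abnormal_items=int(rng.integers(1, 7)),
            ene_recorded=True,
            hypothermia=True,
            abnormal_exam_ge_6h=bool(rng.integers(0, 2)),
            seizures_first_24h=bool(rng.integers(0, 2)),
            apgar5=int(rng.integers(0, 6)),
            nicu_admit=True,
            discharged_home=False,
        )
    if g is StudyGroup.ACIDOSIS_NO_HIE:
        ph = 7.00 if boundary else float(rng.uniform(6.75, 6.95))
        return InfantRecord(
            infant_id,
            cord_gases=[BloodGas("venous", ph=ph, base_deficit=float(rng.uniform(11, 15)))],
            ene_abnormal_items=0,
            apgar5=int(rng.integers(7, 11)),
        )
    if g is StudyGroup.HEALTHY_NO_BG:
        return InfantRecord(infant_id, apgar5=int(rng.integers(7, 11)))
    if g is StudyGroup.HEALTHY_NO_ACIDOSIS:
        return InfantRecord(
            infant_id,
            cord_gases=[BloodGas("arterial", ph=float(rng.uniform(7.15, 7.35)),
                                 base_deficit=float(rng.uniform(0, 6)))],
            apgar5=int(rng.integers(7, 11)),
        )
    if g is StudyGroup.INTERVENTION_NO_BG:
        return InfantRecord(
            infant_id, apgar5=int(rng.integers(7, 11)), nicu_admit=True
        )
    if g is StudyGroup.INTERVENTION_NO_ACIDOSIS:
        return InfantRecord(
            infant_id,
            cord_gases=[BloodGas("arterial", ph=float(rng.uniform(7.1, 7.3)),
                                 base_deficit=float(rng.uniform(0, 6)))],
            apgar5=int(rng.integers(0, 7)),
            nicu_admit=True,
        )
    if g is StudyGroup.DISTANT_HIE:
        return InfantRecord(
            infant_id,
            cord_gases=[BloodGas("arterial", ph=float(rng.uniform(7.1, 7.3)),
                                 base_deficit=float(rng.uniform(0, 6)))],
            hie_imaging_pattern=True,
            apgar5=int(rng.integers(4, 9)),
            nicu_admit=True,
        )
    if g is StudyGroup.DEATH_UNDER_6H:
        return InfantRecord(
            infant_id,
            cord_gases=[BloodGas("arterial", ph=float(rng.uniform(6.7, 7.1)),
                                 base_deficit=float(rng.uniform(8, 20)))],
            death_age_h=float(rng.uniform(0.2, 5.5)),
            death_or_transfer=True,
            discharged_home=False,
            apgar5=int(rng.integers(0, 4)),
        )
    raise ValueError(f"cannot generate group {group}")


def simulate_cohort(
    n: int,
    mix: dict[StudyGroup, float] | None = None,
    seed: int = 0,
    boundary_stress: bool = False,
) -> tuple[list[InfantRecord], list[StudyGroup], list[bool]]:
    """Generate ``n`` infant records with known study-group labels.

    ``mix`` maps groups to fractions summing to 1 (default: uniform over
    the eight groups).  In ``boundary_stress`` mode a subset of acidosis
    records is planted exactly at pH 7.00 and flagged boundary=True in
    the returned flag list.
    """
    groups = [g for g in StudyGroup if g is not StudyGroup.UNCLASSIFIED]
    if mix is None:
        mix = {g: 1.0 / len(groups) for g in groups}
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError("mix must sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(
        [g.value for g in mix], size=n, p=[mix[g] for g in mix]
    )
    records, out_labels, boundary_flags = [], [], []
    for i, gname in enumerate(labels):
        g = StudyGroup(gname)
        boundary = bool(
            boundary_stress
            and g in (StudyGroup.PERINATAL_HIE, StudyGroup.ACIDOSIS_NO_HIE)
            and rng.random() < 0.2
        )
        records.append(_make_record(rng, f"INF{i:05d}", g, boundary))
        out_labels.append(g)
        boundary_flags.append(boundary)
    return records, out_labels, boundary_flags
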