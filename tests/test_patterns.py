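"""Baseline, acceleration/deceleration, contraction detection and subtyping."""

import numpy as np
import pytest

from ctgproc.patterns import (
    Event,
    PatternConfig,
    classify_deceleration,
    detect_acc_dec,
    detect_contractions,
    detect_patterns,
    estimate_baseline,
)
from ctgproc.segsig import DELTA, EFMRecord, build_segmented


def fhr_signal(values, start=-3600.0):
    t = start + np.arange(len(values)) * DELTA
    return build_segmented(zip(t, values), measurement="FHR")


def plateau(base, height, onset_i, dur_i, n):
    v = np.full(n, float(base))
    v[onset_i : onset_i + dur_i] += height
    return v


class TestBaseline:
    def test_flat_hour_single_bas(self):
        n = 14400  # 1 h
        events, _ = estimate_baseline(fhr_signal(np.full(n, 140.0)))
        bas = [e for e in events if e.type == "BAS"]
        assert len(bas) == 1
        assert bas[0].attrs["level"] == pytest.approx(140.0, abs=0.1)
        assert bas[0].attrs["slope_bpm_per_min"] == pytest.approx(0.0, abs=0.01)

    def test_planted_deceleration_does_not_drag_baseline(self):
        n = 14400
        v = np.full(n, 140.0)
        v[7000:7400] -= 40.0  # 100 s deep deceleration
        events, chunks = estimate_baseline(fhr_signal(v))
        _, _, b = chunks[0]
        assert np.nanmax(np.abs(b - 140.0)) < 1.0

    def test_linear_drift_slope_recovered(self):
        n = 14400
        v = np.linspace(140.0, 150.0, n)  # +10 bpm over one hour
        events, _ = estimate_baseline(fhr_signal(v))
        bas = [e for e in events if e.type == "BAS"]
        slope_per_h = sum(
            e.attrs["slope_bpm_per_min"] * 60 * e.duration for e in bas
        ) / sum(e.duration for e in bas)
        assert slope_per_h == pytest.approx(10.0, rel=0.15)

    def test_short_span_gets_no_baseline(self):
        n = 400  # 100 s < 2 min
        events, chunks = estimate_baseline(fhr_signal(np.full(n, 140.0)))
        assert [e for e in events if e.type == "BAS"] == []
        assert np.isnan(chunks[0][2]).all()


class TestAccDec:
    def test_plateau_acceleration_detected(self):
        n = 14400
        v = plateau(140, 20.0, 7000, 80, n)  # +20 bpm for 20 s
        evs = detect_acc_dec(fhr_signal(v))
        accs = [e for e in evs if e.type == "ACC"]
        assert len(accs) == 1
        assert accs[0].attrs["height"] == pytest.approx(20.0, abs=0.5)

    def test_15bpm_exactly_is_not_an_event(self):
        n = 14400
        v = plateau(140, 15.0, 7000, 200, n)
        evs = detect_acc_dec(fhr_signal(v))
        assert [e for e in evs if e.type == "ACC"] == []

    def test_15s_exactly_is_not_an_event(self):
        n = 14400
        v = plateau(140, -20.0, 7000, 60, n)  # 60 samples = 15.0 s
        evs = detect_acc_dec(fhr_signal(v))
        assert [e for e in evs if e.type == "DEC"] == []

    def test_just_over_both_thresholds_detected(self):
        n = 14400
        v = plateau(140, -17.0, 7000, 68, n)  # 17 bpm, 17 s
        evs = detect_acc_dec(fhr_signal(v))
        decs = [e for e in evs if e.type == "DEC"]
        assert len(decs) == 1
        assert decs[0].attrs["height"] == pytest.approx(17.0, abs=0.5)

    def test_area_in_beats(self):
        n = 14400
        v = plateau(140, 20.0, 7000, 80, n)
        evs = detect_acc_dec(fhr_signal(v))
        acc = [e for e in evs if e.type == "ACC"][0]
        # 20 bpm excess for 20 s ~ 20*20/60 beats
        assert acc.attrs["area_beats"] == pytest.approx(20 * 20 / 60, rel=0.1)


class TestDecSubtype:
    def dec(self, duration, onset_to_nadir, nadir=None, start=0.0):
        nadir = nadir if nadir is not None else start + onset_to_nadir
        return Event(
            "G", "DEC", start, start + duration,
            {"onset_to_nadir_s": onset_to_nadir, "nadir_s": nadir, "height": 20},
        )

    def con(self, start, end, peak):
        return Event("G", "CON", start, end, {"peak_s": peak})

    def test_prolonged(self):
        assert classify_deceleration(self.dec(130, 60), []) == "prolonged"

    def test_abrupt_is_variable(self):
        assert classify_deceleration(self.dec(60, 10), []) == "variable"

    def test_gradual_late(self):
        d = self.dec(90, 45, nadir=55.0)
        c = self.con(0, 70, peak=30.0)  # nadir 25 s after the peak
        assert classify_deceleration(d, [c]) == "late"

    def test_gradual_early(self):
        d = self.dec(90, 45, nadir=40.0)
        c = self.con(0, 80, peak=35.0)
        assert classify_deceleration(d, [c]) == "early"

    def test_gradual_unpaired_variable(self):
        assert classify_deceleration(self.dec(90, 45), []) == "variable"


class TestContractions:
    def ua_with_bells(self, centers, height=40.0, width=70.0, n=14400, tone=10.0):
        t = -3600 + np.arange(n) * DELTA
        v = np.full(n, tone)
        for c in centers:
            m = np.abs(t - c) < width / 2
            v[m] += height * 0.5 * (1 + np.cos(2 * np.pi * (t[m] - c) / width))
        return build_segmented(zip(t, v), measurement="UA", units="0-100")

    def test_planted_bell_height_recovered(self):
        ua = self.ua_with_bells([-1800.0])
        cons = detect_contractions(ua)
        assert len(cons) == 1
        assert cons[0].attrs["height"] == pytest.approx(40.0, abs=2.0)

    def test_flat_ua_none(self):
        t = -3600 + np.arange(14400) * DELTA
        ua = build_segmented(zip(t, np.full(14400, 12.0)), measurement="UA")
        assert detect_contractions(ua) == []

    def test_six_contractions_three_minutes_apart(self):
        centers = [-3000 + k * 180 for k in range(6)]
        cons = detect_contractions(self.ua_with_bells(centers))
        assert len(cons) == 6


class TestPartition:
    def test_bas_acc_dec_rin_partition_interpretable_time(self):
        rng = np.random.default_rng(3)
        n = 14400
        v = 140 + 2 * rng.standard_normal(n)
        v = plateau(0, 25.0, 4000, 100, n) + v  # one ACC
        v[9000:9200] -= 30.0  # one DEC
        fhr = fhr_signal(v)
        rec = EFMRecord(guid="G", stage="repaired", signals={"FHR": fhr})
        evs = detect_patterns(rec)
        fhr_evs = [e for e in evs if e.type in ("BAS", "ACC", "DEC", "RIN")]
        total = sum(e.duration for e in fhr_evs)
        assert total == pytest.approx(n * DELTA, abs=DELTA)
        # no overlaps
        fhr_evs.sort(key=lambda e: e.start_s)
        for a, b in zip(fhr_evs, fhr_evs[1:]):
            assert b.start_s >= a.end_s - 1e-6


class TestPlantedRecovery:
    def test_noise_free_events_recovered_exactly(self):
        """Planted events >= 2 bpm / 2 s over thresholds: 100 % recovery."""
        n = 4 * 14400  # 4 h
        v = np.full(n, 140.0)
        planted = []
        for k, onset in enumerate(range(4000, n - 4000, 8000)):
            if k % 2 == 0:
                v[onset : onset + 80] += 17.0  # ACC: 17 bpm, 20 s
                planted.append(("ACC", onset))
            else:
                v[onset : onset + 100] -= 25.0  # DEC: 25 bpm, 25 s
                planted.append(("DEC", onset))
        evs = detect_acc_dec(fhr_signal(v, start=-n * DELTA))
        got = [(e.type, e.start_s) for e in evs if e.type in ("ACC", "DEC")]
        assert len(got) == len(planted)  # PPV = 100 %
        starts = {-n * DELTA + i * DELTA: typ for typ, i in planted}
        for typ, s in got:  # sensitivity = 100 %, correct extents
            assert starts.get(s) == typ
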