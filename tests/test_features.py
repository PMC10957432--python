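"""Epoch segmentation, sequential block, and the variability battery."""

import numpy as np
import pytest

from ctgproc.features import (
    DEFAULT_MASK,
    FeatureConfig,
    assemble_feature_matrix,
    classical_variability,
    complexity,
    decompose_spectral,
    entropies,
    extract_features,
    hurst_rs,
    lomb_bands,
    prsa,
    segment_epochs,
    sequential_features,
)
from ctgproc.patterns import Event
from ctgproc.segsig import DELTA, EFMRecord, build_segmented

from conftest import apen_bruteforce, prsa_bruteforce, sampen_bruteforce


def record_with_epoch0_samples(n):
    """FHR record whose samples all fall in the last 20-minute epoch."""
    t = -n * DELTA + np.arange(n) * DELTA
    sig = build_segmented(zip(t, np.full(n, 140.0)), measurement="FHR")
    return EFMRecord(guid="G", stage="repaired", signals={"FHR": sig})


class TestSegmentEpochs:
    def test_full_epoch_retained(self):
        eps = segment_epochs(record_with_epoch0_samples(4800))
        assert len(eps) == 1
        assert eps[0]["interpretable_fraction"] == pytest.approx(1.0)

    @pytest.mark.parametrize("n, retained", [(3840, True), (3839, False)])
    def test_retention_boundary(self, n, retained):
        eps = segment_epochs(record_with_epoch0_samples(n))
        assert bool(eps) is retained

    def test_noi_samples_removed_before_counting(self):
        rec = record_with_epoch0_samples(4800)
        # knock out 1000 samples via NOI -> 3800 < 3840 left
        noi = [(-1200.0, -1200.0 + 1000 * DELTA)]
        assert segment_epochs(rec, noi) == []


class TestSequential:
    def test_all_bas_epoch(self):
        evs = [Event("G", "BAS", -1200.0, 0.0, {})]
        out = sequential_features(evs, -1200.0, 0.0)
        assert out["dwell_BAS"] == pytest.approx(1200.0)
        assert all(
            out[f"trans_{a}_{b}"] == 0
            for a in ("BAS", "ACC", "DEC")
            for b in ("BAS", "ACC", "DEC")
        )

    def test_bas_dec_bas_transitions(self):
        evs = [
            Event("G", "BAS", -1200.0, -700.0, {}),
            Event("G", "DEC", -700.0, -650.0, {}, subtype="variable"),
            Event("G", "BAS", -650.0, 0.0, {}),
        ]
        out = sequential_features(evs, -1200.0, 0.0)
        assert out["trans_BAS_DEC"] == 1
        assert out["trans_DEC_BAS"] == 1

    def test_contraction_rate_conversion(self):
        evs = [
            Event("G", "CON", -1200 + k * 180, -1200 + k * 180 + 60,
                  {"peak_s": -1200 + k * 180 + 30})
            for k in range(6)
        ]
        out = sequential_features(evs, -1200.0, 0.0)
        assert out["contraction_rate_per_10min"] == pytest.approx(3.0)

    def test_long_rin_breaks_adjacency(self):
        evs = [
            Event("G", "BAS", -1200.0, -800.0, {}),
            # 100 s unclassified span
            Event("G", "DEC", -700.0, -650.0, {}, subtype="variable"),
        ]
        out = sequential_features(evs, -1200.0, 0.0)
        assert out["trans_BAS_DEC"] == 0

    def test_dec_subtype_frequencies_sum_to_count(self):
        evs = [
            Event("G", "DEC", -1100, -1050, {}, subtype="late"),
            Event("G", "DEC", -1000, -950, {}, subtype="variable"),
            Event("G", "DEC", -900, -850, {}, subtype="early"),
            Event("G", "DEC", -800, -600, {}, subtype="prolonged"),
        ]
        out = sequential_features(evs, -1200.0, 0.0)
        assert out["freq_dec_late"] == 1
        assert out["freq_dec_abrupt"] == 1
        assert out["freq_dec_others"] == 2
        assert (
            out["freq_dec_late"] + out["freq_dec_abrupt"] + out["freq_dec_others"]
            == out["n_dec"]
        )

    def test_cumulative_dwell_before_epoch(self):
        evs = [
            Event("G", "BAS", -3600.0, -1200.0, {}),
            Event("G", "BAS", -1200.0, 0.0, {}),
        ]
        out = sequential_features(evs, -1200.0, 0.0)
        assert out["cumdwell_BAS"] == pytest.approx(2400.0)


class TestSpectral:
    def test_components_sum_to_signal(self):
        rng = np.random.default_rng(0)
        x = 140 + 5 * rng.standard_normal(4800)
        low, high = decompose_spectral(x, DELTA)
        assert np.max(np.abs(low + high - x)) < 1e-9 * np.max(np.abs(x))

    def test_slow_sinusoid_goes_low(self):
        t = np.arange(4800) * DELTA
        x = np.sin(2 * np.pi * 0.010 * t)  # 10 mHz
        low, high = decompose_spectral(x, DELTA)
        assert np.std(high) < 0.05 * np.std(x)

    def test_fast_sinusoid_goes_high(self):
        t = np.arange(4800) * DELTA
        x = np.sin(2 * np.pi * 0.2 * t)
        low, high = decompose_spectral(x, DELTA)
        assert np.std(low) < 0.05 * np.std(x)


class TestPRSA:
    def test_constant_signal_invalid(self):
        assert np.isnan(prsa(np.full(1000, 140.0), "increment", DELTA))

    def test_square_wave_matches_bruteforce(self):
        # +/-a alternation at the T scale
        a = 5.0
        nT = int(2.5 / DELTA)
        x = 140 + a * np.tile(
            np.concatenate([np.ones(nT), -np.ones(nT)]), 60
        )
        for anchor in ("increment", "decrement"):
            got = prsa(x, anchor, DELTA)
            want = prsa_bruteforce(x, anchor, DELTA, 2.5, 25.0)
            assert got == pytest.approx(want, abs=1e-12)

    def test_white_noise_symmetry(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(100_000)
        ac = prsa(x, "increment", DELTA)
        dc = prsa(x, "decrement", DELTA)
        assert ac == pytest.approx(-dc, abs=0.01)
        assert ac > 0 > dc  # anchors select their own direction

    def test_matches_bruteforce_on_noise(self):
        rng = np.random.default_rng(1)
        x = 140 + 5 * rng.standard_normal(300)
        for anchor in ("increment", "decrement"):
            assert prsa(x, anchor, DELTA, T=0.5, L=5.0) == pytest.approx(
                prsa_bruteforce(x, anchor, DELTA, 0.5, 5.0), abs=1e-10
            )


class TestLomb:
    def gappy_sinusoid(self, freq, n=4800):
        # 20 % of the samples removed as two contiguous transmission gaps
        t = np.arange(n) * DELTA
        keep = np.ones(n, dtype=bool)
        keep[1000:1480] = False
        keep[3000:3480] = False
        return t[keep], np.sin(2 * np.pi * freq * t[keep])

    @pytest.mark.parametrize(
        "freq, band", [(0.1, "lf_power"), (0.3, "mf_power"), (0.7, "hf_power")]
    )
    def test_band_concentration_with_gaps(self, freq, band):
        t, x = self.gappy_sinusoid(freq)
        out = lomb_bands(t, x)
        total = out["lf_power"] + out["mf_power"] + out["hf_power"]
        assert out[band] / total >= 0.95

    def test_zero_variance_invalid(self):
        t = np.arange(4800) * DELTA
        out = lomb_bands(t, np.full(4800, 140.0))
        assert all(np.isnan(v) for v in out.values())


class TestEntropies:
    def test_constant_is_degenerate_zero(self):
        out = entropies(np.full(500, 140.0))
        assert out["apen_0.2"] == 0.0 and out["sampen_0.2"] == 0.0

    def test_periodic_below_shuffled(self):
        rng = np.random.default_rng(5)
        saw = np.tile(np.arange(10.0), 50)
        shuffled = saw.copy()
        rng.shuffle(shuffled)
        assert (
            entropies(saw)["sampen_0.2"] < entropies(shuffled)["sampen_0.2"]
        )

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        x = 140 + 5 * rng.standard_normal(120)
        sd = np.std(x)
        out = entropies(x)
        for rf in (0.1, 0.2, 0.3):
            r = np.float32(rf * sd)  # implementation thresholds in float32
            assert out[f"apen_{rf:.1f}"] == pytest.approx(
                apen_bruteforce(x.astype(np.float32), 2, r), abs=1e-5
            )
            assert out[f"sampen_{rf:.1f}"] == pytest.approx(
                sampen_bruteforce(x.astype(np.float32), 2, r), abs=1e-5
            )


class TestComplexity:
    def test_white_noise_hurst_near_half(self):
        rng = np.random.default_rng(11)
        assert hurst_rs(rng.standard_normal(4096)) == pytest.approx(0.5, abs=0.1)

    def test_persistent_process_higher_hurst(self):
        rng = np.random.default_rng(7)
        w = rng.standard_normal(4096)
        ar = np.empty(4096)
        ar[0] = w[0]
        for i in range(1, 4096):
            ar[i] = 0.9 * ar[i - 1] + w[i]
        assert hurst_rs(ar) > hurst_rs(w)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(2048)
        a = complexity(x, DELTA)
        b = complexity(x.copy(), DELTA)
        assert a == b

    def test_constant_invalid(self):
        out = complexity(np.full(1000, 140.0), DELTA)
        assert all(np.isnan(v) for v in out.values())


class TestClassical:
    def test_constant_zero(self):
        out = classical_variability(np.full(480, 140.0), DELTA)
        assert out["stv"] == 0.0 and out["delta"] == 0.0

    def test_grid_alternation_stv(self):
        # 2.5 s-grid samples alternate 130/140
        n = 2400
        x = np.where((np.arange(n) // 10) % 2 == 0, 130.0, 140.0)
        assert classical_variability(x, DELTA)["stv"] == pytest.approx(10.0)

    def test_sawtooth_delta(self):
        # one-minute sawtooth sweeping 120 -> 150
        wn = 240
        x = np.tile(np.linspace(120.0, 150.0, wn), 10)
        assert classical_variability(x, DELTA)["delta"] == pytest.approx(30.0)

    def test_interval_index_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        x = 140 + 5 * rng.standard_normal(2400)
        out = classical_variability(x, DELTA)
        grid = x[::10]
        assert out["interval_index"] == pytest.approx(
            np.mean(np.abs(np.diff(grid))) / np.std(grid)
        )


class TestAssembleMatrix:
    def make_epoch_and_events(self, with_acc=True):
        n = 4800
        t = -1200 + np.arange(n) * DELTA
        rng = np.random.default_rng(0)
        v = 140 + 3 * rng.standard_normal(n)
        events = [Event("G", "BAS", -1200.0, 0.0, {})]
        if with_acc:
            v[2000:2100] += 25
            events = [
                Event("G", "BAS", -1200.0, -700.0, {}),
                Event("G", "ACC", -700.0, -675.0, {}),
                Event("G", "BAS", -675.0, 0.0, {}),
            ]
        epoch = {
            "epoch_index": 0,
            "start_s": -1200.0,
            "end_s": 0.0,
            "times": t,
            "values": v,
            "interpretable_fraction": 1.0,
        }
        return epoch, events

    def test_default_mask_cells_exactly(self):
        epoch, events = self.make_epoch_and_events()
        ef = assemble_feature_matrix(epoch, events, DELTA)
        want = {
            (feat, ev, band)
            for feat, cells in DEFAULT_MASK.items()
            for ev, band in cells
        }
        assert set(ef.variability) == want

    def test_all_bas_epoch_flags_acc_dec_invalid(self):
        epoch, events = self.make_epoch_and_events(with_acc=False)
        ef = assemble_feature_matrix(epoch, events, DELTA)
        assert np.isnan(ef.variability[("mean", "ACC", "low")])
        assert not ef.validity[("mean", "ACC", "low")]
        assert ef.validity[("mean", "BAS", "low")]

    def test_mask_override_adds_without_changing(self):
        epoch, events = self.make_epoch_and_events()
        base = assemble_feature_matrix(epoch, events, DELTA)
        bigger = dict(DEFAULT_MASK)
        bigger["slope"] = DEFAULT_MASK["slope"] + [("ACC", "low")]
        out = assemble_feature_matrix(epoch, events, DELTA, mask=bigger)
        for cell, v in base.variability.items():
            got = out.variability[cell]
            assert (np.isnan(v) and np.isnan(got)) or got == v
        assert ("slope", "ACC", "low") in out.variability


class TestExtract:
    def test_epoch_accounting(self):
        n = 3 * 4800
        t = -n * DELTA + np.arange(n) * DELTA
        rng = np.random.default_rng(1)
        sig = build_segmented(
            zip(t, 140 + 3 * rng.standard_normal(n)), measurement="FHR"
        )
        rec = EFMRecord(guid="G", stage="repaired", signals={"FHR": sig})
        events = [Event("G", "BAS", t[0], 0.0, {})]
        feats = extract_features(rec, events)
        assert len(feats) == 3
        used = sum(f.interpretable_fraction * 4800 for f in feats)
        assert len(feats) * 4800 >= used
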