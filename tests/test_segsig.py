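"""Segmented-signal container and algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctgproc.segsig import (
    DELTA,
    build_segmented,
    concatenate,
    find_gaps,
    from_dense,
    from_seg_lengths,
    intersect,
    to_dense,
)

from conftest import dense_map, oracle_gaps, oracle_intersect_support, random_signal


def make_two_segment():
    """Samples at 0.00..6.25 s and 10.00..14.75 s (4 Hz)."""
    t = np.concatenate([np.arange(0, 6.5, 0.25), np.arange(10.0, 15.0, 0.25)])
    return build_segmented(zip(t, np.full(t.size, 140.0)))


class TestBuild:
    def test_two_segments_from_contiguity_rule(self):
        sig = make_two_segment()
        assert sig.n_segments == 2
        assert list(sig.seg_lengths) == [26, 20]
        assert list(sig.onset_pointers) == [1, 27]
        assert list(sig.onset_offsets) == [0, 26]

    def test_fully_contiguous_single_segment(self):
        t = np.arange(4800) * DELTA - 1200.0
        sig = build_segmented(zip(t, np.full(4800, 140.0)))
        assert sig.n_segments == 1
        assert sig.n_samples == 4800

    def test_printed_five_segment_structure(self):
        # the published example record: five segments with these lengths
        lens = [26136, 11704, 30764, 26880, 66212]
        starts_h = [-16.5108, -14.6275, -13.0372, -9.5442, -7.6442]
        starts = [round(h * 3600 / DELTA) * DELTA for h in starts_h]
        sig = from_seg_lengths(lens, starts)
        assert list(sig.onset_pointers) == [1, 26137, 37841, 68605, 95485]
        assert sig.n_samples == 161696

    @pytest.mark.parametrize(
        "times, err",
        [
            ([0.0, 0.5, 0.25], "unsorted"),
            ([0.0, 0.25, 0.37], "off-grid"),
        ],
    )
    def test_bad_input_rejected(self, times, err):
        with pytest.raises(ValueError, match=err):
            build_segmented([(t, 140.0) for t in times])


class TestFindGaps:
    def test_two_segment_gap(self):
        gaps = find_gaps(make_two_segment())
        assert gaps == [(6.5, 10.0)]
        assert gaps[0][1] - gaps[0][0] == pytest.approx(3.5)

    def test_single_segment_no_gap(self):
        t = np.arange(10) * DELTA
        sig = build_segmented(zip(t, np.ones(10)))
        assert find_gaps(sig) == []

    def test_printed_record_first_gap_duration(self):
        lens = [26136, 11704, 30764, 26880, 66212]
        starts_h = [-16.5108, -14.6275, -13.0372, -9.5442, -7.6442]
        starts = [round(h * 3600 / DELTA) * DELTA for h in starts_h]
        sig = from_seg_lengths(lens, starts)
        gaps = find_gaps(sig)
        assert len(gaps) == 4
        # derived from the printed start times and segment lengths
        expected = (starts_h[1] * 3600) - (starts_h[0] * 3600 + 26136 * DELTA)
        assert gaps[0][1] - gaps[0][0] == pytest.approx(expected, abs=0.5)


class TestDenseRoundTrip:
    def test_two_segment_dense_counts(self):
        times, values = to_dense(make_two_segment())
        assert values.size == 60
        assert int(np.isnan(values).sum()) == 14

    def test_gapless_dense_equals_data(self):
        t = np.arange(100) * DELTA
        sig = build_segmented(zip(t, np.arange(100.0)))
        _, values = to_dense(sig)
        assert np.array_equal(values, sig.data)

    def test_round_trip_fuzzed(self, rng):
        for _ in range(50):
            sig = random_signal(rng)
            times, values = to_dense(sig)
            back = from_dense(times, values)
            assert back.content_equal(sig)

    def test_off_grid_dense_axis_rejected(self):
        with pytest.raises(ValueError):
            from_dense(np.array([0.0, 0.1]), np.array([1.0, 2.0]))


class TestIntersect:
    def test_overlapping_supports(self):
        a = build_segmented(
            zip(np.arange(0, 100, 0.25), np.full(400, 1.0))
        )
        b = build_segmented(
            zip(np.arange(50, 150, 0.25), np.full(400, 2.0))
        )
        a2, b2 = intersect(a, b)
        assert a2.support() == b2.support() == [(50.0, 100.0)]
        assert np.all(a2.data == 1.0) and np.all(b2.data == 2.0)

    def test_disjoint_supports_empty(self):
        a = build_segmented(zip(np.arange(0, 10, 0.25), np.ones(40)))
        b = build_segmented(zip(np.arange(20, 30, 0.25), np.ones(40)))
        a2, b2 = intersect(a, b)
        assert a2.is_empty and b2.is_empty

    def test_delta_mismatch_rejected(self):
        a = build_segmented(zip(np.arange(0, 1, 0.25), np.ones(4)))
        b = build_segmented(zip(np.arange(0, 2, 0.5), np.ones(4)), delta=0.5)
        with pytest.raises(ValueError, match="delta"):
            intersect(a, b)

    def test_matches_dense_oracle_fuzzed(self, rng):
        for _ in range(100):
            a = random_signal(rng)
            b = random_signal(rng)
            a2, b2 = intersect(a, b)
            want = oracle_intersect_support(a, b)
            assert set(dense_map(a2)) == want
            assert set(dense_map(b2)) == want
            # values unchanged
            ma, m2 = dense_map(a), dense_map(a2)
            assert all(ma[k] == m2[k] for k in m2)

    def test_never_increases_samples(self, rng):
        for _ in range(30):
            a, b = random_signal(rng), random_signal(rng)
            a2, b2 = intersect(a, b)
            assert a2.n_samples <= a.n_samples
            assert b2.n_samples <= b.n_samples


class TestConcatenate:
    def test_abutting_halves_fuse(self):
        a = build_segmented(zip(np.arange(0, 10, 0.25), np.ones(40)))
        b = build_segmented(zip(np.arange(10, 20, 0.25), np.ones(40)))
        out = concatenate([a, b])
        assert out.n_segments == 1
        assert out.n_samples == 80

    def test_disjoint_parts_keep_segments(self):
        a = build_segmented(zip(np.arange(0, 10, 0.25), np.ones(40)))
        b = build_segmented(zip(np.arange(20, 30, 0.25), np.ones(40)))
        out = concatenate([a, b])
        assert out.n_segments == 2

    def test_order_invariance(self, rng):
        a = random_signal(rng, start_index=-400)
        b = random_signal(rng, start_index=0)
        assert concatenate([a, b]).content_equal(concatenate([b, a]))

    def test_overlap_rejected(self):
        a = build_segmented(zip(np.arange(0, 10, 0.25), np.ones(40)))
        b = build_segmented(zip(np.arange(5, 15, 0.25), np.ones(40)))
        with pytest.raises(ValueError, match="overlap"):
            concatenate([a, b])

    def test_conserves_sample_count(self, rng):
        a = random_signal(rng, start_index=-500)
        b = random_signal(rng, start_index=0)
        out = concatenate([a, b])
        assert out.n_samples == a.n_samples + b.n_samples


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_gap_listing_matches_dense_oracle(seed):
    """find_gaps agrees with the missing-index runs of the dense map."""
    sig = random_signal(np.random.default_rng(seed))
    assert find_gaps(sig) == oracle_gaps(sig)
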