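"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ctgproc.segsig import DELTA, SegmentedSignal, build_segmented

# ---------------------------------------------------------------------------
# dense-representation oracle: a segmented signal as {grid index: value}


def dense_map(sig: SegmentedSignal) -> dict[int, float]:
    times = sig.sample_times()
    idx = np.round(times / sig.delta).astype(np.int64)
    return dict(zip(idx.tolist(), sig.data.tolist()))


def oracle_gaps(sig: SegmentedSignal) -> list[tuple[float, float]]:
    """Gaps from the dense map: missing-index runs between present samples."""
    idx = sorted(dense_map(sig))
    gaps = []
    for a, b in zip(idx, idx[1:]):
        if b - a > 1:
            gaps.append(((a + 1) * sig.delta, b * sig.delta))
    return gaps


def oracle_intersect_support(
    a: SegmentedSignal, b: SegmentedSignal
) -> set[int]:
    return set(dense_map(a)) & set(dense_map(b))


def signal_from_map(
    m: dict[int, float], delta: float = DELTA, measurement: str = "FHR"
) -> SegmentedSignal:
    items = sorted(m.items())
    return build_segmented(
        [(i * delta, v) for i, v in items], delta=delta, measurement=measurement
    )


def random_signal(
    rng: np.random.Generator,
    max_segments: int = 5,
    max_len: int = 30,
    max_gap: int = 10,
    start_index: int | None = None,
) -> SegmentedSignal:
    """A random small multi-segment signal on the 4 Hz grid."""
    n_seg = int(rng.integers(1, max_segments + 1))
    idx = start_index if start_index is not None else int(rng.integers(-400, 0))
    m: dict[int, float] = {}
    for _ in range(n_seg):
        length = int(rng.integers(1, max_len + 1))
        for _ in range(length):
            m[idx] = float(np.round(rng.uniform(60, 200), 2))
            idx += 1
        idx += int(rng.integers(2, max_gap + 2))  # gap >= 1 missing sample
    return signal_from_map(m)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# brute-force feature oracles (intentionally naive, loop-based)


def apen_bruteforce(x: np.ndarray, m: int, r: float) -> float:
    """O(n^2) approximate entropy straight from the definition."""
    x = np.asarray(x, dtype=float)

    def phi(mm: int) -> float:
        n = len(x) - mm + 1
        total = 0.0
        for i in range(n):
            count = 0
            for j in range(n):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    count += 1
            total += np.log(count / n)
        return total / n

    return phi(m) - phi(m + 1)


def sampen_bruteforce(x: np.ndarray, m: int, r: float) -> float:
    """O(n^2) sample entropy: template matches without self-matches."""
    x = np.asarray(x, dtype=float)
    n = len(x) - m  # templates compared for both lengths

    def count(mm: int) -> int:
        c = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return np.nan  # undefined: no template matches at this tolerance
    return float(-np.log(a / b))


def prsa_bruteforce(x: np.ndarray, anchor: str, delta: float, T: float, L: float) -> float:
    """Direct loop implementation of phase-rectified signal averaging."""
    x = np.asarray(x, dtype=float)
    nT = int(round(T / delta))
    nL = int(round(L / delta))
    anchors = []
    for i in range(nL, len(x) - nL):
        before = np.mean(x[i - nT : i])
        after = np.mean(x[i : i + nT])
        if anchor == "increment" and after > before:
            anchors.append(i)
        elif anchor == "decrement" and after < before:
            anchors.append(i)
    if not anchors:
        return np.nan
    window = np.zeros(4 * nT)
    for i in anchors:
        window += x[i - 2 * nT : i + 2 * nT]
    window /= len(anchors)
    a2 = window[0:nT].mean()
    a1 = window[nT : 2 * nT].mean()
    p1 = window[2 * nT : 3 * nT].mean()
    p2 = window[3 * nT : 4 * nT].mean()
    return float((p1 + p2 - a1 - a2) / 4.0)
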