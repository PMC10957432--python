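"""Epoch segmentation and the FHR/UA feature battery.

The repaired record is divided into non-overlapping 20-minute epochs
tiled backwards from birth.  Uninterpretable (NOI) samples are removed;
an epoch is retained only when at least 80 % of its samples (3840 at
4 Hz) remain.  Two feature blocks are computed per retained epoch:

**Sequential (marked-point-process) block** — per-type dwell times,
cumulative dwell since the start of monitoring, transition counts
between FHR events, contraction rate per 10 minutes, and deceleration
subtype frequencies.

**Variability block** — the FHR is split by Fourier transform into a
low-frequency component (0–30 mHz, slow trends) and a high-frequency
component (30 mHz–2 Hz), each masked by event type (BAS/ACC/DEC), and a
battery of variability measures is evaluated on the cells of a
configurable feature × event × band mask: mean/SD, slope, height/area,
phase-rectified signal averaging (acceleration and deceleration
capacity, deceleration reserve), Lomb-Scargle band powers (LF 30–150
mHz, MF 150–500 mHz, HF 0.5–1 Hz, normalized by variance),
approximate and sample entropy (m=2, r ∈ {0.1,0.2,0.3}·SD), Hurst
exponent (rescaled range), Lyapunov exponent and correlation dimension
(embedding dimension 2, delay 1), and the classical indices STV, LTI,
Delta and the interval index on the 2.5 s grid.

Samples removed inside an epoch are concatenated for the time-domain
features but keep their true timestamps for the Lomb-Scargle
periodogram, which tolerates gaps by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .segsig import EFMRecord, SegmentedSignal
from .patterns import Event

__all__ = [
    "FeatureConfig",
    "EpochFeatures",
    "segment_epochs",
    "sequential_features",
    "decompose_spectral",
    "prsa",
    "lomb_bands",
    "entropies",
    "complexity",
    "classical_variability",
    "assemble_feature_matrix",
    "extract_features",
    "DEFAULT_MASK",
]

_EPS = 1e-9


@dataclass
class FeatureConfig:
    epoch_s: float = 1200.0
    min_coverage: float = 0.80  # -> 3840 samples at 4 Hz
    split_hz: float = 0.030  # low/high component boundary
    band_edges: dict = field(
        default_factory=lambda: {
            "LF": (0.030, 0.150),
            "MF": (0.150, 0.500),
            "HF": (0.500, 1.000),
        }
    )
    prsa_T: float = 2.5  # s
    prsa_L: float = 25.0  # s
    entropy_m: int = 2
    entropy_r: tuple = (0.1, 0.2, 0.3)  # fractions of SD
    stv_step: float = 2.5  # s
    delta_window: float = 60.0  # s
    embed_dim: int = 2
    embed_delay: int = 1
    transition_rin_break_s: float = 30.0

    def min_samples(self, delta: float) -> int:
        return int(round(self.min_coverage * self.epoch_s / delta))


# Table-style default mask: feature -> set of (event, band) cells.
_ALL = [(e, b) for e in ("BAS", "ACC", "DEC") for b in ("low", "high")]
_LOW_BAS = [("BAS", "low")]
_LOW_AD = [("ACC", "low"), ("DEC", "low")]
_HIGH = [(e, "high") for e in ("BAS", "ACC", "DEC")]

DEFAULT_MASK: dict[str, list[tuple[str, str]]] = {
    "mean": list(_ALL),
    "sd": list(_ALL),
    "slope": list(_LOW_BAS),
    "height": list(_LOW_AD),
    "area": list(_LOW_AD),
    "prsa_ac": list(_HIGH),
    "prsa_dc": list(_HIGH),
    "prsa_dr": list(_HIGH),
    "lf_power": list(_HIGH),
    "mf_power": list(_HIGH),
    "hf_power": list(_HIGH),
    "lf_ratio": list(_HIGH),
    "apen_0.1": list(_HIGH),
    "apen_0.2": list(_HIGH),
    "apen_0.3": list(_HIGH),
    "sampen_0.1": list(_HIGH),
    "sampen_0.2": list(_HIGH),
    "sampen_0.3": list(_HIGH),
    "hurst": list(_HIGH),
    "lyapunov": list(_HIGH),
    "corr_dim": list(_HIGH),
    "stv": list(_HIGH),
    "lti": list(_HIGH),
    "delta": list(_HIGH),
    "interval_index": list(_HIGH),
}


@dataclass
class EpochFeatures:
    guid: str
    epoch_index: int
    start_s: float
    end_s: float
    interpretable_fraction: float
    sequential: dict = field(default_factory=dict)
    variability: dict = field(default_factory=dict)  # (feature, event, band) -> value
    validity: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "guid": self.guid,
            "epoch_index": self.epoch_index,
            "start_s": self.start_s,
            "end_s": self.end_s,
            "interpretable_fraction": self.interpretable_fraction,
        }
        row.update(self.sequential)
        for (feat, event, band), v in self.variability.items():
            row[f"{feat}__{event}__{band}"] = v
        return row


# ---------------------------------------------------------------------------
# epoch segmentation


def segment_epochs(
    record: EFMRecord,
    noi: list | None = None,
    cfg: FeatureConfig | None = None,
) -> list[dict]:
    """Tile 20-minute epochs backwards from birth and apply the 80 % rule.

    Returns one dict per *retained* epoch with keys ``epoch_index``,
    ``start_s``, ``end_s``, ``times``, ``values`` (interpretable FHR
    samples) and ``interpretable_fraction``.
    """
    cfg = cfg or FeatureConfig()
    fhr = record.signals.get("FHR")
    if fhr is None or fhr.is_empty:
        return []
    delta = fhr.delta
    times = fhr.sample_times()
    vals = fhr.data
    keep = np.ones(times.size, dtype=bool)
    for iv in noi or []:
        lo, hi = iv[0], iv[1]
        keep &= ~((times >= lo - _EPS) & (times < hi - _EPS))
    times, vals = times[keep], vals[keep]
    if times.size == 0:
        return []
    first = times[0]
    n_epochs = int(np.ceil(-first / cfg.epoch_s))
    min_n = cfg.min_samples(delta)
    epoch_n = int(round(cfg.epoch_s / delta))
    out = []
    for k in range(n_epochs):
        lo = -(k + 1) * cfg.epoch_s
        hi = -k * cfg.epoch_s
        m = (times >= lo - _EPS) & (times < hi - _EPS)
        n = int(m.sum())
        if n < min_n:
            continue
        out.append(
            {
                "epoch_index": k,
                "start_s": lo,
                "end_s": hi,
                "times": times[m],
                "values": vals[m],
                "interpretable_fraction": n / epoch_n,
            }
        )
    return out


# ---------------------------------------------------------------------------
# sequential (marked-point-process) block


def _clip(ev: Event, lo: float, hi: float) -> float:
    return max(0.0, min(ev.end_s, hi) - max(ev.start_s, lo))


def sequential_features(
    events: list[Event],
    epoch_start: float,
    epoch_end: float,
    cfg: FeatureConfig | None = None,
) -> dict:
    """Dwell, cumulative dwell, transitions, contraction rate, DEC subtypes."""
    cfg = cfg or FeatureConfig()
    out: dict = {}
    for typ in ("BAS", "ACC", "DEC", "CON", "RIN", "NOI"):
        out[f"dwell_{typ}"] = sum(
            _clip(e, epoch_start, epoch_end) for e in events if e.type == typ
        )
        out[f"cumdwell_{typ}"] = sum(
            _clip(e, -np.inf, epoch_start) for e in events if e.type == typ
        )

    # transitions among FHR events, in time order; RIN/gaps shorter than
    # transition_rin_break_s do not break adjacency
    fhr_ev = sorted(
        (e for e in events
         if e.type in ("BAS", "ACC", "DEC")
         and e.start_s < epoch_end and e.end_s > epoch_start),
        key=lambda e: e.start_s,
    )
    for a in ("BAS", "ACC", "DEC"):
        for b in ("BAS", "ACC", "DEC"):
            out[f"trans_{a}_{b}"] = 0
    for e1, e2 in zip(fhr_ev, fhr_ev[1:]):
        if e2.start_s - e1.end_s < cfg.transition_rin_break_s:
            out[f"trans_{e1.type}_{e2.type}"] += 1

    cons = [
        e for e in events
        if e.type == "CON"
        and epoch_start <= e.attrs.get("peak_s", (e.start_s + e.end_s) / 2) < epoch_end
    ]
    out["n_contractions"] = len(cons)
    out["contraction_rate_per_10min"] = len(cons) / (
        (epoch_end - epoch_start) / 600.0
    )

    decs = [
        e for e in events
        if e.type == "DEC" and epoch_start <= e.start_s < epoch_end
    ]
    n_late = sum(1 for e in decs if e.subtype == "late")
    n_abrupt = sum(1 for e in decs if e.subtype == "variable")
    n_other = sum(1 for e in decs if e.subtype in ("early", "prolonged"))
    out["n_dec"] = len(decs)
    out["freq_dec_late"] = n_late
    out["freq_dec_abrupt"] = n_abrupt
    out["freq_dec_others"] = n_other
    return out


# ---------------------------------------------------------------------------
# spectral decomposition


def decompose_spectral(
    values: np.ndarray,
    delta: float,
    split_hz: float = 0.030,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a series into low (<= split_hz) and high frequency components.

    Forward FFT, zero the bins outside the band, inverse FFT; the two
    components sum to the original signal exactly (linearity).  The DC
    bin belongs to the low component.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("too few samples for spectral decomposition")
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=delta)
    low_spec = np.where(freqs <= split_hz + _EPS, spec, 0.0)
    low = np.fft.irfft(low_spec, n=n)
    high = x - low
    return low, high


# ---------------------------------------------------------------------------
# PRSA


def prsa(
    x: np.ndarray,
    anchor: str,
    delta: float = 0.25,
    T: float = 2.5,
    L: float = 25.0,
) -> float:
    """Phase-rectified signal averaging capacity.

    Anchors are samples where the mean of the T-window after exceeds
    (``anchor="increment"``, acceleration capacity) or falls below
    (``anchor="decrement"``, deceleration capacity) the mean of the
    T-window before.  Windows of ±L around each anchor are aligned and
    averaged; the capacity is the quarter-sum of the two central
    post-anchor T-means minus the two central pre-anchor T-means.
    Returns NaN when there are no anchors.
    """
    x = np.asarray(x, dtype=float)
    nT = int(round(T / delta))
    nL = int(round(L / delta))
    n = x.size
    if n < 2 * nL + 1 or nT < 1:
        return np.nan
    c = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(nL, n - nL)  # candidate anchors with full +/-L context
    before = (c[i] - c[i - nT]) / nT
    after = (c[i + nT] - c[i]) / nT
    if anchor == "increment":
        sel = after > before
    elif anchor == "decrement":
        sel = after < before
    else:
        raise ValueError("anchor must be 'increment' or 'decrement'")
    anchors = i[sel]
    if anchors.size == 0:
        return np.nan
    offsets = np.arange(-2 * nT, 2 * nT)
    aligned = x[anchors[:, None] + offsets[None, :]]
    X = aligned.mean(axis=0)  # averaged window, index 2*nT == anchor
    a2 = X[0:nT].mean()  # [-2T, -T)
    a1 = X[nT : 2 * nT].mean()  # [-T, 0)
    p1 = X[2 * nT : 3 * nT].mean()  # [0, T)
    p2 = X[3 * nT : 4 * nT].mean()  # [T, 2T)
    return float((p1 + p2 - a1 - a2) / 4.0)


def prsa_features(x: np.ndarray, delta: float, cfg: FeatureConfig) -> dict:
    ac = prsa(x, "increment", delta, cfg.prsa_T, cfg.prsa_L)
    dc = prsa(x, "decrement", delta, cfg.prsa_T, cfg.prsa_L)
    dr = dc - ac if np.isfinite(ac) and np.isfinite(dc) else np.nan
    return {"prsa_ac": ac, "prsa_dc": dc, "prsa_dr": dr}


# ---------------------------------------------------------------------------
# Lomb-Scargle band powers


def lomb_bands(
    times: np.ndarray,
    values: np.ndarray,
    cfg: FeatureConfig | None = None,
) -> dict:
    """Normalized LF/MF/HF band powers on possibly gappy samples.

    The Lomb-Scargle periodogram is evaluated on the actual sample times
    (no interpolation across gaps); band powers are integrated and
    normalized by the signal variance.  Returns NaNs for zero-variance
    input or under 60 s of samples.
    """
    cfg = cfg or FeatureConfig()
    out = {
        "lf_power": np.nan,
        "mf_power": np.nan,
        "hf_power": np.nan,
        "lf_ratio": np.nan,
    }
    t = np.asarray(times, dtype=float)
    x = np.asarray(values, dtype=float)
    if t.size < 16 or (t[-1] - t[0]) < 60.0:
        return out
    var = np.var(x)
    if var < _EPS:
        return out
    xc = x - x.mean()
    fmin = min(e[0] for e in cfg.band_edges.values())
    fmax = max(e[1] for e in cfg.band_edges.values())
    freqs = np.linspace(fmin * 0.5, fmax, 800)
    pgram = sps.lombscargle(t, xc, 2 * np.pi * freqs, normalize=False)
    # scipy returns A^2 * n/4 at each freq; scale to a density so the
    # integral over frequency approximates power
    duration = t[-1] - t[0]
    psd = pgram * 4.0 / t.size * duration
    powers = {}
    for name, (lo, hi) in cfg.band_edges.items():
        m = (freqs >= lo) & (freqs <= hi)
        powers[name] = np.trapezoid(psd[m], freqs[m]) / duration
    out["lf_power"] = powers["LF"] / var
    out["mf_power"] = powers["MF"] / var
    out["hf_power"] = powers["HF"] / var
    denom = powers["MF"] + powers["HF"]
    out["lf_ratio"] = powers["LF"] / denom if denom > _EPS else np.nan
    return out


# ---------------------------------------------------------------------------
# entropies


def _embed_dist(x: np.ndarray, m: int) -> np.ndarray:
    """Chebyshev distance matrix between all m-length template vectors."""
    xf = np.asarray(x, dtype=np.float32)
    n = xf.size - m + 1
    d = np.abs(xf[:n, None] - xf[None, :n])
    for k in range(1, m):
        np.maximum(d, np.abs(xf[k : k + n, None] - xf[None, k : k + n]), out=d)
    return d


def _embed_dist_pair(x: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """(m, m+1) Chebyshev distance matrices, sharing the m-level work."""
    dm = _embed_dist(x, m)
    xf = np.asarray(x, dtype=np.float32)
    n1 = xf.size - m
    dm1 = np.maximum(
        dm[:n1, :n1], np.abs(xf[m : m + n1, None] - xf[None, m : m + n1])
    )
    return dm, dm1


def apen(x: np.ndarray, m: int, r: float) -> float:
    """Approximate entropy (self-matches counted)."""
    x = np.asarray(x, dtype=float)

    def phi(mm: int) -> float:
        d = _embed_dist(x, mm)
        c = (d <= r).mean(axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sampen(x: np.ndarray, m: int, r: float) -> float:
    """Sample entropy (self-matches excluded)."""
    x = np.asarray(x, dtype=float)
    dm = _embed_dist(x, m)
    dm1 = _embed_dist(x, m + 1)
    n1 = dm1.shape[0]
    # compare over the common template count so B >= A
    b = int((dm[:n1, :n1] <= r).sum()) - n1
    a = int((dm1 <= r).sum()) - n1
    if b == 0 or a == 0:
        return np.nan
    return float(-np.log(a / b))


def entropies(x: np.ndarray, cfg: FeatureConfig | None = None) -> dict:
    """ApEn(2,r) and SampEn(2,r) for r in {0.1, 0.2, 0.3} of the SD.

    The two embedding distance matrices are built once and thresholded
    per r, which matches :func:`apen` / :func:`sampen` exactly.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    out: dict = {}
    sd = np.std(x)
    keys = [f"{rf:.1f}" for rf in cfg.entropy_r]
    if x.size < 100:
        for key in keys:
            out[f"apen_{key}"] = np.nan
            out[f"sampen_{key}"] = np.nan
        return out
    if sd < _EPS:
        # perfectly regular signal: zero entropy, flagged degenerate
        for key in keys:
            out[f"apen_{key}"] = 0.0
            out[f"sampen_{key}"] = 0.0
        return out
    m = cfg.entropy_m
    dm, dm1 = _embed_dist_pair(x, m)
    n1 = dm1.shape[0]
    for rf, key in zip(cfg.entropy_r, keys):
        r = rf * sd
        out[f"apen_{key}"] = float(
            np.mean(np.log((dm <= r).mean(axis=1)))
            - np.mean(np.log((dm1 <= r).mean(axis=1)))
        )
        b = int((dm[:n1, :n1] <= r).sum()) - n1
        a = int((dm1 <= r).sum()) - n1
        out[f"sampen_{key}"] = (
            float(-np.log(a / b)) if a > 0 and b > 0 else np.nan
        )
    del dm, dm1
    return out


# ---------------------------------------------------------------------------
# complexity: Hurst, Lyapunov, correlation dimension


def _expected_rs(n: int) -> float:
    """Anis-Lloyd expected rescaled range of white noise at window size n."""
    i = np.arange(1, n)
    s = float(np.sum(np.sqrt((n - i) / i)))
    if n <= 340:
        from scipy.special import gammaln

        front = np.exp(gammaln((n - 1) / 2.0) - gammaln(n / 2.0)) / np.sqrt(np.pi)
    else:
        front = 1.0 / np.sqrt(n * np.pi / 2.0)
    # Peters' finite-sample factor (n - 1/2)/n
    return (n - 0.5) / n * front * s


def hurst_rs(x: np.ndarray) -> float:
    """Hurst exponent by rescaled-range analysis over dyadic window sizes.

    Uses the Anis-Lloyd small-sample correction: the regression is run on
    the deviation of log(R/S) from its white-noise expectation, and 0.5 is
    added back, which removes the well-known upward bias of the raw R/S
    slope at feasible record lengths.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 256 or np.std(x) < _EPS:
        return np.nan
    sizes = []
    s = 16
    while s <= n // 2:
        sizes.append(s)
        s *= 2
    log_s, log_dev = [], []
    for s in sizes:
        k = n // s
        blocks = x[: k * s].reshape(k, s)
        dev = blocks - blocks.mean(axis=1, keepdims=True)
        z = np.cumsum(dev, axis=1)
        rng = z.max(axis=1) - z.min(axis=1)
        std = blocks.std(axis=1)
        ok = std > _EPS
        if not ok.any():
            continue
        rs = np.mean(rng[ok] / std[ok])
        if rs > 0:
            log_s.append(np.log(s))
            log_dev.append(np.log(rs) - np.log(_expected_rs(s)))
    if len(log_s) < 3:
        return np.nan
    slope, _ = np.polyfit(log_s, log_dev, 1)
    return float(0.5 + slope)


def _embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    n = x.size - (dim - 1) * delay
    return np.column_stack([x[k * delay : k * delay + n] for k in range(dim)])


def lyapunov_rosenstein(
    x: np.ndarray,
    delta: float = 0.25,
    dim: int = 2,
    delay: int = 1,
    min_sep: int = 10,
    k_max: int = 40,
    max_points: int = 1200,
) -> float:
    """Largest Lyapunov exponent (per second), Rosenstein's method."""
    x = np.asarray(x, dtype=float)
    if x.size < 256 or np.std(x) < _EPS:
        return np.nan
    if x.size > max_points:  # decimate deterministically to bound cost
        step = int(np.ceil(x.size / max_points))
        x = x[::step]
        delta = delta * step
    Y = _embed(x, dim, delay)
    n = Y.shape[0]
    d = np.sqrt(((Y[:, None, :] - Y[None, :, :]) ** 2).sum(-1))
    ii = np.arange(n)
    d[np.abs(ii[:, None] - ii[None, :]) < min_sep] = np.inf
    nn = np.argmin(d, axis=1)
    valid0 = np.isfinite(d[ii, nn])
    ks = np.arange(1, min(k_max, n // 4))
    mean_log = np.full(ks.size, np.nan)
    for j, k in enumerate(ks):
        ok = valid0 & (ii + k < n) & (nn + k < n)
        if ok.sum() < 10:
            break
        sep = np.linalg.norm(Y[ii[ok] + k] - Y[nn[ok] + k], axis=1)
        sep = sep[sep > _EPS]
        if sep.size < 10:
            break
        mean_log[j] = np.mean(np.log(sep))
    good = np.isfinite(mean_log)
    if good.sum() < 5:
        return np.nan
    slope, _ = np.polyfit(ks[good] * delta, mean_log[good], 1)
    return float(slope)


def correlation_dimension(
    x: np.ndarray,
    dim: int = 2,
    delay: int = 1,
    max_points: int = 1200,
) -> float:
    """Correlation dimension (Grassberger-Procaccia) with embedding (2, 1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 256 or np.std(x) < _EPS:
        return np.nan
    if x.size > max_points:
        step = int(np.ceil(x.size / max_points))
        x = x[::step]
    Y = _embed(x, dim, delay)
    n = Y.shape[0]
    d = np.sqrt(((Y[:, None, :] - Y[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(n, k=1)
    dists = d[iu]
    dists = dists[dists > _EPS]
    if dists.size < 100:
        return np.nan
    r_lo, r_hi = np.percentile(dists, [5, 50])
    if r_hi <= r_lo:
        return np.nan
    rs = np.geomspace(r_lo, r_hi, 12)
    C = np.array([(dists < r).mean() for r in rs])
    ok = C > 0
    if ok.sum() < 4:
        return np.nan
    slope, _ = np.polyfit(np.log(rs[ok]), np.log(C[ok]), 1)
    return float(slope)


def complexity(x: np.ndarray, delta: float = 0.25, cfg: FeatureConfig | None = None) -> dict:
    cfg = cfg or FeatureConfig()
    return {
        "hurst": hurst_rs(x),
        "lyapunov": lyapunov_rosenstein(
            x, delta, cfg.embed_dim, cfg.embed_delay
        ),
        "corr_dim": correlation_dimension(x, cfg.embed_dim, cfg.embed_delay),
    }


# ---------------------------------------------------------------------------
# classical variability indices


def classical_variability(
    x: np.ndarray, delta: float = 0.25, cfg: FeatureConfig | None = None
) -> dict:
    """STV, LTI, Delta and the interval index.

    STV is the mean absolute difference of samples 2.5 s apart; Delta the
    mean one-minute peak-to-peak range; the interval index is STV divided
    by the SD of the 2.5 s-grid samples; LTI is the interquartile range
    of the modulus sqrt(s_j^2 + s_{j+1}^2) of consecutive grid samples.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    out = {"stv": np.nan, "lti": np.nan, "delta": np.nan, "interval_index": np.nan}
    step = max(1, int(round(cfg.stv_step / delta)))
    wn = int(round(cfg.delta_window / delta))
    if x.size < wn:
        return out
    grid = x[::step]
    if grid.size >= 2:
        diffs = np.abs(np.diff(grid))
        out["stv"] = float(np.mean(diffs))
        mod = np.sqrt(grid[:-1] ** 2 + grid[1:] ** 2)
        q75, q25 = np.percentile(mod, [75, 25])
        out["lti"] = float(q75 - q25)
        sd = float(np.std(grid))
        out["interval_index"] = out["stv"] / sd if sd > _EPS else np.nan
    k = x.size // wn
    if k >= 1:
        blocks = x[: k * wn].reshape(k, wn)
        out["delta"] = float(np.mean(blocks.max(axis=1) - blocks.min(axis=1)))
    return out


# ---------------------------------------------------------------------------
# per-epoch assembly


def _label_samples(
    times: np.ndarray, events: list[Event]
) -> np.ndarray:
    """Per-sample event-type label ('BAS'/'ACC'/'DEC' or '')."""
    labels = np.full(times.size, "", dtype=object)
    for ev in events:
        if ev.type in ("BAS", "ACC", "DEC"):
            m = (times >= ev.start_s - _EPS) & (times < ev.end_s - _EPS)
            labels[m] = ev.type
    return labels


def assemble_feature_matrix(
    epoch: dict,
    events: list[Event],
    delta: float,
    cfg: FeatureConfig | None = None,
    mask: dict | None = None,
    guid: str = "",
) -> EpochFeatures:
    """Compute the full feature vector for one retained epoch.

    Only the (feature, event, band) cells present in ``mask`` (default:
    the standard battery layout) are populated; cells whose event has no
    samples in the epoch are flagged invalid (NaN).
    """
    cfg = cfg or FeatureConfig()
    mask = mask if mask is not None else DEFAULT_MASK
    t, x = epoch["times"], epoch["values"]
    low, high = decompose_spectral(x, delta, cfg.split_hz)
    labels = _label_samples(t, events)
    comps = {"low": low, "high": high}

    ef = EpochFeatures(
        guid=guid,
        epoch_index=epoch["epoch_index"],
        start_s=epoch["start_s"],
        end_s=epoch["end_s"],
        interpretable_fraction=epoch["interpretable_fraction"],
        sequential=sequential_features(events, epoch["start_s"], epoch["end_s"], cfg),
    )

    # baseline level of the epoch, for height/area referencing
    bas_low = low[labels == "BAS"]
    bas_level = float(np.mean(bas_low)) if bas_low.size else float(np.mean(low))

    cell_cache: dict = {}
    for event in ("BAS", "ACC", "DEC"):
        sel = labels == event
        for band in ("low", "high"):
            key = (event, band)
            if not sel.any():
                cell_cache[key] = None
                continue
            cell_cache[key] = {
                "t": t[sel],
                "x": comps[band][sel],
            }

    def compute(feat: str, event: str, band: str) -> float:
        cell = cell_cache[(event, band)]
        if cell is None:
            return np.nan
        cx, ct = cell["x"], cell["t"]
        if feat == "mean":
            return float(np.mean(cx))
        if feat == "sd":
            return float(np.std(cx))
        if feat == "slope":
            if cx.size < 2:
                return np.nan
            return float(np.polyfit(ct - ct[0], cx, 1)[0] * 60.0)  # per minute
        if feat == "height":
            devc = cx - bas_level
            return float(np.max(devc)) if event == "ACC" else float(np.min(devc))
        if feat == "area":
            return float(np.sum(np.abs(cx - bas_level)) * delta / 60.0)
        if feat.startswith("prsa_"):
            vals = prsa_features(cx, delta, cfg)
            return vals[feat]
        if feat in ("lf_power", "mf_power", "hf_power", "lf_ratio"):
            return lomb_bands(ct, cx, cfg)[feat]
        if feat.startswith(("apen_", "sampen_")):
            return entropies(cx, cfg)[feat]
        if feat in ("hurst", "lyapunov", "corr_dim"):
            return complexity(cx, delta, cfg)[feat]
        if feat in ("stv", "lti", "delta", "interval_index"):
            return classical_variability(cx, delta, cfg)[feat]
        raise KeyError(f"unknown feature {feat!r}")

    # expensive feature families are computed once per cell and cached
    family_cache: dict = {}

    def compute_cached(feat: str, event: str, band: str) -> float:
        cell = cell_cache[(event, band)]
        if cell is None:
            return np.nan
        fam = None
        if feat.startswith("prsa_"):
            fam = "prsa"
        elif feat in ("lf_power", "mf_power", "hf_power", "lf_ratio"):
            fam = "lomb"
        elif feat.startswith(("apen_", "sampen_")):
            fam = "entropy"
        elif feat in ("hurst", "lyapunov", "corr_dim"):
            fam = "complexity"
        elif feat in ("stv", "lti", "delta", "interval_index"):
            fam = "classical"
        if fam is None:
            return compute(feat, event, band)
        fk = (fam, event, band)
        if fk not in family_cache:
            cx, ct = cell["x"], cell["t"]
            if fam == "prsa":
                family_cache[fk] = prsa_features(cx, delta, cfg)
            elif fam == "lomb":
                family_cache[fk] = lomb_bands(ct, cx, cfg)
            elif fam == "entropy":
                family_cache[fk] = entropies(cx, cfg)
            elif fam == "complexity":
                family_cache[fk] = complexity(cx, delta, cfg)
            elif fam == "classical":
                family_cache[fk] = classical_variability(cx, delta, cfg)
        return family_cache[fk][feat]

    for feat, cells in mask.items():
        for event, band in cells:
            v = compute_cached(feat, event, band)
            ef.variability[(feat, event, band)] = v
            ef.validity[(feat, event, band)] = bool(np.isfinite(v))
    return ef


def extract_features(
    record: EFMRecord,
    events: list[Event],
    noi: list | None = None,
    cfg: FeatureConfig | None = None,
    mask: dict | None = None,
) -> list[EpochFeatures]:
    """Full per-epoch feature extraction on a repaired record."""
    cfg = cfg or FeatureConfig()
    fhr = record.signals.get("FHR")
    delta = fhr.delta if fhr is not None else 0.25
    epochs = segment_epochs(record, noi, cfg)
    return [
        assemble_feature_matrix(ep, events, delta, cfg, mask, guid=record.guid)
        for ep in epochs
    ]
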