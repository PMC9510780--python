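"""Per-window spectral and time-domain ECoG features.

All spectral features derive from Welch periodograms computed independently
per 10 s window (2 s Hann segments, 50 % overlap by default, i.e. 0.5 Hz
resolution and nine segments per window — enough averaging to keep the
magnitude-squared-coherence bias near 1/9 for independent channels):

* spectral edge frequency (SEF95),
* aperiodic (1/f) log-log slope fit over 20-40 Hz,
* canonical band powers (delta/theta/alpha/beta/gamma),
* interhemispheric magnitude-squared coherence averaged over 5-40 Hz.

Time-domain features are sample entropy over 80 ms templates, Lempel-Ziv
(LZ76) complexity of the block-median-thresholded binary sequence, and
block-level burst-suppression metrics from a moving-RMS envelope detector.
Undefined features (e.g. sample entropy with no template matches) are
recorded as NaN, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial import cKDTree

from .preprocess import Block, Window

__all__ = [
    "PSD",
    "BurstIntervals",
    "FeatureConfig",
    "welch_psd",
    "spectral_edge_frequency",
    "aperiodic_slope",
    "band_powers",
    "interhemispheric_coherence",
    "sample_entropy",
    "lz76_word_count",
    "lempel_ziv_complexity",
    "detect_bursts",
    "burst_suppression_metrics",
    "extract_feature_table",
    "DEFAULT_BANDS",
    "FEATURE_BASE_NAMES",
]

#: Canonical EEG band edges in Hz. Gamma is capped at 45 Hz: the band is
#: open-ended above 30 Hz, but the 50 Hz notch and 125 Hz Nyquist make 45 Hz
#: the highest clean edge.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.1, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: Per-channel feature names produced by :func:`extract_feature_table`
#: (each suffixed ``_contra``/``_ipsi``); ``coherence_5_40`` is cross-channel.
FEATURE_BASE_NAMES = (
    "sef95",
    "slope_20_40",
    "bp_delta",
    "bp_theta",
    "bp_alpha",
    "bp_beta",
    "bp_gamma",
    "sampen",
    "lzc",
    "bsr",
    "mean_on_s",
    "mean_off_s",
)


@dataclass(frozen=True)
class PSD:
    """One-sided Welch power spectral density (uV^2/Hz) on a frequency grid."""

    frequencies: np.ndarray
    power: np.ndarray

    def total_power(self) -> float:
        return float(np.trapezoid(self.power, self.frequencies))


@dataclass(frozen=True)
class BurstIntervals:
    """Alternating on/off intervals covering a block: (start_s, end_s, state)."""

    intervals: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        prev_end = None
        prev_state = None
        for start, end, state in self.intervals:
            if state not in ("on", "off") or end <= start:
                raise ValueError("intervals must be positive-length on/off runs")
            if prev_end is not None and (
                abs(start - prev_end) > 1e-9 or state == prev_state
            ):
                raise ValueError("intervals must be contiguous and alternating")
            prev_end, prev_state = end, state


@dataclass(frozen=True)
class FeatureConfig:
    """Every tunable of the feature extractors, with field defaults above."""

    welch_segment_s: float = 2.0
    welch_overlap: float = 0.5
    sef_fraction: float = 0.95
    slope_band_hz: tuple[float, float] = (20.0, 40.0)
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    coherence_band_hz: tuple[float, float] = (5.0, 40.0)
    sampen_template_ms: float = 80.0
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    burst_envelope_ms: float = 50.0
    burst_thresh_factor: float = 0.2
    burst_min_off_ms: float = 100.0
    window_s: float = 10.0


def _welch_params(n: int, fs: float, segment_s: float, overlap: float) -> dict:
    nperseg = int(round(segment_s * fs))
    if nperseg > n:
        raise ValueError("Welch segment longer than the window")
    return dict(
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend=False,
    )


def welch_psd(
    x: np.ndarray,
    sample_rate: float,
    segment_s: float = 2.0,
    overlap: float = 0.5,
) -> PSD:
    """Welch PSD with Hann taper; density scaling (integral ~ variance)."""
    x = np.asarray(x, dtype=float)
    f, p = signal.welch(
        x, scaling="density", **_welch_params(x.size, sample_rate, segment_s, overlap)
    )
    return PSD(frequencies=f, power=p)


def spectral_edge_frequency(psd: PSD, fraction: float = 0.95) -> float:
    """Smallest grid frequency below which ``fraction`` of total power lies."""
    cum = np.cumsum(psd.power)
    if cum[-1] <= 0:
        return float("nan")
    idx = np.searchsorted(cum / cum[-1], fraction)
    idx = min(idx, psd.frequencies.size - 1)
    return float(psd.frequencies[idx])


def aperiodic_slope(psd: PSD, f_lo: float = 20.0, f_hi: float = 40.0) -> float:
    """Least-squares slope of log10(power) vs log10(frequency) in [f_lo, f_hi]."""
    mask = (psd.frequencies >= f_lo) & (psd.frequencies <= f_hi)
    if mask.sum() < 3:
        raise ValueError("need at least 3 grid points in the fit band")
    p = psd.power[mask]
    if np.any(p <= 0):
        return float("nan")
    return float(np.polyfit(np.log10(psd.frequencies[mask]), np.log10(p), 1)[0])


def band_powers(
    psd: PSD, bands: dict[str, tuple[float, float]] | None = None
) -> dict[str, float]:
    """Trapezoidal band-integrated power (uV^2) per named band."""
    bands = dict(DEFAULT_BANDS) if bands is None else bands
    out = {}
    for name, (lo, hi) in bands.items():
        mask = (psd.frequencies >= lo) & (psd.frequencies <= hi)
        out[name] = (
            float(np.trapezoid(psd.power[mask], psd.frequencies[mask]))
            if mask.sum() >= 2
            else 0.0
        )
    return out


def interhemispheric_coherence(
    x: np.ndarray,
    y: np.ndarray,
    sample_rate: float,
    f_lo: float = 5.0,
    f_hi: float = 40.0,
    segment_s: float = 2.0,
    overlap: float = 0.5,
) -> float:
    """Mean magnitude-squared coherence over [f_lo, f_hi].

    Requires at least two Welch segments; a single-segment estimate is
    identically 1 and therefore rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("channels must have equal length")
    params = _welch_params(x.size, sample_rate, segment_s, overlap)
    n_seg = 1 + (x.size - params["nperseg"]) // (params["nperseg"] - params["noverlap"])
    if n_seg < 2:
        raise ValueError("coherence needs >= 2 Welch segments (estimate degenerate)")
    f, coh = signal.coherence(x, y, **params)
    mask = (f >= f_lo) & (f <= f_hi)
    return float(np.mean(coh[mask]))


def sample_entropy(
    x: np.ndarray,
    sample_rate: float,
    template_ms: float = 80.0,
    m: int = 2,
    r_factor: float = 0.2,
    r: float | None = None,
) -> float:
    """Sample entropy with templates spanning ``template_ms``.

    The template span fixes the embedding lag: with m = 2 at 250 Hz the 80 ms
    span gives lag = 10 samples, so an order-m template is
    ``(x[i], x[i+lag], ..., x[i+(m-1)*lag])``. Matching uses Chebyshev
    distance <= r (default ``r_factor`` times the window SD), self-matches
    excluded. Returns ``-ln(A/B)`` where B counts order-m and A order-(m+1)
    template matches; NaN when undefined (no matches, or r = 0).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    lag = max(1, int(round(template_ms / 1000.0 * sample_rate / m)))
    n_templates = n - m * lag
    if n_templates < 2:
        raise ValueError("window too short for the requested template span")
    if r is None:
        r = r_factor * float(x.std())
    if r <= 0:
        return float("nan")

    def _pairs(order: int) -> int:
        emb = np.column_stack([x[k * lag : k * lag + n_templates] for k in range(order)])
        tree = cKDTree(emb)
        total = tree.count_neighbors(tree, r, p=np.inf)
        return int(total - n_templates) // 2

    b = _pairs(m)
    a = _pairs(m + 1)
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))


def lz76_word_count(bits: np.ndarray) -> int:
    """Number of words in the LZ76 exhaustive-history parsing of ``bits``.

    Each new word is the shortest prefix of the remaining sequence that cannot
    be reproduced from the extended history; a final incomplete (reproducible)
    word counts as one.
    """
    s = np.asarray(bits).astype(np.uint8).tobytes()
    n = len(s)
    if n <= 1:
        return n
    c = 0
    p = 0
    while p < n:
        length = 1
        # extend while the candidate word is reproducible from the extended
        # history s[0 : p+length-1] (C-level substring search)
        while p + length <= n and s.find(s[p : p + length], 0, p + length - 1) != -1:
            length += 1
        if p + length > n:
            length = n - p
        c += 1
        p += length
    return c


def lempel_ziv_complexity(x: np.ndarray, threshold: float) -> float:
    """Normalized LZ76 complexity of the thresholded signal.

    The signal is binarized against ``threshold`` (the parent *block* median,
    not the window median) and the word count C normalized as C*log2(n)/n so
    values are window-length invariant (a fair-coin sequence tends to 1).
    """
    x = np.asarray(x, dtype=float)
    bits = (x > threshold).astype(np.uint8)
    n = bits.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    return lz76_word_count(bits) * np.log2(n) / n


def detect_bursts(
    x: np.ndarray,
    sample_rate: float,
    envelope_ms: float = 50.0,
    thresh_factor: float = 0.2,
    min_off_ms: float = 100.0,
) -> BurstIntervals:
    """Burst/suppression segmentation by moving-RMS envelope thresholding.

    Samples whose RMS envelope falls to ``thresh_factor`` times the block's
    90th-percentile envelope (or below) are suppression ("off"); off runs
    shorter than ``min_off_ms`` are merged back into the surrounding bursts.
    """
    x = np.asarray(x, dtype=float)
    if x.size < sample_rate:
        raise ValueError("block must be at least 1 s long")
    n_env = max(1, int(round(envelope_ms / 1000.0 * sample_rate)))
    env = np.sqrt(
        np.convolve(x**2, np.ones(n_env) / n_env, mode="same")
    )
    thresh = thresh_factor * np.percentile(env, 90)
    off = env <= thresh

    # merge short off runs into on
    min_off = int(round(min_off_ms / 1000.0 * sample_rate))
    edges = np.flatnonzero(np.diff(off.astype(np.int8))) + 1
    bounds = np.concatenate([[0], edges, [off.size]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        if off[a] and (b - a) < min_off:
            off[a:b] = False

    edges = np.flatnonzero(np.diff(off.astype(np.int8))) + 1
    bounds = np.concatenate([[0], edges, [off.size]])
    intervals = tuple(
        (a / sample_rate, b / sample_rate, "off" if off[a] else "on")
        for a, b in zip(bounds[:-1], bounds[1:])
    )
    return BurstIntervals(intervals)


def burst_suppression_metrics(intervals: BurstIntervals) -> dict[str, float]:
    """BSR (fraction of time suppressed) and mean on/off interval durations."""
    on = [e - s for s, e, st in intervals.intervals if st == "on"]
    off = [e - s for s, e, st in intervals.intervals if st == "off"]
    total = intervals.intervals[-1][1] - intervals.intervals[0][0]
    return {
        "bsr": float(sum(off) / total) if total > 0 else 0.0,
        "mean_on_s": float(np.mean(on)) if on else 0.0,
        "mean_off_s": float(np.mean(off)) if off else 0.0,
    }


def _window_features(
    win: Window, block_medians: dict[str, float], cfg: FeatureConfig
) -> dict[str, float]:
    row: dict[str, float] = {}
    for side, x in win.channels().items():
        psd = welch_psd(x, win.sample_rate, cfg.welch_segment_s, cfg.welch_overlap)
        row[f"sef95_{side}"] = spectral_edge_frequency(psd, cfg.sef_fraction)
        try:
            row[f"slope_20_40_{side}"] = aperiodic_slope(psd, *cfg.slope_band_hz)
        except ValueError:
            row[f"slope_20_40_{side}"] = float("nan")
        for band, p in band_powers(psd, cfg.bands).items():
            row[f"bp_{band}_{side}"] = p
        row[f"sampen_{side}"] = sample_entropy(
            x, win.sample_rate, cfg.sampen_template_ms, cfg.sampen_m, cfg.sampen_r_factor
        )
        row[f"lzc_{side}"] = lempel_ziv_complexity(x, block_medians[side])
    row["coherence_5_40"] = interhemispheric_coherence(
        win.channel_contra,
        win.channel_ipsi,
        win.sample_rate,
        *cfg.coherence_band_hz,
        segment_s=cfg.welch_segment_s,
        overlap=cfg.welch_overlap,
    )
    return row


def extract_feature_table(
    blocks: list[Block], cfg: FeatureConfig | None = None
) -> pd.DataFrame:
    """One feature row per window with block/segment/animal labels.

    Block-level quantities (binarization threshold for LZC; burst-suppression
    metrics) are computed once per block and replicated onto its windows.
    """
    from .preprocess import window_block

    cfg = cfg or FeatureConfig()
    rows = []
    for block in blocks:
        medians = {side: float(np.median(x)) for side, x in block.channels().items()}
        block_bs = {}
        for side, x in block.channels().items():
            metrics = burst_suppression_metrics(
                detect_bursts(
                    x,
                    block.sample_rate,
                    cfg.burst_envelope_ms,
                    cfg.burst_thresh_factor,
                    cfg.burst_min_off_ms,
                )
            )
            for key, val in metrics.items():
                block_bs[f"{key}_{side}"] = val
        for win in window_block(block, cfg.window_s):
            row = {
                "animal_id": win.animal_id,
                "segment_index": win.segment_index,
                "concentration": win.concentration,
                "window_index": win.window_index,
                "t_start_s": win.t_start_s,
            }
            row.update(_window_features(win, medians, cfg))
            row.update(block_bs)
            rows.append(row)
    return pd.DataFrame(rows)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns (everything except labels/targets)."""
    labels = {"animal_id", "segment_index", "concentration", "window_index", "t_start_s", "era"}
    return [c for c in table.columns if c not in labels]
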