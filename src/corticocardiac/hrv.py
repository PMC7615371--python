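"""Heart-rate-variability metrics in 5-minute segments.

Time domain: RMSSD of successive RR differences.  Frequency domain: the RR
tachogram is cubic-interpolated to a uniform 4 Hz grid, mean-detrended and
Welch-transformed; band powers are integrated over the low-frequency
(0.04-0.15 Hz, largely sympathetic) and high-frequency (0.15-0.4 Hz,
parasympathetic / respiratory sinus arrhythmia) bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal as sps

from .ecg import BeatSeries, RR_MIN_S, RR_MAX_S

logger = logging.getLogger("corticocardiac")

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
RESAMPLE_HZ = 4.0
WELCH_SEG_S = 128.0
SEGMENT_S = 300.0


@dataclass
class HrvSegmentResult:
    segment_start: float
    rmssd: float            # ms
    lf_power: float         # ms^2
    hf_power: float         # ms^2
    lf_hf_ratio: float      # dimensionless, NaN when HF power is zero
    hf_peak_freq: float     # Hz


def _clean_rr(times: np.ndarray, rr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop ectopic/artifact intervals: RR outside physiology or >50% away
    from the previous accepted RR."""
    ok = (rr > RR_MIN_S) & (rr < RR_MAX_S)
    keep = np.zeros(rr.size, dtype=bool)
    prev = None
    for i in range(rr.size):
        if not ok[i]:
            continue
        if prev is not None and abs(rr[i] - prev) > 0.5 * prev:
            continue
        keep[i] = True
        prev = rr[i]
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("RR cleaning dropped %d of %d intervals", n_drop, rr.size)
    return times[keep], rr[keep]


def _window_rr(beats: BeatSeries, window: tuple[float, float]
               ) -> tuple[np.ndarray, np.ndarray]:
    t = beats.r_times
    mask = (t >= window[0]) & (t < window[1])
    tw = t[mask]
    if tw.size < 2:
        return np.empty(0), np.empty(0)
    rr = np.diff(tw)
    return _clean_rr(tw[1:], rr)


def rmssd(beats: BeatSeries, window: tuple[float, float]) -> float:
    """Root-mean-square successive RR difference (ms) within the window.

    Returns NaN when fewer than 3 beats fall inside the window.
    """
    _, rr = _window_rr(beats, window)
    if rr.size < 2:
        logger.info("rmssd: insufficient beats in window %s", window)
        return float("nan")
    return float(np.sqrt(np.mean(np.diff(rr * 1000.0) ** 2)))


def spectral_hrv(beats: BeatSeries, window: tuple[float, float]
                 ) -> tuple[float, float, float, float]:
    """Frequency-domain HRV within a window.

    Returns ``(lf_power, hf_power, lf_hf_ratio, hf_peak_freq)``; powers in
    ms², the ratio NaN when HF power is zero.  Requires a window of at
    least 120 s containing at least half the expected beat count.
    """
    t0, t1 = window
    if t1 - t0 < 120.0:
        raise ValueError("spectral HRV needs a window of at least 120 s")
    times, rr = _window_rr(beats, window)
    if rr.size >= 2:
        expected = (t1 - t0) / float(np.mean(rr))
    else:
        expected = np.inf
    if rr.size < 0.5 * expected or rr.size < 8:
        logger.info("spectral_hrv: too few beats in window %s", window)
        return float("nan"), float("nan"), float("nan"), float("nan")

    grid = np.arange(times[0], times[-1], 1.0 / RESAMPLE_HZ)
    tachogram = interpolate.interp1d(times, rr * 1000.0, kind="cubic")(grid)
    tachogram = tachogram - tachogram.mean()
    nperseg = min(int(WELCH_SEG_S * RESAMPLE_HZ), tachogram.size)
    freqs, psd = sps.welch(tachogram, fs=RESAMPLE_HZ, window="hann",
                           nperseg=nperseg, noverlap=nperseg // 2)

    def band_power(band: tuple[float, float]) -> float:
        lo, hi = band
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    lf = band_power(LF_BAND)
    hf = band_power(HF_BAND)
    ratio = lf / hf if hf > 0 else float("nan")
    hf_mask = (freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])
    hf_peak = float(freqs[hf_mask][np.argmax(psd[hf_mask])]) if hf_mask.any() else float("nan")
    return lf, hf, ratio, hf_peak


def hrv_segments(beats: BeatSeries, t_start: float, t_end: float,
                 segment_s: float = SEGMENT_S) -> list[HrvSegmentResult]:
    """Non-overlapping fixed-length segment metrics aligned to ``t_start``.

    Partial trailing segments are dropped.
    """
    results = []
    start = t_start
    while start + segment_s <= t_end + 1e-9:
        window = (start, start + segment_s)
        lf, hf, ratio, peak = spectral_hrv(beats, window)
        results.append(HrvSegmentResult(
            segment_start=start,
            rmssd=rmssd(beats, window),
            lf_power=lf, hf_power=hf, lf_hf_ratio=ratio, hf_peak_freq=peak,
        ))
        start += segment_s
    return results
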