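"""EEG preprocessing, individual slow-wave detection, and slow-wave activity.

A slow wave is one full cycle of the 0.5-4 Hz filtered EEG: from a downward
zero crossing (the onset), through a negative phase of 0.25-1.25 s whose
trough magnitude reaches the 99th percentile of the filtered signal's
absolute amplitude over the whole recording, through the following positive
phase to the next downward crossing.  Frequency is the inverse of that full
period.  Slow-wave activity (SWA) is Welch power integrated over 0.5-1.5 Hz
in 5-minute segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .ecg import SignalTrace

logger = logging.getLogger("corticocardiac")

SW_BAND = (0.5, 4.0)
SWA_BAND = (0.5, 1.5)
NEG_DURATION_BOUNDS = (0.25, 1.25)
AMP_PERCENTILE = 99.0
TARGET_FS = 100.0


@dataclass
class SlowWaveEvent:
    """One detected cortical slow wave."""

    onset: float         # s, initial downward zero crossing
    trough_time: float   # s
    trough_amp: float    # μV, negative
    neg_duration: float  # s
    end_time: float      # s, next downward zero crossing
    frequency: float     # Hz, 1 / (end_time - onset)

    def __post_init__(self) -> None:
        if not (self.onset < self.trough_time < self.end_time):
            raise ValueError("slow-wave landmarks out of order")
        if self.trough_amp >= 0:
            raise ValueError("trough amplitude must be negative")
        lo, hi = NEG_DURATION_BOUNDS
        if not lo <= self.neg_duration <= hi:
            raise ValueError("negative duration outside detection bounds")


@dataclass
class SwaSegmentResult:
    segment_start: float
    swa_power: float     # μV², 0.5-1.5 Hz band


def preprocess_eeg(eeg: SignalTrace) -> SignalTrace:
    """Zero-phase third-order 0.5-45 Hz Butterworth band-pass, then
    down-sampling to 100 Hz (anti-aliased) if needed."""
    if eeg.fs < 100:
        raise ValueError("EEG sampling rate must be >= 100 Hz")
    sos = sps.butter(3, [0.5, 45.0], btype="bandpass", fs=eeg.fs, output="sos")
    x = sps.sosfiltfilt(sos, eeg.samples)
    fs = eeg.fs
    if fs != TARGET_FS:
        up, down = (np.round([TARGET_FS, fs]) / np.gcd(int(round(TARGET_FS)),
                                                       int(round(fs)))).astype(int)
        x = sps.resample_poly(x, up, down)
        fs = TARGET_FS
    return SignalTrace(x, fs, label=eeg.label or "EEG", t0=eeg.t0)


def sw_filter(eeg: SignalTrace, band: tuple[float, float] = SW_BAND) -> np.ndarray:
    """Zero-phase third-order Butterworth band-pass used for detection."""
    sos = sps.butter(3, list(band), btype="bandpass", fs=eeg.fs, output="sos")
    return sps.sosfiltfilt(sos, eeg.samples)


def _down_crossings(x: np.ndarray) -> np.ndarray:
    """Indices i where the signal crosses from >0 at i to <=0 at i+1."""
    return np.flatnonzero((x[:-1] > 0) & (x[1:] <= 0))


def _cross_time(x: np.ndarray, i: int, fs: float, t0: float) -> float:
    """Linearly interpolated crossing time between samples i and i+1."""
    x0, x1 = x[i], x[i + 1]
    frac = x0 / (x0 - x1) if x0 != x1 else 0.5
    return t0 + (i + frac) / fs


def detect_slow_waves(
    eeg: SignalTrace,
    amp_percentile: float = AMP_PERCENTILE,
    amp_criterion: str = "trough",
) -> list[SlowWaveEvent]:
    """Detect individual slow waves by amplitude and duration thresholding.

    Candidates are spans between consecutive downward zero crossings of the
    0.5-4 Hz filtered signal containing exactly one negative phase followed
    by one positive phase.  A candidate is kept when its negative-phase
    duration lies in [0.25, 1.25] s and its amplitude reaches the
    ``amp_percentile``-th percentile of the absolute filtered signal over
    the whole recording.  ``amp_criterion`` selects whether the trough
    magnitude ("trough") or the trough-to-peak span ("p2p") is thresholded;
    for "p2p" the percentile threshold is doubled to stay comparable.

    The percentile threshold makes the count invariant to any global
    amplitude rescaling of the input.
    """
    if eeg.duration < 60:
        raise ValueError("slow-wave detection needs at least 60 s of EEG")
    x = sw_filter(eeg)
    fs = eeg.fs
    thr = np.percentile(np.abs(x), amp_percentile)
    if amp_criterion not in ("trough", "p2p"):
        raise ValueError("amp_criterion must be 'trough' or 'p2p'")

    downs = _down_crossings(x)
    events: list[SlowWaveEvent] = []
    for a, b in zip(downs[:-1], downs[1:]):
        seg = x[a + 1: b + 1]
        if seg.size < 2:
            continue
        # exactly one negative phase then one positive phase: a single
        # upward crossing inside the span, negative first
        ups = np.flatnonzero((seg[:-1] < 0) & (seg[1:] >= 0))
        if ups.size != 1:
            continue
        up = a + 1 + ups[0]
        onset_t = _cross_time(x, a, fs, eeg.t0)
        up_t = _cross_time(x, up, fs, eeg.t0)
        neg_dur = up_t - onset_t
        if not NEG_DURATION_BOUNDS[0] <= neg_dur <= NEG_DURATION_BOUNDS[1]:
            continue
        neg = x[a + 1: up + 1]
        if neg.size == 0 or neg.min() >= 0:
            continue
        trough_i = a + 1 + int(np.argmin(neg))
        trough_amp = float(x[trough_i])
        if amp_criterion == "trough":
            if -trough_amp < thr:
                continue
        else:
            pos_peak = float(x[up + 1: b + 1].max()) if b > up + 1 else 0.0
            if pos_peak - trough_amp < 2.0 * thr:
                continue
        end_t = _cross_time(x, b, fs, eeg.t0)
        events.append(SlowWaveEvent(
            onset=onset_t,
            trough_time=eeg.t0 + trough_i / fs,
            trough_amp=trough_amp,
            neg_duration=neg_dur,
            end_time=end_t,
            frequency=1.0 / (end_t - onset_t),
        ))
    if not events:
        logger.info("detect_slow_waves: no candidate waves passed the criteria")
    return events


def slow_wave_activity(
    eeg: SignalTrace,
    segment_s: float = 300.0,
    band: tuple[float, float] = SWA_BAND,
) -> list[SwaSegmentResult]:
    """Band power (Welch, μV²) in 0.5-1.5 Hz per fixed-length segment."""
    fs = eeg.fs
    n_seg = int(round(segment_s * fs))
    results = []
    start = 0
    while start + n_seg <= eeg.samples.size:
        seg = eeg.samples[start: start + n_seg]
        nperseg = min(int(30 * fs), seg.size)
        freqs, psd = sps.welch(seg, fs=fs, window="hann", nperseg=nperseg,
                               noverlap=nperseg // 2)
        mask = (freqs >= band[0]) & (freqs <= band[1])
        power = float(np.trapezoid(psd[mask], freqs[mask]))
        results.append(SwaSegmentResult(
            segment_start=eeg.t0 + start / fs, swa_power=power))
        start += n_seg
    return results
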