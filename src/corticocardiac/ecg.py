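"""ECG processing: R-peak detection, heart rate, and beat-template averaging.

The detector is a self-contained Hamilton/Pan-Tompkins-style adaptive QRS
segmenter: band-pass energy envelope, running signal/noise peak estimates,
a refractory period, and missed-beat search-back.  Detections are refined to
the local maximum of the *raw* trace so that R-wave amplitudes are measured
on the unfiltered signal, baseline-subtracted against the preceding isoelectric
segment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

logger = logging.getLogger("corticocardiac")

# Refractory period between accepted beats (s).  Physiological upper bound on
# QRS rate; also the minimum gap the BeatSeries invariant enforces.
REFRACTORY_S = 0.2

# Physiological RR bounds (s): 10-250 bpm.
RR_MIN_S = 0.24
RR_MAX_S = 6.0


@dataclass
class SignalTrace:
    """Uniformly sampled physiological signal (ECG or EEG).

    Parameters
    ----------
    samples : ndarray
        Amplitudes in μV.
    fs : float
        Sampling rate in Hz.
    label : str
        Channel name, e.g. ``"ECG"`` or ``"EEG"``.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"trace {self.label!r} contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class BeatSeries:
    """Detected R-peak times (s) and amplitudes (μV)."""

    r_times: np.ndarray
    r_amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        self.r_amplitudes = np.asarray(self.r_amplitudes, dtype=float)
        if self.r_times.size != self.r_amplitudes.size:
            raise ValueError("r_times and r_amplitudes must have equal length")
        if self.r_times.size >= 2:
            gaps = np.diff(self.r_times)
            if np.any(gaps <= 0):
                raise ValueError("r_times must be strictly increasing")
            if gaps.min() < REFRACTORY_S:
                raise ValueError(
                    f"minimum RR gap {gaps.min():.3f}s violates the "
                    f"{REFRACTORY_S}s refractory period"
                )

    def __len__(self) -> int:
        return int(self.r_times.size)

    @property
    def rr(self) -> np.ndarray:
        """Successive RR intervals in seconds."""
        return np.diff(self.r_times)


@dataclass
class HeartRateSeries:
    """Instantaneous heart rate: 60/RR assigned to each beat interval."""

    times: np.ndarray
    hr: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)

    def resample(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation of the rate onto a uniform grid."""
        return np.interp(grid, self.times, self.hr)


@dataclass
class EcgTemplate:
    """Averaged beat waveform on a lag grid around the R-peak."""

    lags: np.ndarray
    mean_waveform: np.ndarray
    n_beats: int = 0

    def __post_init__(self) -> None:
        peak = int(np.argmax(self.mean_waveform))
        zero = int(np.argmin(np.abs(self.lags)))
        if abs(peak - zero) > 1:
            warnings.warn(
                "template peak is not at lag 0; upstream R alignment is suspect",
                stacklevel=2,
            )


# --------------------------------------------------------------------------
# R-peak detection
# --------------------------------------------------------------------------

def _qrs_envelope(x: np.ndarray, fs: float) -> np.ndarray:
    """Band-passed (8-16 Hz), rectified-derivative, smoothed QRS energy."""
    sos = sps.butter(3, [8.0, 16.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    env = np.abs(np.gradient(bp)) * fs
    win = max(1, int(round(0.08 * fs)))
    return sps.convolve(env, np.ones(win) / win, mode="same")


def detect_r_peaks(ecg: SignalTrace) -> BeatSeries:
    """Detect R-peaks with an adaptive-threshold QRS segmenter.

    The detection pipeline: 8-16 Hz band-pass, rectified-derivative envelope,
    adaptive threshold tracking running signal/noise peak estimates with a
    0.2 s refractory period and a search-back pass when a gap exceeds 1.5x
    the running RR mean.  Each detection is refined to the local maximum of
    the raw signal within ±50 ms; the amplitude is the raw value at the
    refined peak minus a local baseline (median over the 100 ms window
    ending 60 ms before the peak).

    The adaptive threshold makes detection invariant to global amplitude
    scaling, and the band-pass removes any DC offset.
    """
    if ecg.fs < 250:
        raise ValueError("ECG sampling rate must be >= 250 Hz")
    if ecg.duration < 10:
        raise ValueError("ECG must be at least 10 s long")

    x = ecg.samples
    fs = ecg.fs
    if np.ptp(x) == 0:
        warnings.warn("flat ECG signal: no beats detected", stacklevel=2)
        return BeatSeries(np.empty(0), np.empty(0))

    env = _qrs_envelope(x, fs)

    min_dist = int(round(REFRACTORY_S * fs))
    cand_idx, _ = sps.find_peaks(env, distance=min_dist)
    if cand_idx.size == 0:
        warnings.warn("no envelope peaks found: no beats detected", stacklevel=2)
        return BeatSeries(np.empty(0), np.empty(0))

    # Initialise signal/noise estimates from the first few seconds.
    lead = env[: int(min(env.size, 5 * fs))]
    spk = 0.7 * lead.max()
    npk = float(np.median(lead))

    accepted: list[int] = []
    rr_hist: list[float] = []
    last_checked: dict[int, float] = {}  # candidate index -> peak height, for search-back

    def threshold() -> float:
        return npk + 0.25 * (spk - npk)

    for idx in cand_idx:
        p = env[idx]
        if accepted and (idx - accepted[-1]) < min_dist:
            continue
        if p >= threshold():
            # Missed-beat search-back before accepting: if the gap to the
            # previous beat exceeds 1.5x the running RR mean, rescue the
            # largest skipped candidate above half threshold.
            if accepted and rr_hist:
                rr_mean = float(np.mean(rr_hist[-8:]))
                gap = (idx - accepted[-1]) / fs
                if gap > 1.5 * rr_mean:
                    back = [
                        (j, h)
                        for j, h in last_checked.items()
                        if accepted[-1] + min_dist <= j <= idx - min_dist
                        and h >= 0.5 * threshold()
                    ]
                    if back:
                        j = max(back, key=lambda t: t[1])[0]
                        rr_hist.append((j - accepted[-1]) / fs)
                        accepted.append(j)
                        spk = 0.25 * env[j] + 0.75 * spk
            if accepted:
                rr_hist.append((idx - accepted[-1]) / fs)
            accepted.append(idx)
            spk = 0.125 * p + 0.875 * spk
        else:
            npk = 0.125 * p + 0.875 * npk
            last_checked[idx] = p

    if not accepted:
        warnings.warn("threshold never crossed: no beats detected", stacklevel=2)
        return BeatSeries(np.empty(0), np.empty(0))

    # Refine to the raw-signal local maximum within ±50 ms.
    half = int(round(0.05 * fs))
    refined = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(x.size, idx + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    # Re-impose the refractory period after refinement.
    keep = [int(refined[0])]
    for idx in refined[1:]:
        if idx - keep[-1] >= min_dist:
            keep.append(int(idx))
    peaks = np.asarray(keep)

    amps = _r_amplitudes(x, fs, peaks)
    return BeatSeries(ecg.t0 + peaks / fs, amps)


def _r_amplitudes(x: np.ndarray, fs: float, peaks: np.ndarray) -> np.ndarray:
    """Raw peak value minus local baseline (median of the 100 ms window
    ending 60 ms before the peak)."""
    off_hi = int(round(0.06 * fs))
    off_lo = int(round(0.16 * fs))
    amps = np.empty(peaks.size)
    for k, idx in enumerate(peaks):
        lo, hi = max(0, idx - off_lo), max(0, idx - off_hi)
        baseline = float(np.median(x[lo:hi])) if hi > lo else 0.0
        amps[k] = x[idx] - baseline
    return amps


# --------------------------------------------------------------------------
# Derived series
# --------------------------------------------------------------------------

def heart_rate(beats: BeatSeries, clean: bool = True) -> HeartRateSeries:
    """Instantaneous heart rate, 60/RR per beat interval.

    Each rate value is timestamped at the midpoint of its RR interval.
    With ``clean=True`` values outside (10, 250) bpm are dropped.
    """
    if len(beats) < 2:
        raise ValueError("at least 2 beats are required for a heart rate")
    rr = beats.rr
    hr = 60.0 / rr
    times = beats.r_times[:-1] + rr / 2
    if clean:
        ok = (hr > 10.0) & (hr < 250.0)
        if not np.all(ok):
            logger.info("heart_rate: dropped %d values outside (10, 250) bpm", int((~ok).sum()))
        times, hr = times[ok], hr[ok]
    return HeartRateSeries(times, hr)


def beat_template(
    ecg: SignalTrace,
    beats: BeatSeries,
    window: tuple[float, float] = (-0.2, 0.4),
) -> EcgTemplate:
    """Average the raw ECG over per-beat windows around each R-peak.

    Beats whose window exceeds the trace are skipped; fewer than 10 usable
    beats is an error.
    """
    lo = int(round(window[0] * ecg.fs))
    hi = int(round(window[1] * ecg.fs))
    lags = np.arange(lo, hi + 1) / ecg.fs
    idx = np.round((beats.r_times - ecg.t0) * ecg.fs).astype(int)
    usable = idx[(idx + lo >= 0) & (idx + hi < ecg.samples.size)]
    if usable.size < 10:
        raise ValueError(f"only {usable.size} usable beats; need >= 10")
    offsets = np.arange(lo, hi + 1)
    stacked = ecg.samples[usable[:, None] + offsets[None, :]]
    return EcgTemplate(lags, stacked.mean(axis=0), n_beats=int(usable.size))
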