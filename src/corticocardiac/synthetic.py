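"""Synthetic coupled-physiology generator.

Emulates a slow propofol anesthesia study in two arms:

* **Volunteer arm** — a single-channel ECG (500 Hz) and frontal EEG (100 Hz)
  during a slow effect-site concentration ramp 0 → 4 μg/ml → 0.  Heart rate
  rises linearly with concentration, respiratory sinus arrhythmia shrinks
  with dose, R-wave amplitude falls with dose, and ~1 Hz cortical slow waves
  appear above a concentration threshold with saturating incidence.  Each
  slow wave is, with probability κ, onset-locked a fixed lag after the
  nearest preceding heartbeat — the coupling the entropy analysis is built
  to detect.  Ground-truth beat times, amplitudes, wave onsets and coupling
  flags are returned alongside the rendered traces.

* **Clinical arm** — a long-format table of heart rate sampled every 5 s
  with propofol/fentanyl/desflurane effect-site concentrations and
  demographics, generated from a linear mixed model (fixed effects + drug
  interactions + per-patient random intercept) with optional spike
  artifacts, for exercising the mixed-effects heart-rate fit.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .ecg import SignalTrace, RR_MIN_S, RR_MAX_S

# ECG beat template: Gaussian bumps (amplitude μV, center s, width s) for the
# P-QRS-T complex.  The R bump is rescaled per beat to the target R amplitude.
# The T wave is kept small so the beat's 0.5-1.5 Hz (slow-wave band) energy is
# centred on the R-peak: time-locked band-filtered averages then read out beat
# timing without a morphology-induced lag (verified in the test suite).
ECG_BUMPS = (
    (60.0, -0.16, 0.020),   # P
    (-80.0, -0.030, 0.010),  # Q
    (1000.0, 0.0, 0.011),    # R (rescaled per beat)
    (-120.0, 0.035, 0.010),  # S
    (40.0, 0.20, 0.030),     # T
)

def _default_coeffs() -> np.ndarray:
    # Fixed effects of the clinical heart-rate model:
    # intercept, age, BMI, ASA, sex=F, propofol, fentanyl, desflurane,
    # prop*fent, prop*des, fent*des.
    return np.array(
        [45.444, 0.213, 0.122, 1.976, 0.367, 1.319, -2.604, -1.838,
         0.988, -0.711, 0.463]
    )


@dataclass
class VolunteerSimConfig:
    """Configuration of one simulated volunteer recording.

    Defaults reproduce the study conditions the analyses assume: a
    10/48/10/48-minute awake/induction/peak/emergence profile (scalable by
    ``phase_scale``), heart rate 56.1 + 4.23·Ce bpm, R amplitude
    966 − 20.75·Ce μV (a −83 μV swing over the full 4 μg/ml ramp), and a
    447 ms R-peak → slow-wave-onset coupling lag.
    """

    phase_durations: tuple[float, float, float, float] = (600.0, 2880.0, 600.0, 2880.0)
    phase_scale: float = 1.0
    ce_max: float = 4.0                 # μg/ml
    hr_intercept: float = 56.1          # bpm at Ce=0, cohort mean
    hr_intercept_sd: float = 10.0       # bpm between-subject spread
    hr_slope: float = 4.23              # bpm per μg/ml, cohort mean
    hr_slope_sd: float = 1.0            # bpm per μg/ml between-subject spread
    rsa_freq: float = 0.25              # Hz (respiration)
    rsa_amp_base: float = 40.0          # ms RR modulation at Ce=0
    rsa_amp_slope: float = -8.0         # ms per μg/ml (HF variability shrinks)
    lf_amp: float = 15.0                # ms low-frequency RR modulation
    lf_freq: float = 0.09               # Hz
    rr_noise_ms: float = 3.0            # white RR jitter, ms
    rwa_base: float = 966.0             # μV R amplitude at Ce=0, cohort mean
    rwa_base_sd: float = 150.0          # μV between-subject spread
    rwa_slope: float = -20.75           # μV per μg/ml, cohort mean
    rwa_slope_sd: float = 8.0           # μV per μg/ml between-subject spread
    rwa_noise: float = 15.0             # per-beat amplitude jitter, μV
    ecg_noise: float = 5.0              # additive white ECG noise, μV
    sw_rate_max: float = 8.0            # slow waves per minute at saturation
    sw_ce_onset: float = 1.0            # μg/ml below which no slow waves occur
    sw_ce_half: float = 2.0             # μg/ml at half-maximal incidence
    sw_rate_width: float = 0.3          # μg/ml sigmoid width
    sw_coupling_prob: float = 0.5       # κ ∈ [0, 1]
    sw_coupling_lag: float = 0.447      # s from R-peak to slow-wave onset
    sw_lock: str = "onset"              # "onset" | "trough"
    sw_freq_mean: float = 1.0           # Hz
    sw_freq_sd: float = 0.1             # Hz per-wave jitter
    sw_freq_subject_sd: float = 0.05    # Hz between-subject spread
    sw_freq_hr_coef: float = 0.0        # Hz per bpm of subject baseline HR
                                        # deviation (0 = no HR/frequency link)
    sw_amp: float = 80.0                # μV trough amplitude
    sw_amp_sd: float = 4.0              # μV per-wave jitter
    eeg_noise_exponent: float = 1.0     # background 1/f^α slope
    eeg_noise_scale: float = 12.0       # μV background standard deviation
    fs_ecg: float = 500.0
    fs_eeg: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.phase_durations) or self.phase_scale <= 0:
            raise ValueError("phase durations must be positive")
        if not 0.0 <= self.sw_coupling_prob <= 1.0:
            raise ValueError("coupling probability must be in [0, 1]")
        if self.fs_ecg < 250:
            raise ValueError("fs_ecg must be >= 250 Hz")
        if self.fs_eeg < 50:
            raise ValueError("fs_eeg must be >= 50 Hz")
        if self.sw_lock not in ("onset", "trough"):
            raise ValueError("sw_lock must be 'onset' or 'trough'")
        for ce in (0.0, self.ce_max):
            hr = self.hr_intercept + self.hr_slope * ce
            if not 10.0 < hr < 250.0:
                raise ValueError(f"configured heart rate {hr:.1f} bpm at Ce={ce} "
                                 "is outside (10, 250)")

    @property
    def durations(self) -> np.ndarray:
        return np.asarray(self.phase_durations) * self.phase_scale

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    def phase_window(self, phase: str) -> tuple[float, float]:
        """Time span (s) of one of 'awake', 'induction', 'peak', 'emergence'."""
        names = ("awake", "induction", "peak", "emergence")
        edges = np.concatenate([[0.0], np.cumsum(self.durations)])
        i = names.index(phase)
        return float(edges[i]), float(edges[i + 1])

    def ce_at(self, t: np.ndarray) -> np.ndarray:
        """Piecewise-linear effect-site concentration profile (μg/ml)."""
        d = self.durations
        e = np.concatenate([[0.0], np.cumsum(d)])
        knots_t = [e[0], e[1], e[2], e[3], e[4]]
        knots_c = [0.0, 0.0, self.ce_max, self.ce_max, 0.0]
        return np.interp(np.asarray(t, dtype=float), knots_t, knots_c)

    def sw_rate(self, ce: np.ndarray) -> np.ndarray:
        """Slow-wave incidence (waves/min) vs concentration: a sigmoid that
        saturates at ``sw_rate_max``, forced to zero below ``sw_ce_onset``."""
        ce = np.asarray(ce, dtype=float)
        rate = self.sw_rate_max / (1.0 + np.exp(-(ce - self.sw_ce_half) / self.sw_rate_width))
        return np.where(ce < self.sw_ce_onset, 0.0, rate)


@dataclass
class VolunteerRecording:
    """One simulated volunteer: traces, concentration series, ground truth."""

    ecg: SignalTrace
    eeg: SignalTrace
    ce_series: np.ndarray          # μg/ml, one value per second
    truth_beats: np.ndarray        # R-peak times, s
    truth_rwa: np.ndarray          # per-beat R amplitude, μV
    truth_sw_onsets: np.ndarray    # slow-wave onset times, s
    truth_coupled_flags: np.ndarray  # bool per wave
    config: VolunteerSimConfig | None = None

    def __post_init__(self) -> None:
        if self.truth_beats.size >= 2:
            gaps = np.diff(self.truth_beats)
            if np.any(gaps <= 0):
                raise ValueError("truth_beats must be strictly increasing")
            if gaps.min() <= RR_MIN_S or gaps.max() >= RR_MAX_S:
                raise ValueError("simulated RR interval outside (0.24, 6) s")
        if self.truth_sw_onsets.size >= 2 and np.any(np.diff(self.truth_sw_onsets) <= 0):
            raise ValueError("truth_sw_onsets must be strictly increasing")


# --------------------------------------------------------------------------
# Volunteer arm
# --------------------------------------------------------------------------

def _simulate_beats(config: VolunteerSimConfig, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """Beat times from the instantaneous-rate model with RSA/LF modulation.

    Per-subject dose-response parameters (intercept, slope, R amplitude and
    its slope) are drawn first, giving the cohort its between-subject
    spread; the draws come before any beat-level randomness so the
    event-level and full simulations stay aligned.
    """
    subj_icpt = config.hr_intercept + config.hr_intercept_sd * rng.standard_normal()
    subj_slope = config.hr_slope + config.hr_slope_sd * rng.standard_normal()
    subj_rwa_base = config.rwa_base + config.rwa_base_sd * rng.standard_normal()
    subj_rwa_slope = config.rwa_slope + config.rwa_slope_sd * rng.standard_normal()
    total = config.total_duration
    times = []
    t = float(rng.uniform(0.2, 1.0))  # random phase of the first beat
    while t < total - 1.0:
        ce = float(config.ce_at(t))
        hr = subj_icpt + subj_slope * ce
        rsa_amp = max(0.0, config.rsa_amp_base + config.rsa_amp_slope * ce)
        mod_ms = (
            rsa_amp * np.sin(2 * np.pi * config.rsa_freq * t)
            + config.lf_amp * np.sin(2 * np.pi * config.lf_freq * t)
            + config.rr_noise_ms * rng.standard_normal()
        )
        rr = 60.0 / hr + mod_ms / 1000.0
        if not RR_MIN_S < rr < RR_MAX_S:
            raise ValueError(f"configuration produced RR={rr:.3f} s at t={t:.0f} s")
        times.append(t)
        t += rr
    beats = np.asarray(times)
    ce_b = config.ce_at(beats)
    rwa = subj_rwa_base + subj_rwa_slope * ce_b \
        + config.rwa_noise * rng.standard_normal(beats.size)
    return beats, rwa, subj_icpt


def _simulate_wave_events(
    config: VolunteerSimConfig, beats: np.ndarray, rng: np.random.Generator,
    subj_icpt: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Slow-wave onsets, coupling flags, per-wave frequency and amplitude.

    Candidate times come from an inhomogeneous Poisson process (thinning)
    following the sigmoid incidence curve; a candidate is then either locked
    to the nearest preceding R-peak (probability κ) or jittered uniformly.
    With ``sw_freq_hr_coef`` nonzero, the subject's mean wave frequency is
    tied to their baseline heart-rate deviation (faster hearts, faster
    waves).
    """
    total = config.total_duration
    freq_mean = config.sw_freq_mean \
        + config.sw_freq_subject_sd * rng.standard_normal()
    if subj_icpt is not None and config.sw_freq_hr_coef != 0.0:
        freq_mean += config.sw_freq_hr_coef * (subj_icpt - config.hr_intercept)
    rate_max = config.sw_rate_max / 60.0  # per second
    candidates = []
    if rate_max > 0:
        t = 0.0
        while True:
            t += rng.exponential(1.0 / rate_max)
            if t >= total - 3.0:
                break
            rate = float(config.sw_rate(config.ce_at(t))) / 60.0
            if rng.random() < rate / rate_max:
                candidates.append(t)

    onsets, flags, freqs, amps = [], [], [], []
    for t_c in candidates:
        freq = max(0.5, rng.normal(freq_mean, config.sw_freq_sd))
        amp = max(50.0, rng.normal(config.sw_amp, config.sw_amp_sd))
        coupled = rng.random() < config.sw_coupling_prob
        if coupled and beats.size:
            k = int(np.searchsorted(beats, t_c, side="right")) - 1
            if k < 0:
                continue
            onset = beats[k] + config.sw_coupling_lag
            if config.sw_lock == "trough":
                # trough of the negative half-sine sits half a negative
                # duration after the onset; shift so the trough carries the lag
                onset -= 0.5 * (0.45 / freq)
            flag = True
        else:
            onset = t_c + rng.uniform(-0.5, 0.5)
            flag = False
        if 2.5 < onset < total - 3.0:
            onsets.append(onset)
            flags.append(flag)
            freqs.append(freq)
            amps.append(amp)

    order = np.argsort(onsets)
    onsets = np.asarray(onsets)[order]
    flags = np.asarray(flags, dtype=bool)[order]
    freqs = np.asarray(freqs)[order]
    amps = np.asarray(amps)[order]

    # Enforce separation of at least one wave period plus margin.
    keep = []
    last_end = -np.inf
    for i, onset in enumerate(onsets):
        period = 1.0 / freqs[i]
        if onset > last_end + 0.3:
            keep.append(i)
            last_end = onset + period
    keep = np.asarray(keep, dtype=int)
    return onsets[keep], flags[keep], freqs[keep], amps[keep]


def simulate_volunteer_events(
    config: VolunteerSimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Event-level fast path: ground-truth beats and slow waves only.

    Returns ``(beats, rwa, sw_onsets, coupled_flags, sw_freqs, sw_amps)``
    without rendering any traces; used where only event statistics matter.
    Draws are ordered identically to :func:`simulate_volunteer`, so the
    events match the full simulation for the same config.
    """
    rng = np.random.default_rng(config.seed)
    beats, rwa, subj_icpt = _simulate_beats(config, rng)
    onsets, flags, freqs, amps = _simulate_wave_events(config, beats, rng, subj_icpt)
    return beats, rwa, onsets, flags, freqs, amps


def _render_ecg(
    config: VolunteerSimConfig,
    beats: np.ndarray,
    rwa: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    fs = config.fs_ecg
    n = int(round(config.total_duration * fs))
    x = rng.standard_normal(n) * config.ecg_noise
    half_lo, half_hi = -0.30, 0.50
    for t_beat, amp in zip(beats, rwa):
        i0 = max(0, int(np.ceil((t_beat + half_lo) * fs)))
        i1 = min(n, int(np.floor((t_beat + half_hi) * fs)) + 1)
        t_rel = np.arange(i0, i1) / fs - t_beat
        seg = np.zeros_like(t_rel)
        for a, c, s in ECG_BUMPS:
            if c == 0.0:
                a = amp  # R bump carries the per-beat amplitude
            seg += a * np.exp(-0.5 * ((t_rel - c) / s) ** 2)
        x[i0:i1] += seg
    return x


def _wave_shape(freq: float, fs: float, amp: float = 1.0
                ) -> tuple[float, np.ndarray]:
    """The slow-wave waveform sampled at ``fs``: a half-amplitude positive
    lead lobe, the negative half-sine, and an area-matched positive tail.
    Returns ``(lead duration, samples)``; the raw onset (downward zero
    crossing) sits ``lead`` seconds after the first sample."""
    d_lead = 0.30 / freq
    d_neg = 0.45 / freq
    d_pos = 0.55 / freq
    lead_amp = 0.5 * amp
    tail_amp = (amp * d_neg - lead_amp * d_lead) / d_pos
    t = np.arange(int(round((d_lead + d_neg + d_pos) * fs))) / fs
    seg = np.where(
        t < d_lead,
        lead_amp * np.sin(np.pi * t / d_lead),
        np.where(
            t < d_lead + d_neg,
            -amp * np.sin(np.pi * (t - d_lead) / d_neg),
            tail_amp * np.sin(np.pi * (t - d_lead - d_neg) / d_pos),
        ),
    )
    return d_lead, seg


_onset_shift_cache: dict[tuple[float, float], float] = {}


def _onset_shift(freq: float, fs: float) -> float:
    """Offset of the band-filtered downward zero crossing from the raw wave
    onset.

    Slow-wave onsets are *defined* on the 0.5-4 Hz filtered signal, and
    band-limiting a transient waveform moves its zero crossing slightly
    inward.  Ground truth is therefore expressed in the filtered-onset
    convention: the renderer shifts the raw waveform by this offset so the
    truth onset is what the detection observable places at that time.
    """
    key = (round(freq, 2), fs)
    if key not in _onset_shift_cache:
        f = key[0]
        d_lead, seg = _wave_shape(f, fs)
        pad = int(round(4 * fs))
        x = np.zeros(2 * pad + seg.size)
        x[pad: pad + seg.size] = seg
        sos1 = sps.butter(3, [0.5, 45.0], btype="bandpass", fs=fs, output="sos")
        sos2 = sps.butter(3, [0.5, 4.0], btype="bandpass", fs=fs, output="sos")
        y = sps.sosfiltfilt(sos2, sps.sosfiltfilt(sos1, x))
        raw_onset = (pad + d_lead * fs) / fs
        downs = np.flatnonzero((y[:-1] > 0) & (y[1:] <= 0))
        times = np.array([
            (i + y[i] / (y[i] - y[i + 1])) / fs for i in downs])
        _onset_shift_cache[key] = float(times[np.argmin(np.abs(times - raw_onset))]
                                        - raw_onset)
    return _onset_shift_cache[key]


def _pink_noise(n: int, exponent: float, scale: float, fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Gaussian background with 1/f^α spectrum (flat below 0.5 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.maximum(f, 0.5) ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x * (scale / sd) if sd > 0 else x


def _render_eeg(
    config: VolunteerSimConfig,
    onsets: np.ndarray,
    freqs: np.ndarray,
    amps: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    fs = config.fs_eeg
    n = int(round(config.total_duration * fs))
    x = _pink_noise(n, config.eeg_noise_exponent, config.eeg_noise_scale, fs, rng)
    for onset, freq, amp in zip(onsets, freqs, amps):
        # truth onsets use the filtered-crossing convention: shift the raw
        # waveform so its band-filtered downward crossing lands on `onset`
        raw_onset = onset - _onset_shift(freq, fs)
        d_lead, shape = _wave_shape(freq, fs, amp)
        i0 = int(round((raw_onset - d_lead) * fs))
        j0 = max(0, -i0)
        i1 = min(n, i0 + shape.size)
        if i1 > max(i0, 0):
            x[max(i0, 0): i1] += shape[j0: j0 + (i1 - max(i0, 0))]
    return x


def simulate_volunteer(config: VolunteerSimConfig) -> VolunteerRecording:
    """Simulate one volunteer recording (ECG + EEG + ground truth).

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    beats, rwa, subj_icpt = _simulate_beats(config, rng)
    onsets, flags, freqs, amps = _simulate_wave_events(config, beats, rng, subj_icpt)
    ecg = _render_ecg(config, beats, rwa, rng)
    eeg = _render_eeg(config, onsets, freqs, amps, rng)
    seconds = np.arange(int(config.total_duration))
    return VolunteerRecording(
        ecg=SignalTrace(ecg, config.fs_ecg, label="ECG"),
        eeg=SignalTrace(eeg, config.fs_eeg, label="EEG"),
        ce_series=config.ce_at(seconds),
        truth_beats=beats,
        truth_rwa=rwa,
        truth_sw_onsets=onsets,
        truth_coupled_flags=flags,
        config=config,
    )


# --------------------------------------------------------------------------
# Clinical arm
# --------------------------------------------------------------------------

@dataclass
class ClinicalSimConfig:
    """Configuration of the simulated clinical cohort.

    The fixed-effect defaults are the clinical heart-rate model coefficients
    (intercept, age, BMI, ASA, sex=F, propofol, fentanyl, desflurane and the
    three pairwise drug interactions); heart rate is generated directly from
    that linear predictor plus a per-patient random intercept and residual
    noise, with occasional off-scale spike artifacts.
    """

    n_patients: int = 96
    coeffs: np.ndarray = field(default_factory=_default_coeffs)
    random_intercept_sd: float = 7.0   # bpm between-patient spread
    residual_sd: float = 3.0           # bpm within-patient noise
    sample_interval: float = 5.0       # s
    duration: float = 3600.0           # s per patient
    artifact_rate: float = 2.0         # expected spikes per hour
    age_range: tuple[int, int] = (61, 86)
    bmi_mean: float = 27.0
    bmi_sd: float = 4.0
    asa3_prob: float = 0.5
    female_prop: float = 0.3125
    prop_bolus_range: tuple[float, float] = (3.0, 5.0)   # μg/ml induction peak
    prop_decay_s: float = 1800.0
    des_level_range: tuple[float, float] = (3.0, 7.0)    # % end-tidal plateau
    des_rise_s: float = 600.0
    fent_bolus_range: tuple[float, float] = (1.0, 2.0)   # ng/ml per bolus
    fent_interval_s: float = 1800.0
    fent_decay_s: float = 1800.0
    fent_rise_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.coeffs.size != 11:
            raise ValueError("expected 11 fixed-effect coefficients")
        if self.residual_sd < 0 or self.random_intercept_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.sample_interval <= 0 or self.duration <= 0:
            raise ValueError("sample_interval and duration must be positive")


def clinical_linear_predictor(df: pd.DataFrame, coeffs: np.ndarray) -> np.ndarray:
    """Evaluate the fixed-effect part of the clinical heart-rate model.

    HR = β0 + β1·age + β2·BMI + β3·ASA + β4·(sex=F) + β5·prop + β6·fent
         + β7·des + β8·prop·fent + β9·prop·des + β10·fent·des
    """
    b = np.asarray(coeffs, dtype=float)
    sex_f = (df["sex"] == "F").astype(float).to_numpy()
    p, f, d = (df[c].to_numpy() for c in ("prop_ugml", "fent_ngml", "des_pct"))
    return (
        b[0]
        + b[1] * df["age"].to_numpy()
        + b[2] * df["bmi"].to_numpy()
        + b[3] * df["asa"].to_numpy()
        + b[4] * sex_f
        + b[5] * p + b[6] * f + b[7] * d
        + b[8] * p * f + b[9] * p * d + b[10] * f * d
    )


def simulate_clinical(config: ClinicalSimConfig) -> pd.DataFrame:
    """Simulate the clinical cohort table (long format, one row per 5 s sample).

    Columns: patient_id, t_s, hr_bpm, prop_ugml, fent_ngml, des_pct, age,
    bmi, asa, sex.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.duration, config.sample_interval)
    frames = []
    for pid in range(1, config.n_patients + 1):
        age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
        bmi = float(np.clip(rng.normal(config.bmi_mean, config.bmi_sd), 17.0, 45.0))
        asa = 3 if rng.random() < config.asa3_prob else 2
        sex = "F" if rng.random() < config.female_prop else "M"

        # records start shortly after induction: trajectories are already
        # part-way along their exponentials, keeping them smooth at the
        # 2-minute scale the median preprocessing operates on
        p0 = rng.uniform(*config.prop_bolus_range)
        prop = p0 * np.exp(-(t + 300.0) / config.prop_decay_s)
        des_level = rng.uniform(*config.des_level_range)
        des = des_level * (1.0 - np.exp(-(t + 300.0) / config.des_rise_s))
        fent = np.zeros_like(t)
        bolus_t = -300.0
        while bolus_t < config.duration:
            b = rng.uniform(*config.fent_bolus_range)
            dt = t - bolus_t
            fent += np.where(dt >= 0, b * np.exp(-dt / config.fent_decay_s)
                             * (1.0 - np.exp(-dt / config.fent_rise_s)), 0.0)
            bolus_t += config.fent_interval_s * rng.uniform(0.7, 1.3)

        df = pd.DataFrame({
            "patient_id": pid, "t_s": t,
            "prop_ugml": prop, "fent_ngml": fent, "des_pct": des,
            "age": age, "bmi": bmi, "asa": asa, "sex": sex,
        })
        hr = clinical_linear_predictor(df, config.coeffs)
        hr = hr + rng.normal(0.0, config.random_intercept_sd)
        hr = hr + rng.normal(0.0, config.residual_sd, size=hr.size)

        n_art = rng.poisson(config.artifact_rate * config.duration / 3600.0)
        if n_art > 0:
            pos = rng.choice(t.size, size=min(n_art, t.size), replace=False)
            high = rng.random(pos.size) < 0.5
            hr[pos] = np.where(high, rng.uniform(300.0, 400.0, pos.size),
                               rng.uniform(0.0, 5.0, pos.size))
        df["hr_bpm"] = hr
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    cols = ["patient_id", "t_s", "hr_bpm", "prop_ugml", "fent_ngml",
            "des_pct", "age", "bmi", "asa", "sex"]
    return out[cols]


# --------------------------------------------------------------------------
# Config and recording I/O
# --------------------------------------------------------------------------

def _config_to_dict(config) -> dict:
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = [float(x) for x in v]
        elif isinstance(v, tuple):
            d[k] = list(v)
    return d


def save_config(config, path: str | Path) -> None:
    """Write a config as a round-trippable key: value text file."""
    Path(path).write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=False))


def load_volunteer_config(path: str | Path) -> VolunteerSimConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["phase_durations"] = tuple(d["phase_durations"])
    return VolunteerSimConfig(**d)


def load_clinical_config(path: str | Path) -> ClinicalSimConfig:
    d = yaml.safe_load(Path(path).read_text())
    for k in ("age_range", "prop_bolus_range", "des_level_range", "fent_bolus_range"):
        d[k] = tuple(d[k])
    return ClinicalSimConfig(**d)


def save_recording(rec: VolunteerRecording, outdir: str | Path) -> dict[str, Path]:
    """Write a volunteer recording as plain-text CSV files.

    ``signals_<ch>.csv`` hold the traces, ``concentration.csv`` the per-second
    effect-site series, ``ground_truth_*.csv`` the simulated events, and
    ``sim_config.yaml`` the generating configuration (including the seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for trace in (rec.ecg, rec.eeg):
        p = outdir / f"signal_{trace.label.lower()}.csv"
        pd.DataFrame({"t_s": trace.times, "uv": trace.samples}).to_csv(
            p, index=False, float_format="%.4f")
        paths[trace.label] = p
    p = outdir / "concentration.csv"
    pd.DataFrame({"t_s": np.arange(rec.ce_series.size), "ce_ugml": rec.ce_series}
                 ).to_csv(p, index=False, float_format="%.4f")
    paths["ce"] = p
    p = outdir / "ground_truth_beats.csv"
    pd.DataFrame({"r_time_s": rec.truth_beats, "rwa_uv": rec.truth_rwa}).to_csv(
        p, index=False, float_format="%.5f")
    paths["beats"] = p
    p = outdir / "ground_truth_slow_waves.csv"
    pd.DataFrame({"onset_s": rec.truth_sw_onsets,
                  "coupled": rec.truth_coupled_flags.astype(int)}).to_csv(
        p, index=False, float_format="%.5f")
    paths["waves"] = p
    if rec.config is not None:
        p = outdir / "sim_config.yaml"
        save_config(rec.config, p)
        paths["config"] = p
    return paths


def load_recording(outdir: str | Path) -> VolunteerRecording:
    """Read back a recording written by :func:`save_recording`."""
    outdir = Path(outdir)
    config = load_volunteer_config(outdir / "sim_config.yaml")
    traces = {}
    for label in ("ECG", "EEG"):
        df = pd.read_csv(outdir / f"signal_{label.lower()}.csv")
        fs = config.fs_ecg if label == "ECG" else config.fs_eeg
        traces[label] = SignalTrace(df["uv"].to_numpy(), fs, label=label,
                                    t0=float(df["t_s"].iloc[0]))
    ce = pd.read_csv(outdir / "concentration.csv")["ce_ugml"].to_numpy()
    beats = pd.read_csv(outdir / "ground_truth_beats.csv")
    waves = pd.read_csv(outdir / "ground_truth_slow_waves.csv")
    return VolunteerRecording(
        ecg=traces["ECG"], eeg=traces["EEG"], ce_series=ce,
        truth_beats=beats["r_time_s"].to_numpy(),
        truth_rwa=beats["rwa_uv"].to_numpy(),
        truth_sw_onsets=waves["onset_s"].to_numpy(),
        truth_coupled_flags=waves["coupled"].to_numpy().astype(bool),
        config=config,
    )
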