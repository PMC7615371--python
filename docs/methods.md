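# Methods

This note documents the models and procedures implemented in
`corticocardiac`, the defaults and why they were chosen, and what the
synthetic-data validation does and does not demonstrate.

## Synthetic coupled physiology

### Volunteer arm

One recording covers four phases — awake, induction, peak anesthesia,
emergence — of 10/48/10/48 minutes by default (`phase_scale` shortens all
four proportionally; the packaged tests and the acceptance script use
quarter-length phases to keep runtimes modest, which preserves every
statistical structure except the number of 5-minute segments per subject).
The effect-site concentration Ce(t) is piecewise-linear across the phases,
peaking at 4 μg/ml.  No pharmacokinetic model is applied: concentration is
an input to the generator, not an output.

**Heartbeats.**  Beat times integrate an instantaneous rate

    HR(t) = a_i + b_i · Ce(t)

with per-subject intercept a_i ~ N(56.1, 10²) bpm and slope
b_i ~ N(4.23, 1.0²) bpm/(μg/ml).  The cohort means are the dose-response
the analyses are expected to recover; the intercept spread matches the
between-subject variability typical of resting heart rate, while the slope
spread is set somewhat below the dispersion reported for per-subject slope
estimates, since those estimates carry their own measurement error on top
of true heterogeneity.  RR intervals are modulated by respiratory sinus
arrhythmia (0.25 Hz; amplitude 40 ms at Ce = 0, shrinking by 8 ms per
μg/ml, floored at 0 — high-frequency variability collapses with dose), a
low-frequency term (15 ms at 0.09 Hz), and 3 ms white jitter.  Configs
whose rates leave (10, 250) bpm or whose RR leaves (0.24, 6) s are
rejected.

**ECG.**  Each beat renders a fixed analytic P-QRS-T template (Gaussian
bumps) whose R bump is scaled to r_i + s_i·Ce(t) plus 15 μV per-beat
jitter, with r_i ~ N(966, 150²) μV and s_i ~ N(−20.75, 8²) μV/(μg/ml)
(−83 μV over the full ramp at the cohort mean).  The T wave is deliberately
small: the time-locked coupling analysis reads beat timing out of the
0.5–1.5 Hz filtered ECG, and a large T wave shifts the low-frequency
centroid of the beat away from the R-peak by ~100 ms, which would corrupt
lag estimates irrespective of the analysis code.  Morphological QT
shortening is not modelled; only the R amplitude is quantified downstream.

**EEG.**  Background is Gaussian 1/f^α noise (α = 1, 12 μV SD, spectrum
flattened below 0.5 Hz).  Slow waves are biphasic waveforms — a
half-amplitude positive lead lobe, a negative half-sine (0.45/f s), and an
area-matched positive tail (0.55/f s) — with per-wave frequency
N(1.0, 0.1²) Hz and trough amplitude N(80, 4²) μV.  The amplitude spread
is kept at 5% so that the detector's 99th-percentile amplitude criterion
retains ≥ 90% of true waves, the regime the coupling analyses assume;
larger spreads shade smoothly into deliberate partial-detection regimes.
Incidence follows a sigmoid of concentration saturating at 8 waves/min
(half-maximal at 2 μg/ml, width 0.3, zero below 1 μg/ml): the saturating
shape is the qualitative behaviour of slow-wave activity under deepening
anesthesia, and absolute rates at these doses are not well constrained, so
a mid-range plausible value was fixed once.

**Onset convention.**  Slow-wave onsets are *defined* throughout as the
downward zero crossing of the 0.5–4 Hz filtered signal.  Band-limiting a
~1 s transient narrows its negative lobe, moving that crossing ≈ 20 ms
inside the raw waveform's zero crossing.  The generator therefore expresses
ground truth in the filtered-onset convention: it computes the raw-to-
filtered crossing offset for the wave shape (cached per frequency) and
shifts the rendered waveform so the truth onset is exactly where the
detection observable puts it.  Without this, every truth-versus-detected
comparison — and the coupling lag — would carry a constant bias that
belongs to the observable's definition, not to detection error.

**Coupling.**  With probability κ (`sw_coupling_prob`, default 0.5) a
candidate wave is placed with its onset `sw_coupling_lag` (default 447 ms)
after the nearest preceding R-peak; otherwise it is jittered uniformly
within ±0.5 s of its Poisson candidate time.  A config switch locks the
trough instead of the onset.  Ground-truth flags record which waves were
coupled.  Optionally (`sw_freq_hr_coef`) the subject's mean wave frequency
is tied to their baseline heart-rate deviation to emulate the
faster-heart/faster-waves association.

### Clinical arm

96 patients, 5-s sampling, 1 h per patient by default.  Demographics:
age uniform 61–86, BMI ~ N(27, 4²), ASA 2/3 evenly, 31% female.  Drug
trajectories are smooth at the 2-minute scale (propofol decaying from a
3–5 μg/ml induction bolus with τ = 30 min, desflurane rising to a 3–7%
plateau with τ = 10 min, fentanyl boluses with 5-min rise and 30-min
decay), entering the record ~5 min after induction so no trajectory has
strong curvature inside a smoothing window.  Heart rate is the
eleven-coefficient fixed-effect predictor plus a per-patient random
intercept (SD 7 bpm) and white residual (SD 3 bpm), with spike artifacts
(HR > 250 or < 10) injected at 2/h.

## Analysis choices

* **R-peak detection** is a self-contained adaptive segmenter in the
  Hamilton/Pan-Tompkins family: 8–16 Hz zero-phase band-pass,
  rectified-derivative envelope smoothed over 80 ms, running signal/noise
  peak estimates with threshold `noise + 0.25·(signal − noise)`, 0.2 s
  refractory, and search-back at 1.5× the running RR mean.  Detections are
  refined to the raw-signal maximum within ±50 ms; amplitude is measured
  baseline-subtracted on the raw trace (median of the 100 ms window ending
  60 ms pre-peak), since filtering would distort the quantity under study.
* **HRV**: RR intervals outside 0.24–6 s or deviating > 50% from the
  previous accepted interval are excluded.  The tachogram is
  cubic-interpolated to 4 Hz, mean-detrended, and Welch-transformed
  (128-s Hann segments, 50% overlap); LF = 0.04–0.15 Hz,
  HF = 0.15–0.4 Hz by trapezoidal integration, in ms².  Segments are
  non-overlapping 5-minute windows aligned to the recording start; partial
  trailing segments are dropped.  An LF/HF ratio with zero HF power is
  reported missing, never infinite.
* **Slow-wave detection**: third-order zero-phase Butterworth 0.5–4 Hz;
  candidates are spans between consecutive downward zero crossings with
  exactly one negative-then-positive phase; keep when the negative phase
  lasts 0.25–1.25 s and |trough| reaches the 99th percentile of the
  absolute filtered signal over the whole recording.  The percentile is
  per-recording (one saturating anesthetic episode), applied to the trough
  (onset and duration are defined on the negative phase); a trough-to-peak
  alternative is exposed.  Wave frequency is 1/(onset-to-next-onset).
  Crossing times are linearly interpolated between samples.
* **RS intervals**: "8 nearest beats" is implemented as 4 preceding + 4
  following the onset (a beat coincident with the onset counts as
  preceding, RS₋₁ = 0); a strict nearest-by-absolute-offset mode is
  config-selectable.  RS₋₁ values exceeding the window's mean heart period
  are excluded from the histogram, not clipped (excess counts logged).
* **Entropy sign convention**: SH is computed as −Σ P ln P (natural log),
  so SH_P = SH/ln N lands in [0, 1] with SH_P = 0 at perfect coupling.
* **Surrogates**: the canonical single-histogram calibration bins each 200-draw
  uniform series once into 10 bins; Monte-Carlo and the χ²₉ second-order
  expansion agree at 0.9693/0.9697.  Binning the same draws through
  40-value windows instead yields means near 0.948 — a different
  finite-sample bias — so the windowed surrogate is the default
  null for hypothesis tests on the subject-mean statistic, while the
  single-histogram mode reproduces the canonical 0.970 threshold.
* **Time-locked averages** epoch ±2 s around onsets; the ECG is band
  filtered 0.5–1.5 Hz (configurable; 0.5–4 Hz is the common alternative)
  *before* epoching, and the reported peak lag is the maximum of the
  band-filtered average within [−1, 0) s.
* **Clinical preprocessing**: off-scale HR set missing first, then a
  centered, missing-aware 24-sample (2-min) moving median per patient; the
  operation is idempotent.  The mixed model is fit by REML with Wald
  intervals.  Because the median filter makes neighbouring samples share
  23/24 of their window — residuals become strongly autocorrelated and
  naive per-sample fitting understates standard errors several-fold — the
  fit thins to one sample per 2-minute window and drops the half-window
  record edges (where the centered median is truncated and systematically
  biased on monotone trajectories).  `thin_s=None` restores the
  every-sample fit.

## Problem sizes

Tests and the acceptance script simulate volunteers at quarter-length
phases (29 min/recording): 16 subjects for dose-response and R-amplitude
recovery, 8 fully coupled subjects for the lag recovery, 50 clinical
replicates for coefficient-coverage checks.  These sizes were chosen as the
smallest at which the recovered quantities stabilise well inside their
validation tolerances.

## What the synthetic validation does not show

The generator produces clean, stationary, single-channel signals: no
electrode artifacts, movement, ectopy, or drifting noise floors; ECG
morphology is a fixed template (no QT modulation, no morphological
variability); EEG has no spindles, alpha, burst suppression, or
multi-channel structure, and slow waves arrive as isolated events rather
than continuous deep-anesthesia trains.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generative
assumptions — not robustness to real-recording pathologies, for which the
artifact filters here (refractory period, RR cleaning, percentile
thresholds, median smoothing) are standard but untested against real data.
The entropy test's sensitivity depends on the coupling model used (fixed
lag after the preceding beat); other coupling geometries would need their
own power analysis.
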