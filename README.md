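# corticocardiac

Analysis toolkit for the cardiac side-effects of propofol anesthesia and
their coupling to cortical slow waves, built for two study designs:

* a **volunteer arm**: single-channel ECG (500 Hz) and frontal EEG (100 Hz)
  recorded through a slow propofol effect-site concentration ramp
  (0 → 4 μg/ml → 0), from which the package tracks heart rate, R-wave
  amplitude, heart-rate variability, individual slow waves, and the timing
  relationship between heartbeats and slow-wave onsets;
* a **clinical arm**: long-format tables of heart rate sampled every 5 s
  with propofol/fentanyl/desflurane effect-site concentrations and
  demographics, modelled with a linear mixed-effects regression.

Because raw recordings of this kind are rarely shareable, the package ships
a synthetic coupled-physiology generator with known ground truth
(`synthetic` module).  Every analysis is validated by parameter recovery
against that ground truth.

## The statistics at the core

**Cortico-cardiac coupling test.**  For each detected slow wave (onset =
initial downward zero crossing of the 0.5–4 Hz EEG), the offsets of the 8
nearest heartbeats are collected; RS₋₁ is the interval from the immediately
preceding R-peak to the onset.  Over a moving window of 40 waves, the RS₋₁
values are placed in a 10-bin histogram with outer limits 0 and the window's
mean heart period, and scored by the proportional Shannon entropy

```
SH  = −Σ_b P_b ln P_b        SH_max = ln N        SH_P = SH / SH_max
```

SH_P = 0 under perfect phase-locking and SH_P = 1 when heartbeats are
uniformly spread through the cardiac cycle.  Significance is calibrated
against surrogate series of uniform random numbers: 10,000 series of 200
draws each, one histogram per series, whose 0.1st percentile (≈ 0.970)
is the P = 0.001 decision threshold.  A bias-matched surrogate mode that
mirrors the 40-wave windowing of the subject statistic is also provided
and is the default for hypothesis tests on synthetic cohorts.

**Clinical mixed model.**

```
HR [bpm] = β0 + β1·age + β2·BMI + β3·ASA + β4·(sex=F)
         + β5·prop + β6·fent + β7·des
         + β8·prop·fent + β9·prop·des + β10·fent·des + (1 | patient)
```

fit by REML with Wald 95% intervals after artifact exclusion
(HR outside 10–250 bpm) and a centered 2-minute moving-median smoothing.

## Worked example

```python
import corticocardiac as cc

cfg = cc.VolunteerSimConfig(phase_scale=0.25, seed=2, sw_coupling_prob=1.0)
rec   = cc.simulate_volunteer(cfg)               # ECG + EEG + ground truth
beats = cc.detect_r_peaks(rec.ecg)               # R-peak times/amplitudes
eeg   = cc.preprocess_eeg(rec.eeg)               # 0.5-45 Hz, 100 Hz
waves = cc.detect_slow_waves(eeg)                # individual slow waves

ent = cc.windowed_entropy(cc.rs_intervals(beats, waves), beats)
cal = cc.surrogate_threshold(seed=1)             # single-histogram calibration
tla = cc.time_locked_average(rec.ecg, eeg, waves)
print(f"waves: {len(waves)}  mean SH_P: {ent.subject_mean_shp:.3f}  "
      f"threshold: {cal.threshold:.3f}  ECG peak lag: {tla.peak_lag*1000:.0f} ms")
```

prints

```
waves: 100  mean SH_P: 0.122  threshold: 0.969  ECG peak lag: -448 ms
```

i.e. on a fully coupled recording the windowed entropy (0.122) falls far
below the uniform-null threshold (0.969) — heartbeat timings are
concentrated in the slow-wave cycle — and the band-filtered ECG averaged
around slow-wave onsets peaks 448 ms before the onset, recovering the
configured 447 ms coupling lag.

The same chain runs end to end with
`corticocardiac run-all --seed 1 --out run1/` (see `corticocardiac --help`
for the individual subcommands), writing segment tables, event lists,
entropy and surrogate results, and a key-value summary.

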