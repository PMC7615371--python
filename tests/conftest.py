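"""Shared fixtures: small simulated recordings reused across test modules.

Recordings use quarter-length phases (2.5/12/2.5/12 min) so one simulation
carries the full awake → induction → peak → emergence structure at a size
the whole suite can afford to re-analyse repeatedly.
"""

from __future__ import annotations

import numpy as np
import pytest

import corticocardiac as cc

PHASE_SCALE = 0.25


@pytest.fixture(scope="session")
def vol_default():
    """Default-config volunteer recording with detections run once."""
    cfg = cc.VolunteerSimConfig(phase_scale=PHASE_SCALE, seed=1)
    rec = cc.simulate_volunteer(cfg)
    beats = cc.detect_r_peaks(rec.ecg)
    eeg = cc.preprocess_eeg(rec.eeg)
    waves = cc.detect_slow_waves(eeg)
    return {"cfg": cfg, "rec": rec, "beats": beats, "eeg": eeg, "waves": waves}


@pytest.fixture(scope="session")
def vol_coupled():
    """Fully coupled (κ=1) volunteer recording with detections."""
    cfg = cc.VolunteerSimConfig(phase_scale=PHASE_SCALE, seed=2,
                                sw_coupling_prob=1.0)
    rec = cc.simulate_volunteer(cfg)
    beats = cc.detect_r_peaks(rec.ecg)
    eeg = cc.preprocess_eeg(rec.eeg)
    waves = cc.detect_slow_waves(eeg)
    return {"cfg": cfg, "rec": rec, "beats": beats, "eeg": eeg, "waves": waves}


def match_events(detected: np.ndarray, truth: np.ndarray, tol: float
                 ) -> tuple[float, float]:
    """(recall, precision) of detected event times against ground truth."""
    if detected.size == 0 or truth.size == 0:
        return 0.0, 0.0
    d = np.abs(detected[:, None] - truth[None, :])
    recall = float((d.min(axis=0) < tol).mean())
    precision = float((d.min(axis=1) < tol).mean())
    return recall, precision


@pytest.fixture
def segment_ce():
    """Per-5-min-segment mean concentration for a config."""
    def _seg(cfg: cc.VolunteerSimConfig, n: int) -> np.ndarray:
        t = np.arange(int(cfg.total_duration), dtype=float)
        _, ce = cc.segment_means(t, cfg.ce_at(t), 0.0, cfg.total_duration)
        return ce[:n]
    return _seg
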