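"""Shared fixtures: synthetic sessions generated once per test run."""

import numpy as np
import pytest

import respgamma as rg


@pytest.fixture(scope="session")
def wake_session_300():
    """300-s wake-only session at 1000 Hz: 1-Hz respiration (cycle CV 0.1),
    one exhalation-locked 40-Hz burst per breath at 3x the detection
    threshold, kappa=2 phase locking."""
    cfg = rg.GenConfig(duration_s=300.0, fs_hz=1000.0, seed=1)
    schedule = rg.StateSchedule([(0.0, 300.0, "wake")])
    traces, truth = rg.generate_session(cfg, schedule)
    return cfg, schedule, traces, truth


@pytest.fixture(scope="session")
def mixed_session():
    """400-s session at 500 Hz with a clearly separated wake/NREM/REM
    schedule aligned to 20-s epoch boundaries."""
    cfg = rg.GenConfig(duration_s=400.0, fs_hz=500.0, seed=2)
    schedule = rg.StateSchedule([(0.0, 240.0, "wake"),
                                 (240.0, 340.0, "NREM"),
                                 (340.0, 400.0, "REM")])
    traces, truth = rg.generate_session(cfg, schedule)
    return cfg, schedule, traces, truth


@pytest.fixture(scope="session")
def gamma_locked_unit():
    """Spike train strongly locked to the trough of a pure 40-Hz
    oscillation (von Mises kappa=4, 2-ms refractory, >= 500 spikes)."""
    fs = 1000.0
    t = np.arange(int(120 * fs)) / fs
    lfp = rg.Trace(100 * np.sin(2 * np.pi * 40 * t), fs, "mPFC")
    params = rg.SpikeGenParams(base_rate_hz=20.0, gamma_kappa=4.0, seed=1)
    spikes = rg.generate_spikes(lfp, None, params)
    return lfp, params, spikes


def match_events(detected: np.ndarray, truth: np.ndarray,
                 tol_s: float) -> tuple[float, float]:
    """Greedy one-to-one matching; returns (recall, precision)."""
    detected = np.sort(np.asarray(detected, float))
    truth = np.sort(np.asarray(truth, float))
    used = np.zeros(len(detected), bool)
    hits = 0
    for t in truth:
        if len(detected) == 0:
            break
        i = int(np.argmin(np.where(used, np.inf, np.abs(detected - t))))
        if not used[i] and abs(detected[i] - t) <= tol_s:
            used[i] = True
            hits += 1
    recall = hits / len(truth) if len(truth) else 1.0
    precision = hits / len(detected) if len(detected) else 1.0
    return recall, precision
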