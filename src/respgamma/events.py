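"""Detection of gamma bursts, sleep spindles and slow waves.

Gamma bursts are peaks of the sliding-window RMS of the 30-55 Hz band-passed
prefrontal signal (25 uV threshold, wake only).  Spindles are
supra-threshold episodes of 10-15 Hz power within NREM, revised by the fixed
drop-short / merge / drop-long sequence.  Slow waves are high-amplitude
narrow peaks of the 1-8 Hz signal in NREM bracketed by zero crossings that
mark DOWN-state onset and UP-state onset.  Each burst can be assigned the
phase of the respiration-related potential by linear interpolation between
the troughs of the slow LFP envelope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal, stats

from .core import (Trace, StateSchedule, bandpass, lowpass, decimate_to,
                   sliding_rms, moving_average_detrend, contiguous_regions)
from .sleepstate import StateLabels

GAMMA_BAND = (30.0, 55.0)
BURST_RMS_TAU_S = 0.025
BURST_THRESHOLD_UV = 25.0
BURST_MIN_SEPARATION_S = 0.2
SPINDLE_BAND = (10.0, 15.0)
SPINDLE_MIN_S = 0.3
SPINDLE_MERGE_S = 0.3
SPINDLE_MAX_S = 3.0
SLOW_WAVE_MIN_UV = 150.0
SLOW_WAVE_MAX_WIDTH_S = 0.2
SLOW_WAVE_CROSSING_S = 0.25


def _state_mask(states, fs: float, n: int, state: str) -> np.ndarray:
    """Sample mask for a state from StateLabels, StateSchedule or None."""
    if states is None:
        return np.ones(n, dtype=bool)
    if isinstance(states, (StateLabels, StateSchedule)):
        return states.mask(state, fs, n)
    raise TypeError(f"unsupported state container {type(states)!r}")


# ---------------------------------------------------------------------------
# gamma bursts
# ---------------------------------------------------------------------------

def gamma_rms(mpfc: Trace, band: tuple[float, float] = GAMMA_BAND,
              tau_s: float = BURST_RMS_TAU_S) -> Trace:
    """30-55 Hz band-passed signal RMS with a centred 25-ms sliding window,
    on the 1000-Hz decimated trace."""
    if mpfc.fs < 1000:
        raise ValueError("gamma burst detection requires fs >= 1000 Hz")
    tr = decimate_to(mpfc, 1000.0)
    filt = bandpass(tr.data, tr.fs, *band)
    return tr.copy_with(sliding_rms(filt, tr.fs, tau_s))


def detect_gamma_bursts(mpfc: Trace, states=None,
                        threshold_uv: float = BURST_THRESHOLD_UV,
                        min_separation_s: float = BURST_MIN_SEPARATION_S
                        ) -> pd.DataFrame:
    """Gamma bursts as supra-threshold RMS peaks within wake epochs.

    Returns a table with ``t_peak_s``, ``rms_peak_uv``, ``duration_ms``,
    ``t_start_s``, ``t_end_s`` and ``state``.  Competing peaks closer than
    ``min_separation_s`` are resolved in favour of the larger one.
    """
    rms = gamma_rms(mpfc)
    fs = rms.fs
    wake = _state_mask(states, fs, rms.n, "wake")
    peaks, props = signal.find_peaks(rms.data, height=threshold_uv,
                                     distance=max(int(min_separation_s * fs), 1))
    keep = wake[peaks]
    peaks, heights = peaks[keep], props["peak_heights"][keep]
    above = rms.data >= threshold_uv
    regions = contiguous_regions(above)
    starts = np.array([r[0] for r in regions], dtype=int)
    stops = np.array([r[1] for r in regions], dtype=int)
    rows = []
    for p, h in zip(peaks, heights):
        ri = np.searchsorted(starts, p, side="right") - 1
        s, e = (starts[ri], stops[ri]) if ri >= 0 and p < stops[ri] else (p, p + 1)
        rows.append({
            "t_peak_s": p / fs,
            "rms_peak_uv": h,
            "t_start_s": s / fs,
            "t_end_s": e / fs,
            "duration_ms": (e - s) / fs * 1000.0,
            "state": "wake",
        })
    return pd.DataFrame(rows, columns=["t_peak_s", "rms_peak_uv", "t_start_s",
                                       "t_end_s", "duration_ms", "state"])


def assign_rr_phase(event_times_s: np.ndarray, mpfc: Trace
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Phase of the respiration-related potential at each event time.

    The mPFC signal is decimated to 100 Hz and lowpassed below 5 Hz; troughs
    of the slow envelope define consecutive 0-to-2pi periods, and event times
    are mapped linearly within their enclosing trough-to-trough interval.
    Events before the first or after the last trough are dropped.

    Returns ``(phases_rad, kept_event_times)``.
    """
    low = decimate_to(mpfc, 100.0) if mpfc.fs > 100 else mpfc
    slow = lowpass(low.data, low.fs, 5.0)
    troughs, _ = signal.find_peaks(-slow,
                                   distance=max(int(0.1 * low.fs), 1))
    if len(troughs) < 2:
        raise ValueError("fewer than 2 troughs in the slow envelope")
    trough_t = troughs / low.fs
    ev = np.asarray(event_times_s, float)
    inside = (ev >= trough_t[0]) & (ev < trough_t[-1])
    ev = ev[inside]
    idx = np.searchsorted(trough_t, ev, side="right") - 1
    frac = (ev - trough_t[idx]) / (trough_t[idx + 1] - trough_t[idx])
    return 2 * np.pi * frac, ev


# ---------------------------------------------------------------------------
# spindles
# ---------------------------------------------------------------------------

def _revise_intervals(intervals: list[tuple[float, float]],
                      min_s: float = SPINDLE_MIN_S,
                      merge_s: float = SPINDLE_MERGE_S,
                      max_s: float = SPINDLE_MAX_S
                      ) -> list[tuple[float, float]]:
    """Fixed 3-step revision: drop < min_s, merge gaps < merge_s,
    drop > max_s.  The order is part of the contract."""
    kept = [(s, e) for s, e in intervals if e - s >= min_s]
    merged: list[tuple[float, float]] = []
    for s, e in kept:
        if merged and s - merged[-1][1] < merge_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s <= max_s]


def spindle_power(trace: Trace, band: tuple[float, float] = SPINDLE_BAND
                  ) -> np.ndarray:
    """Squared 10-15 Hz bandpass smoothed with a 100-ms RMS window."""
    filt = bandpass(trace.data, trace.fs, *band)
    return sliding_rms(filt, trace.fs, 0.1) ** 2


def detect_spindles(trace: Trace, states=None, sd_mult: float = 0.5
                    ) -> pd.DataFrame:
    """Spindle episodes: 10-15 Hz power above mean + 0.5 SD (statistics over
    NREM samples), revised by drop-short, merge, drop-long."""
    power = spindle_power(trace)
    nrem = _state_mask(states, trace.fs, trace.n, "NREM")
    if not nrem.any():
        return pd.DataFrame(columns=["t_start_s", "t_end_s", "duration_s",
                                     "peak_power"])
    mu, sd = power[nrem].mean(), power[nrem].std()
    if sd <= 1e-12 * max(mu, 1.0):  # constant power: nothing to detect
        return pd.DataFrame(columns=["t_start_s", "t_end_s", "duration_s",
                                     "peak_power"])
    above = (power > mu + sd_mult * sd) & nrem
    intervals = [(s / trace.fs, e / trace.fs)
                 for s, e in contiguous_regions(above)]
    revised = _revise_intervals(intervals)
    rows = [{"t_start_s": s, "t_end_s": e, "duration_s": e - s,
             "peak_power": power[int(s * trace.fs):int(e * trace.fs)].max()}
            for s, e in revised]
    return pd.DataFrame(rows, columns=["t_start_s", "t_end_s", "duration_s",
                                       "peak_power"])


# ---------------------------------------------------------------------------
# slow waves
# ---------------------------------------------------------------------------

def detect_slow_waves(mpfc: Trace, states=None,
                      min_amp_uv: float = SLOW_WAVE_MIN_UV,
                      max_width_s: float = SLOW_WAVE_MAX_WIDTH_S
                      ) -> pd.DataFrame:
    """Slow waves as zero-crossings around high-amplitude narrow peaks.

    The trace is decimated to 100 Hz, detrended by removing a 1-s moving
    average, and band-limited to 1-8 Hz.  Peaks above ``min_amp_uv`` with
    full width at half maximum <= ``max_width_s`` inside NREM are kept when
    a rising zero crossing occurs within 250 ms before the peak (DOWN-state
    onset) and a falling one within 250 ms after (UP-state onset).
    """
    low = decimate_to(mpfc, 100.0) if mpfc.fs > 100 else mpfc
    fs = low.fs
    x = moving_average_detrend(low.data, fs, 1.0)
    x = bandpass(x, fs, 1.0, 8.0)
    nrem = _state_mask(states, fs, low.n, "NREM")
    peaks, _ = signal.find_peaks(x, height=min_amp_uv,
                                 distance=max(int(0.25 * fs), 1))
    if len(peaks):
        widths = signal.peak_widths(x, peaks, rel_height=0.5)[0] / fs
        peaks = peaks[(widths <= max_width_s) & nrem[peaks]]
    win = int(SLOW_WAVE_CROSSING_S * fs)
    rows = []
    for p in peaks:
        pre = x[max(p - win, 0):p + 1]
        post = x[p:min(p + win + 1, low.n)]
        rising = np.where((pre[:-1] <= 0) & (pre[1:] > 0))[0]
        falling = np.where((post[:-1] >= 0) & (post[1:] < 0))[0]
        if len(rising) == 0 or len(falling) == 0:
            continue
        onset = (max(p - win, 0) + rising[-1]) / fs
        offset = (p + falling[0] + 1) / fs
        rows.append({"t_onset_s": onset, "t_peak_s": p / fs,
                     "t_offset_s": offset, "peak_amp_uv": x[p]})
    return pd.DataFrame(rows, columns=["t_onset_s", "t_peak_s", "t_offset_s",
                                       "peak_amp_uv"])


def up_down_gamma(mpfc: Trace, slow_waves: pd.DataFrame,
                  band: tuple[float, float] = GAMMA_BAND,
                  window_s: float = 0.2) -> tuple[pd.DataFrame, dict]:
    """Gamma power in the first 200 ms of each UP state versus the 200 ms of
    the preceding DOWN state, with a paired comparison statistic."""
    if len(slow_waves) == 0:
        return (pd.DataFrame(columns=["t_peak_s", "gamma_up", "gamma_down"]),
                {"n": 0, "statistic": np.nan, "p": np.nan})
    filt = bandpass(mpfc.data, mpfc.fs, *band)
    rows = []
    for _, ev in slow_waves.iterrows():
        i_up = int(ev.t_offset_s * mpfc.fs)
        i_dn = int(ev.t_onset_s * mpfc.fs)
        w = int(window_s * mpfc.fs)
        if i_up + w > mpfc.n or i_dn + w > mpfc.n:
            continue
        rows.append({"t_peak_s": ev.t_peak_s,
                     "gamma_up": float(np.mean(filt[i_up:i_up + w] ** 2)),
                     "gamma_down": float(np.mean(filt[i_dn:i_dn + w] ** 2))})
    table = pd.DataFrame(rows, columns=["t_peak_s", "gamma_up", "gamma_down"])
    if len(table) < 2 or np.allclose(table.gamma_up, table.gamma_down):
        stat = {"n": len(table), "statistic": 0.0,
                "p": 1.0 if len(table) else np.nan}
    else:
        res = stats.ttest_rel(table.gamma_up, table.gamma_down)
        stat = {"n": len(table), "statistic": float(res.statistic),
                "p": float(res.pvalue)}
    return table, stat
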