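"""State-wise spectra, band-power dynamics, coherence and lag analysis.

Welch spectra use 1-s Hann windows with 50% overlap (1-Hz resolution spans
the respiration-related rhythm through gamma).  Wavelet coherence uses the
analytic (complex) Morlet wavelet with boxcar smoothing over 3 scales and
0.25 s, without which magnitude-squared coherence is identically 1.
Cross-correlation lags between gamma-band (30-80 Hz) signals are searched
within +/-50 ms to avoid cycle-skipping onto the ~25 ms gamma side-lobes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal
from scipy.optimize import least_squares

from .core import Trace, bandpass, contiguous_regions
from .events import _state_mask

WELCH_NPERSEG_S = 1.0
GAMMA_XCORR_BAND = (30.0, 80.0)
MAX_LAG_S = 0.05


# ---------------------------------------------------------------------------
# spectra and band power
# ---------------------------------------------------------------------------

@dataclass
class StateSpectrum:
    freqs: np.ndarray
    power: dict[str, np.ndarray]      # state -> mean PSD (uV^2/Hz)
    n_segments: dict[str, int]


def state_spectra(trace: Trace, states,
                  state_names: tuple[str, ...] = ("wake", "NREM", "REM")
                  ) -> StateSpectrum:
    """Welch periodograms accumulated and averaged within each state."""
    nperseg = int(WELCH_NPERSEG_S * trace.fs)
    freqs = np.fft.rfftfreq(nperseg, 1 / trace.fs)
    power: dict[str, np.ndarray] = {}
    n_segments: dict[str, int] = {}
    for state in state_names:
        mask = _state_mask(states, trace.fs, trace.n, state)
        psds, counts = [], 0
        for s, e in contiguous_regions(mask):
            if e - s < 2 * nperseg:
                continue
            f, p = signal.welch(trace.data[s:e], fs=trace.fs,
                                window="hann", nperseg=nperseg,
                                noverlap=nperseg // 2)
            psds.append(p)
            counts += 1
        if counts == 0:
            continue
        power[state] = np.mean(psds, axis=0)
        n_segments[state] = counts
        freqs = f
    return StateSpectrum(freqs=freqs, power=power, n_segments=n_segments)


def band_power_windows(trace: Trace, band: tuple[float, float],
                       states=None, win_s: float = 5.0,
                       sub_s: float = 0.5) -> pd.DataFrame:
    """Band power in non-overlapping windows with the within-window SD.

    Power is the mean square of the band-passed signal per ``win_s`` window;
    the SD is taken over ``sub_s`` sub-block powers, quantifying burstiness
    of band power inside the window.
    """
    if trace.duration_s < win_s:
        raise ValueError("trace shorter than one window")
    filt = bandpass(trace.data, trace.fs, *band)
    per = int(win_s * trace.fs)
    sub = int(sub_s * trace.fs)
    n_win = trace.n // per
    labels = (states.sample_states(trace.fs, trace.n)
              if states is not None else np.full(trace.n, "", dtype=object))
    rows = []
    for i in range(n_win):
        seg = filt[i * per:(i + 1) * per] ** 2
        subs = seg[: (len(seg) // sub) * sub].reshape(-1, sub).mean(axis=1)
        lab = labels[i * per + per // 2]
        rows.append({"t_start_s": i * win_s, "power": float(seg.mean()),
                     "power_sd": float(subs.std()), "state": lab})
    return pd.DataFrame(rows)


def fit_decay(x: np.ndarray, y: np.ndarray) -> tuple[dict, float]:
    """Robust nonlinear least-squares fit of y = a*exp(-b*x) + c.

    Returns the parameter dict and the Pearson correlation between the
    fitted curve and the data.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 10:
        raise ValueError("need at least 10 points")
    span = np.ptp(x) if np.ptp(x) > 0 else 1.0
    p0 = np.array([max(y.max() - y.min(), 1e-9), 1.0 / span, y.min()])

    def resid(p):
        return p[0] * np.exp(-p[1] * x) + p[2] - y

    sol = least_squares(resid, p0, loss="soft_l1",
                        bounds=([0, 0, -np.inf], [np.inf, np.inf, np.inf]))
    if not sol.success:
        raise RuntimeError(f"decay fit did not converge: {sol.message}")
    a, b, c = sol.x
    fit = a * np.exp(-b * x) + c
    if np.std(fit) < 1e-12 or np.std(y) < 1e-12:
        r = 0.0
    else:
        r = float(np.corrcoef(fit, y)[0, 1])
    return {"a": float(a), "b": float(b), "c": float(c)}, r


# ---------------------------------------------------------------------------
# coherence
# ---------------------------------------------------------------------------

def welch_coherence(a: Trace, b: Trace,
                    segments: list[tuple[float, float]] | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence per segment, averaged over segments.

    Each segment must span at least 8 Welch windows (1-s Hann, 50% overlap);
    with a single averaging window coherence degenerates to 1.
    """
    if a.fs != b.fs or a.n != b.n:
        raise ValueError("traces must share sampling rate and duration")
    nperseg = int(WELCH_NPERSEG_S * a.fs)
    if segments is None:
        segments = [(0.0, a.duration_s)]
    cohs = []
    for s0, s1 in segments:
        i0, i1 = int(s0 * a.fs), int(s1 * a.fs)
        n_windows = max((i1 - i0 - nperseg // 2) // (nperseg // 2), 0)
        if n_windows < 8:
            raise ValueError("segment supports fewer than 8 averaging windows")
        f, c = signal.coherence(a.data[i0:i1], b.data[i0:i1], fs=a.fs,
                                window="hann", nperseg=nperseg,
                                noverlap=nperseg // 2)
        cohs.append(c)
    return f, np.mean(cohs, axis=0)


def coherence_product(coh1: np.ndarray, coh2: np.ndarray) -> np.ndarray:
    """Frequency-wise product of two mean coherence functions, highlighting
    peaks common to both signal pairs."""
    return np.asarray(coh1) * np.asarray(coh2)


def _morlet_cwt(x: np.ndarray, fs: float, freqs: np.ndarray) -> np.ndarray:
    wavelet = "cmor1.5-1.0"
    fc = pywt.central_frequency(wavelet)
    scales = fc * fs / freqs
    coeffs, _ = pywt.cwt(x, scales, wavelet, sampling_period=1 / fs)
    return coeffs


def _smooth(m: np.ndarray, n_scales: int, n_time: int) -> np.ndarray:
    k_t = np.ones(max(n_time, 1)) / max(n_time, 1)
    out = np.apply_along_axis(
        lambda r: np.convolve(r, k_t, mode="same"), 1, m)
    k_s = np.ones(max(n_scales, 1)) / max(n_scales, 1)
    return np.apply_along_axis(
        lambda c: np.convolve(c, k_s, mode="same"), 0, out)


def wavelet_coherence(a: np.ndarray, b: np.ndarray, fs: float,
                      freqs: np.ndarray) -> np.ndarray:
    """Analytic-Morlet wavelet coherence, smoothed with a boxcar over 3
    scales and 0.25 s (values in [0, 1])."""
    wa = _morlet_cwt(a, fs, freqs)
    wb = _morlet_cwt(b, fs, freqs)
    n_time = int(0.25 * fs)
    sab = _smooth(wa * np.conj(wb), 3, n_time)
    saa = _smooth(np.abs(wa) ** 2, 3, n_time)
    sbb = _smooth(np.abs(wb) ** 2, 3, n_time)
    coh = np.abs(sab) ** 2 / np.maximum(saa * sbb, 1e-300)
    return np.clip(coh, 0.0, 1.0)


def exhalation_triggered_coherence(a: Trace, b: Trace,
                                   exhal_onsets: np.ndarray,
                                   window_s: float = 2.5,
                                   freqs: np.ndarray | None = None
                                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean wavelet coherence in windows centred on exhalation onsets.

    Onsets whose window would leave the recording are skipped; at least 10
    usable onsets are required.  Returns ``(t_axis, freqs, mean_coherence)``
    with t = 0 at exhalation onset.
    """
    if a.fs != b.fs or a.n != b.n:
        raise ValueError("traces must share sampling rate and duration")
    if freqs is None:
        freqs = np.geomspace(2.0, 60.0, 30)
    fs = a.fs
    half = int(window_s / 2 * fs)
    usable = [t for t in np.asarray(exhal_onsets)
              if int(t * fs) - half >= 0 and int(t * fs) + half <= a.n]
    if len(usable) < 10:
        raise ValueError("need at least 10 exhalation onsets fully inside "
                         "the recording")
    acc = None
    for t0 in usable:
        i = int(t0 * fs)
        coh = wavelet_coherence(a.data[i - half:i + half],
                                b.data[i - half:i + half], fs, freqs)
        acc = coh if acc is None else acc + coh
    mean_coh = acc / len(usable)
    t_axis = (np.arange(2 * half) - half) / fs
    return t_axis, np.asarray(freqs), mean_coh


# ---------------------------------------------------------------------------
# cross-correlation lags
# ---------------------------------------------------------------------------

@dataclass
class LagResult:
    """Lag of the highest positive cross-correlogram peak.

    ``lag_ms`` is positive when the first signal leads the second.
    """

    pair: str
    state: str
    lag_ms: float
    peak_correlation: float
    reliable: bool


def gamma_xcorr_lag(a: Trace, b: Trace,
                    band: tuple[float, float] = GAMMA_XCORR_BAND,
                    max_lag_s: float = MAX_LAG_S,
                    pair: str = "", state: str = "") -> LagResult:
    """Normalized cross-correlation of gamma-band signals and the lag of its
    highest positive peak within +/-``max_lag_s``.

    Segments of 200-500 s match the intended use; shorter inputs are
    accepted.  When no positive peak exists, or the peak correlation is
    within chance level (3/sqrt(n)), the result is flagged unreliable with
    lag NaN.
    """
    if a.fs != b.fs or a.n != b.n:
        raise ValueError("traces must share sampling rate and duration")
    hi = min(band[1], a.fs / 2 * 0.9)
    xa = bandpass(a.data, a.fs, band[0], hi)
    xb = bandpass(b.data, b.fs, band[0], hi)
    xa = (xa - xa.mean()) / (xa.std() or 1.0)
    xb = (xb - xb.mean()) / (xb.std() or 1.0)
    max_lag = int(max_lag_s * a.fs)
    full = signal.correlate(xa, xb, mode="full", method="fft") / a.n
    lags = np.arange(-(a.n - 1), a.n)
    sel = np.abs(lags) <= max_lag
    cc, ll = full[sel], lags[sel]
    # correlate peaks at negative index when b is a delayed copy of a;
    # negate so that positive lag means "a leads b"
    peaks, _ = signal.find_peaks(cc)
    if cc.argmax() in (0, len(cc) - 1) or len(peaks) == 0:
        peaks = np.append(peaks, cc.argmax()).astype(int)
    pos = peaks[cc[peaks] > 0]
    # chance level uses the effective sample count of the band-limited
    # signals (2 * bandwidth / fs independent samples per point)
    n_eff = max(a.n * 2 * (hi - band[0]) / a.fs, 4.0)
    chance = 3.0 / np.sqrt(n_eff)
    if len(pos) == 0:
        return LagResult(pair, state, np.nan, float(cc.max()), False)
    best = pos[np.argmax(cc[pos])]
    lag_ms = -ll[best] / a.fs * 1000.0
    return LagResult(pair, state, float(lag_ms), float(cc[best]),
                     bool(cc[best] > chance))
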