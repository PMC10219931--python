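"""Core signal containers and filtering primitives.

All extracellular signals are carried as :class:`Trace` objects in microvolts,
membrane potential in millivolts, injected current in nanoamperes, and time in
seconds from the start of the recording.  Filtering is zero-phase throughout
(forward-backward Butterworth) so that event timing is preserved for the
downstream phase analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal


@dataclass
class Trace:
    """One uniformly sampled signal.

    Parameters
    ----------
    data : ndarray
        Sample values.
    fs : float
        Sampling rate in Hz.
    label : str
        Channel label (e.g. ``"mPFC"``, ``"RESP"``).
    units : str
        Physical units of ``data`` (``"uV"``, ``"mV"``, ``"nA"``, ``"V"``).
    """

    data: np.ndarray
    fs: float
    label: str = ""
    units: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("Trace data must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.data.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def copy_with(self, data: np.ndarray, fs: float | None = None) -> "Trace":
        return replace(self, data=np.asarray(data, float),
                       fs=self.fs if fs is None else fs)


@dataclass
class StateSchedule:
    """Ordered, contiguous (start_s, end_s, state) segments covering a session.

    States are ``"wake"``, ``"NREM"`` or ``"REM"``.
    """

    segments: list[tuple[float, float, str]] = field(default_factory=list)

    VALID_STATES = ("wake", "NREM", "REM")

    def __post_init__(self) -> None:
        prev_end = None
        for start, end, state in self.segments:
            if state not in self.VALID_STATES:
                raise ValueError(f"unknown state {state!r}")
            if end <= start:
                raise ValueError("segment end must exceed start")
            if prev_end is not None and abs(start - prev_end) > 1e-9:
                raise ValueError("segments must be contiguous and ordered")
            prev_end = end

    @property
    def duration_s(self) -> float:
        return self.segments[-1][1] if self.segments else 0.0

    def state_at(self, t: float) -> str:
        for start, end, state in self.segments:
            if start <= t < end:
                return state
        raise ValueError(f"time {t} outside schedule")

    def sample_states(self, fs: float, n: int) -> np.ndarray:
        """State label per sample (object array of strings)."""
        out = np.empty(n, dtype=object)
        for start, end, state in self.segments:
            i0 = int(round(start * fs))
            i1 = min(int(round(end * fs)), n)
            out[i0:i1] = state
        # samples past the last segment inherit its state
        if self.segments:
            i1 = int(round(self.segments[-1][1] * fs))
            if i1 < n:
                out[i1:] = self.segments[-1][2]
        return out

    def mask(self, state: str, fs: float, n: int) -> np.ndarray:
        return self.sample_states(fs, n) == state


# ---------------------------------------------------------------------------
# filtering primitives
# ---------------------------------------------------------------------------

def bandpass(x: np.ndarray, fs: float, lo: float, hi: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass."""
    nyq = fs / 2.0
    if not (0 < lo < hi):
        raise ValueError(f"invalid band ({lo}, {hi})")
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def lowpass(x: np.ndarray, fs: float, hi: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth lowpass."""
    if not (0 < hi < fs / 2.0):
        raise ValueError(f"cutoff {hi} Hz outside (0, Nyquist)")
    sos = signal.butter(order, hi, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def decimate_to(trace: Trace, fs_new: float) -> Trace:
    """Downsample with anti-aliasing to ``fs_new`` (8th-order Chebyshev AA
    filter for integer factors, polyphase FIR otherwise)."""
    if fs_new > trace.fs:
        raise ValueError("decimate_to cannot upsample")
    if abs(fs_new - trace.fs) < 1e-9:
        return trace
    ratio = trace.fs / fs_new
    if abs(ratio - round(ratio)) < 1e-9:
        q = int(round(ratio))
        y = trace.data
        # cascade decimation for large factors to keep the IIR filter stable
        while q > 12:
            for f in (10, 8, 6, 5, 4, 3, 2):
                if q % f == 0:
                    y = signal.decimate(y, f, zero_phase=True)
                    q //= f
                    break
            else:
                break
        if q > 1:
            y = signal.decimate(y, q, zero_phase=True)
        return trace.copy_with(y, fs=fs_new)
    from fractions import Fraction
    frac = Fraction(fs_new / trace.fs).limit_denominator(1000)
    y = signal.resample_poly(trace.data, frac.numerator, frac.denominator)
    return trace.copy_with(y, fs=fs_new)


def sliding_rms(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Centered sliding-window RMS (boxcar of ``window_s`` seconds)."""
    w = max(int(round(window_s * fs)), 1)
    kernel = np.ones(w) / w
    ms = np.convolve(x ** 2, kernel, mode="same")
    return np.sqrt(np.maximum(ms, 0.0))


def moving_average_detrend(x: np.ndarray, fs: float, tau_s: float) -> np.ndarray:
    """Subtract a ``tau_s``-second moving average (the "DC remove" step)."""
    w = max(int(round(tau_s * fs)), 1)
    kernel = np.ones(w) / w
    baseline = np.convolve(x, kernel, mode="same")
    return x - baseline


def contiguous_regions(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges where ``mask`` is True."""
    mask = np.asarray(mask, bool)
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    stops = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))
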