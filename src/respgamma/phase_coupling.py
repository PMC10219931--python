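"""Phase-amplitude coupling and circular statistics.

Instantaneous phase and amplitude come from the analytic signal of the
zero-phase band-passed trace.  The modulation index (MI) is the
Kullback-Leibler divergence of the phase-binned, normalised amplitude
profile from the uniform distribution, divided by log(N); MI is 0 for a
flat profile and 1 when all amplitude falls in a single bin.  MI uses 18
phase bins; 360-bin profiles are kept for plotting.  Comodulograms scan MI
over 1-Hz-wide phase bands (0.2-5 Hz by default) against amplitude bands
spanning 25-60 Hz.  Phase-locking of event times is quantified by the mean
resultant vector and the Rayleigh uniformity test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import Trace, bandpass, lowpass

MI_N_BINS = 18
PROFILE_N_BINS = 360
DEFAULT_MI_PHASE_BAND = (0.2, 2.5)
DEFAULT_MI_AMP_BAND = (30.0, 60.0)
COMOD_PHASE_RANGE = (0.2, 5.0)
COMOD_AMP_RANGE = (25.0, 60.0)


def analytic_phase_amp(trace: Trace, band: tuple[float, float]
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase (radians, [-pi, pi]) and amplitude envelope of
    the band-passed analytic signal."""
    lo, hi = band
    if hi >= trace.fs / 2:
        raise ValueError(f"band edge {hi} Hz exceeds Nyquist")
    filt = bandpass(trace.data, trace.fs, lo, hi)
    analytic = signal.hilbert(filt)
    return np.angle(analytic), np.abs(analytic)


def phase_binned_profile(phase: np.ndarray, amp: np.ndarray,
                         n_bins: int = PROFILE_N_BINS
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Mean amplitude per phase bin over uniform bins spanning [-pi, pi].

    Empty bins are returned as NaN.  Returns ``(bin_centers, profile)``.
    """
    phase = np.asarray(phase, float)
    amp = np.asarray(amp, float)
    if phase.shape != amp.shape:
        raise ValueError("phase and amplitude series must be equal length")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=amp, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, profile


def modulation_index(profile: np.ndarray) -> float:
    """Tort modulation index of a phase-binned amplitude profile.

    MI = (log N - H(p)) / log N where p is the profile normalised to sum 1
    and H its Shannon entropy (natural log).  Empty (NaN) bins contribute
    zero amplitude, with the 0*log0 := 0 convention.
    """
    p = np.asarray(profile, float).copy()
    p[~np.isfinite(p)] = 0.0
    if np.any(p < 0):
        raise ValueError("profile must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("profile has zero total amplitude")
    p = p / total
    nz = p > 0
    h = -np.sum(p[nz] * np.log(p[nz]))
    n = len(p)
    return float(np.clip((np.log(n) - h) / np.log(n), 0.0, 1.0))


def pac_mi(trace: Trace,
           phase_band: tuple[float, float] = DEFAULT_MI_PHASE_BAND,
           amp_band: tuple[float, float] = DEFAULT_MI_AMP_BAND,
           n_bins: int = MI_N_BINS) -> float:
    """Modulation index between a slow phase band and a fast amplitude band
    of the same trace."""
    phase, _ = analytic_phase_amp(trace, phase_band)
    _, amp = analytic_phase_amp(trace, amp_band)
    _, profile = phase_binned_profile(phase, amp, n_bins)
    return modulation_index(profile)


@dataclass
class Comodulogram:
    """MI over a grid of (phase band, amplitude band) pairs."""

    mi: np.ndarray                      # [n_phase_bands, n_amp_bands]
    phase_bands: list[tuple[float, float]]
    amp_bands: list[tuple[float, float]]

    def argmax_bands(self) -> tuple[tuple[float, float], tuple[float, float]]:
        i, j = np.unravel_index(np.argmax(self.mi), self.mi.shape)
        return self.phase_bands[i], self.amp_bands[j]


def _band_grid(lo: float, hi: float, width: float) -> list[tuple[float, float]]:
    out = []
    a = lo
    while a + width <= hi + 1e-9:
        out.append((round(a, 3), round(a + width, 3)))
        a += width
    return out


def comodulogram(trace: Trace,
                 phase_bands: list[tuple[float, float]] | None = None,
                 amp_bands: list[tuple[float, float]] | None = None,
                 n_bins: int = MI_N_BINS) -> Comodulogram:
    """MI matrix over phase-band x amplitude-band pairs (defaults: 1-Hz-wide
    phase bands over 0.2-5 Hz, 5-Hz-wide amplitude bands over 25-60 Hz)."""
    if phase_bands is None:
        phase_bands = _band_grid(*COMOD_PHASE_RANGE, 1.0)
    if amp_bands is None:
        amp_bands = _band_grid(*COMOD_AMP_RANGE, 5.0)
    amps = [analytic_phase_amp(trace, b)[1] for b in amp_bands]
    mi = np.zeros((len(phase_bands), len(amp_bands)))
    for i, pb in enumerate(phase_bands):
        phase, _ = analytic_phase_amp(trace, pb)
        for j, amp in enumerate(amps):
            _, prof = phase_binned_profile(phase, amp, n_bins)
            mi[i, j] = modulation_index(prof)
    return Comodulogram(mi, list(phase_bands), list(amp_bands))


def pac_surrogate_threshold(trace: Trace, phase_band, amp_band,
                            n_surrogates: int = 200, min_shift_s: float = 1.0,
                            quantile: float = 0.95, seed: int = 0,
                            n_bins: int = MI_N_BINS) -> float:
    """Surrogate MI threshold from circular time-shifts of the amplitude
    series (uniform offsets of at least ``min_shift_s``), preserving the
    autocorrelation of both series."""
    rng = np.random.default_rng(seed)
    phase, _ = analytic_phase_amp(trace, phase_band)
    _, amp = analytic_phase_amp(trace, amp_band)
    n = len(amp)
    min_shift = int(min_shift_s * trace.fs)
    if n <= 2 * min_shift:
        raise ValueError("trace too short for the surrogate shift range")
    vals = np.empty(n_surrogates)
    for k in range(n_surrogates):
        shift = rng.integers(min_shift, n - min_shift)
        _, prof = phase_binned_profile(phase, np.roll(amp, shift), n_bins)
        vals[k] = modulation_index(prof)
    return float(np.quantile(vals, quantile))


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

@dataclass
class CircStatResult:
    """Mean direction, resultant length and Rayleigh uniformity p-value."""

    mean_angle_rad: float
    resultant_length: float
    n: int
    p_rayleigh: float


def rayleigh(phases: np.ndarray) -> CircStatResult:
    """Rayleigh test of circular uniformity.

    Uses the small-sample-corrected approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - (n R)^2)) - (1 + 2n)).
    """
    phases = np.asarray(phases, float)
    if phases.size < 3:
        raise ValueError("Rayleigh test requires at least 3 phases")
    if not np.all(np.isfinite(phases)):
        raise ValueError("phases must be finite")
    n = phases.size
    c, s = np.cos(phases).sum(), np.sin(phases).sum()
    r = np.hypot(c, s) / n
    rn = r * n
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n ** 2 - rn ** 2)) - (1 + 2 * n))
    p = float(np.clip(p, 1e-300, 1.0))  # keep p in (0, 1] despite underflow
    return CircStatResult(mean_angle_rad=float(np.arctan2(s, c)),
                          resultant_length=float(min(r, 1.0)), n=int(n),
                          p_rayleigh=p)


# ---------------------------------------------------------------------------
# respiration phase
# ---------------------------------------------------------------------------

def respiration_phase(resp: Trace, convention: str = "thermocouple"
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous respiration phase with 0 rad at exhalation onset.

    The signal is lowpassed below 5 Hz and the Hilbert angle taken; the
    phase is rotated so that detected exhalation onsets (rising
    mean-crossings for a thermocouple, falling for a piezo sensor) sit at
    phase 0.  Returns ``(phase_per_sample, exhalation_onset_times)``.
    """
    if convention not in ("thermocouple", "piezo"):
        raise ValueError(f"unknown sensor convention {convention!r}")
    x = lowpass(resp.data, resp.fs, 5.0)
    if convention == "piezo":
        x = -x  # piezo voltage falls at exhalation onset
    xm = x - x.mean()
    crossings = np.where((xm[:-1] <= 0) & (xm[1:] > 0))[0] + 1
    onsets = crossings / resp.fs
    raw_phase = np.angle(signal.hilbert(xm))
    if len(crossings):
        ref = np.angle(np.mean(np.exp(1j * raw_phase[crossings])))
    else:
        ref = 0.0
    phase = np.angle(np.exp(1j * (raw_phase - ref)))
    return phase, onsets
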