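"""Extracellular spike analysis and intracellular event analysis.

Spike detection replaces online template matching with an offline chain:
300-8000 Hz bandpass, robust threshold crossings, 3-ms waveform extraction,
PCA (3 components) and k-means clustering with silhouette-based acceptance
of well-separated clusters.  Peri-event time histograms carry a shuffle
(uniform event-time jitter) null for per-bin significance.  Intracellular
routines detect action potentials (peaks 10 SD above the mean), EPSPs
(dV/dt peaks), phase profiles of the membrane potential, and input
resistance per respiratory phase class from current pulses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .core import Trace, bandpass, lowpass
from .phase_coupling import (CircStatResult, phase_binned_profile, rayleigh)
from .synthgen import VmTrace

SPIKE_BAND = (300.0, 8000.0)
WAVEFORM_MS = 3.0
REFRACTORY_S = 0.001


@dataclass
class SpikeTrain:
    """Sorted single unit: spike times, waveforms and cluster identity."""

    unit_id: int
    times_s: np.ndarray
    waveforms: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    quality: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, float)
        if np.any(np.diff(self.times_s) < REFRACTORY_S - 1e-12):
            raise ValueError("spike times violate the 1-ms refractory period")


# ---------------------------------------------------------------------------
# spike detection / sorting-lite
# ---------------------------------------------------------------------------

def detect_spikes(wideband: Trace, threshold_sd: float = 5.0,
                  max_units: int = 3, min_silhouette: float = 0.4,
                  seed: int = 0) -> list[SpikeTrain]:
    """Threshold + PCA + k-means spike sorting.

    The wideband trace is band-passed 300-8000 Hz (capped below Nyquist),
    candidate spikes are peaks of the absolute filtered signal above
    ``threshold_sd`` robust standard deviations (MAD-based), 3-ms waveforms
    are clustered on their first 3 principal components, and only
    well-separated clusters (mean silhouette >= ``min_silhouette``) are
    split into distinct units; otherwise all spikes form a single unit.
    """
    if wideband.fs < 10_000:
        raise ValueError("spike detection requires fs >= 10 kHz")
    hi = min(SPIKE_BAND[1], wideband.fs / 2 * 0.95)
    filt = bandpass(wideband.data, wideband.fs, SPIKE_BAND[0], hi)
    sigma = np.median(np.abs(filt)) / 0.6745
    thr = threshold_sd * sigma
    # peak spacing of half the waveform window suppresses filter-ringing
    # side lobes of the same spike; the larger extremum is kept
    dist = max(int(WAVEFORM_MS / 2 / 1000 * wideband.fs), 1)
    peaks, _ = signal.find_peaks(np.abs(filt), height=thr, distance=dist)
    half = int(WAVEFORM_MS / 2 / 1000 * wideband.fs)
    peaks = peaks[(peaks >= half) & (peaks < wideband.n - half)]
    if len(peaks) == 0:
        return []
    waves = np.stack([filt[p - half:p + half] for p in peaks])
    times = peaks / wideband.fs
    if len(peaks) < 10:
        return [SpikeTrain(0, times, waves, "unsorted (too few spikes)")]
    n_pc = min(3, waves.shape[1], len(peaks) - 1)
    pcs = PCA(n_components=n_pc, random_state=seed).fit_transform(waves)
    best_k, best_sil, best_labels = 1, -1.0, np.zeros(len(peaks), int)
    for k in range(2, max_units + 1):
        if len(peaks) <= k:
            break
        labels = KMeans(n_clusters=k, n_init=10,
                        random_state=seed).fit_predict(pcs)
        sil = silhouette_score(pcs, labels)
        if sil > best_sil:
            best_k, best_sil, best_labels = k, sil, labels
    if best_k == 1 or best_sil < min_silhouette:
        return [SpikeTrain(0, times, waves, "single cluster")]
    units = []
    for u in range(best_k):
        sel = best_labels == u
        units.append(SpikeTrain(u, times[sel], waves[sel],
                                f"silhouette={best_sil:.2f}"))
    return units


# ---------------------------------------------------------------------------
# PETH / ISI / autocorrelation
# ---------------------------------------------------------------------------

@dataclass
class Peth:
    """Peri-event time histogram with a shuffle-based significance mask."""

    bin_edges_s: np.ndarray
    rate_hz: np.ndarray
    n_sweeps: int
    significant: np.ndarray          # bool per bin, two-sided p < alpha
    alpha: float = 0.01


def _event_counts(spikes: np.ndarray, events: np.ndarray,
                  edges: np.ndarray) -> np.ndarray:
    counts = np.zeros(len(edges) - 1)
    for ev in events:
        rel = spikes[(spikes >= ev + edges[0]) & (spikes < ev + edges[-1])] - ev
        counts += np.histogram(rel, bins=edges)[0]
    return counts


def peth(spike_times: np.ndarray, event_times: np.ndarray,
         window_s: float = 3.0, bin_s: float = 0.001,
         n_shuffles: int = 500, alpha: float = 0.01,
         bonferroni: bool = False, seed: int = 0) -> Peth:
    """Spike rate around events in 1-ms bins (count / (n_sweeps * binwidth)).

    The null is built by jittering event times uniformly within
    +/- window/2, ``n_shuffles`` times; a bin is significant when its count
    falls outside the two-sided ``alpha`` quantiles of its null counts
    (optionally Bonferroni-corrected across bins).
    """
    events = np.asarray(event_times, float)
    if events.size < 10:
        raise ValueError("need at least 10 events")
    spikes = np.sort(np.asarray(spike_times, float))
    half = window_s / 2
    edges = np.arange(-half, half + bin_s / 2, bin_s)
    counts = _event_counts(spikes, events, edges)
    rate = counts / (events.size * bin_s)
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, len(counts)))
    for i in range(n_shuffles):
        jit = events + rng.uniform(-half, half, events.size)
        null[i] = _event_counts(spikes, jit, edges)
    a = alpha / len(counts) if bonferroni else alpha
    lo = np.quantile(null, a / 2, axis=0)
    hi = np.quantile(null, 1 - a / 2, axis=0)
    sig = (counts < lo) | (counts > hi)
    return Peth(bin_edges_s=edges, rate_hz=rate, n_sweeps=int(events.size),
                significant=sig, alpha=alpha)


def isi_histogram(spike_times: np.ndarray,
                  within_intervals: list[tuple[float, float]] | None = None,
                  bin_ms: float = 1.0, max_isi_ms: float = 100.0
                  ) -> tuple[np.ndarray, np.ndarray, float]:
    """Interspike-interval histogram restricted to provided intervals.

    Both spikes of a pair must fall inside the same interval (e.g. the same
    gamma burst).  Returns ``(bin_centers_ms, counts, mode_ms)``.
    """
    spikes = np.sort(np.asarray(spike_times, float))
    if within_intervals is None:
        isis = np.diff(spikes)
    else:
        parts = []
        for s, e in within_intervals:
            inside = spikes[(spikes >= s) & (spikes <= e)]
            if inside.size > 1:
                parts.append(np.diff(inside))
        isis = np.concatenate(parts) if parts else np.empty(0)
    isis_ms = isis * 1000.0
    isis_ms = isis_ms[isis_ms <= max_isi_ms]
    if isis_ms.size < 50:
        raise ValueError("fewer than 50 interspike intervals")
    # bins centred on integer multiples of the bin width, so a perfectly
    # periodic train reports its exact period
    edges = np.arange(bin_ms / 2, max_isi_ms + bin_ms, bin_ms)
    counts, _ = np.histogram(isis_ms, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, counts, float(centers[np.argmax(counts)])


def spike_autocorr(spike_times: np.ndarray, span_ms: float = 100.0,
                   bin_ms: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Autocorrelogram of spike-pair lags within +/-``span_ms``; the
    zero-lag (self-pair) bin is excluded."""
    spikes = np.sort(np.asarray(spike_times, float))
    if spikes.size < 100:
        raise ValueError("need at least 100 spikes")
    span = span_ms / 1000.0
    lags = []
    for i, t in enumerate(spikes):
        j = np.searchsorted(spikes, t + span, side="right")
        lags.append(spikes[i + 1:j] - t)
    fwd = np.concatenate(lags) * 1000.0 if lags else np.empty(0)
    all_lags = np.concatenate([fwd, -fwd])
    # bins centred on integer multiples of the bin width keep the histogram
    # exactly mirror-symmetric
    edges = np.arange(-span_ms - bin_ms / 2, span_ms + bin_ms, bin_ms)
    counts, _ = np.histogram(all_lags, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    counts[np.abs(centers) < bin_ms / 2] = 0
    return centers, counts


# ---------------------------------------------------------------------------
# intracellular analysis
# ---------------------------------------------------------------------------

def detect_aps(vm: VmTrace, sd_mult: float = 10.0) -> np.ndarray:
    """Action potentials as local maxima more than ``sd_mult`` SD above the
    mean membrane potential, with a 2-ms refractory period."""
    x = vm.vm
    thr = x.mean() + sd_mult * x.std()
    peaks, _ = signal.find_peaks(x, height=thr,
                                 distance=max(int(0.002 * vm.fs), 1))
    return peaks / vm.fs


def detect_epsps(vm: VmTrace, sd_mult: float = 2.0,
                 ap_times: np.ndarray | None = None) -> np.ndarray:
    """EPSP onsets as peaks of dV/dt above mean + ``sd_mult`` SD of dV/dt.

    The membrane potential is lowpassed below 1000 Hz before
    differentiation; events within 3 ms of an action potential are excluded.
    """
    if vm.fs < 5000:
        raise ValueError("EPSP detection requires fs >= 5 kHz")
    if not 1.0 <= sd_mult <= 3.0:
        raise ValueError("sd_mult must lie in [1, 3]")
    x = lowpass(vm.vm, vm.fs, min(1000.0, vm.fs / 2 * 0.9))
    dvdt = np.gradient(x) * vm.fs
    edge = int(0.02 * vm.fs)  # filter transients at the trace ends
    core = dvdt[edge:-edge] if len(dvdt) > 2 * edge else dvdt
    if core.std() <= 1e-9 * max(abs(core.mean()), 1.0):
        return np.empty(0)  # flat slope (e.g. linear ramp): no events
    thr = core.mean() + sd_mult * core.std()
    peaks, _ = signal.find_peaks(dvdt, height=thr,
                                 distance=max(int(0.003 * vm.fs), 1))
    peaks = peaks[(peaks >= edge) & (peaks < len(dvdt) - edge)]
    times = peaks / vm.fs
    if ap_times is None:
        ap_times = detect_aps(vm)
    if len(ap_times):
        near_ap = np.min(np.abs(times[:, None] - ap_times[None, :]), axis=1) \
            if times.size else np.empty(0)
        times = times[near_ap > 0.003]
    return times


def vm_phase_profile(vm: VmTrace, phase: np.ndarray,
                     event_times: np.ndarray | None = None,
                     n_bins: int = 360
                     ) -> tuple[np.ndarray, np.ndarray, CircStatResult | None]:
    """Respiration-phase profile of the membrane potential envelope.

    The Vm is detrended (5-s moving average removed), range-normalised to
    100%, and the magnitude of its analytic signal is averaged per phase
    bin.  When event times (EPSPs or APs) are given, their phases are tested
    for circular uniformity with the Rayleigh test.
    """
    w = int(5 * vm.fs)
    x = vm.vm - np.convolve(vm.vm, np.ones(w) / w, mode="same")
    # drop half the detrending window at each end (edge transients)
    lo, hi = w // 2, len(x) - w // 2
    full_phase = np.asarray(phase)
    x = x[lo:hi]
    phase = full_phase[lo:hi]
    rng_ = np.ptp(x)
    if rng_ > 0:
        x = 100.0 * (x - x.min()) / rng_
    mag = np.abs(signal.hilbert(x - x.mean()))
    centers, profile = phase_binned_profile(phase, mag, n_bins)
    circ = None
    if event_times is not None and len(event_times) >= 3:
        idx = np.clip((np.asarray(event_times) * vm.fs).astype(int),
                      0, len(full_phase) - 1)
        circ = rayleigh(full_phase[idx])
    return centers, profile, circ


@dataclass
class RiResult:
    """Input resistance per respiratory phase class."""

    ri_mohm: dict[str, tuple[float, float]]       # class -> (mean, sd)
    per_pulse: list[tuple[str, float]]            # (class, Ri) per pulse
    t_statistic: float
    p_value: float


def input_resistance(vm: VmTrace,
                     pulses: list[tuple[float, float, float, str]],
                     steady_frac: float = 0.3,
                     baseline_s: float = 0.05) -> RiResult:
    """Input resistance Ri = dV_steady / dI per pulse, grouped by phase class.

    ``pulses`` lists ``(time_s, amplitude_nA, duration_s, phase_class)``
    with phase class ``"inhalation"`` or ``"exhalation"``.  The steady-state
    voltage is the mean over the last ``steady_frac`` of the pulse minus the
    50-ms pre-pulse baseline.  Pulses containing an action potential are
    excluded.  Requires at least 3 usable pulses per class.
    """
    ap_times = detect_aps(vm)
    per_pulse: list[tuple[str, float]] = []
    for t0, amp, dur, cls in pulses:
        if amp == 0:
            raise ValueError("pulse amplitude must be nonzero")
        i0, i1 = int(t0 * vm.fs), int((t0 + dur) * vm.fs)
        if i1 > len(vm.vm):
            continue
        if len(ap_times) and np.any((ap_times >= t0) & (ap_times <= t0 + dur)):
            continue
        ib = max(i0 - int(baseline_s * vm.fs), 0)
        baseline = vm.vm[ib:i0].mean()
        steady0 = i1 - max(int(steady_frac * (i1 - i0)), 1)
        dv = vm.vm[steady0:i1].mean() - baseline
        per_pulse.append((cls, float(dv / amp)))
    groups = {cls: np.array([ri for c, ri in per_pulse if c == cls])
              for cls in ("inhalation", "exhalation")}
    for cls, vals in groups.items():
        if vals.size < 3:
            raise ValueError(f"fewer than 3 usable pulses in class {cls!r}")
    res = stats.ttest_ind(groups["inhalation"], groups["exhalation"])
    return RiResult(
        ri_mohm={cls: (float(v.mean()), float(v.std(ddof=1)))
                 for cls, v in groups.items()},
        per_pulse=per_pulse,
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )
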