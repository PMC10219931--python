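"""Synthetic session generator with exact ground truth.

Emulates the statistical structure of prefronto-thalamic recordings during
natural sleep and wake: a ~1 Hz respiration-related potential (RR) coherent
with breathing, brief 30-55 Hz gamma bursts phase-locked to exhalation during
wake, an NREM slow oscillation with nested 10-15 Hz spindles and weak UP-state
gamma, tonic REM gamma without RR, state-dependent EMG/EOG variance, 1/f
background noise, gamma-phase-locked spiking and membrane-potential traces
with exhalation-locked EPSPs.  Every placed event is returned in a
:class:`GroundTruth` record so detector recall/precision can be measured
exactly.

Generation is bit-reproducible for a fixed master seed; per-channel random
streams are spawned deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.special import i0

from .core import Trace, StateSchedule, bandpass


@dataclass
class GenConfig:
    """Knobs of the synthetic session generator.

    Defaults reflect the phenomenology of wake prefrontal recordings:
    ~1 breath/s, one gamma burst per breath at 40 Hz lasting ~380 ms,
    burst amplitude well above the 25 uV RMS detection threshold.
    """

    duration_s: float = 300.0
    fs_hz: float = 1000.0
    resp_rate_hz: float = 1.0
    resp_cycle_cv: float = 0.1          # CV of lognormal cycle lengths
    coupling_kappa: float = 2.0         # von Mises concentration of burst phases
    preferred_phase_rad: float = 0.0    # 0 = exhalation onset / RR trough
    burst_rate_per_breath: float = 1.0
    gamma_freq_hz: float = 40.0
    gamma_burst_amp_uv: float = 100.0   # peak envelope; RMS peak ~ amp/sqrt(2)
    gamma_burst_dur_ms: float = 382.0
    rr_amp_uv: float = 100.0
    so_freq_hz: float = 1.0
    so_amp_uv: float = 300.0
    so_pulse_sigma_s: float = 0.05
    nrem_delta_uv: float = 80.0         # RMS of 1-4 Hz NREM noise floor
    nrem_up_gamma_amp_uv: float = 30.0
    spindle_density_per_min: float = 6.0
    spindle_freq_hz: float = 12.5
    spindle_amp_uv: float = 60.0
    rem_gamma_uv: float = 20.0          # RMS of tonic REM gamma
    emg_sigma_uv: tuple[float, float, float] = (100.0, 20.0, 5.0)  # wake/NREM/REM
    eog_sigma_uv: tuple[float, float] = (5.0, 50.0)                # non-REM/REM
    noise_exponent: float = 1.0         # 1/f^a slope of background
    noise_amp_uv: float = 10.0          # broadband RMS of background
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs_hz < 200:
            raise ValueError("fs_hz must be at least 200 Hz")
        if self.resp_rate_hz <= 0:
            raise ValueError("resp_rate_hz must be positive")
        if self.coupling_kappa < 0:
            raise ValueError("coupling_kappa must be >= 0")
        for name in ("gamma_burst_amp_uv", "rr_amp_uv", "so_amp_uv",
                     "spindle_amp_uv", "noise_amp_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Exact event times placed in a synthetic session."""

    burst_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    burst_phases_rad: np.ndarray = field(default_factory=lambda: np.empty(0))
    spindle_intervals: list[tuple[float, float]] = field(default_factory=list)
    slow_wave_peaks_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    spike_times_s: dict[str, np.ndarray] = field(default_factory=dict)
    epsp_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    state_schedule: StateSchedule | None = None


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# respiration
# ---------------------------------------------------------------------------

def generate_respiration(cfg: GenConfig,
                         rng: np.random.Generator | None = None
                         ) -> tuple[Trace, np.ndarray, np.ndarray]:
    """Thermocouple-style respiration signal.

    Voltage rises during exhalation; each cycle starts at an exhalation onset
    (rising mean-crossing).  Cycle lengths are lognormal with mean
    ``1/resp_rate_hz`` and coefficient of variation ``resp_cycle_cv``.

    Returns
    -------
    trace : Trace
        Respiration signal (volts, arbitrary scale).
    onsets : ndarray
        Exact exhalation-onset times (cycle starts) within the recording.
    phase : ndarray
        Instantaneous respiration phase per sample in [0, 2pi), 0 at
        exhalation onset.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mean_len = 1.0 / cfg.resp_rate_hz
    cv = cfg.resp_cycle_cv
    n_cycles = int(np.ceil(cfg.duration_s / mean_len)) + 10
    if cv <= 0:
        lengths = np.full(n_cycles, mean_len)
    else:
        sig2 = np.log1p(cv ** 2)
        mu = np.log(mean_len) - sig2 / 2.0
        lengths = rng.lognormal(mean=mu, sigma=np.sqrt(sig2), size=n_cycles)
    boundaries = np.concatenate([[0.0], np.cumsum(lengths)])
    n = int(round(cfg.duration_s * cfg.fs_hz))
    t = np.arange(n) / cfg.fs_hz
    idx = np.searchsorted(boundaries, t, side="right") - 1
    frac = (t - boundaries[idx]) / lengths[idx]
    phase = 2 * np.pi * frac
    data = np.sin(phase)
    onsets = boundaries[:-1][boundaries[:-1] < cfg.duration_s]
    return Trace(data, cfg.fs_hz, "RESP", "V"), onsets, phase


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def _one_over_f(n: int, fs: float, exponent: float, rms: float,
                rng: np.random.Generator) -> np.ndarray:
    """Gaussian background with power spectrum ~ 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _gauss_burst(t: np.ndarray, center: float, dur_s: float, amp: float,
                 freq: float, carrier_phase: float) -> np.ndarray:
    """Gaussian-windowed sinusoid (Morlet-like), window sigma = dur/4,
    truncated at +/- 2 sigma."""
    sigma = dur_s / 4.0
    env = amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    env[np.abs(t - center) > 2 * sigma] = 0.0
    return env * np.cos(2 * np.pi * freq * (t - center) + carrier_phase)


def generate_session(cfg: GenConfig, schedule: StateSchedule
                     ) -> tuple[dict[str, Trace], GroundTruth]:
    """Generate a full multichannel session (mPFC/Reu/HC/EMG/EOG/RESP).

    Wake segments carry RR (trough at exhalation onset) plus gamma bursts
    whose centre phases are von Mises distributed around
    ``preferred_phase_rad`` with concentration ``coupling_kappa``.  NREM
    segments carry slow-oscillation pulses with UP-state gamma and nested
    spindles; REM carries tonic gamma and no RR.  EMG variance decreases
    wake > NREM > REM and EOG bursts occur only in REM.
    """
    if schedule.duration_s > cfg.duration_s + 1e-9:
        raise ValueError("schedule extends beyond cfg.duration_s")
    fs = cfg.fs_hz
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs
    (rng_resp, rng_bg, rng_burst, rng_nrem, rng_emg, rng_eog,
     rng_rem, rng_aux) = _streams(cfg.seed, 8)

    resp, onsets, resp_phase = generate_respiration(cfg, rng_resp)
    state_samples = schedule.sample_states(fs, n)
    wake = state_samples == "wake"
    nrem = state_samples == "NREM"
    rem = state_samples == "REM"

    mpfc = _one_over_f(n, fs, cfg.noise_exponent, cfg.noise_amp_uv, rng_bg)
    reu = _one_over_f(n, fs, cfg.noise_exponent, cfg.noise_amp_uv, rng_aux)
    hc = _one_over_f(n, fs, cfg.noise_exponent, cfg.noise_amp_uv,
                     np.random.default_rng(rng_aux.integers(2 ** 31)))

    # --- wake: RR + exhalation-locked gamma bursts -------------------------
    rr = -cfg.rr_amp_uv * np.cos(resp_phase)
    mpfc[wake] += rr[wake]
    reu[wake] += 0.8 * rr[wake]

    burst_times, burst_phases = [], []
    cycle_edges = np.concatenate([onsets, [cfg.duration_s]])
    frac_rate = cfg.burst_rate_per_breath
    for i in range(len(onsets)):
        c0, c1 = cycle_edges[i], cycle_edges[i + 1]
        if schedule.state_at(min(c0 + 1e-9, cfg.duration_s - 1e-9)) != "wake":
            continue
        n_b = int(np.floor(frac_rate))
        if rng_burst.random() < frac_rate - n_b:
            n_b += 1
        for _ in range(n_b):
            theta = rng_burst.vonmises(cfg.preferred_phase_rad,
                                       cfg.coupling_kappa) \
                if cfg.coupling_kappa > 0 else rng_burst.uniform(-np.pi, np.pi)
            tc = c0 + (theta / (2 * np.pi)) * (c1 - c0)
            dur = cfg.gamma_burst_dur_ms / 1000.0
            if tc - dur / 2 < 0 or tc + dur / 2 > cfg.duration_s:
                continue
            if schedule.state_at(tc) != "wake":
                continue
            carrier = rng_burst.uniform(0, 2 * np.pi)
            lo = max(int((tc - dur) * fs), 0)
            hi = min(int((tc + dur) * fs) + 1, n)
            w = _gauss_burst(t[lo:hi], tc, dur, cfg.gamma_burst_amp_uv,
                             cfg.gamma_freq_hz, carrier)
            mpfc[lo:hi] += w
            reu[lo:hi] += 0.6 * w
            hc[lo:hi] += 0.4 * w
            burst_times.append(tc)
            burst_phases.append(theta % (2 * np.pi))

    # --- NREM: slow-oscillation pulses, UP gamma, spindles, delta floor ----
    sw_peaks = []
    spindles: list[tuple[float, float]] = []
    if nrem.any():
        delta_noise = bandpass(rng_nrem.standard_normal(n), fs, 1.0, 4.0)
        delta_noise *= cfg.nrem_delta_uv / max(delta_noise.std(), 1e-12)
        mpfc[nrem] += delta_noise[nrem]
        for seg0, seg1, state in schedule.segments:
            if state != "NREM":
                continue
            period = 1.0 / cfg.so_freq_hz
            tc = seg0 + period
            while tc < min(seg1, cfg.duration_s) - period / 2:
                tc_j = tc + rng_nrem.normal(0, 0.05 * period)
                lo = max(int((tc_j - 0.3) * fs), 0)
                hi = min(int((tc_j + 0.3) * fs) + 1, n)
                mpfc[lo:hi] += cfg.so_amp_uv * np.exp(
                    -0.5 * ((t[lo:hi] - tc_j) / cfg.so_pulse_sigma_s) ** 2)
                # weak gamma in the UP state following the DOWN peak
                up_c = tc_j + 0.25
                lo2 = max(int((up_c - 0.2) * fs), 0)
                hi2 = min(int((up_c + 0.2) * fs) + 1, n)
                mpfc[lo2:hi2] += _gauss_burst(
                    t[lo2:hi2], up_c, 0.2, cfg.nrem_up_gamma_amp_uv,
                    cfg.gamma_freq_hz, rng_nrem.uniform(0, 2 * np.pi))
                sw_peaks.append(tc_j)
                tc += period
            # spindles on a jittered grid, kept > 1 s apart
            if cfg.spindle_density_per_min > 0:
                step = 60.0 / cfg.spindle_density_per_min
                ts = seg0 + step / 2
                while ts < min(seg1, cfg.duration_s) - 2.0:
                    dur = rng_nrem.uniform(0.5, 1.5)
                    s0 = ts + rng_nrem.uniform(0, 0.2)
                    s1 = s0 + dur
                    if s1 < min(seg1, cfg.duration_s):
                        lo = int(s0 * fs)
                        hi = int(s1 * fs)
                        env = np.hanning(hi - lo)
                        mpfc[lo:hi] += (cfg.spindle_amp_uv * env *
                                        np.sin(2 * np.pi * cfg.spindle_freq_hz
                                               * (t[lo:hi] - s0)))
                        spindles.append((s0, s1))
                    ts += step

    # --- REM: tonic gamma, no RR ------------------------------------------
    if rem.any() and cfg.rem_gamma_uv > 0:
        g = bandpass(rng_rem.standard_normal(n), fs, 30.0, 55.0)
        g *= cfg.rem_gamma_uv / max(g.std(), 1e-12)
        mpfc[rem] += g[rem]
        reu[rem] += 0.8 * g[rem]

    # --- EMG / EOG: amplitude-modulated white noise ------------------------
    emg_sigma = np.full(n, cfg.emg_sigma_uv[0])
    emg_sigma[nrem] = cfg.emg_sigma_uv[1]
    emg_sigma[rem] = cfg.emg_sigma_uv[2]
    emg = emg_sigma * rng_emg.standard_normal(n)
    eog_sigma = np.full(n, cfg.eog_sigma_uv[0])
    eog_sigma[rem] = cfg.eog_sigma_uv[1]
    eog = eog_sigma * rng_eog.standard_normal(n)

    traces = {
        "mPFC": Trace(mpfc, fs, "mPFC", "uV"),
        "Reu": Trace(reu, fs, "Reu", "uV"),
        "HC": Trace(hc, fs, "HC", "uV"),
        "EMG": Trace(emg, fs, "EMG", "uV"),
        "EOG": Trace(eog, fs, "EOG", "uV"),
        "RESP": resp,
    }
    truth = GroundTruth(
        burst_times_s=np.array(burst_times),
        burst_phases_rad=np.array(burst_phases),
        spindle_intervals=spindles,
        slow_wave_peaks_s=np.array(sw_peaks),
        state_schedule=schedule,
    )
    return traces, truth


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

@dataclass
class SpikeGenParams:
    """Inhomogeneous point-process parameters for a synthetic unit."""

    base_rate_hz: float = 20.0
    gamma_band: tuple[float, float] = (30.0, 55.0)
    gamma_kappa: float = 0.0          # phase-locking to the gamma cycle
    gamma_pref_rad: float = np.pi     # trough of the LFP oscillation
    rr_depth: float = 0.0             # multiplicative RR-phase modulation in [0,1]
    rr_pref_rad: float = np.pi
    refractory_s: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate_hz < 0 or self.rr_depth < 0:
            raise ValueError("rates and modulation depths must be >= 0")


def generate_spikes(lfp: Trace, resp_phase: np.ndarray | None,
                    params: SpikeGenParams) -> np.ndarray:
    """Spike times from a rate multiplicatively modulated by gamma phase
    (trough-preferring von Mises factor) and optionally by respiration phase,
    with an absolute refractory period.

    The gamma phase is taken from the analytic signal of the band-passed LFP,
    so spikes are locked to the oscillation actually present in the trace.
    """
    rng = np.random.default_rng(params.seed)
    fs = lfp.fs
    filt = bandpass(lfp.data, fs, *params.gamma_band)
    gphase = np.angle(signal.hilbert(filt))
    rate = np.full(lfp.n, params.base_rate_hz)
    if params.gamma_kappa > 0:
        k = params.gamma_kappa
        rate = rate * np.exp(k * np.cos(gphase - params.gamma_pref_rad)) / i0(k)
    if params.rr_depth > 0:
        if resp_phase is None:
            raise ValueError("rr_depth > 0 requires a respiration phase series")
        rate = rate * (1.0 + params.rr_depth *
                       np.cos(resp_phase - params.rr_pref_rad))
    rate = np.maximum(rate, 0.0)
    # thinning of a homogeneous process at the rate ceiling
    rmax = rate.max()
    if rmax <= 0:
        return np.empty(0)
    n_cand = rng.poisson(rmax * lfp.duration_s)
    cand = np.sort(rng.uniform(0, lfp.duration_s, n_cand))
    keep = rng.random(n_cand) < rate[np.minimum(
        (cand * fs).astype(int), lfp.n - 1)] / rmax
    times = cand[keep]
    out = []
    last = -np.inf
    for ti in times:
        if ti - last >= params.refractory_s:
            out.append(ti)
            last = ti
    return np.asarray(out)


# ---------------------------------------------------------------------------
# membrane potential
# ---------------------------------------------------------------------------

@dataclass
class VmGenParams:
    """Parameters of the synthetic intracellular trace."""

    v_rest_mv: float = -70.0
    so_amp_mv: float = 12.0           # UP-state depolarization
    so_freq_hz: float = 1.0
    epsp_rate_per_cycle: float = 3.0
    epsp_kappa: float = 3.0
    epsp_pref_rad: float = np.pi      # exhalation-to-inhalation transition
    epsp_amp_mv: float = 2.0
    epsp_rise_ms: float = 1.0
    epsp_tau_ms: float = 15.0
    ap_threshold_mv: float = -52.0
    ap_amp_mv: float = 60.0
    r_inh_mohm: float = 60.0          # input resistance during inhalation
    r_exh_mohm: float = 40.0          # lower during exhalation (synaptic drive)
    membrane_tau_ms: float = 10.0
    noise_mv: float = 0.2
    seed: int = 0


@dataclass
class VmTrace:
    """Membrane potential (mV) with the sample-aligned injected current (nA)."""

    vm: np.ndarray
    current: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.vm = np.asarray(self.vm, float)
        self.current = np.asarray(self.current, float)
        if self.vm.shape != self.current.shape:
            raise ValueError("vm and current must be sample-aligned")


def generate_vm(resp: Trace, resp_phase: np.ndarray,
                schedule: StateSchedule,
                pulse_protocol: list[tuple[float, float, float]],
                params: VmGenParams) -> tuple[VmTrace, GroundTruth]:
    """Synthetic intracellular recording.

    Slow-oscillation bimodality (UP/DOWN alternation during NREM-labelled
    segments), exhalation-locked EPSPs (sharp rise, exponential decay),
    threshold-triggered action potentials, and rectangular current pulses
    whose voltage response scales with a respiration-phase-dependent input
    resistance (lower during exhalation).

    ``pulse_protocol`` lists ``(time_s, amplitude_nA, duration_s)``; pulses
    must not overlap.
    """
    rng = np.random.default_rng(params.seed)
    fs = resp.fs
    n = resp.n
    t = np.arange(n) / fs
    duration = n / fs

    proto = sorted(pulse_protocol)
    for (t0, _, d0), (t1, _, _) in zip(proto, proto[1:]):
        if t0 + d0 > t1:
            raise ValueError("overlapping current pulses")

    # membrane noise is low-passed at the membrane time-constant corner
    # frequency, so its dV/dt stays well below EPSP rise slopes
    corner = 1.0 / (2 * np.pi * params.membrane_tau_ms / 1000.0)
    noise = signal.sosfiltfilt(
        signal.butter(2, min(corner, fs / 2 * 0.9), fs=fs, output="sos"),
        rng.standard_normal(n))
    noise *= params.noise_mv / max(noise.std(), 1e-12)
    vm = np.full(n, params.v_rest_mv) + noise

    # slow oscillation: smoothed UP/DOWN square wave inside NREM segments
    if params.so_amp_mv > 0:
        sq = 0.5 * (1 + signal.square(2 * np.pi * params.so_freq_hz * t))
        sq = signal.sosfiltfilt(
            signal.butter(2, 8.0, fs=fs, output="sos"), sq)
        in_so = schedule.mask("NREM", fs, n)
        vm[in_so] += params.so_amp_mv * sq[in_so]

    # exhalation-locked EPSPs: one cycle = one 2pi sweep of resp phase
    unwrapped = np.unwrap(resp_phase)
    n_cycles = int(unwrapped[-1] // (2 * np.pi))
    epsp_times = []
    rise = params.epsp_rise_ms / 1000.0
    tau = params.epsp_tau_ms / 1000.0
    kernel_t = np.arange(0, 8 * tau, 1 / fs)
    kernel = (1 - np.exp(-kernel_t / rise)) * np.exp(-kernel_t / tau)
    kernel *= params.epsp_amp_mv / kernel.max()
    for c in range(n_cycles):
        n_e = rng.poisson(params.epsp_rate_per_cycle)
        for _ in range(n_e):
            theta = rng.vonmises(params.epsp_pref_rad, params.epsp_kappa)
            target = 2 * np.pi * c + (theta % (2 * np.pi))
            idx = np.searchsorted(unwrapped, target)
            if 0 < idx < n - len(kernel):
                vm[idx:idx + len(kernel)] += kernel
                epsp_times.append(t[idx])

    # current pulses: exponential charging, Ri set by respiration phase class
    current = np.zeros(n)
    taum = params.membrane_tau_ms / 1000.0
    for t0, amp_na, dur in proto:
        i0_, i1 = int(t0 * fs), min(int((t0 + dur) * fs), n)
        if i0_ >= n:
            continue
        current[i0_:i1] = amp_na
        mid_phase = resp_phase[min((i0_ + i1) // 2, n - 1)] % (2 * np.pi)
        ri = params.r_exh_mohm if mid_phase < np.pi else params.r_inh_mohm
        tt = t[i0_:i1] - t0
        vm[i0_:i1] += amp_na * ri * (1 - np.exp(-tt / taum))
        # discharge back to baseline after the pulse
        i2 = min(i1 + int(5 * taum * fs), n)
        if i1 < n:
            vm[i1:i2] += (amp_na * ri * (1 - np.exp(-dur / taum)) *
                          np.exp(-(t[i1:i2] - (t0 + dur)) / taum))

    # action potentials where the subthreshold trace crosses threshold
    peaks, _ = signal.find_peaks(vm, height=params.ap_threshold_mv,
                                 distance=max(int(0.005 * fs), 1))
    ap_t = np.arange(-int(0.0005 * fs), int(0.0005 * fs) + 1)
    for p in peaks:
        lo, hi = p + ap_t[0], p + ap_t[-1] + 1
        if lo >= 0 and hi <= n:
            vm[lo:hi] += params.ap_amp_mv * np.exp(
                -0.5 * (ap_t / (0.0002 * fs)) ** 2)

    truth = GroundTruth(epsp_times_s=np.asarray(sorted(epsp_times)),
                        spike_times_s={"vm": t[peaks]},
                        state_schedule=schedule)
    return VmTrace(vm, current, fs), truth
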