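"""Spike sorting, PETH, ISI/autocorrelation, and intracellular analysis."""

import numpy as np
import pytest

import respgamma as rg
from conftest import match_events


# ---------------------------------------------------------------------------
# spike detection / sorting
# ---------------------------------------------------------------------------

def _inject(x, fs, times, waveform):
    half = len(waveform) // 2
    for t in times:
        i = int(t * fs)
        x[i - half:i - half + len(waveform)] += waveform
    return x


def test_noise_only_yields_no_units():
    rng = np.random.default_rng(0)
    tr = rg.Trace(3 * rng.standard_normal(int(5 * 20000)), 20000.0)
    assert rg.detect_spikes(tr, threshold_sd=6.0) == []


def test_single_unit_count_matches_injection():
    rng = np.random.default_rng(1)
    fs = 20000.0
    x = 3 * rng.standard_normal(int(20 * fs))
    t_ax = np.arange(-30, 30)
    w = -90 * np.exp(-0.5 * (t_ax / 4) ** 2)
    times = np.sort(rng.uniform(0.1, 19.9, 300))
    times = times[np.concatenate([[True], np.diff(times) > 0.005])]
    _inject(x, fs, times, w)
    units = rg.detect_spikes(rg.Trace(x, fs), threshold_sd=5.0)
    total = sum(len(u.times_s) for u in units)
    assert abs(total - len(times)) <= 0.01 * len(times)


def test_two_waveform_shapes_sorted_correctly():
    rng = np.random.default_rng(2)
    fs = 20000.0
    x = 3 * rng.standard_normal(int(20 * fs))
    t_ax = np.arange(-30, 30)
    w1 = -80 * np.exp(-0.5 * (t_ax / 4) ** 2)
    w2 = 60 * np.exp(-0.5 * (t_ax / 10) ** 2) * np.cos(t_ax / 6)
    t1 = np.sort(rng.uniform(0.1, 19.9, 200))
    t2 = np.sort(rng.uniform(0.1, 19.9, 150))
    _inject(x, fs, t1, w1)
    _inject(x, fs, t2, w2)
    units = rg.detect_spikes(rg.Trace(x, fs), threshold_sd=5.0)
    assert len(units) == 2
    # map each unit to the injected train it overlaps best
    correct = total = 0
    for u in units:
        r1, _ = match_events(u.times_s, t1, 0.002)
        r2, _ = match_events(u.times_s, t2, 0.002)
        best = t1 if r1 * len(t1) > r2 * len(t2) else t2
        for t in u.times_s:
            total += 1
            correct += int(np.min(np.abs(best - t)) < 0.002)
    assert correct / total >= 0.98


# ---------------------------------------------------------------------------
# PETH
# ---------------------------------------------------------------------------

def test_peth_integral_identity():
    """Sum of rate*binwidth over the window equals the mean spike count per
    sweep, exactly."""
    rng = np.random.default_rng(3)
    spikes = np.sort(rng.uniform(0, 300, 4000))
    events = np.sort(rng.uniform(5, 295, 60))
    p = rg.peth(spikes, events, n_shuffles=20, seed=0)
    total = (p.rate_hz * np.diff(p.bin_edges_s)).sum()
    per_sweep = np.mean([np.sum((spikes >= e - 1.5) & (spikes < e + 1.5))
                         for e in events])
    assert total == pytest.approx(per_sweep, rel=1e-12)


def test_peth_poisson_null_rates():
    rng = np.random.default_rng(4)
    spikes = np.sort(rng.uniform(0, 600, 600 * 20))
    events = np.sort(rng.uniform(10, 590, 100))
    p = rg.peth(spikes, events, n_shuffles=300, seed=0)
    assert p.rate_hz.mean() == pytest.approx(20.0, rel=0.05)
    assert p.significant.mean() < 0.02  # <= 2x nominal alpha = 0.01


def test_spikes_at_events_give_single_significant_bin():
    # events spaced > the 3-s window so neighbouring events stay out of it
    rng = np.random.default_rng(21)
    events = 5.0 + np.cumsum(rng.uniform(3.2, 4.0, 100))
    spikes = events.copy()
    p = rg.peth(spikes, events, n_shuffles=200, seed=1)
    centers = (p.bin_edges_s[:-1] + p.bin_edges_s[1:]) / 2
    hot = np.where(p.significant & (p.rate_hz > p.rate_hz.mean()))[0]
    assert len(hot) == 1
    assert abs(centers[hot[0]]) < 0.002


def test_peth_shows_rr_firing_dip():
    """A unit whose rate dips at the RR peak shows a significant trough at
    lag 0 in the peri-peak PETH."""
    cfg = rg.GenConfig(duration_s=400, fs_hz=500, resp_cycle_cv=0.0, seed=5)
    resp, onsets, phase = rg.generate_respiration(cfg)
    lfp = rg.Trace(np.zeros(resp.n), resp.fs)
    params = rg.SpikeGenParams(base_rate_hz=15.0, gamma_kappa=0.0,
                               rr_depth=0.8, rr_pref_rad=0.0, seed=6)
    spikes = rg.generate_spikes(lfp, phase, params)
    rr_peaks = onsets[5:-5] + 0.5  # trough-preferring unit dips at RR peaks
    p = rg.peth(spikes, rr_peaks, n_shuffles=200, seed=2)
    centers = (p.bin_edges_s[:-1] + p.bin_edges_s[1:]) / 2
    near = np.abs(centers) < 0.05
    assert p.rate_hz[near].mean() < 0.5 * p.rate_hz.mean()
    sig_low = p.significant & (p.rate_hz < p.rate_hz.mean())
    far = np.abs(centers) > 0.4
    # significantly-low bins concentrate at lag 0, far above the nominal
    # per-bin false-positive rate
    assert sig_low[near].mean() > 10 * p.alpha
    assert sig_low[near].mean() > 3 * sig_low[far].mean()


def test_peth_requires_ten_events():
    with pytest.raises(ValueError):
        rg.peth(np.arange(100.0), np.arange(5.0), n_shuffles=10)


# ---------------------------------------------------------------------------
# ISI and autocorrelation
# ---------------------------------------------------------------------------

def test_isi_of_periodic_train_is_single_bin():
    spikes = np.arange(0, 10, 0.025)
    centers, counts, mode = rg.isi_histogram(spikes)
    assert mode == 25.0
    assert (counts > 0).sum() == 1


def test_isi_of_poisson_train_decays():
    rng = np.random.default_rng(7)
    spikes = np.cumsum(rng.exponential(0.02, 5000))
    _, counts, _ = rg.isi_histogram(spikes)
    third = len(counts) // 3
    assert counts[:third].mean() > 2 * counts[-third:].mean()


def test_gamma_locked_isi_mode_at_25ms(gamma_locked_unit):
    _, _, spikes = gamma_locked_unit
    assert len(spikes) >= 500
    _, _, mode = rg.isi_histogram(spikes)
    assert abs(mode - 25.0) <= 1.0


def test_cycle_skipping_adds_harmonic_mode():
    """Thinning a periodic 40-Hz train with skip probability 0.5 yields ISI
    modes at 25 and 50 ms."""
    rng = np.random.default_rng(8)
    base = np.arange(0, 60, 0.025)
    spikes = base[rng.random(len(base)) < 0.5]
    centers, counts, _ = rg.isi_histogram(spikes)
    top2 = set(np.round(centers[np.argsort(counts)[-2:]]))
    assert top2 == {25.0, 50.0}


def test_isi_restricted_to_intervals():
    spikes = np.array([0.0, 0.025, 1.0, 1.025] * 60) + \
        np.repeat(np.arange(60) * 2.0, 4)
    intervals = [(i * 2.0 - 0.1, i * 2.0 + 0.1) for i in range(60)]
    _, counts, mode = rg.isi_histogram(np.sort(spikes), intervals)
    # only the within-interval 25-ms pairs survive
    assert mode == 25.0
    assert counts.sum() == 60


def test_autocorr_periodic_peaks_and_symmetry():
    spikes = np.arange(0, 30, 0.025)
    centers, counts = rg.spike_autocorr(spikes)
    assert np.array_equal(counts, counts[::-1])
    peak_lags = set(np.abs(centers[counts == counts.max()]))
    assert 25.0 in peak_lags
    assert counts[np.abs(centers) == 50.0].max() > 0
    assert counts[np.abs(centers) < 0.5].sum() == 0  # zero-lag excluded


def test_autocorr_poisson_flat_beyond_refractory():
    rng = np.random.default_rng(9)
    spikes = np.cumsum(rng.exponential(0.01, 20000))
    centers, counts = rg.spike_autocorr(spikes)
    outer = counts[np.abs(centers) > 5]
    assert outer.std() / outer.mean() < 0.15


# ---------------------------------------------------------------------------
# intracellular
# ---------------------------------------------------------------------------

def _vm_session(seed=10, duration=40.0, fs=5000.0, **vm_kwargs):
    cfg = rg.GenConfig(duration_s=duration, fs_hz=fs, resp_cycle_cv=0.05,
                       seed=seed)
    resp, onsets, phase = rg.generate_respiration(cfg)
    params = rg.VmGenParams(seed=seed, **vm_kwargs)
    sched = rg.StateSchedule([(0, duration, "wake")])
    vmt, truth = rg.generate_vm(resp, phase, sched, [], params)
    return vmt, truth, phase


def test_subthreshold_trace_has_no_aps():
    vmt, _, _ = _vm_session(so_amp_mv=0.0, epsp_rate_per_cycle=0.0)
    assert len(rg.detect_aps(vmt)) == 0


def test_ap_count_matches_ground_truth():
    vmt, truth, _ = _vm_session(so_amp_mv=0.0, epsp_rate_per_cycle=6.0,
                                epsp_amp_mv=8.0, ap_threshold_mv=-58.0)
    truth_aps = truth.spike_times_s["vm"]
    assert len(truth_aps) >= 10
    det = rg.detect_aps(vmt)
    assert len(det) == len(truth_aps)


def test_ap_threshold_arithmetic_on_toy_trace():
    # sparse 100-mV spikes: mean 0.1, sd ~3.16, threshold ~31.7 < 100
    block = np.zeros(1000)
    block[500] = 100.0
    vmt = rg.VmTrace(np.tile(block, 20), np.zeros(20000), 1000.0)
    mu, sd = vmt.vm.mean(), vmt.vm.std()
    assert mu + 10 * sd == pytest.approx(0.1 + 10 * np.sqrt(
        (100.0 ** 2 / 1000) - 0.1 ** 2), rel=1e-9)
    det = rg.detect_aps(vmt)
    assert np.all(vmt.vm[(det * 1000).astype(int)] > mu + 10 * sd)
    assert len(det) == 20


def test_linear_ramp_has_no_epsps():
    vmt = rg.VmTrace(np.linspace(-70, -60, 50000), np.zeros(50000), 5000.0)
    assert len(rg.detect_epsps(vmt, 2.0, ap_times=np.empty(0))) == 0


def test_epsp_recovery_and_phase_locking():
    vmt, truth, phase = _vm_session(so_amp_mv=0.0, epsp_amp_mv=1.0,
                                    epsp_kappa=3.0)
    det = rg.detect_epsps(vmt, 2.0)
    recall, precision = match_events(det, truth.epsp_times_s, 0.005)
    assert recall >= 0.9
    assert precision >= 0.9
    idx = np.clip((det * vmt.fs).astype(int), 0, len(phase) - 1)
    r = rg.rayleigh(phase[idx])
    d = np.angle(np.exp(1j * (r.mean_angle_rad - np.pi)))
    assert abs(d) < 0.3


def test_epsp_count_monotone_in_threshold():
    vmt, _, _ = _vm_session(so_amp_mv=0.0, epsp_amp_mv=1.0)
    counts = [len(rg.detect_epsps(vmt, m, ap_times=np.empty(0)))
              for m in (1.0, 2.0, 3.0)]
    assert counts[0] >= counts[1] >= counts[2]


def test_vm_phase_profile_flat_for_constant():
    n = 50000
    vmt = rg.VmTrace(np.full(n, -65.0), np.zeros(n), 5000.0)
    phase = np.angle(np.exp(1j * np.linspace(0, 40 * np.pi, n)))
    _, profile, _ = rg.vm_phase_profile(vmt, phase)
    assert np.nanstd(profile) < 1e-6


def test_vm_profile_peaks_near_locked_phase():
    vmt, truth, phase = _vm_session(so_amp_mv=0.0, epsp_amp_mv=3.0,
                                    epsp_kappa=5.0)
    centers, profile, circ = rg.vm_phase_profile(vmt, phase,
                                                 truth.epsp_times_s)
    peak_phase = centers[np.nanargmax(profile)]
    d = np.angle(np.exp(1j * (peak_phase - np.pi)))
    assert abs(d) < np.deg2rad(30)
    assert circ.p_rayleigh < 0.001


def test_uniform_events_not_phase_locked():
    vmt, _, phase = _vm_session(so_amp_mv=0.0, epsp_rate_per_cycle=0.0)
    rng = np.random.default_rng(11)
    events = rng.uniform(1, 39, 200)
    _, _, circ = rg.vm_phase_profile(vmt, phase, events)
    assert circ.p_rayleigh > 0.05


# ---------------------------------------------------------------------------
# input resistance
# ---------------------------------------------------------------------------

def test_ri_ohms_law_on_noiseless_pulse():
    fs = 5000.0
    n = int(4 * fs)
    vm = np.zeros(n)
    i0, i1 = int(1.0 * fs), int(1.5 * fs)
    vm[i0:i1] = -15.0
    current = np.zeros(n)
    current[i0:i1] = -0.5
    res = rg.input_resistance(
        rg.VmTrace(vm, current, fs),
        [(1.0, -0.5, 0.5, "inhalation")] * 3
        + [(1.0, -0.5, 0.5, "exhalation")] * 3)
    assert res.ri_mohm["inhalation"][0] == pytest.approx(30.0, abs=1e-9)


def test_ri_recovered_from_generator():
    cfg = rg.GenConfig(duration_s=60, fs_hz=5000, resp_cycle_cv=0.0, seed=12)
    resp, onsets, phase = rg.generate_respiration(cfg)
    params = rg.VmGenParams(so_amp_mv=0.0, epsp_rate_per_cycle=0.0,
                            r_inh_mohm=60.0, r_exh_mohm=40.0, seed=12)
    # pulses alternating between early (exhalation) and late (inhalation)
    pulses, tagged = [], []
    for i, k in enumerate(range(5, 55, 2)):
        offset, cls = ((0.05, "exhalation") if i % 2
                       else (0.55, "inhalation"))
        pulses.append((k + offset, -0.5, 0.3))
        tagged.append((k + offset, -0.5, 0.3, cls))
    sched = rg.StateSchedule([(0, 60, "wake")])
    vmt, _ = rg.generate_vm(resp, phase, sched, pulses, params)
    res = rg.input_resistance(vmt, tagged)
    assert res.ri_mohm["inhalation"][0] == pytest.approx(60.0, rel=0.05)
    assert res.ri_mohm["exhalation"][0] == pytest.approx(40.0, rel=0.05)
    assert res.p_value < 0.01


def test_equal_resistances_not_significant():
    """With identical Ri in both phase classes the class comparison should
    rarely reach significance (18 of 20 seeds above p=0.05)."""
    hits = 0
    for seed in range(20):
        cfg = rg.GenConfig(duration_s=30, fs_hz=5000, resp_cycle_cv=0.0,
                           seed=seed)
        resp, _, phase = rg.generate_respiration(cfg)
        params = rg.VmGenParams(so_amp_mv=0.0, epsp_rate_per_cycle=0.0,
                                r_inh_mohm=50.0, r_exh_mohm=50.0, seed=seed)
        pulses, tagged = [], []
        for i, k in enumerate(range(3, 27, 2)):
            offset, cls = ((0.05, "exhalation") if i % 2
                           else (0.55, "inhalation"))
            pulses.append((k + offset, -0.5, 0.3))
            tagged.append((k + offset, -0.5, 0.3, cls))
        sched = rg.StateSchedule([(0, 30, "wake")])
        vmt, _ = rg.generate_vm(resp, phase, sched, pulses, params)
        res = rg.input_resistance(vmt, tagged)
        hits += int(res.p_value > 0.05)
    assert hits >= 18
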