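# Methods

## Scope and signal model

The package analyses multichannel extracellular recordings (LFP/EEG in µV,
EMG/EOG in µV, respiration in sensor volts, 100 Hz–20 kHz sampling) and
intracellular membrane potential (mV) with an aligned injected-current
channel (nA). Time is in seconds from recording start. All filtering is
zero-phase (4th-order Butterworth, forward–backward) so detected event times
and phases are not biased by filter delay; decimation uses an 8th-order
anti-aliasing stage (cascaded for large factors).

The phenomenon of interest: during wakefulness the prefrontal LFP carries a
~1 Hz respiration-related rhythm (RR) whose troughs coincide with
exhalation, and transient gamma bursts (30–55 Hz, a few hundred ms) occur
once per breath, phase-locked to exhalation. In NREM the dominant structures
are the slow oscillation (UP/DOWN alternation) with nested 10–15 Hz spindles
and weak UP-state gamma; REM carries tonic gamma without RR.

## Sleep-state scoring

The mPFC signal is decimated to 100 Hz; its delta component is the 1–4 Hz
bandpass. mPFC, delta, EMG and EOG are squared and averaged in contiguous
5-s bins. A bin is NREM when mPFC and delta exceed their recording-wide
mean + 1 SD and EMG falls below mean − 1 SD; remaining bins start as wake,
and wake bins with EMG < mean − 1 SD and EOG > mean + 1 SD become REM (this
automates, with the same rule, what is otherwise a manual REM-correction
step). Four bins form a 20-s epoch labelled by strict majority (≥ 3 of 4);
2–2 ties are unresolvable and become "Transition".

Because thresholds are z-scores over the whole recording, the rule presumes
wake-predominant sessions: with wake fraction w and EMG variance dominated
by wake, mean − 1 SD of the EMG feature is positive only for w ≳ 0.6. The
synthetic demonstration schedules therefore use roughly 60 % wake / 25 %
NREM / 15 % REM. Labels are exactly invariant to rescaling any channel by a
positive constant; a zero-variance feature degenerates its threshold to the
mean and is flagged in the returned threshold table.

## Event detection

**Gamma bursts.** The mPFC trace is decimated to 1000 Hz, band-passed
30–55 Hz, and its RMS computed in a centred 25-ms sliding window ("RMS,
τ = 0.025" is implemented as windowed rather than exponential smoothing,
matching windowed RMS-amplitude processing). Local RMS maxima ≥ 25 µV inside
wake epochs are bursts; burst duration is the contiguous supra-threshold
interval containing the peak (the threshold at which the reported
382 ± 90 ms durations can be recalibrated); peaks closer than 200 ms are
resolved in favour of the larger one, preventing double counts within one
burst envelope.

**RR phase of events.** The mPFC signal is decimated to 100 Hz and
low-passed < 5 Hz; troughs of this slow envelope define consecutive 0-to-2π
periods and event times are mapped linearly within their enclosing
trough-to-trough interval. Events outside the first/last trough are dropped.
The assignment is invariant to amplitude scaling.

**Spindles.** Spindle power is the squared 10–15 Hz bandpass smoothed with a
100-ms RMS window; the threshold mean + 0.5 SD is computed over NREM samples
only (the statistic's support is not otherwise specified; NREM-only keeps it
stable across wake-heavy sessions). Supra-threshold intervals are revised in
a fixed order — drop < 300 ms, merge gaps < 300 ms, drop > 3 s — which is a
contract: a short fragment dropped in step 1 cannot bridge two intervals in
step 2.

**Slow waves.** The trace is decimated to 100 Hz, detrended by removing a
1-s moving average, and band-limited to 1–8 Hz. Peaks > 150 µV with full
width at half maximum ≤ 200 ms inside NREM are kept when a rising zero
crossing exists within 250 ms before the peak (DOWN-state onset) and a
falling one within 250 ms after (UP-state onset). UP/DOWN gamma compares
30–55 Hz mean-square power in [offset, offset + 0.2 s] versus
[onset, onset + 0.2 s] with a paired t-test.

## Phase–amplitude coupling and circular statistics

Instantaneous phase and amplitude are the angle and magnitude of the
analytic signal of the band-passed trace. The modulation index uses 18
phase bins (the 360-bin profile is reserved for plots): the mean-amplitude
profile is normalised to sum 1 and MI = [log N − H(p)]/log N with natural-log
Shannon entropy; empty bins contribute zero with 0·log 0 := 0, and the
result is clipped to [0, 1] against floating-point underrun. MI is exactly 0
for a flat profile, 1 for a single-bin profile, and invariant to amplitude
scaling and profile rotation.

Default MI bands are 0.2–2.5 Hz (phase) → 30–60 Hz (amplitude);
comodulograms scan 1-Hz-wide phase bands over 0.2–5 Hz against 5-Hz-wide
amplitude bands over 25–60 Hz. The two grids are deliberately kept as
separate defaults of their respective operations. Since no analytic null is
available for MI, significance uses a surrogate distribution built by
circularly time-shifting the amplitude series by uniform offsets ≥ 1 s
(200 surrogates, 95th percentile), which preserves the autocorrelation of
both series.

The Rayleigh test uses the small-sample-corrected approximation
p = exp(√(1 + 4n + 4(n² − (nR̄)²)) − (1 + 2n)), clipped to (0, 1]; it agrees
with the independent implementation in pingouin to 1e-9 relative.

Respiration phase is the Hilbert angle of the < 5 Hz low-passed respiration
signal, rotated so that detected exhalation onsets sit at 0 rad. Exhalation
onsets are rising mean-crossings for a thermocouple sensor (voltage rises
with exhalation) and falling crossings for a piezo chest strap; the sensor
convention must be declared.

## Spectra, coherence, lags

State-wise spectra are Welch averages (1-s Hann windows, 50 % overlap —
1-Hz resolution spans RR through gamma; window length and overlap are a
documented choice) over the contiguous runs of each state. Band-power
dynamics use non-overlapping 5-s windows (mean square of the band-passed
signal) with a within-window SD over 0.5-s sub-blocks quantifying
burstiness. Exponential decays y = a·e^(−bx) + c are fitted by robust
(soft-L1) nonlinear least squares with non-negative a, b; the reported r is
the Pearson correlation between fit and data.

Welch coherence requires ≥ 8 averaging windows per segment (with one window
magnitude-squared coherence is identically 1); segment coherences are
averaged, and a frequency-wise product of two mean coherence functions
reproduces the common-peak map construction. Wavelet coherence uses the
analytic (complex) Morlet wavelet with boxcar smoothing over 3 scales ×
0.25 s; windows of 2.5 s are centred on exhalation onsets (≥ 10 usable
onsets required) and averaged.

Cross-correlation lags between 30–80 Hz band-passed signal pairs are
searched within ±50 ms — wider windows risk cycle-skipping onto the ~25-ms
gamma side-lobes. The reported lag (positive = first signal leads) is the
highest positive peak; reliability requires the peak to exceed 3/√n_eff
where n_eff = n · 2·bandwidth/fs accounts for the autocorrelation of
band-limited noise. The estimator is antisymmetric under operand swap and
recovers constructed 2–20 ms delays within ±1 ms at SNR 1.

## Spikes and intracellular analysis

Online template matching is replaced by an offline chain: 300–8000 Hz
bandpass (capped below Nyquist), candidate spikes as |signal| peaks above a
robust (MAD-based) multiple of the noise SD with peak spacing of half the
3-ms waveform window (suppressing filter-ringing side lobes of the same
spike), PCA to 3 components, k-means over k = 2…3 and silhouette-based
acceptance (mean silhouette ≥ 0.4) — otherwise all spikes form one unit.
This keeps the original acceptance notion of "well-separated PCA clusters"
without the incremental template bookkeeping.

PETHs accumulate spikes in 1-ms bins over ±1.5 s around events; rate =
count/(n_sweeps × bin width), so the integral of rate × bin width equals
the mean spikes per sweep exactly. The shuffle null jitters event times
uniformly within ±1.5 s (default 500 shuffles); a bin is significant outside
the two-sided α = 0.01 null quantiles, uncorrected by default (an optional
Bonferroni flag exists). ISI histograms are restricted to provided intervals
(e.g. detected gamma bursts), with 1-ms bins centred on integer lags so a
perfectly periodic 40-Hz train reports exactly 25 ms. Autocorrelograms use
the same centred binning (mirror-symmetric by construction) and exclude the
zero-lag bin.

APs are Vm peaks > mean + 10 SD (2-ms refractory). EPSPs are peaks of dV/dt
(Vm low-passed < 1000 Hz, then differentiated) above mean + 1…3 SD;
detections within 3 ms of an AP or within 20 ms of the trace ends (filter
transients) are excluded, and a flat-slope guard returns no events when the
dV/dt variance is numerically zero. Vm phase profiles detrend with a 5-s
moving average (dropping half a window at each end), min–max normalise to
100 %, and bin the analytic-signal magnitude by respiration phase (360
bins); event phases are tested with the Rayleigh test. Input resistance per
pulse is ΔV_steady/ΔI with the steady window the last 30 % of the pulse
minus a 50-ms pre-pulse baseline (the steady-state window is a package
choice); pulses containing APs are excluded, ≥ 3 pulses per phase class are
required, and classes are compared by t-test.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions of the analyses:

- **Respiration**: lognormal cycle lengths (strictly positive), mean
  1 breath/s, CV 0.1; the signal rises at exhalation onset (thermocouple
  convention); onsets are exact ground truth.
- **Wake**: RR component −cos(phase) (trough at exhalation onset) at
  100 µV; per cycle, ⌊rate⌋ + Bernoulli(frac) gamma bursts (default rate 1 —
  exactly one per breath) with von Mises centre phases (default κ = 2 about
  exhalation onset); bursts are Gaussian-windowed 40-Hz sinusoids, window
  σ = duration/4, default duration 382 ms, amplitude 100 µV (RMS peak
  ≈ 71 µV, ~3× the 25 µV detection threshold). Burst waveforms are shared
  (scaled) across mPFC/Reu/HC so inter-regional gamma coherence exists.
- **NREM**: 300 µV Gaussian slow-wave pulses (σ = 50 ms → FWHM ≈ 118 ms)
  at 1 Hz with jitter, weak 40-Hz gamma in the following UP window, spindles
  (Hann-windowed 12.5 Hz, 0.5–1.5 s, 6/min) and a 1–4 Hz noise floor
  (80 µV RMS) giving the delta dominance the scorer expects.
- **REM**: tonic band-limited gamma, no RR. EMG is white noise with
  state-dependent SD 100/20/5 µV (wake/NREM/REM); EOG bursts only in REM.
- **Background**: 1/f^a Gaussian noise (FFT-shaped, default a = 1,
  10 µV RMS); its log–log PSD slope matches the exponent within 10 % over
  2–80 Hz.
- **Spikes**: inhomogeneous point process by thinning; rate multiplicatively
  modulated by gamma phase (von Mises factor, trough-preferring) and
  optionally RR phase; absolute refractory 2 ms. At ~0.5 spikes per gamma
  cycle the ISI mode sits at the 25-ms gamma period; at ≳ 1 spike/cycle
  within-burst doublets dominate instead — the defaults use 20 Hz base rate.
- **Vm**: rest −70 mV; smoothed UP/DOWN square wave (12 mV) in NREM-labelled
  segments; EPSP kernels (1-ms rise, 15-ms decay) at von Mises phases
  (default preference π, the exhalation→inhalation transition); APs inserted
  where the subthreshold trace crosses threshold; rectangular current pulses
  with exponential charging (τ_m = 10 ms) scaled by a phase-class input
  resistance (default 60 MΩ inhalation / 40 MΩ exhalation); membrane noise
  is low-passed at the membrane time-constant corner 1/(2πτ_m) ≈ 16 Hz, so
  its dV/dt stays physiologically far below EPSP rise slopes.

One master seed spawns deterministic per-channel streams; generation is
bit-reproducible. What the generator does **not** emulate: movement and
electrode artifacts, non-stationary breathing rates, volume conduction,
spike waveform drift and overlap, 50/60 Hz interference, and the amplitude
distribution of real bursts (only the mean duration is matched — the source
distribution is unreported). Detector scores on synthetic data are
therefore upper bounds relative to real recordings with artifacts.

## Problem sizes and numerical choices

Validation runs use desk-scale sizes chosen as the package's own test
conditions: 300-s wake sessions at 1 kHz for burst recovery, 400-s
three-state sessions at 500 Hz for scoring, 300-s spike trains for ISI
statistics, 40–60 s Vm traces at 5 kHz for intracellular checks. The modal
inter-burst interval uses 0.1-s histogram bins with edges at multiples of
the bin width; ISI/autocorrelation bins are centred on integer lags.
Tie-breaks: competing burst peaks keep the larger; k-means uses a fixed
random state; epoch ties are Transition. Degenerate inputs (constant
signals, zero-variance features, flat dV/dt, empty event lists) return
empty results or mean-degenerate thresholds rather than raising, except
where a precondition is genuinely violated (too-short recordings, missing
troughs, invalid bands), which raises with a message naming the constraint.

## Known limitations

- The scoring rule is threshold-based and global; it does not handle long
  recordings with drifting noise floors (no per-hour normalisation) and
  requires wake-predominant sessions.
- Burst "duration" depends on the 25 µV threshold; no attempt is made to
  deconvolve overlapping bursts.
- The spike sorter is deliberately minimal (no drift correction or overlap
  resolution) and caps at 3 units per channel.
- Wavelet-coherence smoothing parameters (3 scales × 0.25 s) trade variance
  against time–frequency resolution; very short windows (< 1 s) are not
  meaningful with them.
- EDF output quantises to 16 bits over each channel's range (relative error
  ~1.5e-5), and sampling rates must be integer samples per second.
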