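"""Automated wake/NREM/REM scoring from LFP, EMG and EOG.

The rule operates on mean-square features in contiguous 5-s bins: a bin is
NREM when both the broadband prefrontal signal and its delta (1-4 Hz)
component exceed their recording-wide mean + 1 SD while the EMG falls below
mean - 1 SD; remaining bins start as wake, and wake bins with low EMG and
high EOG are relabelled REM.  Bins are then aggregated into 20-s epochs by
strict majority (>= 3 of 4 bins), ties and split epochs becoming
"Transition".

Because thresholds are z-scores over the whole recording, the rule presumes
recordings in which wake is the prevalent state; labels are invariant to
rescaling any input channel by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Trace, StateSchedule, bandpass, decimate_to

BIN_S = 5.0
BINS_PER_EPOCH = 4
EPOCH_S = BIN_S * BINS_PER_EPOCH


@dataclass
class BinFeatures:
    """Mean-square features per contiguous 5-s bin."""

    t_start_s: np.ndarray
    mean_sq_mpfc: np.ndarray
    mean_sq_delta: np.ndarray
    mean_sq_emg: np.ndarray
    mean_sq_eog: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_start_s": self.t_start_s,
            "mean_sq_mpfc": self.mean_sq_mpfc,
            "mean_sq_delta": self.mean_sq_delta,
            "mean_sq_emg": self.mean_sq_emg,
            "mean_sq_eog": self.mean_sq_eog,
        })


@dataclass
class StateLabels:
    """Per-bin and per-epoch state labels with the thresholds used."""

    bin_labels: np.ndarray                      # state per 5-s bin
    epoch_labels: np.ndarray                    # state per 20-s epoch
    thresholds_used: dict[str, tuple[float, float]] = field(default_factory=dict)
    bin_s: float = BIN_S

    def epoch_frame(self) -> pd.DataFrame:
        starts = np.arange(len(self.epoch_labels)) * EPOCH_S
        return pd.DataFrame({"epoch_start_s": starts,
                             "epoch_end_s": starts + EPOCH_S,
                             "state": self.epoch_labels})

    def sample_states(self, fs: float, n: int) -> np.ndarray:
        """Epoch label per sample; samples past the last full epoch are
        labelled 'Transition'."""
        out = np.full(n, "Transition", dtype=object)
        per_epoch = int(round(EPOCH_S * fs))
        for i, lab in enumerate(self.epoch_labels):
            out[i * per_epoch: min((i + 1) * per_epoch, n)] = lab
        return out

    def mask(self, state: str, fs: float, n: int) -> np.ndarray:
        return self.sample_states(fs, n) == state

    @classmethod
    def from_schedule(cls, schedule: StateSchedule, duration_s: float
                      ) -> "StateLabels":
        """Oracle labels derived directly from a ground-truth schedule
        (majority state within each bin)."""
        n_bins = int(duration_s // BIN_S)
        labels = np.empty(n_bins, dtype=object)
        for i in range(n_bins):
            mid = i * BIN_S + BIN_S / 2
            labels[i] = schedule.state_at(min(mid, schedule.duration_s - 1e-9))
        return aggregate_epochs(labels)


def _bin_mean_sq(x: np.ndarray, fs: float, n_bins: int) -> np.ndarray:
    per = int(round(BIN_S * fs))
    return (x[: n_bins * per] ** 2).reshape(n_bins, per).mean(axis=1)


def compute_bin_features(mpfc: Trace, emg: Trace, eog: Trace) -> BinFeatures:
    """Mean-square of the 100-Hz-decimated mPFC, its 1-4 Hz delta component,
    and the raw EMG/EOG, in contiguous 5-s bins."""
    durations = {tr.label or k: tr.duration_s
                 for k, tr in (("mpfc", mpfc), ("emg", emg), ("eog", eog))}
    if max(durations.values()) - min(durations.values()) > BIN_S / 2:
        raise ValueError(f"trace durations differ: {durations}")
    if mpfc.duration_s < BIN_S:
        raise ValueError("recording shorter than one 5-s bin")
    if mpfc.fs < 200:
        raise ValueError("mPFC sampling rate must be >= 200 Hz")
    low = decimate_to(mpfc, 100.0)
    delta = bandpass(low.data, 100.0, 1.0, 4.0)
    n_bins = int(min(durations.values()) // BIN_S)
    return BinFeatures(
        t_start_s=np.arange(n_bins) * BIN_S,
        mean_sq_mpfc=_bin_mean_sq(low.data, 100.0, n_bins),
        mean_sq_delta=_bin_mean_sq(delta, 100.0, n_bins),
        mean_sq_emg=_bin_mean_sq(emg.data, emg.fs, n_bins),
        mean_sq_eog=_bin_mean_sq(eog.data, eog.fs, n_bins),
    )


def score_bins(features: BinFeatures) -> tuple[np.ndarray, dict]:
    """Classify each 5-s bin as wake, NREM or REM.

    NREM: mPFC and delta mean-square above mean + 1 SD and EMG below
    mean - 1 SD.  Wake bins with EMG below mean - 1 SD and EOG above
    mean + 1 SD become REM.  Statistics are computed per feature over the
    whole recording; a zero-variance feature degenerates its threshold to
    the mean (flagged in the returned thresholds).
    """
    n = len(features.t_start_s)
    if n < 12:
        raise ValueError("need at least 12 bins (one minute) of context")
    thresholds: dict[str, tuple[float, float]] = {}

    def stats(x: np.ndarray, name: str) -> tuple[float, float]:
        mu, sd = float(np.mean(x)), float(np.std(x))
        thresholds[name] = (mu, sd)
        return mu, sd

    mu_m, sd_m = stats(features.mean_sq_mpfc, "mpfc")
    mu_d, sd_d = stats(features.mean_sq_delta, "delta")
    mu_e, sd_e = stats(features.mean_sq_emg, "emg")
    mu_o, sd_o = stats(features.mean_sq_eog, "eog")

    nrem = ((features.mean_sq_mpfc > mu_m + sd_m)
            & (features.mean_sq_delta > mu_d + sd_d)
            & (features.mean_sq_emg < mu_e - sd_e))
    labels = np.where(nrem, "NREM", "wake").astype(object)
    rem = ((labels == "wake")
           & (features.mean_sq_emg < mu_e - sd_e)
           & (features.mean_sq_eog > mu_o + sd_o))
    labels[rem] = "REM"
    return labels, thresholds


def aggregate_epochs(bin_labels: np.ndarray,
                     thresholds: dict | None = None) -> StateLabels:
    """Combine 5-s bins into 20-s epochs by strict majority (>= 3 of 4);
    epochs without one, including 2-2 ties, are 'Transition'.  A trailing
    partial epoch is dropped."""
    bin_labels = np.asarray(bin_labels, dtype=object)
    if len(bin_labels) < BINS_PER_EPOCH:
        raise ValueError("need at least 4 bins for one epoch")
    n_epochs = len(bin_labels) // BINS_PER_EPOCH
    epochs = np.empty(n_epochs, dtype=object)
    for i in range(n_epochs):
        group = bin_labels[i * BINS_PER_EPOCH:(i + 1) * BINS_PER_EPOCH]
        vals, counts = np.unique(group.astype(str), return_counts=True)
        best = counts.argmax()
        epochs[i] = vals[best] if counts[best] >= 3 else "Transition"
    return StateLabels(bin_labels=bin_labels, epoch_labels=epochs,
                       thresholds_used=thresholds or {})


def score_session(mpfc: Trace, emg: Trace, eog: Trace) -> StateLabels:
    """Full scoring chain: features -> bin labels -> 20-s epochs."""
    feats = compute_bin_features(mpfc, emg, eog)
    labels, thresholds = score_bins(feats)
    return aggregate_epochs(labels, thresholds)
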