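"""Session loading, the analysis pipeline, and run manifests.

A :class:`SessionBundle` maps channel labels to traces with per-channel
units and a provenance log.  ``run_pipeline`` executes the standard stage
order (score -> events -> pac -> coherence -> spikes) on a bundle, writing
one CSV per product plus a JSON manifest carrying parameters, counts and a
configuration hash so outputs from different configs never collide.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import edf as edfio
from .core import Trace
from .sleepstate import score_session, StateLabels
from . import events as ev
from . import phase_coupling as pc
from . import spectral as sp

REQUIRED_CHANNELS = {
    "score": ("mPFC", "EMG", "EOG"),
    "events": ("mPFC",),
    "pac": ("mPFC", "RESP"),
    "coherence": ("mPFC", "Reu", "RESP"),
    "lags": ("mPFC", "Reu"),
}

DEFAULT_ALIASES = {
    "mpfc": "mPFC", "pfc": "mPFC", "reu": "Reu", "re": "Reu",
    "hc": "HC", "hpc": "HC", "emg": "EMG", "eog": "EOG",
    "resp": "RESP", "respiration": "RESP",
}


@dataclass
class SessionBundle:
    """Channel map plus recording metadata and a provenance log."""

    channels: dict[str, Trace]
    metadata: dict = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def require(self, labels: tuple[str, ...], stage: str) -> None:
        missing = [lb for lb in labels if lb not in self.channels]
        if missing:
            raise KeyError(f"stage {stage!r} requires missing channel(s) "
                           f"{missing}; available: {list(self.channels)}")

    def __getitem__(self, label: str) -> Trace:
        return self.channels[label]


def _canonical(label: str, aliases: dict[str, str]) -> str:
    return aliases.get(label.strip().lower(), label.strip())


def read_session(path: str | Path, fmt: str | None = None,
                 aliases: dict[str, str] | None = None) -> SessionBundle:
    """Load an EDF or CSV/TSV recording into a session bundle.

    CSV files need a header row with a time column named ``t`` (seconds)
    followed by one column per channel; sampling must be uniform.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    aliases = {**DEFAULT_ALIASES, **(aliases or {})}
    if fmt is None:
        fmt = "EDF" if path.suffix.lower() == ".edf" else "CSV"
    if fmt.upper() == "EDF":
        raw = edfio.read_edf(path)
        channels = {_canonical(k, aliases): tr for k, tr in raw.items()}
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep)
        if "t" not in df.columns:
            raise ValueError("CSV session needs a time column named 't'")
        t = df["t"].to_numpy(float)
        dt = np.diff(t)
        if len(dt) < 1 or np.ptp(dt) > 1e-6 * np.mean(dt) + 1e-12:
            raise ValueError("CSV time column is not uniformly sampled")
        fs = 1.0 / float(np.mean(dt))
        channels = {}
        for col in df.columns:
            if col == "t":
                continue
            name = _canonical(col, aliases)
            channels[name] = Trace(df[col].to_numpy(float), fs, name, "uV")
    for name, tr in channels.items():
        tr.label = name
    bundle = SessionBundle(channels=channels,
                           metadata={"source": str(path), "format": fmt})
    bundle.provenance.append(f"loaded {len(channels)} channels from {path}")
    return bundle


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(bundle: SessionBundle, out_dir: str | Path,
                 config: dict | None = None) -> dict:
    """Execute score -> events -> pac -> coherence (-> spikes) and write
    CSV products plus a JSON manifest.  Stages can be restricted with
    ``config["stages"]``; a stage failure halts with a stage-scoped error
    and partial outputs are preserved."""
    config = dict(config or {})
    stages = config.get("stages", ["score", "events", "pac", "coherence"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    manifest: dict = {"config_hash": chash, "config": config,
                      "stages": {}, "skipped": []}
    states: StateLabels | None = None
    bursts = None

    def record(stage: str, **info):
        manifest["stages"][stage] = info

    try:
        if "score" in stages:
            bundle.require(REQUIRED_CHANNELS["score"], "score")
            states = score_session(bundle["mPFC"], bundle["EMG"], bundle["EOG"])
            df = states.epoch_frame()
            df.to_csv(out / f"states_{chash}.csv", index=False)
            record("score", n_epochs=len(df),
                   counts={s: int((df.state == s).sum())
                           for s in df.state.unique()})
        else:
            manifest["skipped"].append("score")

        if "events" in stages:
            bundle.require(REQUIRED_CHANNELS["events"], "events")
            bursts = ev.detect_gamma_bursts(bundle["mPFC"], states)
            if len(bursts):
                phases, kept = ev.assign_rr_phase(
                    bursts.t_peak_s.to_numpy(), bundle["mPFC"])
                keep = np.isin(bursts.t_peak_s.to_numpy(), kept)
                bursts = bursts[keep].reset_index(drop=True)
                bursts["rr_phase_rad"] = phases
            bursts.to_csv(out / f"gamma_bursts_{chash}.csv", index=False)
            spindles = ev.detect_spindles(bundle["mPFC"], states)
            spindles.to_csv(out / f"spindles_{chash}.csv", index=False)
            sws = ev.detect_slow_waves(bundle["mPFC"], states)
            sws.to_csv(out / f"slow_waves_{chash}.csv", index=False)
            record("events", n_bursts=len(bursts), n_spindles=len(spindles),
                   n_slow_waves=len(sws))
        else:
            manifest["skipped"].append("events")

        if "pac" in stages:
            bundle.require(REQUIRED_CHANNELS["pac"], "pac")
            mi = pc.pac_mi(bundle["mPFC"])
            como = pc.comodulogram(bundle["mPFC"])
            pd.DataFrame(
                como.mi,
                index=[f"{a}-{b}Hz" for a, b in como.phase_bands],
                columns=[f"{a}-{b}Hz" for a, b in como.amp_bands],
            ).to_csv(out / f"comodulogram_{chash}.csv")
            record("pac", mi=float(mi),
                   argmax=[list(b) for b in como.argmax_bands()])
        else:
            manifest["skipped"].append("pac")

        if "coherence" in stages:
            bundle.require(REQUIRED_CHANNELS["coherence"], "coherence")
            f, coh = sp.welch_coherence(bundle["mPFC"], bundle["Reu"])
            pd.DataFrame({"freq_hz": f, "coherence": coh}).to_csv(
                out / f"coherence_{chash}.csv", index=False)
            lag = sp.gamma_xcorr_lag(bundle["mPFC"], bundle["Reu"],
                                     pair="mPFC-Reu")
            pd.DataFrame([lag.__dict__]).to_csv(
                out / f"lags_{chash}.csv", index=False)
            record("coherence", gamma_band_mean=float(
                coh[(f >= 30) & (f <= 55)].mean()), lag_ms=lag.lag_ms)
        else:
            manifest["skipped"].append("coherence")
    except Exception as exc:  # noqa: BLE001 - stage-scoped reporting
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / f"manifest_{chash}.json").write_text(
            json.dumps(manifest, indent=2, default=str))
        raise
    (out / f"manifest_{chash}.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return manifest
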