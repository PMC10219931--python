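"""Minimal EDF (European Data Format) writing and reading.

Writing implements the EDF specification directly (ASCII header, 16-bit
little-endian samples in 1-s data records, per-channel physical scaling);
reading goes through ``mne.io.read_raw_edf``.  Sampling rates must be whole
numbers of samples per 1-s record, and the recording is truncated to whole
records on write.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from .core import Trace

_RECORD_S = 1.0


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, traces: dict[str, Trace]) -> None:
    """Write channels to an EDF file (16-bit, 1-s records).

    All channels may have different sampling rates but must share the same
    duration; each rate must be an integer number of samples per second.
    """
    traces = dict(traces)
    if not traces:
        raise ValueError("no channels to write")
    n_records = int(min(tr.duration_s for tr in traces.values()) // _RECORD_S)
    if n_records < 1:
        raise ValueError("recording shorter than one 1-s data record")
    labels, spr, phys_min, phys_max, digital = [], [], [], [], []
    for label, tr in traces.items():
        ns = tr.fs * _RECORD_S
        if abs(ns - round(ns)) > 1e-6:
            raise ValueError(f"{label}: fs must be integer samples per second")
        ns = int(round(ns))
        x = tr.data[: n_records * ns]
        pmin, pmax = float(x.min()), float(x.max())
        if pmax - pmin < 1e-9:
            pmax = pmin + 1.0
        scaled = np.round((x - pmin) / (pmax - pmin)
                          * 65535.0 - 32768.0).astype("<i2")
        labels.append(label)
        spr.append(ns)
        phys_min.append(pmin)
        phys_max.append(pmax)
        digital.append(scaled.reshape(n_records, ns))
    ns_total = len(labels)
    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate X X X X", 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(str(256 * (1 + ns_total)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field(str(int(_RECORD_S)), 8),
        _field(str(ns_total), 4),
    ])
    sig_hdr = b"".join([
        b"".join(_field(lab, 16) for lab in labels),
        b"".join(_field("", 80) for _ in labels),
        b"".join(_field(traces[lab].units, 8) for lab in labels),
        b"".join(_field(f"{v:.6g}", 8) for v in phys_min),
        b"".join(_field(f"{v:.6g}", 8) for v in phys_max),
        b"".join(_field("-32768", 8) for _ in labels),
        b"".join(_field("32767", 8) for _ in labels),
        b"".join(_field("", 80) for _ in labels),
        b"".join(_field(str(s), 8) for s in spr),
        b"".join(_field("", 32) for _ in labels),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig_hdr)
        for rec in range(n_records):
            for d in digital:
                fh.write(d[rec].tobytes())


def read_edf(path: str | Path) -> dict[str, Trace]:
    """Read an EDF file into labelled traces (microvolt-scale channels are
    returned in uV, others in their header units)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    orig_units = getattr(raw, "_orig_units", {}) or {}
    scale = {"uV": 1e6, "µV": 1e6, "mV": 1e3, "V": 1.0, "nA": 1e9}
    out: dict[str, Trace] = {}
    for i, name in enumerate(raw.ch_names):
        unit = orig_units.get(name, "uV")
        factor = scale.get(unit, 1e6)
        data = raw.get_data(picks=[i])[0] * factor  # mne returns volts
        out[name] = Trace(data, float(raw.info["sfreq"]), name,
                          "uV" if unit == "µV" else unit)
    return out
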