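"""Minimal EDF (European Data Format) output, plus MNE-backed input.

Recordings are exported as standard EDF — fixed-layout ASCII header,
one-second data records of little-endian 16-bit integers scaled between
per-channel physical and digital ranges — with one EEG (Oz) and one EOG
channel, and the event/behavior table as a TSV sidecar.  Reading goes
through :func:`mne.io.read_raw_edf`, which also makes any EDF reader a
round-trip check on the writer.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Recording

_DIG_MAX = 32767


def _field(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    recording: Recording,
    path: str | Path,
    physical_range_uv: float = 1000.0,
    labels: tuple[str, str] = ("EEG Oz", "EOG horizontal"),
) -> Path:
    """Write the recording's EEG and EOG channels to an EDF file.

    Signals are clipped to ``+/-physical_range_uv`` and quantized to 16
    bits; the trace is zero-padded to a whole number of 1 s records.
    The event table is written alongside as ``<stem>_events.tsv``.
    Returns the EDF path.
    """
    path = Path(path)
    if path.suffix.lower() != ".edf":
        path = path.with_suffix(".edf")
    fs = recording.fs
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(fs)  # samples per 1 s record, per channel
    signals = [np.asarray(recording.eeg, float), np.asarray(recording.eog, float)]
    n = max(len(s) for s in signals)
    n_records = math.ceil(n / spr)

    header = b"".join([
        _field("0", 8),                              # version
        _field("X X X X", 80),                       # patient id (anonymous)
        _field("Startdate X pactacs X synthetic", 80),
        _field("01.01.00", 8), _field("00.00.00", 8),  # date, time
        _field(str(256 * (1 + len(signals))), 8),    # header bytes
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),                              # record duration, s
        _field(str(len(signals)), 4),
    ])
    per_sig = [
        [_field(lab, 16) for lab in labels],
        [_field("AgAgCl electrode", 80)] * 2,
        [_field("uV", 8)] * 2,
        [_field(f"{-physical_range_uv:g}", 8)] * 2,
        [_field(f"{physical_range_uv:g}", 8)] * 2,
        [_field(str(-_DIG_MAX - 1), 8)] * 2,
        [_field(str(_DIG_MAX), 8)] * 2,
        [_field("", 80)] * 2,
        [_field(str(spr), 8)] * 2,
        [_field("", 32)] * 2,
    ]
    header += b"".join(b"".join(block) for block in per_sig)

    scale = _DIG_MAX / physical_range_uv
    digitized = []
    for s in signals:
        buf = np.zeros(n_records * spr)
        buf[: len(s)] = np.clip(s, -physical_range_uv, physical_range_uv)
        digitized.append(np.round(buf * scale).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for d in digitized:
                fh.write(d[r * spr : (r + 1) * spr].tobytes())

    recording.events.to_csv(
        path.with_name(path.stem + "_events.tsv"), sep="\t", index=False
    )
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF written by :func:`write_edf` back into a Recording."""
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads volts; recordings are in uV
    ev_path = path.with_name(path.stem + "_events.tsv")
    events = (
        pd.read_csv(ev_path, sep="\t")
        if ev_path.exists()
        else pd.DataFrame({"sample": [], "onset_s": []})
    )
    return Recording(eeg=data[0], eog=data[1], events=events, fs=float(raw.info["sfreq"]))
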