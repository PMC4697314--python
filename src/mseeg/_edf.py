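"""Minimal EDF (European Data Format) I/O.

Writing produces a plain 16-bit EDF file (one physical-dimension ``uV``
signal per EEG channel, equal sampling rates).  Reading goes through MNE's
EDF reader so that the hand-written writer is always checked against an
independent parser.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _fmt(value: float, width: int) -> bytes:
    """ASCII-format a number into exactly ``width`` bytes (EDF header field)."""
    for prec in range(6, -1, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {value} in {width} chars")


def _txt(s: str, width: int) -> bytes:
    b = s.encode("ascii", "replace")[:width]
    return b.ljust(width)


def write_edf(path: str | Path, data: np.ndarray, sampling_rate: float,
              channel_labels: list[str]) -> None:
    """Write a channels x samples matrix (microvolts) as a 16-bit EDF file.

    Uses 1-second data records when the sample count is a whole number of
    seconds, otherwise a single record spanning the file.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    fs = float(sampling_rate)
    if n_samp % int(fs) == 0 and fs == int(fs):
        spr = int(fs)                      # samples per record
        n_rec = n_samp // spr
        rec_dur = 1.0
    else:
        spr = n_samp
        n_rec = 1
        rec_dur = n_samp / fs

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    header = b""
    header += _txt("0", 8)
    header += _txt("X X X X", 80)                  # patient id
    header += _txt("Startdate X X X X", 80)        # recording id
    header += _txt("01.01.00", 8)
    header += _txt("00.00.00", 8)
    header += _txt(str(256 * (1 + n_ch)), 8)
    header += _txt("", 44)
    header += _txt(str(n_rec), 8)
    header += _fmt(rec_dur, 8)
    header += _txt(str(n_ch), 4)
    for lab in channel_labels:
        header += _txt(lab, 16)
    header += _txt("", 80) * n_ch                  # transducer
    header += _txt("uV", 8) * n_ch
    for v in pmin:
        header += _fmt(v, 8)
    for v in pmax:
        header += _fmt(v, 8)
    header += _txt(str(dmin), 8) * n_ch
    header += _txt(str(dmax), 8) * n_ch
    header += _txt("", 80) * n_ch                  # prefiltering
    header += _txt(str(spr), 8) * n_ch
    header += _txt("", 32) * n_ch

    # physical -> digital, per channel
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (data in microvolts, sampling rate, labels)."""
    from mne.io import read_raw_edf

    raw = read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE holds EEG in volts
    return data, float(raw.info["sfreq"]), list(raw.ch_names)
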