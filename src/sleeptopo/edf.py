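"""Minimal European Data Format (EDF) reader and writer.

Implements the plain EDF subset needed for interchange of synthetic and real
recordings: an ASCII header, one-second data records, 16-bit little-endian
samples with per-signal physical scaling. No annotations, no EDF+
discontinuities. Amplitudes survive a write/read round trip to within the
16-bit quantization of the per-channel physical range.
"""

from __future__ import annotations

import os

import numpy as np

from .spectra import Recording

__all__ = ["read_edf", "write_edf"]

_HDR = 256  # bytes, fixed header and per-signal blocks


def _field(text: str, width: int) -> bytes:
    s = text[:width].ljust(width)
    return s.encode("ascii")


def _num_field(value: float, width: int = 8) -> bytes:
    """Format a number into a fixed-width ASCII field without truncation."""
    for prec in range(6, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width:
            return _field(s, width)
    raise ValueError(f"cannot represent {value} in {width} characters")


def write_edf(recording: Recording, path: str | os.PathLike) -> None:
    """Write a Recording as plain EDF (1-s records, 16-bit samples).

    The per-channel physical range is the symmetric data maximum; trailing
    samples that do not fill a whole record are dropped.
    """
    fs = recording.sampling_rate
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    x = np.asarray(recording.samples, dtype=float)
    n_ch, n_samp = x.shape
    n_rec = n_samp // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one 1-s data record")
    x = x[:, : n_rec * spr]
    pmax = np.maximum(np.abs(x).max(axis=1), 1e-6)
    # round the range through its ASCII header representation so writer and
    # reader use bit-identical scaling
    pmax = np.array([float(_num_field(v).decode()) for v in pmax])
    pmin = -pmax
    dmax, dmin = 32767, -32768
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.rint((x - pmin[:, None]) / scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as f:
        f.write(_field("0", 8))
        f.write(_field(f"subject {recording.subject_id}", 80))
        f.write(_field(f"timepoint {recording.time_point}", 80))
        f.write(_field("01.01.00", 8))
        f.write(_field("00.00.00", 8))
        f.write(_field(str(_HDR * (1 + n_ch)), 8))
        f.write(_field("", 44))
        f.write(_field(str(n_rec), 8))
        f.write(_field("1", 8))
        f.write(_field(str(n_ch), 4))
        for label in recording.channel_labels:
            f.write(_field(label, 16))
        f.write(_field("", 80) * n_ch)                      # transducer
        f.write(_field("uV", 8) * n_ch)                     # dimension
        for v in pmin:
            f.write(_num_field(v))
        for v in pmax:
            f.write(_num_field(v))
        f.write(_field(str(dmin), 8) * n_ch)
        f.write(_field(str(dmax), 8) * n_ch)
        f.write(_field("", 80) * n_ch)                      # prefilter
        f.write(_field(str(spr), 8) * n_ch)
        f.write(_field("", 32) * n_ch)
        # data records: per record, all samples of signal 1, then signal 2 ...
        blocks = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        f.write(np.ascontiguousarray(blocks).tobytes())


def read_edf(path: str | os.PathLike,
             channels: list[str] | None = None) -> Recording:
    """Read a plain EDF file into a Recording.

    ``channels`` optionally selects a labelled subset (e.g. the EEG channels
    of a montage that also carries EOG/EMG signals). All selected signals
    must share one sampling rate.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"EDF file not found: {path}")
    with open(path, "rb") as f:
        hdr = f.read(_HDR)
        if len(hdr) < _HDR:
            raise ValueError(f"malformed EDF header in {path}")
        patient = hdr[8:88].decode("ascii", "replace").strip()
        rec_field = hdr[88:168].decode("ascii", "replace").strip()
        n_rec = int(hdr[236:244].decode("ascii"))
        duration = float(hdr[244:252].decode("ascii"))
        n_sig = int(hdr[252:256].decode("ascii"))
        sig_hdr = f.read(_HDR * n_sig)

        def block(offset: int, width: int) -> list[str]:
            start = offset * n_sig
            return [sig_hdr[start + i * width: start + (i + 1) * width]
                    .decode("ascii", "replace").strip()
                    for i in range(n_sig)]

        # per-signal byte offsets within the signal header: label 0,
        # transducer 16, dimension 96, phys min/max 104/112, dig min/max
        # 120/128, prefilter 136, samples-per-record 216
        labels = block(0, 16)
        pmin = np.array([float(v) for v in block(104, 8)])
        pmax = np.array([float(v) for v in block(112, 8)])
        dmin = np.array([float(v) for v in block(120, 8)])
        dmax = np.array([float(v) for v in block(128, 8)])
        spr = np.array([int(v) for v in block(216, 8)])

        if channels is None:
            sel = list(range(n_sig))
        else:
            missing = [c for c in channels if c not in labels]
            if missing:
                raise ValueError(f"channels not in EDF: {missing}")
            sel = [labels.index(c) for c in channels]
        rates = {spr[i] / duration for i in sel}
        if len(rates) != 1:
            raise ValueError("selected channels have mixed sampling rates; "
                             "pass an explicit channel subset")
        fs = rates.pop()

        raw = np.frombuffer(f.read(), dtype="<i2")
    per_rec = int(spr.sum())
    if raw.size < n_rec * per_rec:
        raise ValueError(f"EDF data truncated in {path}")
    raw = raw[: n_rec * per_rec].reshape(n_rec, per_rec)
    offsets = np.concatenate([[0], np.cumsum(spr)])
    out = np.empty((len(sel), int(n_rec * spr[sel[0]])), dtype=float)
    scale = (pmax - pmin) / (dmax - dmin)
    for row, i in enumerate(sel):
        dig = raw[:, offsets[i]: offsets[i + 1]].reshape(-1).astype(float)
        out[row] = (dig - dmin[i]) * scale[i] + pmin[i]
    sid = patient.removeprefix("subject ").strip()
    tp = 1
    if rec_field.startswith("timepoint "):
        try:
            tp = int(rec_field.split()[1])
        except (IndexError, ValueError):
            tp = 1
    return Recording(samples=out, sampling_rate=fs,
                     channel_labels=[labels[i] for i in sel],
                     subject_id=sid, time_point=tp)
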