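"""Minimal EDF (European Data Format) export/import for waveform records.

Implements the plain EDF layout directly (ASCII headers, 16-bit little-endian
samples, 1-s data records): no EDF library is assumed. Records whose duration
is not a whole number of seconds are zero-padded to the next record boundary.
"""

from __future__ import annotations

import struct
from typing import BinaryIO

import numpy as np

from .psg_sim import PsgRecord

__all__ = ["export_edf", "import_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field too long: {value!r} > {width}")
    return b.ljust(width)


def export_edf(record: PsgRecord, path: str) -> None:
    """Write a record to ``path`` as standard EDF.

    Physical ranges are set per channel to cover the data symmetrically, so
    re-import reproduces samples within one quantization step.
    """
    if record.n_samples == 0:
        raise ValueError("cannot export an empty record")
    labels = list(record.data.keys())
    ns = len(labels)
    rate = record.rate
    n_records = int(np.ceil(record.n_samples / rate))

    phys_ranges = {}
    for ch in labels:
        peak = float(np.max(np.abs(record.data[ch])))
        # round up to the 0.1 uV written in the ASCII header so writer and
        # reader quantize against identical physical ranges
        peak = float(np.ceil(max(peak, 1.0) * 10) / 10)
        phys_ranges[ch] = (-peak, peak)

    with open(path, "wb") as f:
        f.write(_ascii("0", 8))
        f.write(_ascii("X", 80))              # patient id
        f.write(_ascii("dreamlink simulated", 80))
        f.write(_ascii("01.01.00", 8))
        f.write(_ascii("00.00.00", 8))
        f.write(_ascii(str(256 * (ns + 1)), 8))
        f.write(_ascii("", 44))
        f.write(_ascii(str(n_records), 8))
        f.write(_ascii("1", 8))               # record duration, seconds
        f.write(_ascii(str(ns), 4))

        f.write(b"".join(_ascii(ch, 16) for ch in labels))
        f.write(b"".join(_ascii("simulated", 80) for _ in labels))
        f.write(b"".join(_ascii("uV", 8) for _ in labels))
        f.write(b"".join(_ascii(f"{phys_ranges[ch][0]:.1f}", 8) for ch in labels))
        f.write(b"".join(_ascii(f"{phys_ranges[ch][1]:.1f}", 8) for ch in labels))
        f.write(b"".join(_ascii(str(_DIG_MIN), 8) for _ in labels))
        f.write(b"".join(_ascii(str(_DIG_MAX), 8) for _ in labels))
        f.write(b"".join(_ascii("BP filtered", 80) for _ in labels))
        f.write(b"".join(_ascii(str(rate), 8) for _ in labels))
        f.write(b"".join(_ascii("", 32) for _ in labels))

        padded = {}
        for ch in labels:
            x = np.zeros(n_records * rate)
            x[: record.n_samples] = record.data[ch]
            pmin, pmax = phys_ranges[ch]
            scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
            dig = np.clip(np.round((x - pmin) / scale) + _DIG_MIN, _DIG_MIN, _DIG_MAX)
            padded[ch] = dig.astype("<i2")
        for r in range(n_records):
            for ch in labels:
                f.write(padded[ch][r * rate : (r + 1) * rate].tobytes())


def _read_field(f: BinaryIO, width: int) -> str:
    return f.read(width).decode("ascii").strip()


def import_edf(path: str) -> PsgRecord:
    """Read an EDF file written by :func:`export_edf` back into a record."""
    with open(path, "rb") as f:
        f.read(8 + 80 + 80 + 8 + 8 + 8 + 44)
        n_records = int(_read_field(f, 8))
        rec_dur = float(_read_field(f, 8))
        ns = int(_read_field(f, 4))

        labels = [_read_field(f, 16) for _ in range(ns)]
        f.read(80 * ns)  # transducer
        f.read(8 * ns)   # dimension
        pmins = [float(_read_field(f, 8)) for _ in range(ns)]
        pmaxs = [float(_read_field(f, 8)) for _ in range(ns)]
        dmins = [int(_read_field(f, 8)) for _ in range(ns)]
        dmaxs = [int(_read_field(f, 8)) for _ in range(ns)]
        f.read(80 * ns)  # prefiltering
        nsamp = [int(_read_field(f, 8)) for _ in range(ns)]
        f.read(32 * ns)

        data = {ch: [] for ch in labels}
        for _ in range(n_records):
            for k, ch in enumerate(labels):
                raw = np.frombuffer(f.read(2 * nsamp[k]), dtype="<i2").astype(float)
                scale = (pmaxs[k] - pmins[k]) / (dmaxs[k] - dmins[k])
                data[ch].append((raw - dmins[k]) * scale + pmins[k])

    rate = int(round(nsamp[0] / rec_dur))
    return PsgRecord({ch: np.concatenate(chunks) for ch, chunks in data.items()}, rate=rate)
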