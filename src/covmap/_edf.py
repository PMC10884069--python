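"""Minimal EDF writer.

Writes uncompressed 16-bit EDF with one signal per channel and a single data
record spanning the whole recording (EDF permits fractional record durations).
Values are stored in microvolts; the digital range is the full 16-bit span, so
the quantization step per channel is ``(physmax - physmin) / 65535``.

Reading is delegated to :func:`mne.io.read_raw_edf`; only writing is
implemented here.
"""

from __future__ import annotations

import datetime
import os

import numpy as np

_DIG_MIN = -32768
_DIG_MAX = 32767


def _ascii(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} ascii chars")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    """Format a number into a fixed-width ascii field without losing parseability."""
    if float(value) == int(value) and abs(value) < 10 ** (width - 1):
        s = str(int(value))
        if len(s) <= width:
            return _ascii(s, width)
    for prec in range(width - 1, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width and "inf" not in s:
            return _ascii(s, width)
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(path: str | os.PathLike, data_uv: np.ndarray, sfreq: float,
              ch_names: list[str]) -> None:
    """Write ``data_uv`` (channels x samples, microvolts) as a 16-bit EDF file."""
    data = np.asarray(data_uv, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (channels x samples)")
    n_ch, n_samp = data.shape
    if n_ch != len(ch_names):
        raise ValueError("channel count does not match name list")
    if n_samp == 0:
        raise ValueError("cannot write an empty recording")

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0

    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    now = datetime.datetime(2000, 1, 1)
    record_duration = n_samp / sfreq

    header = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii("Startdate X X X X", 80),
        _ascii(now.strftime("%d.%m.%y"), 8),
        _ascii(now.strftime("%H.%M.%S"), 8),
        _ascii(str(256 * (1 + n_ch)), 8),
        _ascii("", 44),
        _ascii("1", 8),                      # number of data records
        _num(record_duration, 8),
        _ascii(str(n_ch), 4),
    ])

    def field(values, width):
        return b"".join(_ascii(v, width) if isinstance(v, str) else _num(v, width)
                        for v in values)

    header += field([n[:16] for n in ch_names], 16)        # labels
    header += field(["" for _ in ch_names], 80)            # transducer
    header += field(["uV" for _ in ch_names], 8)           # physical dimension
    header += field(list(pmin), 8)
    header += field(list(pmax), 8)
    header += field([_DIG_MIN] * n_ch, 8)
    header += field([_DIG_MAX] * n_ch, 8)
    header += field(["" for _ in ch_names], 80)            # prefiltering
    header += field([n_samp] * n_ch, 8)                    # samples per record
    header += field(["" for _ in ch_names], 32)            # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())  # one record: channels sequentially


def quantization_step(data_uv: np.ndarray) -> np.ndarray:
    """Per-channel amplitude resolution of the EDF encoding of ``data_uv``."""
    data = np.asarray(data_uv, dtype=float)
    span = data.max(axis=1) - data.min(axis=1)
    span[span <= 0] = 2.0
    return span / (_DIG_MAX - _DIG_MIN)
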