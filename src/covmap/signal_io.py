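"""Recordings, montage references, filtering and file I/O.

The central container is :class:`Recording`: a channels-by-samples matrix of
potentials in microvolts with a sampling rate and per-channel metadata.
Preprocessing mirrors standard clinical intracranial practice: demeaning and
50 Hz notch, a within-grid common average reference for subdural grids, a
bipolar montage along strips and depth shafts, downsampling to 500 Hz, and a
2-20 Hz band-pass plus common average reference for the scalp channels.

All frequency-selective filters are 4th-order Butterworth IIR applied
forward-backward (zero phase), so band-limited features stay time-aligned
with the microstate timelines they are later regressed on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from . import _edf
from .errors import FormatError, InvalidMontageError

CHANNEL_KINDS = ("scalp", "grid", "strip", "depth")
INTRACRANIAL_KINDS = ("grid", "strip", "depth")


@dataclass(frozen=True)
class ChannelInfo:
    """Name, electrode category and montage group of one channel.

    ``group`` identifies the physical grid/strip/shaft a contact belongs to and
    must be non-empty for intracranial kinds; ``roi`` is an optional anatomical
    region label used only for aggregation of covariance maps.
    """

    name: str
    kind: str
    group: str = ""
    roi: str | None = None

    def __post_init__(self):
        if self.kind not in CHANNEL_KINDS:
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.kind in INTRACRANIAL_KINDS and not self.group:
            raise ValueError(f"intracranial channel {self.name!r} needs a group")


@dataclass
class Recording:
    """Multichannel time series in microvolts."""

    data: np.ndarray
    sfreq: float
    channels: list[ChannelInfo] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("data rows must match channel metadata length")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")

    # -- convenience -------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def ch_names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.sfreq, list(self.channels))

    def pick(self, names: list[str]) -> "Recording":
        index = {c.name: i for i, c in enumerate(self.channels)}
        missing = [n for n in names if n not in index]
        if missing:
            raise ValueError(f"unknown channels: {missing}")
        rows = [index[n] for n in names]
        return Recording(self.data[rows].copy(), self.sfreq,
                         [self.channels[i] for i in rows])

    def with_data(self, data: np.ndarray) -> "Recording":
        return Recording(np.asarray(data, dtype=float), self.sfreq,
                         list(self.channels))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _default_channels(names: list[str]) -> list[ChannelInfo]:
    return [ChannelInfo(n, "scalp", "scalp") for n in names]


def read_recording(path: str | os.PathLike,
                   channel_table: str | os.PathLike | None = None) -> Recording:
    """Read an EDF file or a BrainVision triplet (via its ``.vhdr``).

    Channel kind/group/roi metadata is taken from the optional sidecar TSV
    (columns ``name, kind, group, roi``); channels absent from the table
    default to scalp.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if path.suffix.lower() == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        elif path.suffix.lower() == ".vhdr":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raise FormatError(f"unsupported extension {path.suffix!r} "
                              "(expected .edf or .vhdr)")
    except FormatError:
        raise
    except Exception as exc:  # mne raises assorted OSError/ValueError subclasses
        raise FormatError(f"could not read {path}: {exc}") from exc

    data = raw.get_data() * 1e6  # MNE keeps EEG in volts
    channels = _default_channels(list(raw.ch_names))
    if channel_table is not None:
        table = {c.name: c for c in read_channel_table(channel_table)}
        channels = [table.get(c.name, c) for c in channels]
    return Recording(data, float(raw.info["sfreq"]), channels)


def write_recording(rec: Recording, path: str | os.PathLike) -> None:
    """Write a recording as 16-bit EDF (names and sfreq preserved exactly)."""
    path = Path(path)
    if path.suffix.lower() != ".edf":
        raise FormatError("write_recording only writes EDF files")
    _edf.write_edf(path, rec.data, rec.sfreq, rec.ch_names)


def read_channel_table(path: str | os.PathLike) -> list[ChannelInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"name", "kind"}
    if not required.issubset(df.columns):
        raise FormatError(f"channel table needs columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        roi = getattr(row, "roi", "") or None
        out.append(ChannelInfo(row.name, row.kind,
                               getattr(row, "group", "") or "", roi))
    return out


def write_channel_table(channels: list[ChannelInfo], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [{"name": c.name, "kind": c.kind, "group": c.group, "roi": c.roi or ""}
         for c in channels]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Montage references
# ---------------------------------------------------------------------------

def common_average(rec: Recording, within_group: bool = False) -> Recording:
    """Re-reference to a common average.

    With ``within_group`` each montage group is referenced to its own mean
    (the within-grid common average); otherwise the mean across all channels
    is removed, as done for the scalp montage. Either way the referenced
    group's channel mean is exactly zero at every sample.
    """
    data = rec.data.copy()
    if within_group:
        groups: dict[str, list[int]] = {}
        for i, c in enumerate(rec.channels):
            groups.setdefault(c.group, []).append(i)
        for group, rows in groups.items():
            if len(rows) < 2:
                raise InvalidMontageError(
                    f"group {group!r} has a single channel; cannot re-reference")
            data[rows] -= data[rows].mean(axis=0, keepdims=True)
    else:
        if rec.n_channels < 2:
            raise InvalidMontageError("common average needs at least 2 channels")
        data -= data.mean(axis=0, keepdims=True)
    return rec.with_data(data)


def bipolar_montage(rec: Recording, group: str) -> Recording:
    """Reference a strip/shaft to its immediate neighbor along the array.

    Channel order within ``group`` is taken as the physical contact order;
    the n contacts yield n-1 derived channels named ``a-b``.
    """
    rows = [i for i, c in enumerate(rec.channels) if c.group == group]
    if len(rows) < 2:
        raise InvalidMontageError(
            f"group {group!r} has {len(rows)} channel(s); bipolar montage needs >= 2")
    data = rec.data[rows][:-1] - rec.data[rows][1:]
    chans = []
    for a, b in zip(rows[:-1], rows[1:]):
        ca, cb = rec.channels[a], rec.channels[b]
        chans.append(ChannelInfo(f"{ca.name}-{cb.name}", ca.kind, ca.group, ca.roi))
    return Recording(data, rec.sfreq, chans)


# ---------------------------------------------------------------------------
# Filters and resampling (all zero-phase)
# ---------------------------------------------------------------------------

def _check_cutoff(cutoff: float, sfreq: float) -> None:
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= sfreq / 2:
        raise ValueError(f"cutoff {cutoff} Hz is at or above Nyquist ({sfreq / 2} Hz)")


def demean(rec: Recording) -> Recording:
    return rec.with_data(rec.data - rec.data.mean(axis=1, keepdims=True))


def notch(rec: Recording, freq: float, quality: float = 30.0) -> Recording:
    """Zero-phase notch (default 50 Hz line frequency)."""
    _check_cutoff(freq, rec.sfreq)
    b, a = signal.iirnotch(freq, quality, fs=rec.sfreq)
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    return rec.with_data(signal.filtfilt(b, a, data, axis=1))


def bandpass(rec: Recording, lo: float, hi: float, order: int = 4) -> Recording:
    if not lo < hi:
        raise ValueError("bandpass needs lo < hi")
    _check_cutoff(hi, rec.sfreq)
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.sfreq, output="sos")
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    return rec.with_data(signal.sosfiltfilt(sos, data, axis=1))


def lowpass(rec: Recording, cutoff: float, order: int = 4) -> Recording:
    """Zero-phase low-pass; the mean is deliberately kept (envelope smoothing)."""
    _check_cutoff(cutoff, rec.sfreq)
    sos = signal.butter(order, cutoff, btype="lowpass", fs=rec.sfreq, output="sos")
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=1))


def resample(rec: Recording, sfreq_new: float) -> Recording:
    """Polyphase resampling with anti-alias filtering.

    The output length is ``round(n * sfreq_new / sfreq)`` so duration in
    seconds is preserved to within one sample.
    """
    if sfreq_new <= 0:
        raise ValueError("target sampling rate must be positive")
    if sfreq_new == rec.sfreq:
        return rec.copy()
    frac = Fraction(sfreq_new / rec.sfreq).limit_denominator(10000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    target = int(round(rec.n_samples * sfreq_new / rec.sfreq))
    out = out[:, :target]
    if out.shape[1] < target:  # resample_poly may fall one short of round()
        out = np.pad(out, ((0, 0), (0, target - out.shape[1])), mode="edge")
    return Recording(out, sfreq_new, list(rec.channels))
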