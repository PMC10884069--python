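"""Temporo-spectral evolution (TSE): band-limited log amplitude envelopes.

For each frequency band a channel's TSE is obtained by zero-phase band-pass
filtering, full-wave rectification, zero-phase low-pass smoothing at half the
band's lower edge, and a natural-log transform with a small positive floor.
The result is a channels-by-samples matrix aligned sample-for-sample with the
source recording, suitable as the dependent side of timeline-weighted
covariance mapping.

The five canonical bands are theta 4-8 Hz, alpha 9-12 Hz, beta 13-30 Hz,
low-gamma 30-70 Hz and broadband high-gamma 70-150 Hz; the smoothing cutoff
is tied to the band (theta smooths at 2 Hz, high-gamma at 35 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import Recording, bandpass, lowpass

#: Amplitude floor (microvolts) added before the log so silent channels stay finite.
LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band; the envelope smoothing cutoff is ``lo / 2``."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not 0 < self.lo < self.hi:
            raise ValueError(f"band {self.name!r} needs 0 < lo < hi")

    @property
    def smooth_cutoff(self) -> float:
        return self.lo / 2.0


def band_catalog() -> list[BandDefinition]:
    """The five analysis bands, theta through broadband high-gamma."""
    return [
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha", 9.0, 12.0),
        BandDefinition("beta", 13.0, 30.0),
        BandDefinition("low-gamma", 30.0, 70.0),
        BandDefinition("high-gamma", 70.0, 150.0),
    ]


def band_by_name(name: str) -> BandDefinition:
    for band in band_catalog():
        if band.name == name:
            return band
    raise ValueError(f"unknown band {name!r}; expected one of "
                     f"{[b.name for b in band_catalog()]}")


@dataclass
class TSEMatrix:
    """Log band-amplitude envelopes, channels x samples, aligned with the source."""

    values: np.ndarray
    band: BandDefinition
    sfreq: float
    ch_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.isfinite(self.values).all():
            raise ValueError("TSE values must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def band_envelope(rec: Recording, band: BandDefinition) -> np.ndarray:
    """Smoothed band amplitude (microvolts, before the log transform).

    Rectified band-passed signal, low-pass filtered at ``band.lo / 2``;
    clipped at zero because zero-phase smoothing can slightly undershoot.
    """
    if band.hi >= rec.sfreq / 2:
        raise ValueError(
            f"band {band.name!r} upper edge {band.hi} Hz is not below "
            f"Nyquist ({rec.sfreq / 2} Hz)")
    narrow = bandpass(rec, band.lo, band.hi)
    rectified = narrow.with_data(np.abs(narrow.data))
    smoothed = lowpass(rectified, band.smooth_cutoff)
    return np.clip(smoothed.data, 0.0, None)


def compute_tse(rec: Recording, band: BandDefinition) -> TSEMatrix:
    """Band-pass, rectify, smooth at half the low edge, log-transform."""
    env = band_envelope(rec, band)
    return TSEMatrix(np.log(env + LOG_FLOOR), band, rec.sfreq, rec.ch_names)
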