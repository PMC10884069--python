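"""Synthetic scalp + intracranial data with known ground truth.

Every downstream stage of the pipeline is validated against data from this
module: a piecewise-constant microstate label sequence with a smooth positive
field-strength envelope, scalp EEG rendered as amplitude-scaled template
topographies plus spatial noise, intracranial channels whose band-limited
amplitude is modulated up or down in proportion to a chosen class timeline,
and optional injected interictal-discharge-like bursts.

Coupling model. Each intracranial channel is 1/f ("pink") broadband noise.
For a coupling (channel, band, class, gain) the channel's band-filtered
component x_b is amplitude-modulated by the normalized class timeline w(t)
(timeline divided by its maximum, so w is in [0, 1]):

    x -> x + gain * w(t) * x_b(t),

i.e. the band's analytic amplitude becomes (1 + gain * w) times its baseline
while other bands stay untouched. |gain| < 1 keeps the modulated amplitude
positive; the sign of gain is the ground truth for the sign of the
recovered covariance-map beta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .errors import EmptyDataError
from .microstate import MONTAGE_10_20, TemplateSet, standard_positions
from .signal_io import ChannelInfo, Recording
from .tse import band_by_name, band_catalog

BAND_NAMES = tuple(b.name for b in band_catalog())


@dataclass
class MicrostateSequence:
    """Ground-truth label sequence plus its field-strength envelope."""

    labels: np.ndarray
    amplitude: np.ndarray
    sfreq: float
    k: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.labels.shape != self.amplitude.shape:
            raise ValueError("labels and amplitude must have equal length")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    def timeline(self, class_index: int) -> np.ndarray:
        """Ground-truth timeline of one class: amplitude where active, else 0."""
        return self.amplitude * (self.labels == class_index)

    def normalized_timeline(self, class_index: int) -> np.ndarray:
        t = self.timeline(class_index)
        peak = t.max()
        if peak <= 0:
            raise EmptyDataError(f"class {class_index} never occurs")
        return t / peak


@dataclass(frozen=True)
class CouplingSpec:
    """One ground-truth (channel, band, class, gain) coupling cell."""

    channel: str
    band: str
    class_index: int
    gain: float

    def __post_init__(self):
        if self.band not in BAND_NAMES:
            raise ValueError(f"band {self.band!r} not one of {BAND_NAMES}")
        if not abs(self.gain) < 1:
            raise ValueError("|gain| must be < 1 to keep amplitude positive")
        if self.class_index < 0:
            raise ValueError("class_index must be nonnegative")


def generate_microstate_sequence(n_samples: int, sfreq: float,
                                 mean_duration: float, k: int,
                                 seed: int | None = None) -> MicrostateSequence:
    """Piecewise-constant labels with geometric segment lengths (minimum 2).

    Segment lengths are 1 + Geometric(p) samples with mean
    ``mean_duration * sfreq`` — the simplest memoryless law consistent with
    quasi-stable periods. Successive segments always change class (for k > 1);
    the incoming class is drawn from a softmax over per-class preference
    signals that drift on a ~0.5 s timescale, emulating the slow waxing and
    waning of class occupancy seen in resting-state recordings (and giving
    class timelines realistic low-frequency power). The amplitude envelope is
    rectified Gaussian-smoothed white noise squashed into [0.75, 1.25]: a
    smooth, strictly positive GFP-like envelope with many local maxima per
    second.
    """
    if n_samples <= 0 or sfreq <= 0 or mean_duration <= 0:
        raise ValueError("n_samples, sfreq and mean_duration must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    mean_len = mean_duration * sfreq
    if mean_len < 2:
        raise ValueError("mean_duration must span at least 2 samples")

    rng = np.random.default_rng(seed)
    p = 1.0 / (mean_len - 1.0) if mean_len > 2 else 1.0

    # slowly drifting per-class preference (softmax weights at segment starts)
    drift = gaussian_filter1d(rng.standard_normal((k, n_samples)),
                              sigma=max(1.0, 0.5 * sfreq), axis=1, mode="reflect")
    sd = drift.std(axis=1, keepdims=True)
    drift = np.where(sd > 0, drift / np.where(sd > 0, sd, 1.0), 0.0)
    drift = 1.5 * np.tanh(drift)  # bounded: no class collapses to zero occupancy

    labels = np.empty(n_samples, dtype=int)
    pos = 0
    current = int(rng.integers(k))
    while pos < n_samples:
        length = 1 + int(rng.geometric(min(p, 1.0)))
        labels[pos:pos + length] = current
        pos += length
        if k > 1 and pos < n_samples:
            weights = np.exp(drift[:, pos])
            weights[current] = 0.0
            current = int(rng.choice(k, p=weights / weights.sum()))

    smooth = gaussian_filter1d(rng.standard_normal(n_samples),
                               sigma=max(1.0, 0.02 * sfreq), mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    amplitude = 0.75 + 0.5 * np.tanh(np.abs(smooth))
    return MicrostateSequence(labels, amplitude, float(sfreq), k)


def render_scalp_eeg(seq: MicrostateSequence, templates: TemplateSet,
                     noise_sd: float, seed: int | None = None) -> Recording:
    """Scalp EEG: amplitude-scaled active template plus spatial Gaussian noise.

    Each sample equals ``amplitude(t) * map(labels(t))`` (microvolt scale of
    the unit-norm template) plus zero-mean white spatial noise of standard
    deviation ``noise_sd`` per electrode; the output is average-referenced.
    """
    if seq.n_samples == 0:
        raise ValueError("empty microstate sequence")
    if templates.n_electrodes < 3:
        raise ValueError("need at least 3 electrodes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if seq.labels.max() >= templates.k:
        raise ValueError("sequence uses more classes than the template set has")

    rng = np.random.default_rng(seed)
    data = templates.maps[seq.labels].T * seq.amplitude[None, :]
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd,
                                 size=(templates.n_electrodes, seq.n_samples))
    data -= data.mean(axis=0, keepdims=True)
    channels = [ChannelInfo(name, "scalp", "scalp") for name in templates.montage]
    return Recording(data, seq.sfreq, channels)


def _pink_noise(rng: np.random.Generator, n: int, sfreq: float) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise, flat below 1 Hz."""
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    spectrum *= 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    x = np.fft.irfft(spectrum, n)
    return x / x.std()


def _bandpass_array(x: np.ndarray, lo: float, hi: float, sfreq: float) -> np.ndarray:
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, x)


def render_intracranial(seq: MicrostateSequence, couplings: list[CouplingSpec],
                        n_channels: int, sfreq: float,
                        seed: int | None = None,
                        channel_sd: float = 20.0) -> Recording:
    """Pink-noise intracranial channels with band-amplitude couplings applied.

    Channels are named ``IC01 .. ICnn`` (grid kind, one montage group).
    ``sfreq`` must exceed 300 Hz so the 70-150 Hz band is representable.
    """
    if sfreq <= 300:
        raise ValueError("sfreq must exceed 300 Hz (high-gamma band)")
    if n_channels < 1:
        raise ValueError("need at least one channel")
    names = [f"IC{i + 1:02d}" for i in range(n_channels)]
    unknown = [c.channel for c in couplings if c.channel not in names]
    if unknown:
        raise ValueError(f"coupled channels not generated: {unknown}")
    for c in couplings:
        if c.class_index >= seq.k:
            raise ValueError(f"coupling class {c.class_index} >= k={seq.k}")

    rng = np.random.default_rng(seed)
    data = np.stack([_pink_noise(rng, seq.n_samples, sfreq) for _ in names])
    data *= channel_sd
    for spec in couplings:
        band = band_by_name(spec.band)
        row = names.index(spec.channel)
        component = _bandpass_array(data[row], band.lo, band.hi, sfreq)
        w = seq.normalized_timeline(spec.class_index)
        data[row] = data[row] + spec.gain * w * component
    channels = [ChannelInfo(n, "grid", "grid1") for n in names]
    return Recording(data, float(sfreq), channels)


def inject_ieds(rec: Recording, times: list[float], duration: float,
                amplitude_sd: float, seed: int | None = None,
                channel: str | None = None) -> Recording:
    """Add 25-80 Hz-band bursts of the stated duration to one channel.

    Each burst is a near-rectangular (Tukey) windowed 50 Hz carrier with a
    random phase. ``amplitude_sd`` scales the burst's peak amplitude in units
    of the target channel's 25-80 Hz band standard deviation — the scale on
    which the z-scored analytic-amplitude detector operates — so that the
    burst's supra-threshold time tracks its nominal duration rather than the
    detection filter's ring-down. With an empty ``times`` list the input is
    returned unchanged.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if amplitude_sd <= 0:
        raise ValueError("amplitude_sd must be positive")
    out = rec.copy()
    if not times:
        return out
    row = 0 if channel is None else rec.ch_names.index(channel)
    rng = np.random.default_rng(seed)
    n_burst = max(3, int(round(duration * rec.sfreq)))
    t = np.arange(n_burst) / rec.sfreq
    window = signal.windows.tukey(n_burst, alpha=0.15)
    band_sd = _bandpass_array(rec.data[row] - rec.data[row].mean(),
                              25.0, 80.0, rec.sfreq).std()
    scale = amplitude_sd * (band_sd if band_sd > 0 else rec.data[row].std() or 1.0)
    for t0 in times:
        start = int(round(t0 * rec.sfreq))
        if t0 < 0 or start + n_burst > rec.n_samples:
            raise ValueError(f"burst at {t0} s does not fit inside the record")
        phase = rng.uniform(0, 2 * np.pi)
        out.data[row, start:start + n_burst] += (
            scale * window * np.sin(2 * np.pi * 50.0 * t + phase))
    return out


def synthetic_template_set(montage: list[str] | None = None) -> TemplateSet:
    """Synthetic 7-class template set on the 10-20 montage.

    A stand-in for a published normative 7-map microstate template set (which
    is not redistributable): seven mutually orthogonal smooth topographies
    built from dipolar and quadrupolar spherical-harmonic-like fields sampled
    at idealized 10-20 electrode positions, then average-referenced,
    orthonormalized (QR) and labelled A-G. Orthogonality makes ground-truth
    recovery tests sharp; the maps are synthetic and carry no normative
    anatomical meaning.
    """
    montage = list(montage) if montage is not None else list(MONTAGE_10_20)
    pos = standard_positions(montage)
    x, y, z = pos.T
    basis = np.column_stack([
        y - x,          # left-posterior to right-anterior diagonal
        y + x,          # right-posterior to left-anterior diagonal
        z,              # vertex-focal field
        x * y,          # quadrupolar fields
        x * z,
        y * z,
        x**2 - y**2,
    ])
    basis = basis - basis.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(basis)
    q *= np.sign(np.diag(r))[None, :]  # deterministic sign convention
    return TemplateSet(q.T, montage, list("ABCDEFG"))
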