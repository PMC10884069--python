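"""Microstate segmentation against a fixed template set.

Scalp EEG microstates are brief (tens of ms) periods of quasi-stable field
topography. Segmentation here is template-based: at each peak of the Global
Field Power (GFP, the spatial RMS of the average-referenced potential) the
momentary map is assigned to the template with the highest absolute spatial
correlation (polarity-invariant), and labels between peaks are filled from
the nearest peak in time. Each class k gets a timeline

    values[k, t] = r_k(t)^2 * GFP(t)^2,

the squared field strength explained by the assigned template — zero wherever
the sample is masked or assigned to another class — which downstream serves
as the regressor weight for covariance mapping.

Also provided: polarity-invariant modified k-means over GFP-peak maps,
optimal template matching, and spherical-spline spatial resampling of
template sets between montages (Perrin-style splines, order m=4).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre
from scipy.optimize import linear_sum_assignment

from .errors import InvalidMontageError
from .signal_io import Recording

#: The 19 electrodes of the classic 10-20 montage, in conventional order.
MONTAGE_10_20 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
]

UNASSIGNED = -1


def standard_positions(names: list[str] | None = None) -> np.ndarray:
    """Idealized unit-sphere positions for standard 10-20 electrode names.

    Positions come from the standard_1020 montage shipped with MNE, projected
    radially onto the unit sphere (x right, y anterior, z superior).
    """
    import mne

    import warnings

    names = list(names) if names is not None else list(MONTAGE_10_20)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)  # montage rename in MNE
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    missing = [n for n in names if n not in pos]
    if missing:
        raise InvalidMontageError(f"no standard position for electrodes {missing}")
    xyz = np.array([pos[n] for n in names], dtype=float)
    norms = np.linalg.norm(xyz, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise InvalidMontageError("degenerate electrode position at origin")
    return xyz / norms


@dataclass
class TemplateSet:
    """K topographic template maps over a named electrode montage.

    Maps are stored average-referenced (zero mean over electrodes) and
    unit-normalized; construction enforces both.
    """

    maps: np.ndarray
    montage: list[str]
    names: list[str] | None = None

    def __post_init__(self):
        maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if maps.shape[1] != len(self.montage):
            raise ValueError("map width must equal montage length")
        maps = maps - maps.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(maps, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("degenerate template: constant (zero after "
                             "average reference) map")
        self.maps = maps / norms[:, None]
        if self.names is None:
            self.names = [chr(ord("A") + i) if i < 26 else str(i)
                          for i in range(maps.shape[0])]
        if len(self.names) != maps.shape[0]:
            raise ValueError("template names must match map count")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.maps.shape[1]


@dataclass
class MicrostateTimelines:
    """Per-class explained-strength timelines plus the label sequence.

    ``labels[t]`` is the assigned class index or :data:`UNASSIGNED` at masked
    samples; ``values[k, t]`` is nonzero only where ``labels[t] == k``.
    """

    values: np.ndarray
    labels: np.ndarray
    sfreq: float

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape[1] != self.labels.shape[0]:
            raise ValueError("values and labels length mismatch")
        if np.any(self.values < 0):
            raise ValueError("timeline values must be nonnegative")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def timeline(self, class_index: int) -> np.ndarray:
        return self.values[class_index]


# ---------------------------------------------------------------------------
# GFP
# ---------------------------------------------------------------------------

def gfp(rec: Recording) -> np.ndarray:
    """Global Field Power: spatial RMS of the average-referenced potential."""
    if rec.n_channels < 2:
        raise ValueError("GFP needs at least two channels")
    centered = rec.data - rec.data.mean(axis=0, keepdims=True)
    return np.sqrt(np.mean(centered**2, axis=0))


def gfp_peaks(g: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima ``g[i-1] < g[i] >= g[i+1]``.

    Endpoints are never peaks; a monotone series has none. For plateaus the
    left edge of the plateau is the peak (strict rise, non-strict fall).
    """
    g = np.asarray(g, dtype=float)
    if g.ndim != 1 or g.size < 3:
        return np.array([], dtype=int)
    inner = np.arange(1, g.size - 1)
    keep = (g[inner] > g[inner - 1]) & (g[inner] >= g[inner + 1])
    return inner[keep]


# ---------------------------------------------------------------------------
# Spherical-spline template resampling
# ---------------------------------------------------------------------------

def _spline_g(cosang: np.ndarray, m: int = 4, n_terms: int = 7) -> np.ndarray:
    """Perrin g-function: truncated Legendre series for spline order ``m``."""
    n = np.arange(1, n_terms + 1)
    coef = np.zeros(n_terms + 1)
    coef[1:] = (2 * n + 1) / (n**m * (n + 1) ** m)
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coef) / (4 * np.pi)


def resample_templates(templates: TemplateSet,
                       target_montage: list[str],
                       source_pos: np.ndarray | None = None,
                       target_pos: np.ndarray | None = None,
                       reg: float = 1e-8) -> TemplateSet:
    """Spatially resample template maps onto a different electrode montage.

    Uses spherical-spline interpolation (order m=4, degree-7 Legendre
    truncation, Tikhonov regularization ``reg`` on the spline system; the
    default is small relative to the g-kernel scale so interpolation back
    onto the source montage reproduces the maps essentially exactly). Source
    and target positions default to idealized standard-montage unit-sphere
    coordinates looked up by electrode name. Interpolated maps are
    re-average-referenced and renormalized.
    """
    if templates.n_electrodes < 4:
        raise InvalidMontageError("spline resampling needs >= 4 source electrodes")
    src = (standard_positions(templates.montage)
           if source_pos is None else np.asarray(source_pos, dtype=float))
    tgt = (standard_positions(list(target_montage))
           if target_pos is None else np.asarray(target_pos, dtype=float))
    src = src / np.linalg.norm(src, axis=1, keepdims=True)
    tgt = tgt / np.linalg.norm(tgt, axis=1, keepdims=True)

    g_ss = _spline_g(src @ src.T) + reg * np.eye(len(src))
    g_ts = _spline_g(tgt @ src.T)
    n_src = len(src)
    system = np.zeros((n_src + 1, n_src + 1))
    system[:n_src, :n_src] = g_ss
    system[:n_src, n_src] = 1.0
    system[n_src, :n_src] = 1.0

    out = np.empty((templates.k, len(tgt)))
    for i, z in enumerate(templates.maps):
        rhs = np.append(z, 0.0)
        try:
            sol = np.linalg.solve(system, rhs)
        except np.linalg.LinAlgError as exc:
            raise InvalidMontageError(
                f"degenerate electrode configuration: {exc}") from exc
        out[i] = sol[n_src] + g_ts @ sol[:n_src]
    return TemplateSet(out, list(target_montage), list(templates.names))


# ---------------------------------------------------------------------------
# Template assignment
# ---------------------------------------------------------------------------

def _spatial_correlations(data: np.ndarray, templates: TemplateSet) -> np.ndarray:
    """K x T spatial Pearson correlations between samples and template maps.

    Both sides are average-referenced; template maps are unit-norm, so the
    correlation reduces to the normalized projection. Zero maps give r = 0.
    """
    centered = data - data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    return (templates.maps @ centered) / safe


def assign_templates(rec: Recording, templates: TemplateSet,
                     mask: np.ndarray | None = None) -> MicrostateTimelines:
    """Label GFP peaks by best |spatial correlation|, fill by nearest peak.

    ``mask`` (optional) is a boolean per-sample exclusion vector (True =
    excluded); masked samples never host peaks, receive the unassigned label
    and carry zero timeline value.
    """
    if rec.ch_names != list(templates.montage):
        raise ValueError("recording montage does not match template montage")
    n = rec.n_samples
    excluded = np.zeros(n, dtype=bool)
    if mask is not None:
        excluded = np.asarray(getattr(mask, "mask", mask), dtype=bool)
        if excluded.shape[0] != n:
            raise ValueError("mask length does not match recording")

    g = gfp(rec)
    peaks = gfp_peaks(g)
    peaks = peaks[~excluded[peaks]]
    if peaks.size == 0:
        return MicrostateTimelines(np.zeros((templates.k, n)),
                                   np.full(n, UNASSIGNED), rec.sfreq)

    corr = _spatial_correlations(rec.data, templates)   # K x T
    peak_labels = np.argmax(np.abs(corr[:, peaks]), axis=0)

    # nearest peak in time; equidistant ties resolved toward the earlier peak
    t = np.arange(n)
    right = np.searchsorted(peaks, t)
    left = np.clip(right - 1, 0, peaks.size - 1)
    right = np.clip(right, 0, peaks.size - 1)
    d_left = np.abs(t - peaks[left])
    d_right = np.abs(peaks[right] - t)
    nearest = np.where(d_left <= d_right, left, right)
    labels = peak_labels[nearest]

    values = np.zeros((templates.k, n))
    r_assigned = corr[labels, t]
    values[labels, t] = r_assigned**2 * g**2
    labels = labels.copy()
    labels[excluded] = UNASSIGNED
    values[:, excluded] = 0.0
    return MicrostateTimelines(values, labels, rec.sfreq)


# ---------------------------------------------------------------------------
# Polarity-invariant modified k-means
# ---------------------------------------------------------------------------

def kmeans_microstates(rec: Recording, k: int, n_restarts: int = 10,
                       seed: int | None = None,
                       max_iter: int = 200) -> TemplateSet:
    """Cluster GFP-peak topographies into k polarity-invariant prototypes.

    Modified k-means with distance 1 - r^2: maps are assigned to the
    prototype with the largest squared spatial correlation, and each
    prototype is updated to the principal eigenvector of its members' outer
    product sum. The best of ``n_restarts`` random initializations by global
    explained variance is returned.
    """
    rng = np.random.default_rng(seed)
    g = gfp(rec)
    peaks = gfp_peaks(g)
    if peaks.size < k:
        raise ValueError(f"only {peaks.size} GFP peaks for k={k}")
    maps = rec.data[:, peaks] - rec.data[:, peaks].mean(axis=0, keepdims=True)
    norms = np.linalg.norm(maps, axis=0)
    keep = norms > 1e-12
    maps, norms = maps[:, keep], norms[keep]
    unit = maps / norms

    best_maps, best_gev = None, -np.inf
    total_ss = float(np.sum(norms**2))
    for _ in range(max(1, n_restarts)):
        proto = unit[:, rng.choice(unit.shape[1], size=k, replace=False)].T
        labels = np.full(unit.shape[1], -1)
        for _ in range(max_iter):
            corr = proto @ unit                      # k x P
            new_labels = np.argmax(corr**2, axis=0)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                members = maps[:, labels == j]
                if members.shape[1] == 0:            # re-seed an empty cluster
                    proto[j] = unit[:, rng.integers(unit.shape[1])]
                    continue
                u, _, _ = np.linalg.svd(members, full_matrices=False)
                proto[j] = u[:, 0]
            proto -= proto.mean(axis=1, keepdims=True)
            proto /= np.linalg.norm(proto, axis=1, keepdims=True)
        corr = proto @ unit
        gev = float(np.sum((norms * corr[np.argmax(corr**2, axis=0),
                                         np.arange(unit.shape[1])])**2) / total_ss)
        if gev > best_gev:
            best_gev, best_maps = gev, proto.copy()
    return TemplateSet(best_maps, list(rec.ch_names))


@dataclass(frozen=True)
class TemplateMatch:
    """Optimal one-to-one matching between two template sets."""

    pairs: tuple[tuple[int, int], ...]
    abs_r: tuple[float, ...]

    @property
    def mean_abs_r(self) -> float:
        return float(np.mean(self.abs_r))


def template_correlation(a: TemplateSet, b: TemplateSet) -> TemplateMatch:
    """Match maps of ``a`` to maps of ``b`` maximizing mean |spatial r|."""
    if a.k != b.k:
        raise ValueError(f"template counts differ ({a.k} vs {b.k})")
    if list(a.montage) != list(b.montage):
        raise ValueError("template sets are on different montages")
    corr = np.abs(a.maps @ b.maps.T)
    rows, cols = linear_sum_assignment(-corr)
    pairs = tuple((int(i), int(j)) for i, j in zip(rows, cols))
    return TemplateMatch(pairs, tuple(float(corr[i, j]) for i, j in pairs))


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

def write_templates(templates: TemplateSet, tsv_path: str | os.PathLike) -> None:
    """TSV of electrode x map values plus a JSON metadata sidecar."""
    import pandas as pd

    df = pd.DataFrame(templates.maps.T, columns=templates.names)
    df.insert(0, "electrode", templates.montage)
    df.to_csv(tsv_path, sep="\t", index=False)
    meta = {"k": templates.k, "names": list(templates.names),
            "montage": list(templates.montage)}
    with open(str(tsv_path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_templates(tsv_path: str | os.PathLike) -> TemplateSet:
    import pandas as pd

    df = pd.read_csv(tsv_path, sep="\t")
    montage = df["electrode"].tolist()
    names = [c for c in df.columns if c != "electrode"]
    return TemplateSet(df[names].to_numpy().T, montage, names)


def write_timelines(tl: MicrostateTimelines, path: str | os.PathLike,
                    class_names: list[str] | None = None) -> None:
    import pandas as pd

    names = class_names or [f"class_{i}" for i in range(tl.k)]
    df = pd.DataFrame(tl.values.T, columns=names)
    df.insert(0, "label", tl.labels)
    df.insert(0, "time", np.arange(tl.labels.size) / tl.sfreq)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
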