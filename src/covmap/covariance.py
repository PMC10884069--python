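"""Timeline-weighted covariance maps, permutation significance, back-projection R.

The core statistic: for one frequency band and one microstate class, each
intracranial channel's beta is the mean of its centered temporo-spectral
evolution (TSE) weighted by the class timeline,

    beta[c] = sum_t w(t) * (TSE[c, t] - mean_t TSE[c, .]) / sum_t w(t),

over unmasked samples. Centering makes uniform weights give beta = 0, so beta
behaves as a covariance between band amplitude and microstate presence;
positive beta means the band's amplitude is elevated while the class is
present.

Significance is assessed by a permutation test that breaks the temporal
association between the TSE and the timeline with random circular rotations
(rotation preserves both series' autocorrelation; a sample-wise shuffle would
inflate significance given their temporal smoothness). The map-level test
statistic is the RMS of beta across channels, and p-values use the add-one
convention (1 + exceedances) / (n_perm + 1).

Back-projection: the beta-weighted sum of centered TSEs gives a single time
course whose Pearson correlation with the timeline is the map's R value;
maps are conventionally reported only when R > 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .artifacts import ArtifactMask, detect_ieds
from .errors import AlignmentError, EmptyDataError, UndefinedCorrelationError
from .microstate import (MicrostateTimelines, TemplateSet, assign_templates)
from .signal_io import (Recording, bandpass, bipolar_montage, common_average,
                        demean, notch, resample)
from .tse import BandDefinition, TSEMatrix, band_catalog, compute_tse

logger = logging.getLogger(__name__)


def _tse_values(tse) -> np.ndarray:
    return np.atleast_2d(np.asarray(getattr(tse, "values", tse), dtype=float))


def _mask_vector(mask, n: int) -> np.ndarray:
    if mask is None:
        return np.zeros(n, dtype=bool)
    m = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if m.size != n:
        raise ValueError("mask length does not match sample count")
    return m


def covariance_map(tse, timeline: np.ndarray, mask=None) -> np.ndarray:
    """Per-channel timeline-weighted mean of the centered TSE."""
    values = _tse_values(tse)
    w = np.asarray(timeline, dtype=float)
    if w.ndim != 1 or w.size != values.shape[1]:
        raise ValueError("timeline length must match TSE sample count")
    keep = ~_mask_vector(mask, w.size)
    if not keep.any():
        raise EmptyDataError("all samples are masked")
    w = w[keep]
    wsum = w.sum()
    if wsum <= 0:
        raise EmptyDataError("timeline weights sum to zero over unmasked samples")
    centered = values[:, keep] - values[:, keep].mean(axis=1, keepdims=True)
    return centered @ w / wsum


def _map_statistic(beta: np.ndarray) -> float:
    return float(np.sqrt(np.mean(beta**2)))


def permutation_test(tse, timeline: np.ndarray, mask=None,
                     n_perm: int = 1000, seed: int | None = None,
                     offsets: np.ndarray | None = None,
                     min_shift_s: float = 2.0) -> float:
    """Permutation p-value for one covariance map via circular rotation.

    Null maps are computed after circularly rotating the timeline relative to
    the TSE by offsets drawn without replacement from all rotations at least
    ``min_shift_s`` away from zero (in either direction). An explicit
    ``offsets`` list overrides the sampling, for reproducible comparison
    against external implementations. The minimum attainable p is
    ``1 / (n_perm + 1)``.
    """
    values = _tse_values(tse)
    w = np.asarray(timeline, dtype=float)
    n = w.size
    sfreq = float(getattr(tse, "sfreq", 0.0) or 0.0)
    if sfreq > 0 and n / sfreq < 4.0:
        raise ValueError("record shorter than 4 s; rotation null is degenerate")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    observed = _map_statistic(covariance_map(values, w, mask))
    if offsets is None:
        min_shift = int(round(min_shift_s * sfreq)) if sfreq > 0 else max(1, n // 100)
        pool = np.arange(min_shift, n - min_shift + 1)
        if pool.size < n_perm:
            raise ValueError(
                f"only {pool.size} admissible rotations for n_perm={n_perm}")
        rng = np.random.default_rng(seed)
        offsets = rng.choice(pool, size=n_perm, replace=False)
    else:
        offsets = np.asarray(offsets, dtype=int)
        n_perm = offsets.size

    keep = ~_mask_vector(mask, n)
    centered = values[:, keep] - values[:, keep].mean(axis=1, keepdims=True)
    exceed = 0
    for chunk in np.array_split(offsets, max(1, offsets.size // 128)):
        rolled = np.stack([np.roll(w, int(o))[keep] for o in chunk])  # P x T
        sums = rolled.sum(axis=1)
        # a rotation may park all weight inside the masked span; count such
        # degenerate draws as exceedances (conservative) rather than aborting
        degenerate = sums <= 0
        sums[degenerate] = 1.0
        betas = centered @ rolled.T / sums[None, :]                   # C x P
        null = np.sqrt(np.mean(betas**2, axis=0))
        null[degenerate] = np.inf
        exceed += int(np.sum(null >= observed))
    return (1 + exceed) / (n_perm + 1)


def back_projection_r(tse, beta: np.ndarray, timeline: np.ndarray,
                      mask=None) -> float:
    """Correlation between the beta-weighted TSE time course and the timeline."""
    values = _tse_values(tse)
    beta = np.asarray(beta, dtype=float)
    if beta.size != values.shape[0]:
        raise ValueError("beta length must equal channel count")
    w = np.asarray(timeline, dtype=float)
    keep = ~_mask_vector(mask, w.size)
    if not keep.any():
        raise EmptyDataError("all samples are masked")
    centered = values - values.mean(axis=1, keepdims=True)
    y = beta @ centered
    y, w = y[keep], w[keep]
    if np.std(y) == 0 or np.std(w) == 0:
        raise UndefinedCorrelationError(
            "back-projected time course or timeline has zero variance")
    return float(np.corrcoef(y, w)[0, 1])


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class CovarianceMap:
    """One (band, class) covariance map with its significance and strength."""

    beta: np.ndarray
    ch_names: list[str]
    band: BandDefinition
    class_index: int
    p_value: float
    r_value: float
    n_perm: int

    def reportable(self, r_floor: float = 0.1) -> bool:
        return np.isfinite(self.r_value) and self.r_value > r_floor

    @property
    def peak_channel(self) -> str:
        return self.ch_names[int(np.argmax(np.abs(self.beta)))]


def roi_aggregate(maps: list[CovarianceMap],
                  roi_lookup: dict[str, str]) -> pd.DataFrame:
    """Mean beta per (roi, band, class); channels without an ROI are skipped."""
    rows = []
    skipped: set[str] = set()
    for m in maps:
        for name, b in zip(m.ch_names, m.beta):
            roi = roi_lookup.get(name)
            if roi is None:
                skipped.add(name)
                continue
            rows.append({"roi": roi, "band": m.band.name,
                         "class_index": m.class_index, "beta": float(b)})
    if skipped:
        logger.warning("channels without ROI skipped: %s", sorted(skipped))
    if not rows:
        raise EmptyDataError("no channel overlaps the ROI lookup table")
    df = pd.DataFrame(rows)
    out = (df.groupby(["roi", "band", "class_index"], as_index=False)
             .agg(mean_beta=("beta", "mean"), n_channels=("beta", "size")))
    return out


# ---------------------------------------------------------------------------
# End-to-end analysis
# ---------------------------------------------------------------------------

@dataclass
class AnalysisResult:
    maps: list[CovarianceMap]
    table: pd.DataFrame
    timelines: MicrostateTimelines
    mask: ArtifactMask
    roi_summary: pd.DataFrame | None = None
    log: dict = field(default_factory=dict)


def preprocess_intracranial(rec: Recording, notch_freq: float = 50.0) -> Recording:
    """Demean, notch, then per-group referencing.

    Grid groups get a within-grid common average; strip and depth groups are
    re-referenced to the neighboring contact (bipolar). Scalp channels, and
    singleton groups that cannot be re-referenced, pass through unchanged.
    """
    rec = notch(demean(rec), notch_freq)
    groups: dict[str, list[int]] = {}
    for i, c in enumerate(rec.channels):
        groups.setdefault(c.group, []).append(i)
    pieces: list[Recording] = []
    for group, rows in groups.items():
        kinds = {rec.channels[i].kind for i in rows}
        sub = rec.pick([rec.channels[i].name for i in rows])
        if len(rows) >= 2 and kinds <= {"grid"}:
            pieces.append(common_average(sub, within_group=True))
        elif len(rows) >= 2 and kinds <= {"strip", "depth"}:
            pieces.append(bipolar_montage(sub, group))
        else:
            pieces.append(sub)
    data = np.vstack([p.data for p in pieces])
    channels = [c for p in pieces for c in p.channels]
    return Recording(data, rec.sfreq, channels)


def run_full_analysis(scalp: Recording, intracranial: Recording,
                      templates: TemplateSet, config=None,
                      roi_lookup: dict[str, str] | None = None,
                      seed: int | None = None) -> AnalysisResult:
    """The full pipeline: preprocess, mask, segment, TSE, all covariance maps.

    Produces one :class:`CovarianceMap` per (class, band) cell — K x 5 maps —
    each with a permutation p-value and back-projection R, plus a long-format
    results table flagging maps that pass the R reporting floor.
    """
    from .config import RunConfig, validate_config

    cfg = validate_config(config) if config is not None else RunConfig()
    if seed is None:
        seed = cfg.seed

    scalp = resample(scalp, cfg.resample_sfreq)
    intracranial = resample(intracranial, cfg.resample_sfreq)
    if abs(scalp.n_samples - intracranial.n_samples) > 1:
        raise AlignmentError(
            f"scalp ({scalp.n_samples}) and intracranial "
            f"({intracranial.n_samples}) sample counts differ by more than 1 "
            "after resampling")
    n = min(scalp.n_samples, intracranial.n_samples)
    scalp = scalp.with_data(scalp.data[:, :n])
    intracranial = intracranial.with_data(intracranial.data[:, :n])

    if cfg.apply_ied_mask:
        masks = [detect_ieds(r, cfg.ied_lo, cfg.ied_hi, cfg.ied_z,
                             cfg.ied_min_duration, cfg.ied_max_duration,
                             cfg.ied_pad)
                 for r in (scalp, intracranial)]
        mask = ArtifactMask(masks[0].mask | masks[1].mask,
                            masks[0].events + masks[1].events,
                            cfg.resample_sfreq)
    else:
        mask = ArtifactMask(np.zeros(n, dtype=bool), [], cfg.resample_sfreq)

    scalp_proc = common_average(bandpass(scalp, *cfg.scalp_band))
    timelines = assign_templates(scalp_proc, templates, mask)
    ieeg = preprocess_intracranial(intracranial, cfg.notch_freq)

    rng = np.random.default_rng(seed)
    maps: list[CovarianceMap] = []
    rows = []
    for band in cfg.bands:
        tse = compute_tse(ieeg, band)
        for k in range(templates.k):
            w = timelines.timeline(k)
            try:
                beta = covariance_map(tse, w, mask)
                p = permutation_test(tse, w, mask, n_perm=cfg.n_perm,
                                     seed=int(rng.integers(2**31)),
                                     min_shift_s=cfg.min_shift_s)
                r = back_projection_r(tse, beta, w, mask)
            except (EmptyDataError, UndefinedCorrelationError) as exc:
                logger.warning("class %d band %s: %s", k, band.name, exc)
                beta = np.full(tse.n_channels, np.nan)
                p, r = np.nan, np.nan
            cmap = CovarianceMap(beta, tse.ch_names, band, k, p, r, cfg.n_perm)
            maps.append(cmap)
            for name, b in zip(cmap.ch_names, cmap.beta):
                rows.append({"class_index": k, "band": band.name, "channel": name,
                             "beta": float(b), "p": p, "r": r,
                             "reportable": cmap.reportable(cfg.r_floor)})
    table = pd.DataFrame(rows)
    roi_summary = None
    if roi_lookup:
        roi_summary = roi_aggregate(maps, roi_lookup)
    log = {"fraction_masked": mask.fraction_masked,
           "n_events": len(mask.events),
           "peak_label_counts": {
               int(k): int(np.sum(timelines.labels == k))
               for k in range(templates.k)}}
    logger.info("full analysis: %d maps, %.1f%% masked",
                len(maps), 100 * mask.fraction_masked)
    return AnalysisResult(maps, table, timelines, mask, roi_summary, log)
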