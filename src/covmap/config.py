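"""Run configuration with validated defaults.

Defaults encode the analysis settings used throughout the package: 1000
permutation iterations, an R reporting floor of 0.1, IED detection at 3 SD
with the 20-100 ms duration gate and 2.5 s padding, the five canonical
frequency bands, a 2-20 Hz scalp band-pass, 50 Hz notch, and a common
500 Hz analysis rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import yaml

from .errors import ConfigError
from .tse import BandDefinition, band_catalog


@dataclass
class RunConfig:
    n_perm: int = 1000
    r_floor: float = 0.1
    resample_sfreq: float = 500.0
    scalp_band: tuple[float, float] = (2.0, 20.0)
    notch_freq: float = 50.0
    ied_lo: float = 25.0
    ied_hi: float = 80.0
    ied_z: float = 3.0
    ied_min_duration: float = 0.02
    ied_max_duration: float = 0.1
    ied_pad: float = 2.5
    apply_ied_mask: bool = True
    min_shift_s: float = 2.0
    bands: list[BandDefinition] = field(default_factory=band_catalog)
    seed: int | None = None


def _as_band(item) -> BandDefinition:
    if isinstance(item, BandDefinition):
        return item
    if isinstance(item, dict):
        return BandDefinition(item["name"], float(item["lo"]), float(item["hi"]))
    if isinstance(item, (list, tuple)) and len(item) == 3:
        return BandDefinition(str(item[0]), float(item[1]), float(item[2]))
    raise ConfigError(f"bands: cannot interpret {item!r} as a band")


def validate_config(cfg) -> RunConfig:
    """Normalize a RunConfig / dict / YAML-loaded mapping; reject contradictions.

    Errors name the offending field. An empty mapping yields the defaults.
    """
    if cfg is None:
        cfg = RunConfig()
    if isinstance(cfg, dict):
        known = {f.name for f in fields(RunConfig)}
        unknown = set(cfg) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = RunConfig(**cfg)
    if not isinstance(cfg, RunConfig):
        raise ConfigError(f"cannot interpret {type(cfg).__name__} as a RunConfig")

    try:
        bands = [_as_band(b) for b in cfg.bands]
    except ValueError as exc:
        raise ConfigError(f"bands: {exc}") from exc
    cfg = replace(cfg, bands=bands,
                  scalp_band=tuple(float(v) for v in cfg.scalp_band))
    if cfg.n_perm < 1:
        raise ConfigError("n_perm: must be >= 1")
    if not 0 <= cfg.r_floor < 1:
        raise ConfigError("r_floor: must lie in [0, 1)")
    if cfg.resample_sfreq <= 0:
        raise ConfigError("resample_sfreq: must be positive")
    lo, hi = cfg.scalp_band
    if not 0 < lo < hi:
        raise ConfigError("scalp_band: needs 0 < lo < hi")
    if not 0 < cfg.ied_lo < cfg.ied_hi:
        raise ConfigError("ied band: needs 0 < lo < hi")
    if cfg.ied_z <= 0:
        raise ConfigError("ied_z: must be positive")
    if cfg.ied_min_duration <= 0 or cfg.ied_max_duration <= cfg.ied_min_duration:
        raise ConfigError("ied durations: need 0 < min < max")
    if cfg.ied_pad < 0:
        raise ConfigError("ied_pad: must be nonnegative")
    if cfg.min_shift_s <= 0:
        raise ConfigError("min_shift_s: must be positive")
    if not cfg.bands:
        raise ConfigError("bands: at least one band required")
    for band in cfg.bands:
        if not band.lo < band.hi:
            raise ConfigError(f"band {band.name}: lo must be below hi")
        if band.hi >= cfg.resample_sfreq / 2:
            raise ConfigError(
                f"band {band.name}: hi {band.hi} Hz is not below Nyquist at "
                f"{cfg.resample_sfreq} Hz")
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return validate_config(raw)


def config_dict(cfg: RunConfig) -> dict:
    """JSON/YAML-serializable form (for run manifests)."""
    out = {}
    for f in fields(RunConfig):
        v = getattr(cfg, f.name)
        if f.name == "bands":
            v = [{"name": b.name, "lo": b.lo, "hi": b.hi} for b in v]
        elif isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out
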