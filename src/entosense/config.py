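"""Pipeline configuration: defaults, validation, YAML parsing.

All operating constants of the deployed system live here as defaults —
20 kHz stream rate, 2 kHz baseline-estimation rate, 5 kHz passband cutoff,
detection factor 10, 2 s / 50 % baseline boxcar, 500 us erosion, 30 ms
dilation — so no stage hard-codes them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError
from .extract import DetectionParams
from .features import FeatureParams

__all__ = ["PipelineConfig", "validate_config", "config_to_dict"]


@dataclass
class PipelineConfig:
    sample_rate: float = 20000.0
    passband_hz: float = 5000.0
    detection: DetectionParams = field(default_factory=DetectionParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    bin: str = "day"
    exclude_dates: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if not self.sample_rate > 0:
            raise ConfigError("sample_rate must be > 0 (default 20000 Hz)")
        if not 0 < self.passband_hz <= self.sample_rate / 2:
            raise ConfigError(
                "passband_hz must be positive and at most the Nyquist rate "
                f"({self.sample_rate / 2:g} Hz); default 5000 Hz"
            )
        self.detection.validate()
        lo, hi = self.features.search_band
        if not 0 < lo < hi:
            raise ConfigError("features.search_band must satisfy 0 < lo < hi")
        if hi > self.passband_hz:
            raise ConfigError(
                "features.search_band upper edge exceeds the passband cutoff"
            )
        if self.features.prominence_factor <= 0:
            raise ConfigError("features.prominence_factor must be > 0")
        if self.bin not in ("day", "hour"):
            raise ConfigError("bin must be 'day' or 'hour'")
        # keep the feature module's passband in lockstep
        self.features.passband_hz = self.passband_hz
        return self


_DEFAULT_MSG = {
    "snr_factor": 10.0,
    "erode_s": 500e-6,
    "dilate_s": 30e-3,
    "baseline_window_s": 2.0,
    "baseline_overlap": 0.5,
}


def _apply(section_obj, section_name: str, values: dict) -> None:
    valid = {f.name for f in dataclasses.fields(section_obj)}
    for key, val in values.items():
        if key not in valid:
            raise ConfigError(f"unknown field {section_name}.{key}")
        if isinstance(val, list):
            val = tuple(val)
        setattr(section_obj, key, val)


def validate_config(raw: str | dict | None) -> PipelineConfig:
    """Parse a YAML string or mapping into a validated PipelineConfig.

    An empty configuration yields all defaults.  Out-of-range values
    raise :class:`ConfigError` naming the field and its default.
    """
    if raw is None:
        data = {}
    elif isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    else:
        data = dict(raw)
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")

    cfg = PipelineConfig()
    sections = {"detection": cfg.detection, "features": cfg.features}
    for key, val in data.items():
        if key in sections:
            if not isinstance(val, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            _apply(sections[key], key, val)
        elif key in {f.name for f in dataclasses.fields(PipelineConfig)}:
            setattr(cfg, key, val)
        else:
            raise ConfigError(f"unknown configuration field {key!r}")
    try:
        cfg.validate()
    except ConfigError as exc:
        # surface the deployed default alongside the failure where we have it
        for name, default in _DEFAULT_MSG.items():
            if name in str(exc):
                raise ConfigError(f"{exc} (default {default:g})") from None
        raise
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    return dataclasses.asdict(cfg)
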