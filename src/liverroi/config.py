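"""Pipeline configuration: a flat YAML document with namespaced keys.

Defaults reproduce the published protocol settings: resampling to
0.7 x 0.7 x 2.5 mm, 2 cm² ROIs offset 2 cm from the leftmost liver pixel
on three slices 0.5 cm apart, a 40 HU steatosis threshold, and 1000
bootstrap replicates. Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .attenuation import ROIParams


@dataclass
class PipelineConfig:
    target_spacing_mm: tuple[float, float, float] = (0.7, 0.7, 2.5)
    resample: bool = True
    roi: ROIParams = field(default_factory=ROIParams)
    threshold_hu: float = 40.0
    bootstrap_n: int = 1000
    bootstrap_seed: int = 17
    log_level: str = "INFO"

    def to_flat_dict(self) -> dict:
        d = {
            "target_spacing_mm": list(self.target_spacing_mm),
            "resample": self.resample,
            "threshold_hu": self.threshold_hu,
            "bootstrap.n": self.bootstrap_n,
            "bootstrap.seed": self.bootstrap_seed,
            "log_level": self.log_level,
        }
        for key, val in asdict(self.roi).items():
            d[f"roi.{key}"] = val
        return d

    @classmethod
    def from_flat_dict(cls, flat: dict) -> "PipelineConfig":
        known = set(cls().to_flat_dict())
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        roi_kwargs = {k.split(".", 1)[1]: v for k, v in flat.items() if k.startswith("roi.")}
        if roi_kwargs:
            base = asdict(cfg.roi)
            base.update(roi_kwargs)
            cfg.roi = ROIParams(**base)
        if "target_spacing_mm" in flat:
            cfg.target_spacing_mm = tuple(float(s) for s in flat["target_spacing_mm"])
        if "resample" in flat:
            cfg.resample = bool(flat["resample"])
        if "threshold_hu" in flat:
            cfg.threshold_hu = float(flat["threshold_hu"])
        if "bootstrap.n" in flat:
            cfg.bootstrap_n = int(flat["bootstrap.n"])
        if "bootstrap.seed" in flat:
            cfg.bootstrap_seed = int(flat["bootstrap.seed"])
        if "log_level" in flat:
            cfg.log_level = str(flat["log_level"])
        return cfg

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            flat = yaml.safe_load(fh) or {}
        if not isinstance(flat, dict):
            raise ValueError(f"{path}: config must be a mapping of namespaced keys")
        return cls.from_flat_dict(flat)
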