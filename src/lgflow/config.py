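"""Pipeline configuration with study defaults.

Every analysis constant lives here — the 25-km clustering cut, the minimum of
8 individuals per cluster, the >5-missing-loci sample filter, the candidate
nonhabitat resistances {5, 10, 20} and {50, 100, 200} with the r <= 0.7
decorrelation rule, the 1.2-km target resolution, and the 100-iteration /
80%-train / 5-bin cross-validation — all overridable from a YAML file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .surfaces import (
    CANDIDATE_RESISTANCES_HIGH,
    CANDIDATE_RESISTANCES_LOW,
    DEFAULT_CORR_LIMIT,
    ThresholdSpec,
)
from .synthetic import SyntheticConfig


class ConfigError(ValueError):
    pass


#: Default threshold schemes, keyed by variable tag.  ``habitat`` follows the
#: breeding-habitat index (probability thresholds, positive direction, top
#: resistances 20/200); the landscape tags use percent-cover style thresholds.
DEFAULT_THRESHOLD_SPECS: dict[str, dict] = {
    "habitat": {
        "direction": "positive",
        "thresholds": (0.25, 0.50, 0.65),
        "threshold_mode": "absolute",
    },
    "abundance": {
        "direction": "positive",
        "thresholds": (90.0, 70.0, 50.0),  # top-% of cell mass
        "threshold_mode": "percentile",
    },
    "cover_negative": {
        "direction": "negative",
        "thresholds": (0.25, 0.50, 0.75),
        "threshold_mode": "absolute",
    },
}


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings with field-standard defaults."""

    # inputs: either synthetic generation or file paths
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    genotypes_path: str | None = None
    raster_paths: dict = field(default_factory=dict)  # variable -> .asc path
    variables: tuple = ("habitat", "cover_negative")
    threshold_specs: dict = field(default_factory=dict)

    # genetics / clustering
    max_missing_loci: int = 5
    clustering_cut: float = 25.0  # same units as coordinates (km here)
    min_individuals: int = 8
    differentiation: str = "gst_prime"

    # resistance surfaces
    resistances_low: tuple = CANDIDATE_RESISTANCES_LOW
    resistances_high: tuple = CANDIDATE_RESISTANCES_HIGH
    corr_limit: float = DEFAULT_CORR_LIMIT
    target_resolution: float = 1.2  # km
    neighborhood: int = 8

    # cross-validation
    cv_iterations: int = 100
    cv_train_fraction: float = 0.8
    cv_bins: int = 5

    seed: int = 0
    outdir: str = "lgflow_out"

    def __post_init__(self) -> None:
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        specs = dict(DEFAULT_THRESHOLD_SPECS)
        specs.update(self.threshold_specs or {})
        self.threshold_specs = specs
        for var in self.variables:
            if var not in self.threshold_specs:
                raise ConfigError(f"unknown variable tag {var!r}")

    def spec_for(self, variable: str) -> ThresholdSpec:
        raw = dict(self.threshold_specs[variable])
        raw.setdefault("resistances_low", self.resistances_low)
        raw.setdefault("resistances_high", self.resistances_high)
        return ThresholdSpec(variable=variable, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("variables", "resistances_low", "resistances_high"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "threshold_specs" in raw:
            for spec in raw["threshold_specs"].values():
                if "thresholds" in spec:
                    spec["thresholds"] = tuple(spec["thresholds"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
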