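"""Run configuration: defaults, YAML loading, flag overrides."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .comparability import ClassificationThresholds
from .errors import ParameterError
from .radiomics import ExtractionConfig


@dataclass
class RunConfig:
    """All pipeline knobs in one place.

    Defaults follow the study conventions where they exist (1.5 mm
    isotropic grid, 50 % SUVmax threshold, strong/moderate cut-offs
    0.85/0.75 and 0.5/0.5); the texture bin count and wavelet family are
    extraction-side choices documented in the methods note.
    """

    target_spacing_mm: float = 1.5
    threshold_fraction: float = 0.5
    n_bins: int = 64
    wavelet: str = "coif1"
    texture_aggregation: str = "merged"
    icc_form: str = "consistency"
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not (0 < self.threshold_fraction <= 1):
            raise ParameterError("threshold_fraction must be in (0, 1]")
        if self.n_bins < 2:
            raise ParameterError("n_bins must be >= 2")

    def extraction(self) -> ExtractionConfig:
        return ExtractionConfig(
            n_bins=self.n_bins,
            wavelet=self.wavelet,
            texture_aggregation=self.texture_aggregation,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = ClassificationThresholds(**thr)
        return cfg
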