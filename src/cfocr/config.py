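"""Pipeline configuration with lossless YAML round-tripping.

All chart and simulation parameters live here with their canonical
defaults: 20-kb segments, 200-bp windows, 120-bp WPS window, alpha 0.05,
MEWMA lambda 0.2, chart weight eta 0.3, composite rate tau 0.7, 1000
bootstrap/Monte-Carlo replicates. Every source of randomness flows from
the single ``seed`` via per-stage spawned generators.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classifier import ClassifierConfig
from .sensitized import ETA_WARN_THRESHOLD
from .simulate import SimParams

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    segment_bp: int = 20_000
    window_bp: int = 200
    wps_w: int = 120
    candidate_bp: int = 2_000
    alpha: float = 0.05
    lam: float = 0.2
    eta: float = 0.3
    tau: float = 0.7
    B: int = 1000
    n_mc: int = 1000
    alpha_trim: float = 0.25
    calib_n: int = 500
    n_ocr: int = 400
    n_ccr: int = 1000
    n_pocr: int = 400
    n_test_per_class: int = 100
    noise_rate: float = 0.2
    balance_filtered: bool = True
    seed: int = 0
    sim: SimParams = field(default_factory=SimParams)
    classifier: ClassifierConfig = field(
        # compact linear model: higher lr than the deep-model default
        default_factory=lambda: ClassifierConfig(learning_rate=0.02, epochs=200)
    )

    def __post_init__(self) -> None:
        if self.eta >= ETA_WARN_THRESHOLD:
            msg = (f"eta={self.eta} >= {ETA_WARN_THRESHOLD}: partially open "
                   "statistics fall below the control limit and the three-class "
                   "bands degrade; eta <= 0.6 is recommended")
            logger.warning(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimParams(**d["sim"])
        if "classifier" in d and isinstance(d["classifier"], dict):
            d["classifier"] = ClassifierConfig(**d["classifier"])
        return cls(**d)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))
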