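"""Pipeline configuration: validated defaults, YAML loading, digests.

Every tunable stated elsewhere in the package surfaces here so a run is
fully described by (inputs, config, seed).  Unknown keys are rejected and
the effective configuration's digest is echoed into every report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .ranking import DEFAULT_NEGATIVE_PROMPTS, DEFAULT_POSITIVE_PROMPTS


@dataclass
class PromptingConfig:
    prior_quantile: float = 0.15
    prior_window_fraction: float = 0.5
    smooth_sigma: float = 3.0


@dataclass
class ProposalsConfig:
    backend: str = "fallback"
    levels: int = 8
    smooth_sigma: float = 2.0
    closing_radius: int = 2
    max_area_fraction: float = 0.25
    quantile_low: float = 0.05
    quantile_high: float = 0.40


@dataclass
class RankingConfig:
    positive_prompts: list[str] = field(default_factory=lambda: list(DEFAULT_POSITIVE_PROMPTS))
    negative_prompts: list[str] = field(default_factory=lambda: list(DEFAULT_NEGATIVE_PROMPTS))
    weights: dict[str, float] = field(
        default_factory=lambda: {"semantic": 0.5, "geometric": 0.3, "generator": 0.2}
    )
    crop_margin: float = 0.25
    target_area_fraction: float = 0.015
    max_area_fraction: float = 0.20

    def weight_tuple(self) -> tuple[float, float, float]:
        try:
            return (
                float(self.weights["semantic"]),
                float(self.weights["geometric"]),
                float(self.weights["generator"]),
            )
        except KeyError as exc:
            raise ConfigurationError(f"ranking.weights missing key {exc}") from exc


@dataclass
class EvaluationConfig:
    min_quality: int = 7
    bootstrap_ci: bool = False
    bootstrap_resamples: int = 2000


@dataclass
class PipelineConfig:
    seed: int = 0
    prompting: PromptingConfig = field(default_factory=PromptingConfig)
    proposals: ProposalsConfig = field(default_factory=ProposalsConfig)
    ranking: RankingConfig = field(default_factory=RankingConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        w = self.ranking.weight_tuple()
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ConfigurationError(f"ranking weights must be nonnegative and sum to 1, got {w}")
        if not 0 < self.prompting.prior_quantile < 1:
            raise ConfigurationError("prompting.prior_quantile must be in (0, 1)")
        if self.proposals.levels < 1:
            raise ConfigurationError("proposals.levels must be >= 1")
        if not 0 <= self.proposals.quantile_low < self.proposals.quantile_high <= 1:
            raise ConfigurationError("proposal quantile range must satisfy 0 <= low < high <= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {f.name: f for f in fields(cls)}
        unknown = set(data) - set(sections)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, value in data.items():
            f = sections[name]
            if name == "seed":
                kwargs[name] = int(value)
                continue
            sub_cls = f.default_factory().__class__  # type: ignore[misc]
            sub_fields = {sf.name for sf in fields(sub_cls)}
            if not isinstance(value, dict):
                raise ConfigurationError(f"config section {name!r} must be a mapping")
            sub_unknown = set(value) - sub_fields
            if sub_unknown:
                raise ConfigurationError(f"unknown keys in {name!r}: {sorted(sub_unknown)}")
            kwargs[name] = sub_cls(**value)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Short stable hash of the effective configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
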