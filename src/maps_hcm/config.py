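"""Pipeline configuration: YAML/JSON loading, defaults and validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .synthetic import SyntheticSpec


@dataclass
class VariantConfig:
    """One expression construct to score.

    ``phenotype_mix`` overrides the generated mixture directly; when
    absent and ``lof_score`` is given, the nuclear proportion is a
    monotone function of the LOF score (the planted ground-truth
    relationship used by synthetic studies).
    """

    name: str
    lof_score: Optional[float] = None
    phenotype_mix: Optional[tuple[float, float, float]] = None

    def resolve_mix(self) -> tuple[float, float, float]:
        if self.phenotype_mix is not None:
            return tuple(self.phenotype_mix)
        if self.lof_score is None:
            return (0.10, 0.70, 0.20)  # wildtype-like
        lof = min(max(self.lof_score, 0.0), 1.0)
        p_nuc = 0.10 + 0.70 * lof
        p_diff = 0.20
        return (p_nuc, max(1.0 - p_nuc - p_diff, 0.0), p_diff)


@dataclass
class SyntheticStageConfig:
    variants: list[VariantConfig] = field(
        default_factory=lambda: [VariantConfig(name="wildtype", lof_score=0.0)]
    )
    fields_per_variant: int = 8
    calibration_fields_per_class: int = 8
    calibration_blur_sigma: float = 5.0
    spec: dict = field(default_factory=dict)  # SyntheticSpec overrides


@dataclass
class QCStageConfig:
    channel: str = "nucleus"
    threshold: Optional[float] = None  # None -> calibrate


@dataclass
class DetectStageConfig:
    min_area: int = 150
    max_area: int = 30000
    smooth_sigma: float = 0.7
    pad_frac: float = 0.15
    reporter_min_frac: float = 0.5
    iou_threshold: float = 0.5


@dataclass
class FeaturesStageConfig:
    extractor: str = "radial"  # "radial" (weight-free) or "vgg"
    input_size: int = 64
    pool_grid: int = 4
    weights_source: str = "random"


@dataclass
class DiscoverStageConfig:
    k_min: int = 2
    k_max: int = 6
    noise_max_frac: float = 0.2
    n_exemplars: int = 20


@dataclass
class ScoreStageConfig:
    train_variants: list[str] = field(default_factory=list)  # empty -> all
    lof_csv: Optional[str] = None  # defaults to the generated table


@dataclass
class PipelineConfig:
    """Top-level pipeline configuration with a global seed that fans out
    to every stochastic stage."""

    seed: int = 0
    out_root: str = "maps_run"
    mode: str = "score"  # "score" or "discover"
    channel_map: dict = field(
        default_factory=lambda: {"nucleus": 0, "reporter": 1, "target": 2}
    )
    synthetic: SyntheticStageConfig = field(default_factory=SyntheticStageConfig)
    qc: QCStageConfig = field(default_factory=QCStageConfig)
    detect: DetectStageConfig = field(default_factory=DetectStageConfig)
    features: FeaturesStageConfig = field(default_factory=FeaturesStageConfig)
    discover: DiscoverStageConfig = field(default_factory=DiscoverStageConfig)
    score: ScoreStageConfig = field(default_factory=ScoreStageConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_STAGE_TYPES = {
    "synthetic": SyntheticStageConfig,
    "qc": QCStageConfig,
    "detect": DetectStageConfig,
    "features": FeaturesStageConfig,
    "discover": DiscoverStageConfig,
    "score": ScoreStageConfig,
}


def _build(cls, data: dict, context: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    kwargs = {}
    for stage, cls in _STAGE_TYPES.items():
        if stage in data:
            sub = data.pop(stage) or {}
            if stage == "synthetic" and "variants" in sub:
                sub = dict(sub)
                sub["variants"] = [
                    _build(VariantConfig, dict(v), f"synthetic.variants[{i}]")
                    for i, v in enumerate(sub["variants"])
                ]
            kwargs[stage] = _build(cls, sub, stage)
    top_valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_valid
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    return PipelineConfig(**{**data, **kwargs})


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON pipeline config; defaults are filled and
    unknown keys rejected.  An empty file yields the full-default
    config with a warning."""
    import warnings

    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"cannot parse config {path}: {exc}") from exc
    if data is None:
        warnings.warn(f"config {path} is empty; using full defaults")
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return the list of problems; empty iff the config is runnable."""
    issues: list[str] = []
    if config.mode not in ("score", "discover"):
        issues.append(f"mode must be 'score' or 'discover', got {config.mode!r}")
    required_roles = {"nucleus", "reporter", "target"}
    if set(config.channel_map) != required_roles:
        issues.append(
            f"channel_map must define exactly {sorted(required_roles)}, "
            f"got {sorted(config.channel_map)}"
        )
    if config.synthetic.fields_per_variant < 1:
        issues.append("synthetic.fields_per_variant must be >= 1")
    if not config.synthetic.variants:
        issues.append("synthetic.variants must not be empty")
    names = [v.name for v in config.synthetic.variants]
    if len(names) != len(set(names)):
        issues.append("synthetic.variants names must be unique")
    for v in config.synthetic.variants:
        if v.phenotype_mix is not None and abs(sum(v.phenotype_mix) - 1.0) > 1e-9:
            issues.append(
                f"variant {v.name!r}: phenotype_mix sums to "
                f"{sum(v.phenotype_mix):g}, expected 1"
            )
    try:
        SyntheticSpec(**config.synthetic.spec)
    except (TypeError, ValueError) as exc:
        issues.append(f"synthetic.spec invalid: {exc}")
    if config.features.extractor not in ("radial", "vgg"):
        issues.append(f"features.extractor must be 'radial' or 'vgg'")
    if not (2 <= config.discover.k_min <= config.discover.k_max):
        issues.append("discover.k_min/k_max must satisfy 2 <= k_min <= k_max")
    if config.qc.threshold is not None and config.qc.threshold < 0:
        issues.append("qc.threshold must be >= 0")
    return issues
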