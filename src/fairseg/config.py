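"""YAML experiment configuration: data/model/train/audit sections.

A single YAML file drives the command-line workflow::

    seed: 1
    output_dir: runs/demo
    data:
      synthetic:
        distribution: table1        # or {majority: 168, minority: 72}
        seed: 1
        params:
          joint: knee
          image_size: 64
          noise_sigma: 0.08
          bias_delta: 0.5
          disadvantaged_group: [race, black_african_american]
      # alternatively:  manifest: path/to/manifest.csv
    model:
      n_classes: 4
      width_multiplier: 0.125
      use_stem: false
    train:
      strategies: [baseline, balanced, stratified, group_specific]
      protected_attribute: race
      epochs: 5
      batch_size: 4
      learning_rate: 0.003
      loss: cross_entropy
    audit:
      attributes: [race]
      metrics: [iou, dice]
      B: 1000
      alpha: 0.05
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cohort import (
    ATTRIBUTE_LEVELS,
    AgeGroup,
    GroupDistribution,
    Joint,
    Race,
    Sex,
    table1_distribution,
)
from .model import ModelConfig
from .phantom import PhenotypeParams
from .training import STRATEGIES, TrainConfig

__all__ = ["ExperimentConfig", "load_config", "phenotype_params_from_dict",
           "phenotype_params_to_dict"]


def phenotype_params_from_dict(d: dict) -> PhenotypeParams:
    """Build PhenotypeParams from a YAML-friendly mapping (string enum keys)."""
    d = dict(d or {})
    if "joint" in d and d["joint"] is not None:
        d["joint"] = Joint(d["joint"])
    if "sex_width_factor" in d:
        d["sex_width_factor"] = {Sex(k): float(v)
                                 for k, v in d["sex_width_factor"].items()}
    if "race_contrast_offset" in d:
        d["race_contrast_offset"] = {Race(k): float(v)
                                     for k, v in d["race_contrast_offset"].items()}
    if "age_joint_space" in d:
        d["age_joint_space"] = {AgeGroup(k): float(v)
                                for k, v in d["age_joint_space"].items()}
    if "disadvantaged_group" in d:
        attr, level = d["disadvantaged_group"]
        d["disadvantaged_group"] = (attr, ATTRIBUTE_LEVELS[attr](level))
    return PhenotypeParams(**d)


def phenotype_params_to_dict(p: PhenotypeParams) -> dict:
    attr, level = p.disadvantaged_group
    return {
        "joint": p.joint.value if p.joint else None,
        "image_size": p.image_size,
        "sex_width_factor": {k.value: v for k, v in p.sex_width_factor.items()},
        "race_contrast_offset": {k.value: v for k, v in p.race_contrast_offset.items()},
        "age_joint_space": {k.value: v for k, v in p.age_joint_space.items()},
        "noise_sigma": p.noise_sigma,
        "bias_delta": p.bias_delta,
        "disadvantaged_group": [attr, level.value],
        "background": p.background,
        "bone_contrast": p.bone_contrast,
        "jitter": p.jitter,
    }


@dataclass
class ExperimentConfig:
    seed: int = 0
    output_dir: str = "runs/experiment"
    manifest: str | None = None          # pre-existing cohort manifest, or ...
    synthetic: dict | None = None        # ... synthetic-generation block
    model: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.manifest is None and self.synthetic is None:
            raise ValueError("config needs a data source: 'manifest' or 'synthetic'")
        for s in self.strategies():
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}")

    # -- section accessors -------------------------------------------------
    def strategies(self) -> list[str]:
        return list(self.train.get("strategies", ["baseline"]))

    def model_config(self) -> ModelConfig:
        return ModelConfig.from_dict(self.model) if self.model else ModelConfig()

    def train_config(self, strategy: str) -> TrainConfig:
        d = {k: v for k, v in self.train.items() if k != "strategies"}
        if "adam_betas" in d:
            d["adam_betas"] = tuple(d["adam_betas"])
        d.setdefault("seed", self.seed)
        return TrainConfig(strategy=strategy, **d)

    def phenotype_params(self) -> PhenotypeParams:
        return phenotype_params_from_dict((self.synthetic or {}).get("params", {}))

    def distribution(self) -> GroupDistribution:
        spec = (self.synthetic or {}).get("distribution", "table1")
        if spec == "table1":
            return table1_distribution()
        if isinstance(spec, dict) and {"majority", "minority"} <= set(spec):
            from .experiment import knee_distribution_by_race

            return knee_distribution_by_race(int(spec["majority"]),
                                             int(spec["minority"]))
        raise ValueError(f"unrecognized distribution spec {spec!r}")

    def generation_seed(self) -> int:
        return int((self.synthetic or {}).get("seed", self.seed))

    def audit_attributes(self) -> list[str]:
        return list(self.audit.get("attributes",
                                   [self.train.get("protected_attribute", "race")]))

    def audit_metrics(self) -> list[str]:
        return list(self.audit.get("metrics", ["iou", "dice"]))

    def bootstrap_B(self) -> int:
        return int(self.audit.get("B", 1000))

    def alpha(self) -> float:
        return float(self.audit.get("alpha", 0.05))

    # -- provenance --------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def load_config(path: str | Path, seed_override: int | None = None) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    data = raw.pop("data", {}) or {}
    cfg = ExperimentConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "runs/experiment")),
        manifest=data.get("manifest"),
        synthetic=data.get("synthetic"),
        model=raw.get("model", {}) or {},
        train=raw.get("train", {}) or {},
        audit=raw.get("audit", {}) or {},
    )
    if seed_override is not None:
        cfg.seed = int(seed_override)
    return cfg
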