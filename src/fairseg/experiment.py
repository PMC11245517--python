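"""End-to-end bias-injection / bias-mitigation experiments on phantom cohorts.

This is the desk-scale counterpart of the published OAI-scale study: generate
a race-imbalanced knee phantom cohort whose disadvantaged group renders at a
lower contrast-to-noise ratio (bias coefficient ``delta``), train under the
mitigation strategies, and audit group fairness (SER) on the held-out test
split.  Problem sizes default to ~200 training and ~40 test images at 64x64
pixels with a 1/8-width model and 5 epochs, which keeps a full multi-seed
experiment within minutes on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import (
    AgeGroup,
    GroupDistribution,
    Joint,
    Race,
    Sex,
    Split,
    assign_splits,
)
from .metrics import FairnessReport, audit
from .model import ModelConfig
from .phantom import PhenotypeParams, render_cohort
from .training import TrainConfig, train

logger = logging.getLogger(__name__)

__all__ = [
    "knee_distribution_by_race",
    "imbalanced_knee_distribution",
    "desk_model_config",
    "desk_phenotype_params",
    "run_bias_experiment",
    "mean_ser",
]


def knee_distribution_by_race(n_majority: int, n_minority: int) -> GroupDistribution:
    """Knee-only cohort with given White vs Black/African-American totals.

    Sex and age levels are spread as evenly as possible within each race so
    race is the only systematically imbalanced attribute.
    """
    entries: dict = {}
    for race, total in ((Race.white_caucasian, n_majority),
                        (Race.black_african_american, n_minority)):
        cells = [(sex, age) for sex in Sex for age in AgeGroup]
        base, rem = divmod(total, len(cells))
        for i, (sex, age) in enumerate(cells):
            entries[(Joint.knee, sex, race, age)] = base + (1 if i < rem else 0)
    return GroupDistribution(entries, mode="counts")


def imbalanced_knee_distribution(n_majority: int = 168, n_minority: int = 72
                                 ) -> GroupDistribution:
    """Development cohort: 70/30 race imbalance (240 records -> ~200 train)."""
    return knee_distribution_by_race(n_majority, n_minority)


def desk_model_config(n_classes: int = 4) -> ModelConfig:
    """1/8-width, stem-free configuration valid for 64x64 inputs."""
    return ModelConfig(n_classes=n_classes, width_multiplier=1 / 8, use_stem=False)


def desk_phenotype_params(delta: float, image_size: int = 64) -> PhenotypeParams:
    return PhenotypeParams(
        joint=Joint.knee,
        image_size=image_size,
        bias_delta=delta,
        disadvantaged_group=("race", Race.black_african_american),
    )


@dataclass
class BiasExperimentResult:
    delta: float
    seed: int
    reports: dict[str, FairnessReport] = field(default_factory=dict)

    def ser(self, strategy: str, metric: str = "iou") -> float:
        return self.reports[strategy].ser(metric)


def run_bias_experiment(
    seed: int,
    delta: float,
    strategies: tuple[str, ...] = ("baseline", "balanced", "stratified"),
    attribute: str = "race",
    epochs: int = 5,
    image_size: int = 64,
    dist: GroupDistribution | None = None,
    n_test_per_level: int = 20,
) -> BiasExperimentResult:
    """One seed of the mitigation experiment: generate, split, train, audit.

    The training/validation cohort follows the (imbalanced) ``dist``;
    evaluation uses a dedicated composition-balanced test cohort
    (``n_test_per_level`` images per protected-group level, rendered under
    the same phenotype rules) so group score differences reflect the
    difficulty gap rather than test-set composition.
    """
    dist = dist or imbalanced_knee_distribution()
    params = desk_phenotype_params(delta, image_size=image_size)
    samples = render_cohort(dist, params, seed=seed)
    data = {s.record.patient_id: (s.image, s.mask) for s in samples}
    records = assign_splits([s.record for s in samples], (0.85, 0.15, 0.0),
                            seed=seed,
                            stratify_by=["joint", "race", "sex", "age_group"])

    test_dist = knee_distribution_by_race(n_test_per_level, n_test_per_level)
    test_seed = int(np.random.SeedSequence([seed, 0x7E57]).generate_state(1)[0]
                    % 2**31)
    test_samples = render_cohort(test_dist, params, seed=test_seed)
    test_records = []
    for s in test_samples:
        rec = replace(s.record, patient_id="test_" + s.record.patient_id,
                      split=Split.test)
        data[rec.patient_id] = (s.image, s.mask)
        test_records.append(rec)
    model_config = desk_model_config(n_classes=4)

    result = BiasExperimentResult(delta=delta, seed=seed)
    for strategy in strategies:
        cfg = TrainConfig.desk(strategy=strategy, protected_attribute=attribute,
                               epochs=epochs, seed=seed)
        artifact = train(records, model_config, cfg, data=data)
        report = audit(artifact, test_records, attribute, data=data)
        result.reports[strategy] = report
        logger.info("delta=%.2f seed=%d %s: SER(IoU)=%.3f per-level=%s",
                    delta, seed, strategy, report.ser("iou"),
                    report.entries["iou"]["per_level"])
    return result


def mean_ser(results: list[BiasExperimentResult], strategy: str,
             metric: str = "iou") -> float:
    """Mean SER over experiment replicates (seeds)."""
    return float(np.mean([r.ser(strategy, metric) for r in results]))
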