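"""Mitigation samplers, losses, and the training loop."""

import numpy as np
import pytest

from fairseg.cohort import Race, Split
from fairseg.model import ModelConfig
from fairseg.training import (
    TrainConfig,
    balance_by_undersampling,
    loss_value,
    stratified_batches,
    train,
)

from conftest import make_record, make_records


def records_with_counts(counts: dict[Race, int], split=Split.train):
    out = []
    i = 0
    for race, n in counts.items():
        for _ in range(n):
            out.append(make_record(pid=f"r{i:04d}", race=race, split=split))
            i += 1
    return out


class TestUndersampling:
    def test_majority_reduced_to_minority_count(self):
        records = records_with_counts({Race.white_caucasian: 100,
                                       Race.black_african_american: 40})
        out = balance_by_undersampling(records, "race", seed=0)
        counts = {lvl: sum(r.attributes.race is lvl for r in out)
                  for lvl in Race}
        assert counts == {Race.white_caucasian: 40,
                          Race.black_african_american: 40}

    def test_already_balanced_is_identity_multiset(self):
        records = records_with_counts({Race.white_caucasian: 25,
                                       Race.black_african_american: 25})
        out = balance_by_undersampling(records, "race", seed=1)
        assert sorted(r.patient_id for r in out) == \
            sorted(r.patient_id for r in records)

    def test_three_levels_all_reduced_to_smallest(self):
        from fairseg.cohort import AgeGroup

        records = []
        for age, n in [(AgeGroup.age_le_50, 50), (AgeGroup.age_51_64, 30),
                       (AgeGroup.age_65_79, 20)]:
            records += [make_record(pid=f"a{age.value}{i}", age=age,
                                    split=Split.train) for i in range(n)]
        out = balance_by_undersampling(records, "age_group", seed=2)
        assert len(out) == 60
        for age in AgeGroup:
            assert sum(r.attributes.age_group is age for r in out) == 20

    def test_never_increases_any_level(self):
        records = records_with_counts({Race.white_caucasian: 9,
                                       Race.black_african_american: 3})
        out = balance_by_undersampling(records, "race", seed=3)
        ids = {r.patient_id for r in out}
        assert ids <= {r.patient_id for r in records}
        assert len(out) == 6

    def test_deterministic_given_seed(self):
        records = records_with_counts({Race.white_caucasian: 20,
                                       Race.black_african_american: 5})
        a = balance_by_undersampling(records, "race", seed=9)
        b = balance_by_undersampling(records, "race", seed=9)
        assert a == b


class TestStratifiedBatches:
    def test_two_levels_split_batch_evenly(self):
        records = records_with_counts({Race.white_caucasian: 32,
                                       Race.black_african_american: 8})
        for batch in stratified_batches(records, "race", 16, seed=0):
            counts = [sum(r.attributes.race is lvl for r in batch)
                      for lvl in Race]
            assert counts == [8, 8]

    def test_three_level_remainder_rotates(self):
        from fairseg.cohort import AgeGroup

        records = []
        for age in AgeGroup:
            records += [make_record(pid=f"{age.value}{i}", age=age,
                                    split=Split.train) for i in range(16)]
        batches = stratified_batches(records, "age_group", 16, seed=0)
        allocations = [
            tuple(sum(r.attributes.age_group is age for r in batch)
                  for age in AgeGroup)
            for batch in batches[:3]
        ]
        assert allocations == [(6, 5, 5), (5, 6, 5), (5, 5, 6)]

    def test_single_level_degenerates_to_plain_batching(self):
        records = make_records(10, split=Split.train)
        batches = stratified_batches(records, "race", 4, seed=1)
        assert [len(b) for b in batches] == [4, 4, 4]  # ceil(10*1/4) = 3 batches
        seen = [r.patient_id for b in batches for r in b]
        assert set(seen) == {r.patient_id for r in records}

    def test_every_batch_is_balanced_within_one(self):
        records = records_with_counts({Race.white_caucasian: 37,
                                       Race.black_african_american: 11})
        for batch in stratified_batches(records, "race", 7, seed=2):
            counts = [sum(r.attributes.race is lvl for r in batch)
                      for lvl in Race]
            assert max(counts) - min(counts) <= 1

    def test_epoch_length_covers_majority_level(self):
        records = records_with_counts({Race.white_caucasian: 30,
                                       Race.black_african_american: 6})
        batches = stratified_batches(records, "race", 12, seed=0)
        assert len(batches) == int(np.ceil(30 * 2 / 12))

    def test_batch_smaller_than_levels_rejected(self):
        records = records_with_counts({Race.white_caucasian: 4,
                                       Race.black_african_american: 4})
        with pytest.raises(ValueError, match="batch_size"):
            stratified_batches(records, "race", 1, seed=0)


class TestLossValue:
    def test_uniform_two_class_cross_entropy(self):
        scores = np.zeros((1, 2, 4, 4), dtype=np.float32)
        target = np.zeros((1, 4, 4), dtype=np.int64)
        assert loss_value("cross_entropy", scores, target) == \
            pytest.approx(np.log(2))

    def test_perfect_scores_zero_jaccard_and_dice(self):
        target = np.zeros((1, 4, 4), dtype=np.int64)
        target[0, 2:] = 1
        scores = np.where(np.arange(2)[None, :, None, None] == target[:, None],
                          40.0, -40.0)
        assert loss_value("jaccard", scores, target) == pytest.approx(0.0, abs=1e-6)
        assert loss_value("dice", scores, target) == pytest.approx(0.0, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            loss_value("dice", np.zeros((1, 2, 4, 4)), np.zeros((1, 5, 5)))

    def test_unknown_loss_rejected(self):
        with pytest.raises(ValueError, match="loss"):
            loss_value("focal", np.zeros((1, 2, 4, 4)), np.zeros((1, 4, 4)))


def desk_model():
    return ModelConfig(n_classes=4, width_multiplier=1 / 8, use_stem=False)


def split_cohort(samples):
    """First 8 train / next 2 val per race level for the tiny fixture."""
    from dataclasses import replace

    from fairseg.cohort import assign_splits

    records = assign_splits([s.record for s in samples], (0.7, 0.15, 0.15),
                            seed=0, stratify_by=["race"])
    return records


class TestTrainLoop:
    def test_zero_epochs_returns_initial_weights(self, tiny_knee_cohort):
        samples, data = tiny_knee_cohort
        records = split_cohort(samples)
        cfg = TrainConfig.desk(epochs=0, seed=3)
        art = train(records, desk_model(), cfg, data=data)
        from fairseg.model import build_model

        init = build_model(desk_model(), init_seed=cfg.seed)
        for p, q in zip(art.models["all"].parameters(), init.parameters()):
            np.testing.assert_array_equal(p.value, q.value)

    def test_loss_decreases_on_small_fixture(self, tiny_knee_cohort):
        samples, data = tiny_knee_cohort
        records = split_cohort(samples)
        cfg = TrainConfig.desk(epochs=4, seed=1)
        art = train(records, desk_model(), cfg, data=data)
        losses = [h["train_loss"] for h in art.history]
        assert losses[-1] < losses[0]

    def test_group_specific_trains_one_model_per_level(self, tiny_knee_cohort):
        samples, data = tiny_knee_cohort
        records = split_cohort(samples)
        cfg = TrainConfig.desk(strategy="group_specific", epochs=1,
                               protected_attribute="sex", seed=2)
        art = train(records, desk_model(), cfg, data=data)
        assert set(art.models) == {"male", "female"}

    def test_training_is_reproducible(self, tiny_knee_cohort):
        samples, data = tiny_knee_cohort
        records = split_cohort(samples)
        cfg = TrainConfig.desk(epochs=1, seed=8)
        a = train(records, desk_model(), cfg, data=data)
        b = train(records, desk_model(), cfg, data=data)
        for p, q in zip(a.models["all"].parameters(), b.models["all"].parameters()):
            np.testing.assert_array_equal(p.value, q.value)

    def test_balanced_strategy_equalizes_before_training(self, tiny_knee_cohort):
        samples, data = tiny_knee_cohort
        records = split_cohort(samples)
        cfg = TrainConfig.desk(strategy="balanced", epochs=1, seed=0)
        art = train(records, desk_model(), cfg, data=data)
        assert art.config.strategy == "balanced"
        assert len(art.history) == 1

    def test_config_validation(self):
        with pytest.raises(ValueError, match="strategy"):
            TrainConfig(strategy="adversarial")
        with pytest.raises(ValueError, match="learning_rate"):
            TrainConfig(learning_rate=0)
        with pytest.raises(ValueError, match="epochs"):
            TrainConfig(epochs=-1)
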