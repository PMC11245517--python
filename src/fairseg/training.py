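"""Bias-mitigation training strategies and the training loop.

Four data-level strategies address group bias without altering the loss:

* ``baseline`` — train one model on the full training split;
* ``balanced`` — undersample overrepresented protected-group levels to the
  minority size, then train one model;
* ``stratified`` — train one model on mini-batches constructed to contain
  (near-)equal numbers of records from every level;
* ``group_specific`` — train a separate model per level, each seeing only
  its own level's records.

Published training hyperparameters are the defaults: Adam, learning rate
5e-4, cross-entropy loss, 50 epochs, batch size 16, IoU/Dice threshold 0.5.
``TrainConfig.desk()`` provides the scaled-down testing profile.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .cohort import ATTRIBUTE_LEVELS, CohortRecord, Split, group_levels
from .io import load_sample
from .metrics import MaskPair, image_score
from .model import ModelConfig, SegNet, build_model, predict_masks

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainedArtifact",
    "balance_by_undersampling",
    "stratified_batches",
    "train",
    "loss_value",
]

STRATEGIES = ("baseline", "balanced", "stratified", "group_specific")

_LOSSES = {
    "cross_entropy": nn.softmax_cross_entropy,
    "jaccard": nn.soft_jaccard_loss,
    "dice": nn.soft_dice_loss,
}


@dataclass
class TrainConfig:
    strategy: str = "baseline"
    protected_attribute: str = "race"
    learning_rate: float = 5e-4
    epochs: int = 50
    batch_size: int = 16
    loss: str = "cross_entropy"
    optimizer: str = "adam"
    adam_betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.protected_attribute not in ATTRIBUTE_LEVELS:
            raise ValueError(f"unknown protected attribute {self.protected_attribute!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.loss not in _LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """Scaled-down CPU profile: 5 epochs, batch 4, lr 5e-3.

        The published settings (50 epochs, batch 16, lr 5e-4) assume GPU-scale
        data and model; at desk scale the smaller batch buys more optimizer
        steps per epoch and a moderately higher rate converges within the
        short budget without destabilizing training.
        """
        defaults = dict(epochs=5, learning_rate=3e-3, batch_size=4,
                        adam_betas=(0.9, 0.99))
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class TrainedArtifact:
    """Trained model(s) plus training history and configuration.

    ``models`` has the single key ``"all"`` except under the group-specific
    strategy, where it holds one model per protected-group level.
    """

    models: dict[str, SegNet]
    history: list[dict] = field(default_factory=list)
    config: TrainConfig = field(default_factory=TrainConfig)

    def model_for(self, record: CohortRecord, attribute: str | None = None) -> SegNet:
        """Model responsible for a record (its own level's model if group-specific)."""
        if self.config.strategy == "group_specific":
            attr = attribute or self.config.protected_attribute
            level = record.attributes.level(attr).value
            if level not in self.models:
                raise KeyError(f"no model trained for level {level!r}")
            return self.models[level]
        return self.models["all"]


def balance_by_undersampling(
    records: Sequence[CohortRecord], attribute: str, seed: int = 0
) -> list[CohortRecord]:
    """Undersample every level of ``attribute`` to the minority-level count.

    Sampling is uniform without replacement and deterministic given ``seed``;
    record order within a level follows patient_id order of the kept subset.
    """
    levels = group_levels(records, attribute)
    if not levels:
        raise ValueError("no records to balance")
    by_level = {
        lvl: sorted((r for r in records if r.attributes.level(attribute) == lvl),
                    key=lambda r: r.patient_id)
        for lvl in levels
    }
    n_min = min(len(v) for v in by_level.values())
    rng = np.random.default_rng(seed)
    kept: list[CohortRecord] = []
    for lvl in levels:
        members = by_level[lvl]
        idx = rng.choice(len(members), size=n_min, replace=False)
        kept.extend(members[i] for i in sorted(idx))
    return kept


def stratified_batches(
    records: Sequence[CohortRecord],
    attribute: str,
    batch_size: int,
    seed: int = 0,
) -> list[list[CohortRecord]]:
    """One epoch of group-balanced mini-batches.

    Every batch holds ``batch_size // g`` records from each of the g levels;
    the ``batch_size % g`` remainder rotates round-robin across batches so no
    level is systematically favored.  Within a level, records are consumed in
    seeded shuffled order and reshuffled when exhausted, so minority levels
    are oversampled within the epoch.  Epoch length is
    ``ceil(max_level_count * g / batch_size)`` batches.
    """
    levels = group_levels(records, attribute)
    g = len(levels)
    if g == 0:
        raise ValueError("no records to batch")
    if batch_size < g:
        raise ValueError(f"batch_size {batch_size} < number of levels {g}")
    by_level = {
        lvl: sorted((r for r in records if r.attributes.level(attribute) == lvl),
                    key=lambda r: r.patient_id)
        for lvl in levels
    }
    for lvl, members in by_level.items():
        if not members:
            raise ValueError(f"level {lvl.value!r} has no records")

    rng = np.random.default_rng(seed)
    streams = {}

    def draw(lvl, k):
        buf = streams.setdefault(lvl, [])
        while len(buf) < k:
            members = by_level[lvl]
            buf.extend(members[i] for i in rng.permutation(len(members)))
        out, streams[lvl] = buf[:k], buf[k:]
        return out

    n_max = max(len(v) for v in by_level.values())
    n_batches = int(np.ceil(n_max * g / batch_size))
    base, rem = divmod(batch_size, g)
    batches = []
    for t in range(n_batches):
        batch = []
        for i, lvl in enumerate(levels):
            extra = 1 if (i - t) % g < rem else 0
            batch.extend(draw(lvl, base + extra))
        batches.append(batch)
    return batches


def loss_value(loss: str, scores: np.ndarray, target: np.ndarray) -> float:
    """Value of a segmentation loss on raw class scores vs an integer mask batch.

    ``cross_entropy`` is the mean per-pixel multi-class cross-entropy;
    ``jaccard`` and ``dice`` are 1 minus the soft (probability-weighted)
    IoU/Dice averaged over foreground classes.
    """
    if loss not in _LOSSES:
        raise ValueError(f"unknown loss {loss!r}")
    if scores.shape[0] != target.shape[0] or scores.shape[2:] != target.shape[1:]:
        raise ValueError("score and target shapes are inconsistent")
    value, _ = _LOSSES[loss](scores, np.asarray(target))
    return float(value)


def _as_batch(images: list[np.ndarray]) -> np.ndarray:
    return np.stack(images)[:, None, :, :].astype(np.float32)


def _mean_val_iou(model, records, data, n_classes, batch_size=16):
    scores = []
    fg = list(range(1, n_classes))
    for i in range(0, len(records), batch_size):
        chunk = records[i:i + batch_size]
        imgs = _as_batch([data[r.patient_id][0] for r in chunk])
        preds = predict_masks(model, imgs)
        for pred, r in zip(preds, chunk):
            pair = MaskPair(pred, data[r.patient_id][1])
            scores.append(image_score(pair, "iou", foreground_classes=fg))
    return float(np.mean(scores)) if scores else float("nan")


def _snapshot(model: SegNet):
    return ([p.value.copy() for p in model.parameters()],
            [b.copy() for b in model.buffers()])


def _restore(model: SegNet, snap) -> None:
    values, buffers = snap
    for p, v in zip(model.parameters(), values):
        p.value = v.copy()
    from .model import _load_model_buffers

    _load_model_buffers(model, [b.copy() for b in buffers])


def _fit_one(
    records: list[CohortRecord],
    val_records: list[CohortRecord],
    model_config: ModelConfig,
    cfg: TrainConfig,
    data: Mapping[str, tuple[np.ndarray, np.ndarray]],
    model_seed: int,
    tag: str,
) -> tuple[SegNet, list[dict]]:
    model = build_model(model_config, init_seed=model_seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate,
                  betas=tuple(cfg.adam_betas))
    loss_fn = _LOSSES[cfg.loss]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xBA7C4]))

    batch_size = cfg.batch_size
    if cfg.strategy == "group_specific" and len(records) < batch_size:
        logger.warning(
            "group %s has %d records < batch size %d; reducing batch size",
            tag, len(records), batch_size)
        batch_size = max(1, len(records))

    history: list[dict] = []
    best = _snapshot(model)
    best_iou = -np.inf
    for epoch in range(cfg.epochs):
        if cfg.strategy == "stratified":
            batches = stratified_batches(
                records, cfg.protected_attribute, batch_size,
                seed=int(rng.integers(2**31)))
        else:
            order = rng.permutation(len(records))
            batches = [[records[i] for i in order[k:k + batch_size]]
                       for k in range(0, len(records), batch_size)]
        losses = []
        for batch in batches:
            imgs = _as_batch([data[r.patient_id][0] for r in batch])
            masks = np.stack([data[r.patient_id][1] for r in batch]).astype(np.int64)
            logits = model.forward(imgs, train=True)
            loss, dlogits = loss_fn(logits, masks)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        row = {"model": tag, "epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_records:
            val_imgs = _as_batch([data[r.patient_id][0] for r in val_records])
            val_masks = np.stack(
                [data[r.patient_id][1] for r in val_records]).astype(np.int64)
            # evaluate in chunks to bound memory
            vloss = []
            for k in range(0, len(val_records), batch_size):
                logits = model.forward(val_imgs[k:k + batch_size], train=False)
                vloss.append(loss_fn(logits, val_masks[k:k + batch_size])[0])
            row["val_loss"] = float(np.mean(vloss))
            row["val_mean_iou"] = _mean_val_iou(
                model, val_records, data, model_config.n_classes, batch_size)
            if row["val_mean_iou"] > best_iou:  # checkpoint selection rule
                best_iou = row["val_mean_iou"]
                best = _snapshot(model)
        else:
            best = _snapshot(model)
        history.append(row)
        logger.info("model %s epoch %d: %s", tag, epoch, row)
    if cfg.epochs > 0 and val_records:
        _restore(model, best)
    return model, history


def train(
    manifest: Sequence[CohortRecord],
    model_config: ModelConfig,
    train_config: TrainConfig,
    data: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> TrainedArtifact:
    """Train under one mitigation strategy; all randomness flows from the config seed.

    ``manifest`` must carry assigned splits; only train-split records are
    fitted and val-split records drive best-epoch checkpoint selection (by
    mean validation IoU).  ``data`` optionally maps patient_id ->
    (image, mask) arrays; otherwise samples are read from the record paths.
    """
    cfg = train_config
    train_records = [r for r in manifest if r.split is Split.train]
    val_records = [r for r in manifest if r.split is Split.val]
    if not train_records:
        raise ValueError("manifest has no train-split records")
    if data is None:
        data = {r.patient_id: load_sample(r)
                for r in manifest if r.split in (Split.train, Split.val)}

    if cfg.strategy == "stratified":
        g = len(group_levels(train_records, cfg.protected_attribute))
        if cfg.batch_size < g:
            raise ValueError("batch_size must be >= number of group levels")

    if cfg.strategy == "balanced":
        fit_records = balance_by_undersampling(
            train_records, cfg.protected_attribute,
            seed=int(np.random.SeedSequence([cfg.seed, 0xBA1A]).generate_state(1)[0]
                     % 2**31))
    else:
        fit_records = list(train_records)

    models: dict[str, SegNet] = {}
    history: list[dict] = []
    if cfg.strategy == "group_specific":
        for level in group_levels(train_records, cfg.protected_attribute):
            subset = [r for r in fit_records
                      if r.attributes.level(cfg.protected_attribute) == level]
            val_subset = [r for r in val_records
                          if r.attributes.level(cfg.protected_attribute) == level]
            seed = int(np.random.SeedSequence(
                [cfg.seed, zlib.crc32(level.value.encode())]
            ).generate_state(1)[0] % 2**31)
            model, h = _fit_one(subset, val_subset, model_config, cfg, data,
                                model_seed=seed, tag=level.value)
            models[level.value] = model
            history.extend(h)
    else:
        model, h = _fit_one(fit_records, val_records, model_config, cfg, data,
                            model_seed=cfg.seed, tag="all")
        models["all"] = model
        history.extend(h)
    return TrainedArtifact(models=models, history=history, config=cfg)
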