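"""Patient cohort data model, manifest I/O, group arithmetic, and split assignment.

A cohort is a list of :class:`CohortRecord`, one radiograph per patient, each
carrying the protected attributes (sex, race, age group) across which fairness
is audited.  The module also ships the published hip/knee cohort composition
(:func:`table1_distribution`) used to drive the phantom generator.
"""

from __future__ import annotations

import enum
import logging
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "Race",
    "AgeGroup",
    "Joint",
    "Split",
    "ProtectedAttributes",
    "CohortRecord",
    "GroupDistribution",
    "ATTRIBUTE_LEVELS",
    "MANIFEST_COLUMNS",
    "read_manifest",
    "write_manifest",
    "table1_distribution",
    "table1_percentages",
    "group_share",
    "assign_splits",
    "group_levels",
]


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class Race(str, enum.Enum):
    white_caucasian = "white_caucasian"
    black_african_american = "black_african_american"


class AgeGroup(str, enum.Enum):
    age_le_50 = "age_le_50"
    age_51_64 = "age_51_64"
    age_65_79 = "age_65_79"


class Joint(str, enum.Enum):
    hip = "hip"
    knee = "knee"


class Split(str, enum.Enum):
    train = "train"
    val = "val"
    test = "test"
    unassigned = "unassigned"


#: Protected attribute name -> enum class, in canonical declaration order.
ATTRIBUTE_LEVELS: dict[str, type[enum.Enum]] = {
    "sex": Sex,
    "race": Race,
    "age_group": AgeGroup,
}

#: Exact manifest CSV column order.
MANIFEST_COLUMNS = (
    "patient_id",
    "joint",
    "sex",
    "race",
    "age_group",
    "image_path",
    "mask_path",
    "split",
)


@dataclass(frozen=True)
class ProtectedAttributes:
    """One patient's protected-attribute levels (no missing values allowed)."""

    sex: Sex
    race: Race
    age_group: AgeGroup

    def level(self, attribute: str) -> enum.Enum:
        if attribute not in ATTRIBUTE_LEVELS:
            raise KeyError(f"unknown protected attribute {attribute!r}")
        return getattr(self, attribute)


@dataclass(frozen=True)
class CohortRecord:
    """One patient/radiograph: joint, attributes, file paths, split assignment."""

    patient_id: str
    joint: Joint
    attributes: ProtectedAttributes
    image_path: str = ""
    mask_path: str = ""
    split: Split = Split.unassigned


class ManifestError(ValueError):
    """Raised on malformed manifests (unknown levels, duplicate ids, bad header)."""


def _parse_enum(cls: type[enum.Enum], token: str, row: int, column: str) -> enum.Enum:
    try:
        return cls(token)
    except ValueError:
        valid = ", ".join(m.value for m in cls)
        raise ManifestError(
            f"row {row}, column {column!r}: unknown level {token!r} (expected one of: {valid})"
        ) from None


def read_manifest(path: str | Path) -> list[CohortRecord]:
    """Read and validate a cohort manifest CSV into :class:`CohortRecord` objects."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if tuple(df.columns) != MANIFEST_COLUMNS:
        raise ManifestError(
            f"{path}: header {tuple(df.columns)} does not match expected {MANIFEST_COLUMNS}"
        )
    records: list[CohortRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        pid = row.patient_id
        if pid in seen:
            raise ManifestError(f"row {i}: duplicate patient_id {pid!r}")
        seen.add(pid)
        records.append(
            CohortRecord(
                patient_id=pid,
                joint=_parse_enum(Joint, row.joint, i, "joint"),
                attributes=ProtectedAttributes(
                    sex=_parse_enum(Sex, row.sex, i, "sex"),
                    race=_parse_enum(Race, row.race, i, "race"),
                    age_group=_parse_enum(AgeGroup, row.age_group, i, "age_group"),
                ),
                image_path=row.image_path,
                mask_path=row.mask_path,
                split=_parse_enum(Split, row.split, i, "split"),
            )
        )
    return records


def write_manifest(records: Sequence[CohortRecord], path: str | Path) -> None:
    """Write records as a manifest CSV (fixed column order; inverse of read_manifest)."""
    rows = [
        {
            "patient_id": r.patient_id,
            "joint": r.joint.value,
            "sex": r.attributes.sex.value,
            "race": r.attributes.race.value,
            "age_group": r.attributes.age_group.value,
            "image_path": r.image_path,
            "mask_path": r.mask_path,
            "split": r.split.value,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    df.to_csv(path, index=False, lineterminator="\n")


GroupKey = tuple[Joint, Sex, Race, AgeGroup]


@dataclass
class GroupDistribution:
    """Cohort composition over (joint, sex, race, age_group) cells.

    ``mode="counts"`` holds non-negative integer patient counts;
    ``mode="proportions"`` holds per-joint proportions that sum to 1.
    """

    entries: dict[GroupKey, float]
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "proportions"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "counts":
            for key, v in self.entries.items():
                if v < 0 or int(v) != v:
                    raise ValueError(f"count for {key} must be a non-negative integer, got {v}")
        else:
            for joint in {k[0] for k in self.entries}:
                total = sum(v for k, v in self.entries.items() if k[0] == joint)
                if abs(total - 1.0) > 1e-6:
                    raise ValueError(
                        f"proportions for joint {joint.value} sum to {total}, expected 1"
                    )

    def joint_total(self, joint: Joint) -> float:
        if joint not in {k[0] for k in self.entries}:
            raise KeyError(f"joint {joint.value!r} absent from distribution")
        return sum(v for k, v in self.entries.items() if k[0] == joint)

    def total(self) -> float:
        return sum(self.entries.values())


# Published cohort composition: per (sex, race, age-group) percentages of each
# joint's patients, with stated joint totals of 766 hip and 707 knee patients.
_TABLE1_PCT: list[tuple[Sex, Race, AgeGroup, float, float]] = [
    # (sex, race, age_group, hip %, knee %)
    (Sex.male, Race.white_caucasian, AgeGroup.age_le_50, 3.52, 3.65),
    (Sex.male, Race.white_caucasian, AgeGroup.age_51_64, 15.9, 13.2),
    (Sex.male, Race.white_caucasian, AgeGroup.age_65_79, 10.8, 10.6),
    (Sex.male, Race.black_african_american, AgeGroup.age_le_50, 2.8, 1.7),
    (Sex.male, Race.black_african_american, AgeGroup.age_51_64, 6.7, 6.1),
    (Sex.male, Race.black_african_american, AgeGroup.age_65_79, 2.9, 4.4),
    (Sex.female, Race.white_caucasian, AgeGroup.age_le_50, 3.2, 4.7),
    (Sex.female, Race.white_caucasian, AgeGroup.age_51_64, 13.9, 18.4),
    (Sex.female, Race.white_caucasian, AgeGroup.age_65_79, 10.9, 12.7),
    (Sex.female, Race.black_african_american, AgeGroup.age_le_50, 4.9, 3.45),
    (Sex.female, Race.black_african_american, AgeGroup.age_51_64, 17.9, 14.3),
    (Sex.female, Race.black_african_american, AgeGroup.age_65_79, 6.6, 6.8),
]

_JOINT_TOTALS = {Joint.hip: 766, Joint.knee: 707}


def table1_distribution() -> GroupDistribution:
    """Built-in counts-mode cohort composition (hip 766 + knee 707 patients).

    Counts are reconstructed from the published per-cell percentages
    (percentage x joint total, rounded to nearest integer); any residual versus
    the stated joint total is assigned to the joint's largest cell so the
    totals are exact.
    """
    entries: dict[GroupKey, float] = {}
    for joint, total in _JOINT_TOTALS.items():
        col = 3 if joint is Joint.hip else 4
        keys = [(joint, s, r, a) for s, r, a, *_ in _TABLE1_PCT]
        raw = [row[col] / 100.0 * total for row in _TABLE1_PCT]
        counts = [int(np.floor(x + 0.5)) for x in raw]
        residual = total - sum(counts)
        if residual != 0:
            counts[int(np.argmax(counts))] += residual
        for key, c in zip(keys, counts):
            entries[key] = c
    return GroupDistribution(entries, mode="counts")


def table1_percentages() -> GroupDistribution:
    """Proportions-mode version of the published composition.

    Built directly from the printed percentages, normalized per joint (the
    printed hip column sums to 100.02); this is the table from which the
    published pie-chart shares (e.g. 12.4% hip male Black/African American)
    derive exactly.
    """
    entries: dict[GroupKey, float] = {}
    for joint in _JOINT_TOTALS:
        col = 3 if joint is Joint.hip else 4
        total = sum(row[col] for row in _TABLE1_PCT)
        for row in _TABLE1_PCT:
            entries[(joint, row[0], row[1], row[2])] = row[col] / total
    return GroupDistribution(entries, mode="proportions")


def group_share(
    dist: GroupDistribution,
    joint: Joint,
    where: Mapping[str, enum.Enum] | None = None,
) -> float:
    """Percentage of a joint's patients matching a partial attribute predicate.

    ``where`` maps attribute names ("sex", "race", "age_group") to required
    levels; an empty/None predicate matches everything (returns 100).
    """
    where = dict(where or {})
    for name in where:
        if name not in ATTRIBUTE_LEVELS:
            raise KeyError(f"unknown protected attribute {name!r}")
    total = dist.joint_total(joint)
    idx = {"sex": 1, "race": 2, "age_group": 3}
    matching = sum(
        v
        for k, v in dist.entries.items()
        if k[0] is joint and all(k[idx[name]] == level for name, level in where.items())
    )
    return 100.0 * matching / total


def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer split sizes by floor + largest-remainder; ties favor earlier splits."""
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(x)) for x in raw]
    remainders = [x - s for x, s in zip(raw, sizes)]
    leftover = n - sum(sizes)
    # sort by (descending remainder, ascending position): train > val > test on ties
    order = sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))
    for i in order[:leftover]:
        sizes[i] += 1
    return sizes


def _stratum_key(record: CohortRecord, stratify_by: Sequence[str]) -> tuple[str, ...]:
    parts: list[str] = []
    for name in stratify_by:
        if name == "joint":
            parts.append(record.joint.value)
        elif name in ATTRIBUTE_LEVELS:
            parts.append(record.attributes.level(name).value)
        else:
            raise KeyError(f"unknown stratification key {name!r}")
    return tuple(parts)


def assign_splits(
    records: Sequence[CohortRecord],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    stratify_by: Sequence[str] = (),
) -> list[CohortRecord]:
    """Assign train/val/test splits, stratified by the given keys.

    Within each stratum, split sizes follow floor(fraction*n) with
    largest-remainder allocation of leftovers (ties: train > val > test).
    Deterministic given ``seed`` and independent of input ordering (records
    are ordered by patient_id within each stratum before the seeded shuffle).
    A stratum with fewer records than splits is assigned entirely to train,
    with a warning.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    for r in records:
        if r.split is not Split.unassigned:
            raise ValueError(f"record {r.patient_id!r} already assigned to {r.split.value!r}")

    strata: dict[tuple[str, ...], list[CohortRecord]] = {}
    for r in records:
        strata.setdefault(_stratum_key(r, stratify_by), []).append(r)

    assignment: dict[str, Split] = {}
    splits = (Split.train, Split.val, Split.test)
    for key in sorted(strata):
        members = sorted(strata[key], key=lambda r: r.patient_id)
        if len(members) < len(splits):
            logger.warning(
                "stratum %s has %d record(s) < %d splits; assigning all to train",
                key, len(members), len(splits),
            )
            for r in members:
                assignment[r.patient_id] = Split.train
            continue
        # stable per-stratum stream: crc32 of the key keeps this input-order invariant
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, zlib.crc32("/".join(key).encode())])
        )
        perm = rng.permutation(len(members))
        sizes = _largest_remainder_sizes(len(members), fractions)
        bounds = np.cumsum([0] + sizes)
        for split, lo, hi in zip(splits, bounds[:-1], bounds[1:]):
            for i in perm[lo:hi]:
                assignment[members[i].patient_id] = split
    return [replace(r, split=assignment[r.patient_id]) for r in records]


def group_levels(records: Iterable[CohortRecord], attribute: str) -> list[enum.Enum]:
    """Levels of ``attribute`` present in the records, in enum declaration order."""
    if attribute not in ATTRIBUTE_LEVELS:
        raise KeyError(f"unknown protected attribute {attribute!r}")
    present = {r.attributes.level(attribute) for r in records}
    return [level for level in ATTRIBUTE_LEVELS[attribute] if level in present]
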