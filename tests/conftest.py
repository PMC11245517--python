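"""Shared fixtures: tiny phantom cohorts and records, generated in memory."""

from __future__ import annotations

import pytest

from fairseg.cohort import (
    AgeGroup,
    CohortRecord,
    GroupDistribution,
    Joint,
    ProtectedAttributes,
    Race,
    Sex,
    Split,
)
from fairseg.phantom import PhenotypeParams, render_cohort


def make_record(pid="p0", joint=Joint.knee, sex=Sex.male,
                race=Race.white_caucasian, age=AgeGroup.age_51_64,
                split=Split.unassigned) -> CohortRecord:
    return CohortRecord(
        patient_id=pid, joint=joint,
        attributes=ProtectedAttributes(sex=sex, race=race, age_group=age),
        split=split,
    )


def make_records(n, joint=Joint.knee, races=None, sexes=None, split=Split.unassigned):
    races = races or [Race.white_caucasian]
    sexes = sexes or [Sex.male]
    return [
        make_record(pid=f"p{i:03d}", joint=joint, race=races[i % len(races)],
                    sex=sexes[i % len(sexes)], split=split)
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def tiny_knee_cohort():
    """12 knee phantoms (32x32, both sexes/races) with in-memory pixel data."""
    entries = {}
    for sex in Sex:
        for race in Race:
            entries[(Joint.knee, sex, race, AgeGroup.age_51_64)] = 3
    dist = GroupDistribution(entries, mode="counts")
    params = PhenotypeParams(image_size=32)
    samples = render_cohort(dist, params, seed=99)
    data = {s.record.patient_id: (s.image, s.mask) for s in samples}
    return samples, data


@pytest.fixture(scope="session")
def knee_sample():
    """One deterministic 64x64 knee phantom."""
    rec = make_record("k0")
    from fairseg.phantom import render_radiograph

    return render_radiograph(rec, PhenotypeParams(image_size=64), render_seed=42)
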