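"""Deterministic hip/knee phantom radiographs with ground-truth masks.

The generator emulates the anatomical group structure that motivates fairness
auditing of bony-anatomy segmentation -- wider female pelvic/condylar geometry,
race-linked bone-intensity offsets, age-related joint-space narrowing -- as
parametric 2-D shapes on a square canvas, not as anatomically realistic
radiographs.  A controllable bias coefficient ``delta`` lowers the
bone/background contrast (hence the contrast-to-noise ratio) of one designated
disadvantaged group, making group-conditional difficulty, and therefore
measurable segmentation bias, an explicit knob.

Knee scenes contain a distal femur (shaft + condylar ellipse), a proximal
tibia (plateau + shaft) separated by an age-dependent joint space, and a
patellar ellipse; labels are {0 background, 1 femur, 2 tibia, 3 patella}.
Hip scenes contain a pelvic acetabular cup with an iliac column and a
proximal femur (head, neck capsule, shaft); labels are {0 background,
1 pelvis, 2 femur}.  All geometry is defined on a 128-pixel reference canvas
and scaled with ``image_size``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .cohort import (
    AgeGroup,
    CohortRecord,
    GroupDistribution,
    Joint,
    ProtectedAttributes,
    Race,
    Sex,
    write_manifest,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeParams",
    "SyntheticSample",
    "LABEL_SETS",
    "KNEE_LABELS",
    "HIP_LABELS",
    "render_radiograph",
    "render_cohort",
    "generate_cohort",
    "inject_rater_noise",
    "calibrate_rater_noise",
    "structure_intensities",
]

KNEE_LABELS = {"background": 0, "femur": 1, "tibia": 2, "patella": 3}
HIP_LABELS = {"background": 0, "pelvis": 1, "femur": 2}
LABEL_SETS = {Joint.knee: frozenset(KNEE_LABELS.values()),
              Joint.hip: frozenset(HIP_LABELS.values())}

_REF = 128.0  # reference canvas size for all geometry constants


@dataclass
class PhenotypeParams:
    """Phantom-generator knobs.

    Parameters
    ----------
    joint:
        Informational default joint; rendering always follows the record's
        own joint so mixed hip+knee cohorts can be generated in one call.
    image_size:
        Square canvas edge in pixels (>= 32).
    sex_width_factor:
        Multiplier on pelvis/condyle width per sex (female pelvises are
        wider than male ones).
    race_contrast_offset:
        Additive bone/background contrast offset per race level, emulating
        group differences in bone density (default 0 for both).
    age_joint_space:
        Joint-space gap in reference-canvas pixels per age level, narrowing
        with age as in degenerative joint disease.
    noise_sigma:
        SD of additive Gaussian intensity noise (intensity units, image
        dynamic range is [0, 1]).
    bias_delta:
        delta >= 0; a contrast-to-noise penalty on the disadvantaged group:
        its bone/background contrast is multiplied by ``1 - delta`` (floored
        just above 0) while the noise level is shared by all groups, so its
        CNR is a factor (1 - delta) of everyone else's.  The penalty keeps
        the disadvantaged images clean but faint -- a regime a segmenter can
        learn given enough exposure -- and never touches ground-truth masks.
    disadvantaged_group:
        ``(attribute_name, level)`` receiving the delta penalty.
    jitter:
        Relative per-sample geometric jitter (positions/sizes), keeping the
        cohort from being literally identical images.
    """

    joint: Joint | None = None
    image_size: int = 128
    sex_width_factor: dict[Sex, float] = field(
        default_factory=lambda: {Sex.male: 1.0, Sex.female: 1.15})
    race_contrast_offset: dict[Race, float] = field(
        default_factory=lambda: {Race.white_caucasian: 0.0,
                                 Race.black_african_american: 0.0})
    age_joint_space: dict[AgeGroup, float] = field(
        default_factory=lambda: {AgeGroup.age_le_50: 7.0,
                                 AgeGroup.age_51_64: 5.0,
                                 AgeGroup.age_65_79: 3.0})
    noise_sigma: float = 0.08
    bias_delta: float = 0.0
    disadvantaged_group: tuple[str, object] = ("race", Race.black_african_american)
    background: float = 0.15
    bone_contrast: float = 0.45
    jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.bias_delta < 0:
            raise ValueError("bias_delta must be >= 0")
        if any(v <= 0 for v in self.sex_width_factor.values()):
            raise ValueError("sex width factors must be > 0")


@dataclass
class SyntheticSample:
    """A rendered phantom: image in [0,1], integer mask, record, render seed."""

    image: np.ndarray
    mask: np.ndarray
    record: CohortRecord
    render_seed: int

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask dimensions differ")
        if not set(np.unique(self.mask)) <= set(LABEL_SETS[self.record.joint]):
            raise ValueError("mask labels outside the joint's label set")


# per-structure brightness multipliers on the bone contrast
_STRUCT_FACTOR = {
    "femur": 1.00,
    "tibia": 0.92,
    "patella": 1.25,
    "pelvis": 0.88,
    "head": 1.00,
}


def _grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    y, x = np.mgrid[0:n, 0:n]
    return y.astype(np.float64), x.astype(np.float64)


def _ellipse(y, x, cy, cx, ry, rx):
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0


def _rect(y, x, y0, y1, x0, x1):
    return (y >= y0) & (y <= y1) & (x >= x0) & (x <= x1)


def _capsule(y, x, p0, p1, r):
    """Pixels within distance r of the segment p0-p1 (a thick bone 'neck')."""
    (y0, x0), (y1, x1) = p0, p1
    vy, vx = y1 - y0, x1 - x0
    den = vy * vy + vx * vx
    t = np.clip(((y - y0) * vy + (x - x0) * vx) / den, 0.0, 1.0)
    return (y - (y0 + t * vy)) ** 2 + (x - (x0 + t * vx)) ** 2 <= r * r


def _make_jitter(rng, jitter: float, n: int):
    """Memoized per-structure jitter draws.

    ``*_size`` names are relative size perturbations (SD = jitter); all other
    names are pixel offsets (SD = jitter*n for the global shift, 0.6 of that
    per structure).  Draws are truncated at +/-1.5 SD so extreme tails cannot
    collide neighboring structures into each other.
    """
    cache: dict[str, object] = {}

    def trunc_normal(scale, k):
        return np.clip(rng.normal(0.0, scale, size=k), -1.5 * scale, 1.5 * scale)

    def jit(name: str, k: int = 1):
        if name not in cache:
            if name.endswith("_size"):
                cache[name] = float(trunc_normal(jitter, 1)[0])
            else:
                scale = jitter * n * (1.0 if name == "global_shift" else 0.6)
                vals = trunc_normal(scale, k)
                cache[name] = vals if k > 1 else float(vals[0])
        return cache[name]

    return jit


def _is_disadvantaged(record: CohortRecord, params: PhenotypeParams) -> bool:
    attr, level = params.disadvantaged_group
    return record.attributes.level(attr) == level


def structure_intensities(record: CohortRecord, params: PhenotypeParams) -> dict[str, float]:
    """Noise-free intensity of each structure (and background) for a record."""
    contrast = params.bone_contrast + params.race_contrast_offset[record.attributes.race]
    if params.bias_delta > 0 and _is_disadvantaged(record, params):
        contrast *= max(1.0 - params.bias_delta, 0.02)
    names = KNEE_LABELS if record.joint is Joint.knee else HIP_LABELS
    out = {"background": params.background}
    for name in names:
        if name != "background":
            out[name] = params.background + contrast * _STRUCT_FACTOR[name]
    return out




def _render_knee(y, x, s, w, gap, jit):
    """Rasterize knee structures; jit supplies per-structure geometric jitter."""
    dy, dx = jit("global_shift", 2)
    cx = 64.0 * s + dx
    size = 1.0 + jit("femur_size")
    shaft_w = 11.0 * w * s * size
    condyle_y = 46.0 * s + dy
    femur = _rect(y, x, -1, condyle_y, cx - shaft_w + jit("femur_dx"),
                  cx + shaft_w + jit("femur_dx"))
    femur |= _ellipse(y, x, condyle_y, cx + jit("femur_dx"),
                      10.0 * s * size, 17.0 * w * s * size)
    femur_bottom = condyle_y + 10.0 * s * size
    tib_top = femur_bottom + gap
    tsize = 1.0 + jit("tibia_size")
    tdx = jit("tibia_dx")
    plateau_cy = tib_top + 8.0 * s * tsize
    tibia = _ellipse(y, x, plateau_cy, cx + tdx, 8.0 * s * tsize,
                     19.0 * w * s * tsize)
    tibia |= _rect(y, x, plateau_cy, y.shape[0] + 1.0,
                   cx + tdx - 10.0 * w * s * tsize, cx + tdx + 10.0 * w * s * tsize)
    tibia &= ~femur
    psize = 1.0 + jit("patella_size")
    patella = _ellipse(y, x, 38.0 * s + dy + jit("patella_dy"),
                       cx - 29.0 * w * s + jit("patella_dx"),
                       14.0 * s * psize, 8.0 * s * psize)
    extent = cx + abs(tdx) + 19.0 * w * s * tsize  # widest structure: plateau
    return {"femur": femur, "tibia": tibia, "patella": patella}, extent


def _render_hip(y, x, s, w, gap, jit):
    dy, dx = jit("global_shift", 2)
    size = 1.0 + jit("femur_size")
    hy, hx = 54.0 * s + dy, 60.0 * s + dx
    r_head = 12.0 * s * size
    cup_in = r_head + gap
    cup_out = cup_in + 9.0 * s * size
    # acetabular cup: upper-half elliptical annulus, widened by the sex factor
    rho_out = ((x - hx) / (cup_out * w)) ** 2 + ((y - hy) / cup_out) ** 2
    rho_in = ((x - hx) / (cup_in * w)) ** 2 + ((y - hy) / cup_in) ** 2
    cup = (rho_out <= 1.0) & (rho_in > 1.0) & (y <= hy)
    ilium = _rect(y, x, -1, hy - cup_in - 2.0 * s,
                  hx - 10.0 * w * s, hx + 6.0 * w * s)
    pelvis = cup | ilium
    head = _ellipse(y, x, hy, hx, r_head, r_head)
    shaft_top = (hy + 26.0 * s, hx + 20.0 * s)
    neck = _capsule(y, x, (hy, hx), shaft_top, 6.0 * s * size)
    shaft = _rect(y, x, shaft_top[0], y.shape[0] + 1.0,
                  shaft_top[1] - 7.0 * s * size, shaft_top[1] + 7.0 * s * size)
    femur = head | neck | shaft
    extent = hx + cup_out * w
    return {"pelvis": pelvis & ~femur, "femur": femur}, extent


def render_radiograph(
    record: CohortRecord, params: PhenotypeParams, render_seed: int
) -> SyntheticSample:
    """Render one phantom radiograph and its exact ground-truth mask."""
    n = params.image_size
    s = n / _REF
    rng = np.random.default_rng(render_seed)
    jit = _make_jitter(rng, params.jitter, n)
    y, x = _grid(n)
    w = params.sex_width_factor[record.attributes.sex]
    gap = params.age_joint_space[record.attributes.age_group] * s

    if record.joint is Joint.knee:
        shapes, extent = _render_knee(y, x, s, w, gap, jit)
        labels = KNEE_LABELS
    else:
        shapes, extent = _render_hip(y, x, s, w, gap, jit)
        labels = HIP_LABELS
    if extent >= n - 1:
        min_size = int(np.ceil(extent / (n - 1) * n)) + 2
        raise ValueError(
            f"scaled anatomy (extent {extent:.1f}px) exceeds the {n}px canvas; "
            f"use image_size >= {min_size}"
        )

    intensity = structure_intensities(record, params)
    image = np.full((n, n), intensity["background"], dtype=np.float64)
    mask = np.zeros((n, n), dtype=np.uint8)
    for name, shape_mask in shapes.items():  # later structures overwrite earlier
        image[shape_mask] = intensity[name]
        mask[shape_mask] = labels[name]
    if params.noise_sigma > 0:
        image += rng.normal(0.0, params.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return SyntheticSample(image=image, mask=mask, record=record,
                           render_seed=render_seed)


def _render_seed_for(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def render_cohort(
    dist: GroupDistribution,
    params: PhenotypeParams,
    seed: int,
    path_for=None,
) -> list[SyntheticSample]:
    """Render one phantom per cohort entry, in memory.

    Entries are expanded in a canonical sorted order, so patient ids, render
    seeds, and pixels are deterministic functions of (dist, params, seed).
    ``path_for`` optionally maps a patient id to (image_path, mask_path)
    strings recorded in the manifest entries.
    """
    if dist.mode != "counts":
        raise ValueError("cohort rendering needs a counts-mode distribution")
    if dist.total() <= 0:
        raise ValueError("distribution has zero total count")
    samples: list[SyntheticSample] = []
    index = 0
    for key in sorted(dist.entries, key=lambda k: tuple(m.value for m in k)):
        joint, sex, race, age = key
        for _ in range(int(dist.entries[key])):
            pid = f"{joint.value}_{index:05d}"
            image_path, mask_path = path_for(pid) if path_for else ("", "")
            rec = CohortRecord(
                patient_id=pid,
                joint=joint,
                attributes=ProtectedAttributes(sex=sex, race=race, age_group=age),
                image_path=image_path,
                mask_path=mask_path,
            )
            samples.append(
                render_radiograph(rec, params, _render_seed_for(seed, index)))
            index += 1
    return samples


def generate_cohort(
    dist: GroupDistribution,
    params: PhenotypeParams,
    seed: int,
    out_dir: str | Path,
) -> list[CohortRecord]:
    """Render one phantom per cohort entry; write PNGs and a manifest CSV."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    def path_for(pid: str) -> tuple[str, str]:
        return (str(out_dir / "images" / f"{pid}.png"),
                str(out_dir / "masks" / f"{pid}.png"))

    samples = render_cohort(dist, params, seed, path_for=path_for)
    for sample in samples:
        Image.fromarray(
            np.round(sample.image * 255).astype(np.uint8)
        ).save(sample.record.image_path)
        Image.fromarray(sample.mask).save(sample.record.mask_path)
    records = [s.record for s in samples]
    write_manifest(records, out_dir / "manifest.csv")
    logger.info("generated %d phantom radiographs under %s", len(records), out_dir)
    return records


def inject_rater_noise(mask: np.ndarray, dilation_px: int, seed: int = 0) -> np.ndarray:
    """Perturb mask boundaries to emulate inter-rater annotation disagreement.

    Each foreground class is independently dilated or eroded (seeded coin
    flip) by ``dilation_px`` iterations of a 4-connected structuring element;
    the perturbed classes are re-painted in ascending label order.  With a
    fixed seed the perturbed regions are nested across ``dilation_px``, so
    IoU with the original decreases monotonically; 0 px is the identity.
    """
    if dilation_px < 0:
        raise ValueError("dilation_px must be >= 0")
    labels = [int(c) for c in np.unique(mask) if c != 0]
    rng = np.random.default_rng(seed)
    grow = {c: bool(rng.integers(0, 2)) for c in labels}  # drawn before any morphology
    if dilation_px == 0:
        return mask.copy()
    out = np.zeros_like(mask)
    for c in labels:
        binary = mask == c
        op = ndimage.binary_dilation if grow[c] else ndimage.binary_erosion
        out[op(binary, iterations=dilation_px)] = c
    return out


def calibrate_rater_noise(
    masks: list[np.ndarray],
    target_iou: float,
    grid: range = range(0, 5),
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Grid-search ``dilation_px`` so mean original-vs-perturbed IoU matches a target.

    Returns the best dilation and the mean image IoU achieved at each grid
    point (useful for matching a published inter-rater agreement level).
    """
    from .metrics import MaskPair, image_score

    means: dict[int, float] = {}
    for px in grid:
        scores = [
            image_score(MaskPair(inject_rater_noise(m, px, seed=seed + i), m), "iou")
            for i, m in enumerate(masks)
        ]
        means[px] = float(np.mean(scores))
    best = min(means, key=lambda px: abs(means[px] - target_iou))
    return best, means
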