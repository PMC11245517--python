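"""One-sided significance testing of fairness improvement (SER vs. baseline).

A single audit yields one SER value per model; to test whether a mitigation
strategy's SER is significantly below the baseline's, replicate SER values are
generated by a within-group bootstrap over test images: each replicate
resamples images with replacement inside every protected-group level,
recomputes the level mean errors, and takes their max/min ratio.  The two
replicate samples are then compared with a one-sided Welch (unequal-variance)
t-test of

    H0: SER_baseline = SER_candidate   vs.   H1: SER_baseline > SER_candidate

at significance level alpha (default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["SerSample", "bootstrap_ser", "ser_t_test", "reject_null"]


@dataclass(frozen=True)
class SerSample:
    """Bootstrap replicate SER values for one model."""

    model_id: str
    values: np.ndarray  # shape (B,), all >= 1
    seed: int

    @property
    def B(self) -> int:
        return int(self.values.shape[0])

    def __post_init__(self) -> None:
        if self.values.ndim != 1 or self.values.shape[0] < 2:
            raise ValueError("a SerSample needs at least B=2 replicates")
        if np.any(self.values < 1.0 - 1e-12):
            raise ValueError("SER replicates must all be >= 1")


def bootstrap_ser(
    scores_by_level: Mapping[str, Sequence[float]],
    B: int = 1000,
    seed: int = 0,
    model_id: str = "model",
) -> SerSample:
    """Within-group bootstrap of the skewed error ratio.

    ``scores_by_level`` maps each protected-group level to its per-image
    scores (IoU or Dice).  Each of the B replicates resamples images with
    replacement within every level, recomputes the level mean errors
    ``1 - score``, and forms SER = max/min.  Replicates in which one level's
    resampled error is exactly 0 while another's is not are discarded and
    redrawn (the ratio would be infinite); all-zero-error replicates give 1.0.
    """
    levels = list(scores_by_level)
    if len(levels) < 2:
        raise ValueError("bootstrap_ser requires at least two group levels")
    errors = {lvl: 1.0 - np.asarray(scores_by_level[lvl], dtype=float)
              for lvl in levels}
    for lvl, e in errors.items():
        if e.shape[0] < 2:
            raise ValueError(f"level {lvl!r} has fewer than 2 images")

    rng = np.random.default_rng(seed)
    # vectorized draw: (B, n_level) index matrix per level -> replicate means
    means = np.empty((B, len(levels)))
    for j, lvl in enumerate(levels):
        e = errors[lvl]
        idx = rng.integers(0, e.shape[0], size=(B, e.shape[0]))
        means[:, j] = e[idx].mean(axis=1)

    hi = means.max(axis=1)
    lo = means.min(axis=1)
    ser = np.ones(B)
    ok = lo > 0
    ser[ok] = hi[ok] / lo[ok]
    bad = (~ok) & (hi > 0)  # one level at zero error, another above
    n_redrawn = 0
    while np.any(bad):
        n_redrawn += int(bad.sum())
        redraw = np.empty((int(bad.sum()), len(levels)))
        for j, lvl in enumerate(levels):
            e = errors[lvl]
            idx = rng.integers(0, e.shape[0], size=(int(bad.sum()), e.shape[0]))
            redraw[:, j] = e[idx].mean(axis=1)
        hi_r, lo_r = redraw.max(axis=1), redraw.min(axis=1)
        pos = np.flatnonzero(bad)
        fine = lo_r > 0
        ser[pos[fine]] = hi_r[fine] / lo_r[fine]
        zero = (lo_r == 0) & (hi_r == 0)
        ser[pos[zero]] = 1.0
        bad = np.zeros(B, dtype=bool)
        bad[pos[~fine & ~zero]] = True
    if n_redrawn:
        logger.info("bootstrap_ser: redrew %d degenerate replicate(s)", n_redrawn)
    return SerSample(model_id=model_id, values=ser, seed=seed)


def ser_t_test(
    baseline: SerSample,
    candidate: SerSample,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """One-sided Welch t-test of H1: mean SER_baseline > mean SER_candidate.

    Returns ``(p_value, reject)`` with ``reject = p < alpha``.  The degenerate
    zero-variance, equal-mean case is defined as p = 1.0 (no evidence).
    """
    if baseline.B != candidate.B:
        raise ValueError(
            f"replicate counts differ: baseline B={baseline.B}, candidate B={candidate.B}"
        )
    a, b = baseline.values, candidate.values
    if np.array_equal(a, b):
        p = 1.0  # identical replicate vectors carry no evidence against H0
    elif np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if np.mean(a) <= np.mean(b) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False, alternative="greater").pvalue)
    return p, reject_null(p, alpha)


def reject_null(p_value: float, alpha: float = 0.05) -> bool:
    """Decision rule: reject H0 iff p < alpha."""
    if not (0 <= p_value <= 1):
        raise ValueError(f"p-value {p_value} outside [0, 1]")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    return p_value < alpha
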