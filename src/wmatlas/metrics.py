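"""Atlas validation measurements.

* probability-weighted tract FA: FA = sum_i FA_i * P_i / sum_i P_i
* plain masked mean FA (the subject-specific "gold standard")
* slice-wise FA profiles along a tract's major axis
* Dice overlap and Dice-vs-threshold curves against subject tracts
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas_build import ProbabilityMap, ScalarVolume, threshold_map
from .streamline_core import BinaryMask

__all__ = [
    "UndefinedTractError",
    "SliceProfile",
    "DiceCurve",
    "weighted_fa",
    "mean_fa_in_mask",
    "slice_profile",
    "dice",
    "dice_curve",
    "DEFAULT_THRESHOLDS",
]

#: default probability threshold sweep for Dice curves
DEFAULT_THRESHOLDS = np.round(np.arange(0.05, 1.0 + 1e-9, 0.05), 2)

_AXIS_INDEX = {"coronal": 1, "axial": 2}  # slices perpendicular to y / z


class UndefinedTractError(ValueError):
    """Raised when a tract region is empty where a mean is required."""


@dataclass
class SliceProfile:
    """Per-slice mean FA along a tract's major axis.

    ``source`` records whether values are subject-specific mask means or
    probability-weighted atlas means; slices without tract support are
    omitted, so ``slices`` is strictly increasing but not necessarily
    contiguous.
    """

    tract: str
    axis: str
    slices: np.ndarray
    values: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.slices.size != self.values.size:
            raise ValueError("slice/value length mismatch")
        if self.slices.size and np.any(np.diff(self.slices) <= 0):
            raise ValueError("slice indices must be strictly increasing")


@dataclass
class DiceCurve:
    thresholds: np.ndarray
    scores: np.ndarray
    peak: float = field(init=False)

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.thresholds.size != self.scores.size or self.thresholds.size == 0:
            raise ValueError("threshold/score length mismatch")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be increasing")
        self.peak = float(self.scores.max())


def _check_same_grid(a, b) -> None:
    if not a.grid.same_as(b.grid):
        raise ValueError("inputs must share one grid")


def weighted_fa(fa: ScalarVolume, p: ProbabilityMap) -> float:
    """Probability-weighted mean FA over the map's support."""
    _check_same_grid(fa, p)
    wsum = float(p.values.sum())
    if wsum <= 0.0:
        raise UndefinedTractError("probability map has zero total weight")
    return float((fa.values * p.values).sum() / wsum)


def mean_fa_in_mask(fa: ScalarVolume, m: BinaryMask) -> float:
    """Arithmetic mean FA over on-voxels."""
    _check_same_grid(fa, m)
    if m.count == 0:
        raise UndefinedTractError("mask is empty")
    return float(fa.values[m.values].mean())


def slice_profile(fa: ScalarVolume, tract: "ProbabilityMap | BinaryMask",
                  axis: str, name: str = "") -> SliceProfile:
    """Mean FA per slice perpendicular to the major axis.

    For a binary mask the value is the in-slice masked mean; for a
    probability map it is the probability-weighted mean restricted to the
    slice. Slices with no support are omitted.
    """
    _check_same_grid(fa, tract)
    try:
        ax = _AXIS_INDEX[axis]
    except KeyError:
        raise ValueError(f"axis must be coronal|axial, got {axis!r}") from None
    if isinstance(tract, BinaryMask):
        w = tract.values.astype(float)
        source = "subject_specific"
    else:
        w = tract.values
        source = "atlas_weighted"
    sum_axes = tuple(i for i in range(3) if i != ax)
    wsum = w.sum(axis=sum_axes)
    fsum = (fa.values * w).sum(axis=sum_axes)
    keep = wsum > 0.0
    if not keep.any():
        raise UndefinedTractError("tract has no support in any slice")
    idx = np.nonzero(keep)[0]
    return SliceProfile(tract=name, axis=axis, slices=idx,
                        values=fsum[keep] / wsum[keep], source=source)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|a & b| / (|a| + |b|); undefined when both are empty."""
    _check_same_grid(a, b)
    na, nb = a.count, b.count
    if na + nb == 0:
        raise UndefinedTractError("Dice undefined for two empty masks")
    inter = int(np.logical_and(a.values, b.values).sum())
    return 2.0 * inter / (na + nb)


def dice_curve(p: ProbabilityMap, subject_tract: BinaryMask,
               thresholds: np.ndarray = DEFAULT_THRESHOLDS) -> DiceCurve:
    """Dice of {P >= theta} against the subject mask over a threshold sweep.

    A threshold emptying the atlas while the subject mask is non-empty scores
    0 rather than raising.
    """
    _check_same_grid(p, subject_tract)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0 or thresholds.min() <= 0.0 or thresholds.max() > 1.0:
        raise ValueError("thresholds must lie in (0, 1]")
    scores = np.empty_like(thresholds)
    for i, theta in enumerate(thresholds):
        m = threshold_map(p, theta)
        if m.count == 0:
            scores[i] = 0.0 if subject_tract.count > 0 else np.nan
            if subject_tract.count == 0:
                raise UndefinedTractError("both thresholded atlas and subject mask empty")
        else:
            scores[i] = dice(m, subject_tract)
    return DiceCurve(thresholds=thresholds, scores=scores)
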