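"""Group-level atlas construction.

Per-subject binary tract masks, already in a common template space, are
averaged into per-voxel probability maps. Scalar volumes (aDWI, FA) are
averaged voxelwise; diffusion tensor volumes are averaged elementwise
("scalar averaging" of the six independent tensor components) and the
group FA image is computed from the averaged tensor's eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .streamline_core import BinaryMask, VolumeGrid, _check_affine

__all__ = [
    "ProbabilityMap",
    "ScalarVolume",
    "TensorVolume",
    "build_probability_map",
    "average_scalar_volumes",
    "average_tensor_volumes",
    "fa_from_tensor",
    "fa_from_eigenvalues",
    "rigid_part",
    "reorient_tensor_affine",
    "resample_scalar",
    "threshold_map",
    "shift_probability_map",
]

# lower-triangular component order used for 4-D tensor storage
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")
_LT_INDEX = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


@dataclass
class ScalarVolume:
    """Per-voxel scalar field (FA, aDWI, ...) on a grid."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.shape:
            raise ValueError(f"volume shape {vals.shape} != grid {self.grid.shape}")
        self.values = vals


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensor, stored as 6 components
    (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) in the last axis."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (*self.grid.shape, 6):
            raise ValueError(f"tensor shape {vals.shape} != {(*self.grid.shape, 6)}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("tensor components must be finite")
        self.values = vals

    def as_matrices(self) -> np.ndarray:
        """(*shape, 3, 3) symmetric matrices."""
        m = np.empty((*self.grid.shape, 3, 3), dtype=float)
        for k, (i, j) in enumerate(_LT_INDEX):
            m[..., i, j] = self.values[..., k]
            m[..., j, i] = self.values[..., k]
        return m

    @staticmethod
    def from_matrices(grid: VolumeGrid, m: np.ndarray) -> "TensorVolume":
        vals = np.stack([m[..., i, j] for (i, j) in _LT_INDEX], axis=-1)
        return TensorVolume(grid=grid, values=vals)


@dataclass
class ProbabilityMap:
    """Across-subject frequency of binary tract masks; values are k/n_subjects."""

    grid: VolumeGrid
    values: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.shape:
            raise ValueError("probability map shape mismatch")
        if vals.min() < 0.0 or vals.max() > 1.0:
            raise ValueError("probabilities must lie in [0,1]")
        self.values = vals
        self.n_subjects = int(self.n_subjects)

    @property
    def support(self) -> np.ndarray:
        return self.values > 0.0


def _common_grid(items) -> VolumeGrid:
    items = list(items)
    if not items:
        raise ValueError("need at least one volume/mask")
    grid = items[0].grid
    for it in items[1:]:
        if not grid.same_as(it.grid):
            raise ValueError("inputs must share one grid")
    return grid


def build_probability_map(masks: list[BinaryMask]) -> ProbabilityMap:
    """Average binary masks: value(v) = (#masks with v on) / n."""
    grid = _common_grid(masks)
    counts = np.zeros(grid.shape, dtype=np.int64)
    for m in masks:
        counts += m.values
    n = len(masks)
    return ProbabilityMap(grid=grid, values=counts / n, n_subjects=n)


def average_scalar_volumes(vols: list[ScalarVolume]) -> ScalarVolume:
    grid = _common_grid(vols)
    mean = np.mean([v.values for v in vols], axis=0)
    return ScalarVolume(grid=grid, values=mean)


def average_tensor_volumes(vols: list[TensorVolume]) -> TensorVolume:
    grid = _common_grid(vols)
    mean = np.mean([v.values for v in vols], axis=0)
    return TensorVolume(grid=grid, values=mean)


def fa_from_eigenvalues(lam: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam|| over the last axis.

    Zero tensors give FA 0; output clipped to [0,1]. Negative eigenvalues
    (possible after averaging noisy tensors) are clamped to 0 first.
    """
    lam = np.maximum(np.asarray(lam, dtype=float), 0.0)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0.0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def fa_from_tensor(t: TensorVolume) -> ScalarVolume:
    """Fractional anisotropy of each voxel's tensor from its eigenvalues."""
    lam = np.linalg.eigvalsh(t.as_matrices())
    return ScalarVolume(grid=t.grid, values=fa_from_eigenvalues(lam))


def rigid_part(A: np.ndarray) -> np.ndarray:
    """Rotation factor of the polar decomposition of the linear part of A.

    Used to reorient tensors under an affine transform (the rotational part
    of the mapping; shears/scales are discarded), mirroring FSL's vecreg
    behaviour for affine transforms.
    """
    A = _check_affine(A)
    U, _, Vt = np.linalg.svd(A[:3, :3])
    R = U @ Vt
    if np.linalg.det(R) < 0:  # keep a proper rotation
        U[:, -1] *= -1
        R = U @ Vt
    return R


def reorient_tensor_affine(t: TensorVolume, A: np.ndarray) -> TensorVolume:
    """Rotate every voxel tensor by the rigid part of affine A: D' = R D R^T."""
    R = rigid_part(A)
    m = t.as_matrices()
    m2 = np.einsum("ij,...jk,lk->...il", R, m, R)
    return TensorVolume.from_matrices(t.grid, m2)


def resample_scalar(vol: ScalarVolume, xfm: np.ndarray, target: VolumeGrid,
                    order: int = 1, cval: float = 0.0) -> ScalarVolume:
    """Resample a scalar volume through a world-space affine onto a target grid.

    ``xfm`` maps source world coordinates to target world coordinates; output
    voxel j takes the (order-``order`` interpolated) source value at
    ``inv(src.affine) @ inv(xfm) @ target.affine @ j``.
    """
    xfm = _check_affine(xfm)
    M = np.linalg.inv(vol.grid.affine) @ np.linalg.inv(xfm) @ target.affine
    out = ndimage.affine_transform(
        vol.values, M[:3, :3], offset=M[:3, 3], output_shape=target.shape,
        order=order, mode="constant", cval=cval,
    )
    return ScalarVolume(grid=target, values=out)


def threshold_map(p: ProbabilityMap, theta: float) -> BinaryMask:
    """Binary mask {P >= theta}."""
    return BinaryMask(grid=p.grid, values=p.values >= theta)


def shift_probability_map(p: ProbabilityMap, voxel_shift: tuple[int, int, int]) -> ProbabilityMap:
    """Integer-voxel translation of a probability map (zeros shifted in).

    Used to manufacture a deliberately misregistered comparison atlas that
    plays the role the adult atlas plays in the validation: same topology,
    systematically displaced support.
    """
    out = np.zeros_like(p.values)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(voxel_shift):
        n = p.values.shape[ax]
        s = int(s)
        if abs(s) >= n:
            return ProbabilityMap(grid=p.grid, values=out, n_subjects=p.n_subjects)
        if s >= 0:
            dst[ax], src[ax] = slice(s, n), slice(0, n - s)
        else:
            dst[ax], src[ax] = slice(0, n + s), slice(-s, n)
    out[tuple(dst)] = p.values[tuple(src)]
    return ProbabilityMap(grid=p.grid, values=out, n_subjects=p.n_subjects)
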