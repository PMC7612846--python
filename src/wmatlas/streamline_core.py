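"""Streamline geometry: transforms, ROI membership, boolean-query dissection, voxelisation.

Streamlines are ordered polylines in world millimetres (RAS). Virtual
dissection selects the streamlines of a named tract as those passing through
all inclusion regions and no exclusion regions; voxelisation marks every
voxel visited by at least one streamline, yielding the per-subject binary
tract mask that probability maps are built from.

Point-in-voxel convention: a world point belongs to the voxel whose 0-based
index is ``round(inv(affine) @ p)`` (voxel-centre convention). Membership
tests traverse every segment exactly: crossings of the voxel-boundary planes
are computed analytically and the voxel between consecutive crossings is
taken, so the set of visited voxels is independent of the step size the
streamlines were generated with (identical to resampling at an arbitrarily
fine step).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "VolumeGrid",
    "Streamline",
    "Tractogram",
    "BinaryMask",
    "ROIQuery",
    "All",
    "Any",
    "Not",
    "Leaf",
    "TractDefinition",
    "InvalidTransformError",
    "QueryConfigError",
    "apply_affine",
    "streamline_passes",
    "filter_by_query",
    "voxelise",
    "as_streamline",
]

TRACT_NAMES = (
    "ATR", "CG", "CH", "CST", "Fmajor", "Fminor",
    "IFOF", "ILF", "SLF", "SLFt", "UF", "fornix",
)


class InvalidTransformError(ValueError):
    """Raised when an affine is singular or malformed."""


class QueryConfigError(KeyError):
    """Raised when a query leaf does not resolve to a known ROI mask."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel grid with a voxel-index -> world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        A = np.asarray(self.affine, dtype=float)
        if A.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.allclose(A[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("affine last row must be (0,0,0,1)")
        if abs(np.linalg.det(A[:3, :3])) < 1e-12:
            raise InvalidTransformError("grid affine is singular")
        object.__setattr__(self, "shape", shape)
        A = A.copy()
        A.flags.writeable = False
        object.__setattr__(self, "affine", A)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points to 0-based voxel indices (rounded, may be out of bounds)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = self.inverse_affine
        vox = pts @ inv[:3, :3].T + inv[:3, 3]
        return np.rint(vox).astype(np.int64)

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_as(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)


def as_streamline(points: Sequence) -> np.ndarray:
    """Validate a streamline: (N>=2, 3) float array, finite, no repeated consecutive points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("a streamline needs >= 2 points of 3 coordinates")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline coordinates must be finite")
    if np.any(np.all(np.diff(pts, axis=0) == 0.0, axis=1)):
        raise ValueError("consecutive streamline points must be distinct")
    return pts


# A Streamline is represented as an (N, 3) float ndarray; this alias is for
# signatures and documentation.
Streamline = np.ndarray


@dataclass
class Tractogram:
    """A set of streamlines sharing one world space. May be empty."""

    streamlines: list[Streamline] = field(default_factory=list)
    space: str = "world"

    def __post_init__(self) -> None:
        self.streamlines = [as_streamline(s) for s in self.streamlines]

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


@dataclass
class BinaryMask:
    """Boolean voxel mask on a grid."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != self.grid.shape:
            raise ValueError(f"mask shape {vals.shape} != grid shape {self.grid.shape}")
        if vals.dtype != bool:
            uniq = np.unique(vals)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be exactly 0/1")
            vals = vals.astype(bool)
        self.values = vals

    @property
    def count(self) -> int:
        return int(self.values.sum())


# ---------------------------------------------------------------------------
# ROI boolean queries
# ---------------------------------------------------------------------------

class ROIQuery:
    """Base class for boolean expressions over named ROI masks."""

    def evaluate(self, truth: dict[str, bool]) -> bool:
        raise NotImplementedError

    def leaf_names(self) -> set[str]:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    @staticmethod
    def from_dict(d: "dict | str") -> "ROIQuery":
        """Parse the JSON query form: leaves are ROI name strings, nodes are
        single-key dicts among {"all": [...], "any": [...], "not": child}."""
        if isinstance(d, str):
            return Leaf(d)
        if not isinstance(d, dict) or len(d) != 1:
            raise QueryConfigError(f"malformed query node: {d!r}")
        (key, val), = d.items()
        if key == "all":
            return All([ROIQuery.from_dict(c) for c in val])
        if key == "any":
            return Any([ROIQuery.from_dict(c) for c in val])
        if key == "not":
            if isinstance(val, list):
                if len(val) != 1:
                    raise QueryConfigError("'not' wraps exactly one child")
                val = val[0]
            return Not(ROIQuery.from_dict(val))
        raise QueryConfigError(f"unknown query node {key!r}")


@dataclass
class Leaf(ROIQuery):
    name: str

    def evaluate(self, truth: dict[str, bool]) -> bool:
        try:
            return truth[self.name]
        except KeyError as e:
            raise QueryConfigError(f"unresolved ROI name {self.name!r}") from e

    def leaf_names(self) -> set[str]:
        return {self.name}

    def to_dict(self):
        return self.name


@dataclass
class All(ROIQuery):
    children: list[ROIQuery]

    def evaluate(self, truth):
        return all(c.evaluate(truth) for c in self.children)

    def leaf_names(self):
        return set().union(*(c.leaf_names() for c in self.children)) if self.children else set()

    def to_dict(self):
        return {"all": [c.to_dict() for c in self.children]}


@dataclass
class Any(ROIQuery):
    children: list[ROIQuery]

    def evaluate(self, truth):
        return any(c.evaluate(truth) for c in self.children)

    def leaf_names(self):
        return set().union(*(c.leaf_names() for c in self.children)) if self.children else set()

    def to_dict(self):
        return {"any": [c.to_dict() for c in self.children]}


@dataclass
class Not(ROIQuery):
    child: ROIQuery

    def evaluate(self, truth):
        return not self.child.evaluate(truth)

    def leaf_names(self):
        return self.child.leaf_names()

    def to_dict(self):
        return {"not": self.child.to_dict()}


@dataclass
class TractDefinition:
    """A named tract: boolean ROI query plus the slice axis used for profiles.

    ``major_axis`` is "coronal" for tracts projecting anterior/posterior and
    "axial" for tracts projecting dorsal/ventral.
    """

    name: str
    query: ROIQuery
    major_axis: str = "coronal"
    laterality: str = "left"

    def __post_init__(self) -> None:
        if self.major_axis not in ("coronal", "axial"):
            raise ValueError(f"major_axis must be coronal|axial, got {self.major_axis}")
        if self.laterality not in ("left", "right", "commissural"):
            raise ValueError(f"bad laterality {self.laterality!r}")

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "major_axis": self.major_axis,
            "laterality": self.laterality,
            "query": self.query.to_dict(),
        }

    @staticmethod
    def from_json(d: dict) -> "TractDefinition":
        return TractDefinition(
            name=d["name"],
            query=ROIQuery.from_dict(d["query"]),
            major_axis=d.get("major_axis", "coronal"),
            laterality=d.get("laterality", "left"),
        )

    def save(self, path: Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2))

    @staticmethod
    def load(path: Path) -> "TractDefinition":
        return TractDefinition.from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _check_affine(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.shape != (4, 4):
        raise InvalidTransformError("affine must be 4x4")
    if abs(np.linalg.det(A[:3, :3])) < 1e-12:
        raise InvalidTransformError("affine is singular")
    return A


def apply_affine(t: Tractogram, A: np.ndarray) -> Tractogram:
    """Transform every streamline point p to A @ (p, 1); order preserved."""
    A = _check_affine(A)
    R, b = A[:3, :3], A[:3, 3]
    out = [s @ R.T + b for s in t.streamlines]
    return Tractogram(streamlines=out, space=t.space)


def _traverse_voxels(polylines: list[np.ndarray], grid: VolumeGrid
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Exact voxel traversal of polylines.

    Returns (streamline_ids, voxel_indices) for every voxel visited by any
    segment, possibly with duplicates; out-of-grid voxels are NOT filtered
    here. The traversal is exact: segment crossings of the half-integer
    voxel-boundary planes are solved analytically in continuous voxel
    coordinates and the voxel between consecutive crossings is the rounded
    midpoint.
    """
    inv = grid.inverse_affine
    segsA, segsB, seg_sid = [], [], []
    for sid, pts in enumerate(polylines):
        v = pts @ inv[:3, :3].T + inv[:3, 3]
        segsA.append(v[:-1])
        segsB.append(v[1:])
        seg_sid.append(np.full(len(v) - 1, sid))
    A = np.concatenate(segsA)
    B = np.concatenate(segsB)
    sid = np.concatenate(seg_sid)
    D = B - A
    S = len(A)

    ts = [np.zeros(S), np.ones(S)]
    tseg = [np.arange(S), np.arange(S)]
    lo = np.minimum(A, B)
    hi = np.maximum(A, B)
    mlo = np.ceil(lo - 0.5)
    mhi = np.floor(hi - 0.5)
    counts = np.maximum(0, (mhi - mlo + 1)).astype(np.int64)
    counts[D == 0.0] = 0  # grazing a boundary plane exactly: no crossing
    for ax in range(3):
        c = counts[:, ax]
        if c.sum() == 0:
            continue
        seg_idx = np.repeat(np.arange(S), c)
        offs = np.concatenate([np.arange(n) for n in c if n > 0])
        k = mlo[seg_idx, ax] + offs
        t = (k + 0.5 - A[seg_idx, ax]) / D[seg_idx, ax]
        ts.append(t)
        tseg.append(seg_idx)
    t_all = np.concatenate(ts)
    seg_all = np.concatenate(tseg)
    order = np.lexsort((t_all, seg_all))
    t_all, seg_all = t_all[order], seg_all[order]
    same = seg_all[:-1] == seg_all[1:]
    tm = 0.5 * (t_all[:-1] + t_all[1:])[same]
    seg_m = seg_all[:-1][same]
    pts = A[seg_m] + tm[:, None] * D[seg_m]
    vox = np.rint(pts).astype(np.int64)
    return sid[seg_m], vox


def _inbounds(vox: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    shape = np.asarray(grid.shape)
    return np.all((vox >= 0) & (vox < shape), axis=1)


def streamline_passes(s: Streamline, roi: BinaryMask) -> bool:
    """True iff the polyline traverses any on-voxel of the ROI."""
    _, vox = _traverse_voxels([as_streamline(s)], roi.grid)
    ok = _inbounds(vox, roi.grid)
    vox = vox[ok]
    if vox.size == 0:
        return False
    return bool(roi.values[vox[:, 0], vox[:, 1], vox[:, 2]].any())


def _common_grid(masks: Iterable[BinaryMask]) -> VolumeGrid:
    masks = list(masks)
    grid = masks[0].grid
    for m in masks[1:]:
        if not grid.same_as(m.grid):
            raise ValueError("ROI masks must share one grid")
    return grid


def _eval_query_vec(q: ROIQuery, truth: dict[str, np.ndarray]) -> np.ndarray:
    """Evaluate a query over boolean membership vectors (one entry per streamline)."""
    if isinstance(q, Leaf):
        return truth[q.name]
    if isinstance(q, All):
        out = None
        for c in q.children:
            v = _eval_query_vec(c, truth)
            out = v if out is None else out & v
        return out
    if isinstance(q, Any):
        out = None
        for c in q.children:
            v = _eval_query_vec(c, truth)
            out = v if out is None else out | v
        return out
    if isinstance(q, Not):
        return ~_eval_query_vec(q.child, truth)
    raise QueryConfigError(f"unknown query node {type(q).__name__}")


def filter_by_query(t: Tractogram, q: ROIQuery, rois: dict[str, BinaryMask]) -> Tractogram:
    """Keep exactly the streamlines whose ROI membership satisfies the query.

    Leaf truth for a streamline is :func:`streamline_passes` against the named
    mask; membership is computed in one vectorised pass per ROI over the
    resampled points of all streamlines.
    """
    names = q.leaf_names()
    missing = names - set(rois)
    if missing:
        raise QueryConfigError(f"unresolved ROI names: {sorted(missing)}")
    if len(t) == 0:
        return Tractogram(streamlines=[], space=t.space)
    if not names:
        keep = _eval_query_vec(q, {})
        kept = list(t.streamlines) if np.all(keep) else []
        return Tractogram(streamlines=kept, space=t.space)
    grid = _common_grid([rois[n] for n in sorted(names)])
    polylines = [as_streamline(s) for s in t]
    ids, vox = _traverse_voxels(polylines, grid)
    inb = _inbounds(vox, grid)
    vox_in, ids_in = vox[inb], ids[inb]
    truth: dict[str, np.ndarray] = {}
    for name in names:
        on = rois[name].values[vox_in[:, 0], vox_in[:, 1], vox_in[:, 2]]
        truth[name] = np.bincount(ids_in[on], minlength=len(polylines)) > 0
    keep = _eval_query_vec(q, truth)
    kept = [s for s, k in zip(t.streamlines, keep) if k]
    return Tractogram(streamlines=kept, space=t.space)


def voxelise(t: Tractogram, grid: VolumeGrid) -> BinaryMask:
    """Mark every voxel containing at least one sampled streamline position.

    Points mapping outside the grid are dropped. An empty tractogram yields an
    all-zero mask.
    """
    values = np.zeros(grid.shape, dtype=bool)
    if len(t) == 0:
        return BinaryMask(grid=grid, values=values)
    _, vox = _traverse_voxels([as_streamline(s) for s in t], grid)
    vox = vox[_inbounds(vox, grid)]
    if vox.size:
        values[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return BinaryMask(grid=grid, values=values)
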