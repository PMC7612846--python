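"""Synthetic cohorts with analytic ground truth.

Tracts are tubes around parametric 3D curves (lines, quadratic arcs, and one
Y-shaped tract with a body and two posterior limbs, mirroring the fornix
dissection protocol). Each tract carries a deterministic "canonical" bundle
of streamlines covering its tube; subjects are produced by applying a random
affine jitter (rotation, isotropic scale, translation) to the template
geometry, painting an FA field with known per-tract means plus Gaussian
noise, and constructing an axially symmetric diffusion tensor field whose
per-voxel FA matches the painted field exactly. The inverse of the jitter is
stored as the subject-to-template transform; a small optional residual
affine, not captured by the stored transform, emulates registration error.

Because bundle geometry is deterministic given the template, a cohort of
noiseless, identity-transform subjects reproduces the template occupancy
exactly when averaged — the ground truth every atlas-recovery test leans on.

Default cohort sizes follow the study design the generator emulates:
28 atlas + 8 validation controls (the 36 controls together forming the
control group) and 33 cases, with a -0.03 FA case effect on four designated
tracts.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atlas_build import ProbabilityMap, ScalarVolume, TensorVolume, rigid_part
from .streamline_core import (
    All, Any, BinaryMask, Leaf, Not, ROIQuery, TractDefinition, Tractogram,
    VolumeGrid, apply_affine,
)

__all__ = [
    "TractSpec",
    "CohortSpec",
    "TractGroundTruth",
    "Template",
    "SubjectData",
    "default_tracts",
    "make_template",
    "make_subject",
    "make_cohort",
    "sample_fa_table",
    "tensor_from_fa_direction",
    "sphere_mask",
]

_DEFAULT_CASE_EFFECT = {"CG": -0.03, "CH": -0.03, "SLF": -0.03, "fornix": -0.03}


# ---------------------------------------------------------------------------
# Curve primitives
# ---------------------------------------------------------------------------

def _eval_prim(prim, t: np.ndarray) -> np.ndarray:
    kind = prim[0]
    if kind == "line":
        p0, p1 = (np.asarray(p, float) for p in prim[1:])
        return p0 + t[:, None] * (p1 - p0)
    if kind == "bez":
        p0, p1, p2 = (np.asarray(p, float) for p in prim[1:])
        u = (1 - t)[:, None]
        v = t[:, None]
        return u * u * p0 + 2 * u * v * p1 + v * v * p2
    raise ValueError(f"unknown primitive {kind!r}")


def _sample_leg(leg, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample a leg (sequence of primitives) at ~step mm; returns points and
    unit tangents."""
    pts = []
    for prim in leg:
        rough = _eval_prim(prim, np.linspace(0, 1, 33))
        length = np.linalg.norm(np.diff(rough, axis=0), axis=1).sum()
        n = max(8, int(np.ceil(length / step)))
        pts.append(_eval_prim(prim, np.linspace(0, 1, n + 1)))
    points = np.concatenate(pts, axis=0)
    # drop consecutive duplicates at primitive joints
    keep = np.r_[True, np.linalg.norm(np.diff(points, axis=0), axis=1) > 1e-9]
    points = points[keep]
    tang = np.gradient(points, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return points, tang


def _leg_point(leg, t: float) -> np.ndarray:
    """Point at fraction t of a leg's arc length."""
    pts, _ = _sample_leg(leg, 0.5)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.r_[0.0, np.cumsum(seg)]
    target = t * cum[-1]
    i = int(np.searchsorted(cum, target))
    return pts[min(i, len(pts) - 1)]


def _frames(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit normals per point, orthogonal to the tangent, varying smoothly
    for near-straight legs (reference-vector construction)."""
    ref = np.zeros_like(tangents)
    ref[np.arange(len(tangents)), np.argmin(np.abs(tangents), axis=1)] = 1.0
    n1 = np.cross(ref, tangents)
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tangents, n1)
    return n1, n2


_RING_RADII = (0.0, 0.5, 0.9)
_RING_COUNTS = (1, 6, 12)


def _canonical_offsets(radius: float) -> np.ndarray:
    """Deterministic disc covering: centre + two rings (19 offsets)."""
    offs = []
    for frac, cnt in zip(_RING_RADII, _RING_COUNTS):
        if frac == 0.0:
            offs.append(np.zeros((1, 2)))
        else:
            ang = 2 * np.pi * np.arange(cnt) / cnt
            offs.append(frac * radius * np.c_[np.cos(ang), np.sin(ang)])
    return np.concatenate(offs, axis=0)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class TractSpec:
    """One synthetic tract: tube legs, radius, true mean FA, ROI protocol."""

    name: str
    legs: list            # list of legs; a leg is a list of curve primitives
    radius: float
    mean_fa: float
    major_axis: str
    laterality: str = "left"
    y_shaped: bool = False          # body + two limbs, fornix-style query
    exclusion_centre: tuple | None = None  # optional exclusion ROI location


def default_tracts() -> list[TractSpec]:
    """Twelve named tracts laid out in an 88 x 80 x 80 mm box.

    The layout keeps every tract that carries a case effect at >= 14 mm
    centreline distance from every other tract, so painted FA regions and
    atlas supports stay disjoint even under affine jitter, residual
    registration error and interpolation smoothing — cross-talk between a
    designated tract's FA offset and a neighbour's measurement would
    otherwise contaminate the group comparison."""
    def lane_y(x, z, bulge_z=0.0):
        if bulge_z == 0.0:
            return [[("line", (x, 12, z), (x, 68, z))]]
        return [[("bez", (x, 12, z), (x, 40, z + 2 * bulge_z), (x, 68, z))]]

    def lane_x(y, z, bulge_y=0.0):
        if bulge_y == 0.0:
            return [[("line", (12, y, z), (56, y, z))]]
        return [[("bez", (12, y, z), (34, y + 2 * bulge_y, z), (56, y, z))]]

    fornix_body = ("line", (80, 56, 72), (80, 56, 44))
    limb_a = ("bez", (80, 56, 44), (80, 52, 30), (80, 40, 22))
    limb_b = ("bez", (80, 56, 44), (80, 60, 30), (80, 72, 22))

    return [
        TractSpec("ATR", lane_y(8, 12), 3.0, 0.42, "coronal"),
        TractSpec("CG", lane_y(28, 12), 3.0, 0.45, "coronal"),
        TractSpec("CH", lane_y(48, 12), 3.0, 0.40, "coronal"),
        TractSpec("IFOF", lane_y(68, 12), 3.0, 0.48, "coronal"),
        TractSpec("ILF", lane_y(8, 30), 3.0, 0.46, "coronal"),
        TractSpec("SLF", lane_y(28, 30), 3.0, 0.44, "coronal"),
        TractSpec("SLFt", lane_y(48, 30), 3.0, 0.41, "coronal",
                  exclusion_centre=(38, 40, 66)),
        TractSpec("UF", lane_y(64, 30, bulge_z=2.5), 3.0, 0.39, "coronal"),
        TractSpec("Fminor", lane_x(12, 48, bulge_y=3.0), 3.0, 0.52, "coronal",
                  laterality="commissural"),
        TractSpec("Fmajor", lane_x(68, 48, bulge_y=-3.0), 3.0, 0.55, "coronal",
                  laterality="commissural"),
        TractSpec("CST", [[("line", (80, 16, 8), (80, 16, 72))]], 3.0, 0.58,
                  "axial"),
        TractSpec("fornix", [[fornix_body, limb_a], [fornix_body, limb_b]],
                  3.0, 0.36, "axial", laterality="commissural", y_shaped=True),
    ]


@dataclass
class CohortSpec:
    """Synthetic cohort parameters; reproducible from ``seed``."""

    n_atlas: int = 28
    n_validation: int = 8
    n_cases: int = 33
    shape: tuple[int, int, int] = (44, 40, 40)
    voxel_size: float = 2.0
    tracts: list[TractSpec] = field(default_factory=default_tracts)
    background_fa: float = 0.15
    noise_sd: float = 0.05            # voxelwise FA noise
    between_subject_sd: float = 0.012  # per-(subject, tract) FA offset
    rot_deg: float = 3.0              # affine jitter scales
    trans_mm: float = 2.0
    scale_sd: float = 0.03
    residual_rot_deg: float = 0.5     # registration error, not compensated
    residual_trans_mm: float = 0.4
    residual_scale_sd: float = 0.005
    case_effect: dict = field(default_factory=lambda: dict(_DEFAULT_CASE_EFFECT))
    roi_radius: float = 4.0
    streamline_step: float = 1.5
    n_qc_metrics: int = 4
    qc_outliers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_atlas, self.n_validation, self.n_cases):
            if n < 0:
                raise ValueError("cohort counts must be >= 0")
        for t in self.tracts:
            if t.radius <= 0:
                raise ValueError(f"{t.name}: radius must be > 0")
            if not 0.0 < t.mean_fa < 1.0:
                raise ValueError(f"{t.name}: mean FA must lie in (0,1)")

    @property
    def n_controls(self) -> int:
        # controls = atlas + validation subjects, as in the emulated study
        return self.n_atlas + self.n_validation

    def grid(self) -> VolumeGrid:
        A = np.diag([self.voxel_size] * 3 + [1.0])
        return VolumeGrid(shape=self.shape, affine=A)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["tracts"] = [t.name for t in self.tracts]
        return d


# ---------------------------------------------------------------------------
# Template
# ---------------------------------------------------------------------------

@dataclass
class TractGroundTruth:
    name: str
    definition: TractDefinition
    bundle: Tractogram
    occupancy: BinaryMask          # voxelisation of the canonical bundle
    fa_support: BinaryMask         # padded analytic tube support (paint region)
    centreline: np.ndarray         # dense points along all legs
    tangents: np.ndarray
    rois: dict                     # roi name -> (centre, radius)
    mean_fa: float
    major_axis: str

    def probability_map(self) -> ProbabilityMap:
        return ProbabilityMap(grid=self.occupancy.grid,
                              values=self.occupancy.values.astype(float),
                              n_subjects=1)


@dataclass
class Template:
    spec: CohortSpec
    grid: VolumeGrid
    tracts: dict
    rois: dict                     # roi name -> BinaryMask (template space)
    fa: ScalarVolume
    tensor: TensorVolume


def sphere_mask(grid: VolumeGrid, centre, radius: float) -> BinaryMask:
    idx = np.indices(grid.shape).reshape(3, -1).T
    world = grid.voxel_to_world(idx)
    d2 = ((world - np.asarray(centre, float)) ** 2).sum(axis=1)
    vals = (d2 <= radius * radius).reshape(grid.shape)
    return BinaryMask(grid=grid, values=vals)


def _support_pad(grid: VolumeGrid) -> float:
    return float(np.sqrt(3.0) / 2.0 * grid.voxel_sizes.max())


def _tube_support(grid: VolumeGrid, centreline: np.ndarray, radius: float) -> BinaryMask:
    tree = cKDTree(centreline)
    idx = np.indices(grid.shape).reshape(3, -1).T
    world = grid.voxel_to_world(idx)
    d, _ = tree.query(world, k=1, distance_upper_bound=radius + 1e-9)
    vals = np.isfinite(d).reshape(grid.shape)
    return BinaryMask(grid=grid, values=vals)


def _bundle_for_legs(tract: TractSpec, step: float) -> Tractogram:
    """Deterministic canonical bundle: ring offsets carried along each leg in
    its local frame."""
    streamlines = []
    offsets = _canonical_offsets(tract.radius)
    for leg in tract.legs:
        pts, tang = _sample_leg(leg, step)
        n1, n2 = _frames(tang)
        for a, b in offsets:
            streamlines.append(pts + a * n1 + b * n2)
    return Tractogram(streamlines=streamlines)


def _build_rois(tract: TractSpec) -> dict:
    """ROI protocol: two inclusion waypoints per tract; the Y-shaped tract
    uses a body waypoint plus two limb waypoints combined with ANY; an
    optional exclusion sphere exercises NOT."""
    rois = {}
    if tract.y_shaped:
        body_prim = tract.legs[0][0]
        rois[f"{tract.name}_body"] = (_eval_prim(body_prim, np.array([0.5]))[0],)
        for label, leg in zip(("limb_a", "limb_b"), tract.legs):
            rois[f"{tract.name}_{label}"] = (_leg_point([leg[-1]], 0.85),)
    else:
        leg = tract.legs[0]
        rois[f"{tract.name}_1"] = (_leg_point(leg, 0.15),)
        rois[f"{tract.name}_2"] = (_leg_point(leg, 0.85),)
    if tract.exclusion_centre is not None:
        rois[f"{tract.name}_excl"] = (np.asarray(tract.exclusion_centre, float),)
    return {k: v[0] for k, v in rois.items()}


def _build_query(tract: TractSpec) -> ROIQuery:
    if tract.y_shaped:
        q = All([Leaf(f"{tract.name}_body"),
                 Any([Leaf(f"{tract.name}_limb_a"), Leaf(f"{tract.name}_limb_b")])])
    else:
        q = All([Leaf(f"{tract.name}_1"), Leaf(f"{tract.name}_2")])
    if tract.exclusion_centre is not None:
        q = All([*q.children, Not(Leaf(f"{tract.name}_excl"))])
    return q


def tensor_from_fa_direction(fa: np.ndarray, dirs: np.ndarray,
                             lam_perp: float = 5e-4) -> np.ndarray:
    """Axially symmetric tensors with principal axis ``dirs`` and exact FA.

    For eigenvalues (t, 1, 1)*lam_perp, FA = (t-1)/sqrt(t^2+2); inverting
    gives t = (1 + sqrt(1 - (F^2-1)(2F^2-1))) / (1 - F^2). FA is capped at
    0.99 to keep t finite; FA 0 gives an isotropic tensor. Returns the
    6-component (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) array.
    """
    F = np.clip(np.asarray(fa, float), 0.0, 0.99)
    t = (1.0 + np.sqrt(1.0 - (F ** 2 - 1.0) * (2.0 * F ** 2 - 1.0))) / (1.0 - F ** 2)
    d = np.asarray(dirs, float)
    d = d / np.linalg.norm(d, axis=-1, keepdims=True)
    lam1 = t * lam_perp
    outer = d[..., :, None] * d[..., None, :]
    eye = np.eye(3)
    m = lam_perp * eye + (lam1 - lam_perp)[..., None, None] * outer
    return np.stack([m[..., i, j] for (i, j) in
                     [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]], axis=-1)


def make_template(spec: CohortSpec) -> Template:
    """Build the ground-truth template: bundles, ROI masks, occupancy maps,
    padded tube supports, and noiseless FA/tensor fields."""
    from .streamline_core import voxelise

    grid = spec.grid()
    pad = _support_pad(grid)
    if any(t.radius < grid.voxel_sizes.min() / 2 for t in spec.tracts):
        import warnings
        warnings.warn("tube radius below half a voxel: occupancy will alias")

    tracts: dict[str, TractGroundTruth] = {}
    rois: dict[str, BinaryMask] = {}
    for t in spec.tracts:
        bundle = _bundle_for_legs(t, spec.streamline_step)
        cl_pts = []
        cl_tan = []
        for leg in t.legs:
            p, tg = _sample_leg(leg, 0.25)
            cl_pts.append(p)
            cl_tan.append(tg)
        centreline = np.concatenate(cl_pts)
        tangents = np.concatenate(cl_tan)
        occupancy = voxelise(bundle, grid)
        fa_support = _tube_support(grid, centreline, t.radius + pad)
        roi_centres = _build_rois(t)
        troi = {}
        for name, centre in roi_centres.items():
            mask = sphere_mask(grid, centre, spec.roi_radius)
            rois[name] = mask
            troi[name] = (np.asarray(centre, float), spec.roi_radius)
        definition = TractDefinition(name=t.name, query=_build_query(t),
                                     major_axis=t.major_axis,
                                     laterality=t.laterality)
        tracts[t.name] = TractGroundTruth(
            name=t.name, definition=definition, bundle=bundle,
            occupancy=occupancy, fa_support=fa_support, centreline=centreline,
            tangents=tangents, rois=troi, mean_fa=t.mean_fa,
            major_axis=t.major_axis)

    fa_vals, tensor_vals = _paint_fields(
        grid, tracts, {t.name: t.mean_fa for t in spec.tracts},
        spec.background_fa)
    return Template(spec=spec, grid=grid, tracts=tracts, rois=rois,
                    fa=ScalarVolume(grid=grid, values=fa_vals),
                    tensor=TensorVolume(grid=grid, values=tensor_vals))


def _paint_fields(grid, tract_geoms, tract_fa, background_fa,
                  noise=None, rng=None):
    """FA field (background + per-tract means on their supports, optional
    truncated Gaussian noise) and the matching tensor field."""
    fa = np.full(grid.shape, background_fa, dtype=float)
    dirs = np.zeros((*grid.shape, 3), dtype=float)
    dirs[..., 2] = 1.0  # background principal axis
    idx = np.indices(grid.shape).reshape(3, -1).T
    world = grid.voxel_to_world(idx)
    for name, g in tract_geoms.items():
        sup = g.fa_support.values if hasattr(g, "fa_support") else g["support"].values
        cl = g.centreline if hasattr(g, "centreline") else g["centreline"]
        tg = g.tangents if hasattr(g, "tangents") else g["tangents"]
        fa[sup] = tract_fa[name]
        tree = cKDTree(cl)
        flat = sup.reshape(-1)
        _, nearest = tree.query(world[flat], k=1)
        dirs.reshape(-1, 3)[flat] = tg[nearest]
    if noise is not None and noise > 0.0:
        fa = fa + rng.normal(0.0, noise, size=fa.shape)
    fa = np.clip(fa, 0.0, 0.99)
    tensor = tensor_from_fa_direction(fa, dirs)
    return fa, tensor


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    id: str
    group: str                      # "case" | "control"
    role: str                       # "atlas" | "validation" | "case"
    bundles: dict                   # tract name -> Tractogram (subject space)
    fa: ScalarVolume
    tensor: TensorVolume
    rois: dict                      # roi name -> BinaryMask (subject space)
    affine_to_template: np.ndarray
    tract_fa_true: dict             # tract name -> painted FA value

    def whole_tractogram(self) -> Tractogram:
        sl = []
        for name in sorted(self.bundles):
            sl.extend(self.bundles[name].streamlines)
        return Tractogram(streamlines=sl)


def _jitter_affine(rng, centre, rot_deg, trans_mm, scale_sd) -> np.ndarray:
    """Random similarity transform about the volume centre."""
    if rot_deg == 0.0 and trans_mm == 0.0 and scale_sd == 0.0:
        return np.eye(4)
    angles = np.deg2rad(rng.normal(0.0, rot_deg, size=3))
    cx, sx = np.cos(angles[0]), np.sin(angles[0])
    cy, sy = np.cos(angles[1]), np.sin(angles[1])
    cz, sz = np.cos(angles[2]), np.sin(angles[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    s = max(0.5, rng.normal(1.0, scale_sd))
    M = s * (Rz @ Ry @ Rx)
    t = rng.normal(0.0, trans_mm, size=3) if trans_mm > 0 else np.zeros(3)
    A = np.eye(4)
    A[:3, :3] = M
    A[:3, 3] = np.asarray(centre) - M @ np.asarray(centre) + t
    return A


def make_subject(template: Template, subject_id: str, seed: int,
                 group: str = "control", role: str = "atlas",
                 jitter: bool = True, noise: bool = True) -> SubjectData:
    """One subject: jittered geometry, painted FA + tensor, subject ROIs,
    and the stored subject-to-template affine.

    With ``jitter=False`` and ``noise=False`` the subject is an exact copy of
    the template with an identity transform.
    """
    spec = template.spec
    rng = np.random.default_rng(seed)
    centre = np.asarray(template.grid.shape, float) * spec.voxel_size / 2.0
    if jitter:
        J = _jitter_affine(rng, centre, spec.rot_deg, spec.trans_mm, spec.scale_sd)
        Jr = _jitter_affine(rng, centre, spec.residual_rot_deg,
                            spec.residual_trans_mm, spec.residual_scale_sd)
    else:
        J = np.eye(4)
        Jr = np.eye(4)
    Jtot = Jr @ J
    scale_tot = abs(np.linalg.det(Jtot[:3, :3])) ** (1.0 / 3.0)
    R_tot = rigid_part(Jtot)
    pad = _support_pad(template.grid)

    bundles = {}
    subj_geoms = {}
    tract_fa_true = {}
    rois = {}
    for name, g in template.tracts.items():
        bundles[name] = apply_affine(g.bundle, Jtot)
        cl = g.centreline @ Jtot[:3, :3].T + Jtot[:3, 3]
        tg = g.tangents @ R_tot.T
        radius = scale_tot * (spec_radius := next(
            t.radius for t in spec.tracts if t.name == name))
        subj_geoms[name] = {
            "support": _tube_support(template.grid, cl, radius + pad),
            "centreline": cl, "tangents": tg,
        }
        offset = rng.normal(0.0, spec.between_subject_sd) if noise else 0.0
        effect = spec.case_effect.get(name, 0.0) if group == "case" else 0.0
        tract_fa_true[name] = g.mean_fa + offset + effect
        for rname, (centre_r, rad_r) in g.rois.items():
            c2 = Jtot[:3, :3] @ centre_r + Jtot[:3, 3]
            rois[rname] = sphere_mask(template.grid, c2, scale_tot * rad_r)

    class _G:  # adapter for _paint_fields
        pass

    geoms = {}
    for name, d in subj_geoms.items():
        g2 = _G()
        g2.fa_support = d["support"]
        g2.centreline = d["centreline"]
        g2.tangents = d["tangents"]
        geoms[name] = g2
    fa_vals, tensor_vals = _paint_fields(
        template.grid, geoms, tract_fa_true, spec.background_fa,
        noise=spec.noise_sd if noise else None, rng=rng)

    return SubjectData(
        id=subject_id, group=group, role=role, bundles=bundles,
        fa=ScalarVolume(grid=template.grid, values=fa_vals),
        tensor=TensorVolume(grid=template.grid, values=tensor_vals),
        rois=rois, affine_to_template=np.linalg.inv(J),
        tract_fa_true=tract_fa_true)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _subject_plan(spec: CohortSpec):
    plan = []
    for i in range(spec.n_atlas):
        plan.append((f"sub-A{i:02d}", "control", "atlas"))
    for i in range(spec.n_validation):
        plan.append((f"sub-V{i:02d}", "control", "validation"))
    for i in range(spec.n_cases):
        plan.append((f"sub-P{i:02d}", "case", "case"))
    return plan


def make_cohort(spec: CohortSpec, out_dir: "Path | str", force: bool = False) -> Path:
    """Generate a cohort on disk: template, per-subject TCK + NIfTI +
    transform, group table, QC metric table and a ground-truth manifest."""
    from . import cli_io

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not force:
            raise FileExistsError(f"{out} exists; pass force=True to overwrite")
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    template = make_template(spec)
    tdir = out / "template"
    (tdir / "rois").mkdir(parents=True)
    cli_io.write_scalar(template.fa, tdir / "fa.nii")
    cli_io.write_tensor(template.tensor, tdir / "tensor.nii")
    for rname, mask in template.rois.items():
        cli_io.write_mask(mask, tdir / "rois" / f"{rname}.nii")
    (tdir / "tracts").mkdir()
    for name, g in template.tracts.items():
        g.definition.save(tdir / "tracts" / f"{name}.json")
        cli_io.write_mask(g.occupancy, tdir / f"occupancy_{name}.nii")

    ss = np.random.SeedSequence(spec.seed)
    plan = _subject_plan(spec)
    child_seeds = ss.generate_state(len(plan) + 1)
    rows = []
    for (sid, group, role), sd_seed in zip(plan, child_seeds[:-1]):
        subj = make_subject(template, sid, int(sd_seed), group=group, role=role)
        sdir = out / "subjects" / sid
        (sdir / "rois").mkdir(parents=True)
        cli_io.write_tractogram(subj.whole_tractogram(), sdir / "tracto.tck")
        cli_io.write_scalar(subj.fa, sdir / "fa.nii")
        cli_io.write_tensor(subj.tensor, sdir / "tensor.nii")
        np.savetxt(sdir / "transform.txt", subj.affine_to_template, fmt="%.17g")
        for rname, mask in subj.rois.items():
            cli_io.write_mask(mask, sdir / "rois" / f"{rname}.nii")
        rows.append({"subject": sid, "group": group, "role": role,
                     **{f"true_fa_{k}": v for k, v in subj.tract_fa_true.items()}})
    groups = pd.DataFrame(rows)
    groups[["subject", "group", "role"]].to_csv(out / "groups.tsv", sep="\t", index=False)

    qc_rng = np.random.default_rng(int(child_seeds[-1]))
    qc = qc_rng.normal(0.0, 1.0, size=(len(plan), spec.n_qc_metrics))
    for i in range(min(spec.qc_outliers, len(plan))):
        qc[i] += 5.0
    qc_df = pd.DataFrame(qc, columns=[f"metric_{j}" for j in range(spec.n_qc_metrics)])
    qc_df.insert(0, "subject", [p[0] for p in plan])
    qc_df.to_csv(out / "qc_metrics.tsv", sep="\t", index=False, float_format="%.8g")

    manifest = {
        "spec": spec.to_jsonable(),
        "seed": spec.seed,
        "tract_names": [t.name for t in spec.tracts],
        "tract_mean_fa": {t.name: t.mean_fa for t in spec.tracts},
        "case_effect": spec.case_effect,
        "designated_tracts": sorted(k for k, v in spec.case_effect.items() if v != 0.0),
        "occupancy_voxels": {n: g.occupancy.count for n, g in template.tracts.items()},
        "subjects": rows,
        "noise": {"model": "gaussian, truncated to keep FA in [0, 0.99]",
                  "voxel_sd": spec.noise_sd,
                  "between_subject_sd": spec.between_subject_sd},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def sample_fa_table(template: Template, seed: int,
                    n_cases: int | None = None, n_controls: int | None = None,
                    case_effect: dict | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Whole-tract FA tables for cases and controls, drawn from the same
    generative model the imaging pipeline measures.

    The pipeline's whole-tract FA for a subject is the mean of the painted
    tract value plus voxel noise over the tract support, i.e.
    ``mean + between-subject offset (+ case effect) + N(0, sd/sqrt(V))`` for
    V support voxels. Sampling that directly gives distributionally identical
    tables at a fraction of the cost — used for power/calibration studies.
    """
    spec = template.spec
    rng = np.random.default_rng(seed)
    n_cases = spec.n_cases if n_cases is None else n_cases
    n_controls = spec.n_controls if n_controls is None else n_controls
    effect = spec.case_effect if case_effect is None else case_effect
    names = list(template.tracts)
    vox = np.array([template.tracts[n].occupancy.count for n in names], float)
    meas_sd = spec.noise_sd / np.sqrt(vox)
    means = np.array([template.tracts[n].mean_fa for n in names])

    def draw(n, is_case):
        base = means + (np.array([effect.get(nm, 0.0) for nm in names]) if is_case else 0.0)
        vals = (base
                + rng.normal(0.0, spec.between_subject_sd, size=(n, len(names)))
                + rng.normal(0.0, meas_sd, size=(n, len(names))))
        return pd.DataFrame(np.clip(vals, 0.0, 1.0), columns=names)

    return draw(n_cases, True), draw(n_controls, False)
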