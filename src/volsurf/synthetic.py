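"""A fully specified phantom world with known ground truth.

The phantom replaces brain anatomy with a spherical-shell "cortical
ribbon" (every geometric quantity has a closed form or a brute-force
oracle): a cubic template grid holds a shell ribbon between radii
``r_in`` and ``r_out``; the mid-shell icosphere plays the template
surface, its radial projection the common sphere.  A parcellation of
``n_parcels`` angular sectors (farthest-point seeds on the sphere,
nearest-seed assignment) labels the surface; ribbon voxels take the
label of their nearest mid-surface vertex, mirroring how volumetric
cortical parcellations are produced from surface parcellations in
practice.  Two "hemispheres" are the x < 0 and x >= 0 half-shells.

Each synthetic subject is the template pushed through a smooth random
displacement field (Gaussian noise on a coarse control grid, smoothed,
upsampled, scaled to a maximum amplitude ``amplitude`` mm) plus a
jittered spherical registration (small random rotation and smooth
tangential jitter, bounded by ``jitter_deg``).  The exact generating
transforms, and their numerically inverted fields, are recorded, so
the fusion pipeline can be scored against exact ground truth.

Seed discipline: every stochastic draw is keyed by (master seed,
subject index, draw name), so a cohort's leading subjects do not change
when the cohort grows.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage as ndi

from .errors import ValidationError
from .formats_io import (
    LabelTable,
    TriangleMesh,
    VolumeImage,
    read_labels,
    read_mesh,
    read_vertex_data,
    read_volume,
    write_labels,
    write_mesh,
    write_vertex_data,
    write_volume,
)
from .fusion import SubjectBundle, SurfToVolMapping, VolToSurfMapping
from .projection import Parcellation, ProbabilisticMap, make_prob_maps, winner_takes_all
from .surfaces import (
    SphericalRegistration,
    nearest_with_ties,
    normalize_rows,
    resample_to_template,
)
from .transforms import (
    AffineTransform,
    DenseTransform,
    TransformChain,
    VectorField,
    invert_field,
    load_chain,
    resample_volume,
    save_chain,
    _world_to_voxel,
)

__all__ = [
    "PhantomSpec",
    "PhantomTemplate",
    "GroundTruth",
    "EvalData",
    "make_template",
    "make_subject",
    "make_cohort",
    "make_subject_parcellations",
    "make_evaluation_data",
    "baseline_affine",
    "write_cohort",
    "load_cohort",
]

_CONTROL_GRID = 6  # control nodes per axis for the random warps
_CONTROL_SMOOTH_SIGMA = 2.0  # Gaussian sigma, in control-node spacings
_DRAW_CODES = {"warp": 11, "tangential": 13, "parcels": 21}


def _rng(master_seed: int, draw: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        [int(master_seed) & 0x7FFFFFFF, _DRAW_CODES[draw], int(index)]
    )


@dataclass
class PhantomSpec:
    """Parameters of the phantom world.

    Defaults describe the standard study conditions: a 48^3 grid at
    1 mm, shell radii 14-18 mm, 16 parcels, icosphere subdivision 3.
    ``amplitude`` is the per-subject maximum displacement (mm);
    ``jitter_deg`` bounds the spherical-registration perturbation.
    """

    grid_shape: tuple = (48, 48, 48)
    voxel_size: float = 1.0
    r_in: float = 14.0
    r_out: float = 18.0
    n_parcels: int = 16
    n_subjects: int = 8
    amplitude: float = 1.0
    jitter_deg: float = 2.0
    seed: int = 0
    subdivisions: int = 3
    recenter: bool = True

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        half_extent = min(self.grid_shape) * self.voxel_size / 2.0
        if not (0 < self.r_in < self.r_out < half_extent):
            raise ValidationError(
                f"need 0 < r_in < r_out < grid half-extent ({half_extent} mm), "
                f"got r_in={self.r_in}, r_out={self.r_out}"
            )
        if self.n_parcels < 2:
            raise ValidationError("need at least 2 parcels")
        if self.amplitude < 0:
            raise ValidationError("warp amplitude must be nonnegative")
        if self.jitter_deg < 0:
            raise ValidationError("surface jitter angle must be nonnegative")
        if self.n_subjects < 1:
            raise ValidationError("need at least one subject")

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world affine placing the world origin at the grid center."""
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size
        aff[:3, 3] = -(np.array(self.grid_shape) - 1) / 2.0 * self.voxel_size
        return aff

    @property
    def r_mid(self) -> float:
        return 0.5 * (self.r_in + self.r_out)

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "voxel_size": self.voxel_size,
            "r_in": self.r_in,
            "r_out": self.r_out,
            "n_parcels": self.n_parcels,
            "n_subjects": self.n_subjects,
            "amplitude": self.amplitude,
            "jitter_deg": self.jitter_deg,
            "seed": self.seed,
            "subdivisions": self.subdivisions,
            "recenter": self.recenter,
        }


@dataclass
class PhantomTemplate:
    """The phantom's template volume, surfaces and parcellation."""

    spec: PhantomSpec
    ribbon: VolumeImage  # uint8 shell mask
    parc: VolumeImage  # int32 volumetric parcellation (0 outside ribbon)
    mid_surface: TriangleMesh  # icosphere at r_mid, world mm
    sphere: TriangleMesh  # same topology on the unit sphere
    vertex_labels: np.ndarray  # (V,) int32
    label_table: LabelTable
    seed_directions: np.ndarray  # (L, 3) parcel seed unit vectors
    parcel_hemi: np.ndarray  # (L,) hemisphere each parcel belongs to
    vertex_hemi: np.ndarray  # (V,) 0 = x<0, 1 = x>=0
    voxel_hemi: np.ndarray  # (X, Y, Z) likewise

    @property
    def affine(self) -> np.ndarray:
        return self.ribbon.affine

    @property
    def shape(self) -> tuple:
        return self.ribbon.shape

    @property
    def label_ids(self) -> np.ndarray:
        return np.asarray(self.label_table.ids, dtype=np.int64)


@dataclass
class GroundTruth:
    """Exact template mappings implied by the phantom construction."""

    vol2surf: VolToSurfMapping  # template vertex -> its own mid-surface coordinate
    surf2vol: SurfToVolMapping  # ribbon voxel -> nearest mid-surface vertex
    true_fields: list = dc_field(default_factory=list)  # per-subject generating warps


# ---------------------------------------------------------------------------
# template
# ---------------------------------------------------------------------------


def _farthest_point_seeds(
    directions: np.ndarray, n_seeds: int, rng: np.random.Generator
) -> np.ndarray:
    """Greedy farthest-point sampling among unit directions (max-min geodesic)."""
    first = int(rng.integers(len(directions)))
    chosen = [first]
    # geodesic distance is monotone in (1 - dot); track max dot instead
    best_dot = directions @ directions[first]
    for _ in range(n_seeds - 1):
        nxt = int(np.argmin(best_dot))
        chosen.append(nxt)
        best_dot = np.maximum(best_dot, directions @ directions[nxt])
    return directions[chosen]


def _parcel_seeds(
    unit: np.ndarray, n_parcels: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Hemisphere-aware parcel seeds: half drawn in each half-shell.

    Parcels belong to exactly one hemisphere (as anatomical structures
    do), so every parcel can be scored within its own hemisphere.
    Returns (seed directions, per-parcel hemisphere flags).
    """
    n_lh = n_parcels // 2
    n_rh = n_parcels - n_lh
    lh_dirs = unit[unit[:, 0] < 0]
    rh_dirs = unit[unit[:, 0] >= 0]
    seeds = np.concatenate(
        [
            _farthest_point_seeds(lh_dirs, n_lh, rng),
            _farthest_point_seeds(rh_dirs, n_rh, rng),
        ]
    )
    hemi = np.concatenate([np.zeros(n_lh, dtype=np.int8), np.ones(n_rh, dtype=np.int8)])
    return seeds, hemi


def _assign_sectors(
    directions: np.ndarray, seeds: np.ndarray, parcel_hemi: np.ndarray
) -> np.ndarray:
    """Nearest same-hemisphere seed, 1-based; ties resolve to the lowest label."""
    dots = directions @ seeds.T
    dir_hemi = (directions[:, 0] >= 0).astype(np.int8)
    dots = np.where(dir_hemi[:, None] == parcel_hemi[None, :], dots, -np.inf)
    return np.argmax(dots, axis=1).astype(np.int32) + 1


def make_template(spec: PhantomSpec) -> PhantomTemplate:
    """Build the shell ribbon, mid-surface icosphere and angular parcellation."""
    shape = spec.grid_shape
    affine = spec.affine
    idx = np.indices(shape).reshape(3, -1).T
    centers = idx @ affine[:3, :3].T + affine[:3, 3]
    radii = np.linalg.norm(centers, axis=1).reshape(shape)
    ribbon = ((radii >= spec.r_in) & (radii <= spec.r_out)).astype(np.uint8)

    ico = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
    unit = np.asarray(ico.vertices, dtype=float)
    unit = normalize_rows(unit)
    faces = np.asarray(ico.faces, dtype=np.int64)
    sphere = TriangleMesh(unit, faces)
    mid_surface = TriangleMesh(unit * spec.r_mid, faces)

    seeds, parcel_hemi = _parcel_seeds(unit, spec.n_parcels, _rng(spec.seed, "parcels"))
    vertex_labels = _assign_sectors(unit, seeds, parcel_hemi)

    # Volumetric parcellation: ribbon voxels take their nearest mid-surface
    # vertex's label (the standard surface-to-volume label construction).
    parc = np.zeros(shape, dtype=np.int32)
    ribbon_flat = ribbon.reshape(-1).astype(bool)
    rib_centers = centers[ribbon_flat]
    nearest = nearest_with_ties(mid_surface.vertices, rib_centers)
    parc.reshape(-1)[ribbon_flat] = vertex_labels[nearest]

    palette = ["#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00", "#a65628",
               "#f781bf", "#999999"]
    table = LabelTable(
        {
            int(k): (f"parcel_{k:02d}", palette[(k - 1) % len(palette)])
            for k in range(1, spec.n_parcels + 1)
        }
    )
    vertex_hemi = (mid_surface.vertices[:, 0] >= 0).astype(np.int8)
    voxel_hemi = (centers[:, 0] >= 0).astype(np.int8).reshape(shape)
    return PhantomTemplate(
        spec=spec,
        ribbon=VolumeImage(ribbon, affine),
        parc=VolumeImage(parc, affine),
        mid_surface=mid_surface,
        sphere=sphere,
        vertex_labels=vertex_labels,
        label_table=table,
        seed_directions=seeds,
        parcel_hemi=parcel_hemi,
        vertex_hemi=vertex_hemi,
        voxel_hemi=voxel_hemi,
    )


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------


def _control_noise(spec: PhantomSpec, index: int) -> np.ndarray:
    return _rng(spec.seed, "warp", index).standard_normal((_CONTROL_GRID,) * 3 + (3,))


def _field_from_control(spec: PhantomSpec, control: np.ndarray) -> np.ndarray:
    """Smooth, upsample and rescale control-grid noise to a dense warp."""
    shape = spec.grid_shape
    smoothed = np.empty_like(control)
    for c in range(3):
        smoothed[..., c] = ndi.gaussian_filter(
            control[..., c], sigma=_CONTROL_SMOOTH_SIGMA, mode="nearest"
        )
    spacing = (np.array(shape) - 1) / (_CONTROL_GRID - 1)
    grid = np.indices(shape).reshape(3, -1).astype(float)
    coords = grid / spacing[:, None]
    u = np.empty(shape + (3,), dtype=float)
    for c in range(3):
        u[..., c] = ndi.map_coordinates(
            smoothed[..., c], coords, order=3, mode="nearest"
        ).reshape(shape)
    max_norm = float(np.linalg.norm(u, axis=-1).max())
    if spec.amplitude == 0 or max_norm == 0:
        return np.zeros_like(u)
    return u * (spec.amplitude / max_norm)


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def _tangential_draw(spec: PhantomSpec, index: int) -> np.ndarray:
    return _rng(spec.seed, "tangential", index).standard_normal((3, 3))


def _jittered_sphere(
    spec: PhantomSpec, unit: np.ndarray, index: int, tangential: np.ndarray | None = None
) -> np.ndarray:
    """Smooth spherical-registration jitter bounded by ``jitter_deg``.

    The per-vertex displacement is the tangential projection of a
    random linear field, ``d_i = (I - v_i v_i^T) B v_i`` with a Gaussian
    3x3 draw ``B`` (whose antisymmetric part is an infinitesimal
    rotation, so small random rotations are included), rescaled so the
    largest angular displacement equals ``jitter_deg``.  Being linear in
    ``B``, the jitter can be recentered to zero mean across a cohort by
    recentering the draws.
    """
    if spec.jitter_deg == 0:
        return unit.copy()
    if tangential is None:
        tangential = _tangential_draw(spec, index)
    raw = unit @ tangential.T
    d = raw - (raw * unit).sum(axis=1, keepdims=True) * unit
    max_norm = float(np.linalg.norm(d, axis=1).max())
    if max_norm > 0:
        d *= np.deg2rad(spec.jitter_deg) / max_norm
    return normalize_rows(unit + d)


def make_subject(
    spec: PhantomSpec,
    index: int,
    template: PhantomTemplate | None = None,
    control: np.ndarray | None = None,
    tangential: np.ndarray | None = None,
) -> tuple[SubjectBundle, DenseTransform]:
    """One synthetic subject: warped anatomy plus jittered registration.

    Returns the bundle and the generating forward warp (template ->
    subject).  ``control`` and ``tangential`` override the raw noise
    draws (used by :func:`make_cohort` for recentering).
    """
    if template is None:
        template = make_template(spec)
    if control is None:
        control = _control_noise(spec, index)
    u = _field_from_control(spec, control)
    subject_space = f"sub-{index:03d}"
    forward = DenseTransform(
        VectorField(u, template.affine), source="template", target=subject_space
    )
    inverse = invert_field(forward, tol=0.005, max_iter=100)
    vol_chain = TransformChain([forward])
    inverse_chain = TransformChain([inverse])
    ribbon_s = resample_volume(template.ribbon, inverse_chain, interp="nearest")
    subject_vertices = vol_chain.map_points(template.mid_surface.vertices, oob="clamp")
    sphere_coords = _jittered_sphere(spec, template.sphere.vertices, index, tangential)
    reg = SphericalRegistration(
        TriangleMesh(subject_vertices, template.mid_surface.faces),
        sphere_coords,
        template.sphere,
    )
    bundle = SubjectBundle(
        subject_id=subject_space,
        vol_chain=vol_chain,
        inverse_vol_chain=inverse_chain,
        reg=reg,
        ribbon_mask=ribbon_s,
    )
    return bundle, forward


def make_cohort(
    spec: PhantomSpec, template: PhantomTemplate | None = None
) -> tuple[list[SubjectBundle], GroundTruth]:
    """Generate the cohort plus exact ground truth.

    With ``spec.recenter`` (default) the cohort-mean control-grid noise
    and the cohort-mean tangential-jitter draw are subtracted from every
    subject before smoothing/scaling, so the template is the cohort's
    true center on both the volume and the surface side.
    """
    if template is None:
        template = make_template(spec)
    controls = np.stack([_control_noise(spec, i) for i in range(spec.n_subjects)])
    tangentials = np.stack([_tangential_draw(spec, i) for i in range(spec.n_subjects)])
    if spec.recenter and spec.n_subjects > 1:
        controls = controls - controls.mean(axis=0, keepdims=True)
        tangentials = tangentials - tangentials.mean(axis=0, keepdims=True)
    cohort = []
    true_fields = []
    for i in range(spec.n_subjects):
        bundle, forward = make_subject(
            spec, i, template=template, control=controls[i], tangential=tangentials[i]
        )
        cohort.append(bundle)
        true_fields.append(forward)
    truth = GroundTruth(
        vol2surf=_true_vol2surf(template),
        surf2vol=_true_surf2vol(template),
        true_fields=true_fields,
    )
    return cohort, truth


def _true_vol2surf(template: PhantomTemplate) -> VolToSurfMapping:
    return VolToSurfMapping(template.mid_surface.vertices.copy(), n_subjects=0)


def _true_surf2vol(template: PhantomTemplate) -> SurfToVolMapping:
    shape = template.shape
    ribbon = template.ribbon.data.astype(bool)
    n_vox = int(np.prod(shape))
    idx = np.stack(np.unravel_index(np.arange(n_vox), shape, order="F"), axis=1)
    centers = idx @ template.affine[:3, :3].T + template.affine[:3, 3]
    rib_flat = ribbon.ravel(order="F")
    vertex = np.full(n_vox, -1, dtype=np.int32)
    sphere = np.full((n_vox, 3), np.nan)
    lin = np.nonzero(rib_flat)[0]
    nearest = nearest_with_ties(template.mid_surface.vertices, centers[lin])
    vertex[lin] = nearest.astype(np.int32)
    sphere[lin] = template.sphere.vertices[nearest]
    sphere_vol = np.empty(shape + (3,), dtype=float)
    for c in range(3):
        sphere_vol[..., c] = sphere[:, c].reshape(shape, order="F")
    return SurfToVolMapping(
        shape=shape,
        affine=template.affine,
        sphere_coords=sphere_vol,
        coverage=ribbon.astype(float),
        tight_mask=ribbon.copy(),
        loose_mask=ribbon.copy(),
        tight_thresh=0.50,
        loose_thresh=0.15,
        n_subjects=0,
        vertex_index=vertex.reshape(shape, order="F"),
    )


def baseline_affine(spec: PhantomSpec) -> AffineTransform:
    """The phantom's deliberately imperfect template-to-surface-volume affine.

    A fixed 2 degree rotation, 2% isotropic scale and ~1 mm translation
    emulate the residual misalignment an affine-only approach cannot
    remove.  Deterministic: part of the phantom world, not a random draw.
    """
    rot = _rotation_matrix(np.array([0.3, 0.5, 1.0]), np.deg2rad(2.0))
    matrix = np.eye(4)
    matrix[:3, :3] = 1.02 * rot
    matrix[:3, 3] = [1.2, -0.8, 0.6]
    return AffineTransform(matrix, source="template", target="surface-volume")


# ---------------------------------------------------------------------------
# evaluation inputs (the projection-simulation harness)
# ---------------------------------------------------------------------------


def make_subject_parcellations(
    template: PhantomTemplate, cohort: list[SubjectBundle]
) -> list[VolumeImage]:
    """Template parcellation carried into each subject's space (nearest)."""
    return [
        resample_volume(template.parc, b.inverse_vol_chain, interp="nearest")
        for b in cohort
    ]


@dataclass
class EvalData:
    """Inputs for the volume-to-surface and surface-to-volume evaluations.

    ``vol_probs``: volumetric probabilistic map per parcel (subjects'
    parcellations carried to the template grid, averaged).
    ``surf_truth``: reference surface probabilistic maps (subjects'
    surface labels resampled to the template sphere, averaged).
    ``vol_truth``: reference volumetric winner-takes-all parcellation.
    ``surf_parc``: template-surface winner-takes-all parcellation to be
    projected into the volume.
    """

    vol_probs: ProbabilisticMap
    surf_truth: ProbabilisticMap
    vol_truth: Parcellation
    surf_parc: Parcellation
    label_ids: np.ndarray


def make_evaluation_data(
    template: PhantomTemplate,
    cohort: list[SubjectBundle],
    subject_parcs: list[VolumeImage] | None = None,
) -> EvalData:
    """Simulate both evaluation workflows' inputs from the cohort.

    Per subject, the volumetric parcellation travels subject -> template
    grid (volume route) while the surface labels -- the parcellation
    sampled at the subject's own mid-surface vertices -- travel through
    the spherical registration to the template sphere (surface route).
    Averaging each route gives the probabilistic maps; winner-takes-all
    gives the hard parcellations.
    """
    if subject_parcs is None:
        subject_parcs = make_subject_parcellations(template, cohort)
    label_ids = template.label_ids
    vol_parcs = []
    surf_labelings = []
    for bundle, parc_s in zip(cohort, subject_parcs):
        vol_parcs.append(
            resample_volume(parc_s, bundle.vol_chain, interp="nearest").data
        )
        vox = _world_to_voxel(parc_s.affine, bundle.reg.subject_mesh.vertices)
        nearest_idx = np.clip(
            np.round(vox).astype(int), 0, np.array(parc_s.shape) - 1
        )
        subj_labels = parc_s.data[
            nearest_idx[:, 0], nearest_idx[:, 1], nearest_idx[:, 2]
        ]
        surf_labelings.append(
            resample_to_template(bundle.reg, subj_labels.astype(np.int32), interp="nearest")
        )
    vol_probs = make_prob_maps(vol_parcs, label_ids=label_ids, table=template.label_table)
    surf_truth = make_prob_maps(
        surf_labelings, label_ids=label_ids, table=template.label_table
    )
    return EvalData(
        vol_probs=vol_probs,
        surf_truth=surf_truth,
        vol_truth=winner_takes_all(vol_probs),
        surf_parc=winner_takes_all(surf_truth),
        label_ids=label_ids,
    )


# ---------------------------------------------------------------------------
# on-disk cohorts
# ---------------------------------------------------------------------------


def write_cohort(directory, spec: PhantomSpec) -> Path:
    """Simulate and write a full cohort tree plus a manifest JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    template = make_template(spec)
    cohort, truth = make_cohort(spec, template)

    tdir = directory / "template"
    tdir.mkdir(exist_ok=True)
    write_volume(template.ribbon, tdir / "ribbon.nii")
    write_volume(template.parc, tdir / "parcellation.nii")
    write_mesh(template.mid_surface, tdir / "mid_surface.txt")
    write_mesh(template.sphere, tdir / "sphere.txt")
    write_vertex_data(template.vertex_labels, tdir / "vertex_labels.txt")
    write_labels(template.label_table, tdir / "labels.csv")

    gdir = directory / "truth"
    gdir.mkdir(exist_ok=True)
    np.savetxt(
        gdir / "vol2surf_coords.csv",
        truth.vol2surf.coords,
        fmt="%.17g",
        delimiter=",",
        header="x,y,z",
        comments="",
    )
    write_volume(
        VolumeImage(truth.surf2vol.vertex_index, template.affine),
        gdir / "surf2vol_vertex_index.nii",
    )

    subject_dirs = []
    for i, bundle in enumerate(cohort):
        sdir = directory / bundle.subject_id
        sdir.mkdir(exist_ok=True)
        save_chain(bundle.vol_chain, sdir, stem="forward")
        save_chain(bundle.inverse_vol_chain, sdir, stem="inverse")
        write_mesh(bundle.reg.subject_mesh, sdir / "mid_surface.txt")
        write_vertex_data(
            bundle.reg.sphere_coords.reshape(-1), sdir / "sphere_coords.txt"
        )
        write_volume(bundle.ribbon_mask, sdir / "ribbon.nii")
        subject_dirs.append(bundle.subject_id)

    manifest = {
        "format": "volsurf-cohort-1",
        "spec": spec.to_dict(),
        "subjects": subject_dirs,
    }
    text = json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    (directory / "manifest.json").write_text(text)
    checksum = hashlib.sha256(text.encode()).hexdigest()
    (directory / "manifest.sha256").write_text(checksum + "\n")
    return directory / "manifest.json"


def load_cohort(directory) -> tuple[PhantomSpec, PhantomTemplate, list[SubjectBundle], GroundTruth]:
    """Reload a cohort tree written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec = PhantomSpec(**{**manifest["spec"], "grid_shape": tuple(manifest["spec"]["grid_shape"])})

    tdir = directory / "template"
    ribbon = read_volume(tdir / "ribbon.nii")
    parc = read_volume(tdir / "parcellation.nii")
    mid = read_mesh(tdir / "mid_surface.txt")
    sphere = read_mesh(tdir / "sphere.txt")
    vertex_labels = read_vertex_data(tdir / "vertex_labels.txt", dtype=np.int32)
    table = read_labels(tdir / "labels.csv")
    idx = np.indices(ribbon.shape).reshape(3, -1).T
    centers = idx @ ribbon.affine[:3, :3].T + ribbon.affine[:3, 3]
    seeds, parcel_hemi = _parcel_seeds(
        normalize_rows(sphere.vertices), spec.n_parcels, _rng(spec.seed, "parcels")
    )
    template = PhantomTemplate(
        spec=spec,
        ribbon=ribbon,
        parc=VolumeImage(parc.data.astype(np.int32), parc.affine),
        mid_surface=mid,
        sphere=sphere,
        vertex_labels=vertex_labels,
        label_table=table,
        seed_directions=seeds,
        parcel_hemi=parcel_hemi,
        vertex_hemi=(mid.vertices[:, 0] >= 0).astype(np.int8),
        voxel_hemi=(centers[:, 0] >= 0).astype(np.int8).reshape(ribbon.shape),
    )

    cohort = []
    for sid in manifest["subjects"]:
        sdir = directory / sid
        vol_chain = load_chain(sdir / "forward_manifest.json")
        inverse_chain = load_chain(sdir / "inverse_manifest.json")
        sub_mesh = read_mesh(sdir / "mid_surface.txt")
        sphere_coords = read_vertex_data(sdir / "sphere_coords.txt").reshape(-1, 3)
        rib = read_volume(sdir / "ribbon.nii")
        cohort.append(
            SubjectBundle(
                subject_id=sid,
                vol_chain=vol_chain,
                inverse_vol_chain=inverse_chain,
                reg=SphericalRegistration(sub_mesh, sphere_coords, sphere),
                ribbon_mask=rib,
            )
        )
    truth = GroundTruth(
        vol2surf=_true_vol2surf(template), surf2vol=_true_surf2vol(template)
    )
    return spec, template, cohort, truth
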