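"""Registration fusion: cohort-averaged mappings between a volumetric
template grid and a surface template mesh, the coverage masks, the
dilation into the loose mask, and the two single-registration baselines.

The method composes, per subject, the surface-side registration (which
carries every template-surface vertex to a point on the subject's
anatomical surface) with the volume-side registration (which carries
that point into the volumetric template), and then averages the
composed per-subject mappings across the cohort:

* volume -> surface direction: for template vertex ``v`` and subject
  ``s``, the anatomical point ``p = surf_reg_s(v)`` is pushed through
  the subject-to-template chain to a template-volume coordinate
  ``q_s(v)``; the final mapping is the arithmetic mean of ``q_s(v)``
  over subjects.

* surface -> volume direction: each template-grid voxel center is
  pulled into subject space; voxels landing inside the subject's
  cortical ribbon are assigned the common-sphere position of the
  nearest subject mid-surface vertex.  Sphere positions are averaged
  arithmetically over contributing subjects and renormalized to unit
  length.  Not every voxel is cortex in every subject, so each voxel
  carries a coverage fraction; thresholding it (>=) gives the tight
  (default 50%) and loose (default 15%) cortical masks.  The averaged
  mapping is defined on covered voxels and grown outward: every
  loose-but-not-tight voxel copies the sphere coordinate of its
  Euclidean-nearest tight voxel (world mm; ties resolve to the lowest
  linear index, x fastest).

Flat (x-fastest / Fortran) voxel order is used for every linearized
volume array in this module so the dilation tie-break is well defined
on anisotropic grids too.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from .errors import ValidationError
from .formats_io import TriangleMesh, VolumeImage, read_volume, write_volume
from .surfaces import (
    SphericalRegistration,
    nearest_with_ties,
    normalize_rows,
    template_vertex_to_subject_point,
)
from .transforms import AffineTransform, TransformChain, _world_to_voxel

__all__ = [
    "SubjectBundle",
    "VolToSurfMapping",
    "SurfToVolMapping",
    "build_vol2surf",
    "per_subject_vertex_coords",
    "average_partial",
    "build_surf2vol",
    "dilate_mapping",
    "finalize_surf2vol",
    "build_affine_baseline",
    "build_single_registration_baseline",
    "save_vol2surf",
    "load_vol2surf",
    "save_surf2vol",
    "load_surf2vol",
]


@dataclass
class SubjectBundle:
    """Everything fusion needs from one subject.

    ``vol_chain`` maps template-volume points into subject anatomical
    space (the pull-back direction for resampling subject images onto
    the template grid); ``inverse_vol_chain`` maps subject points back
    into the template (used to push surface vertices).  ``ribbon_mask``
    is the subject's binary cortical-ribbon volume in subject space.
    """

    subject_id: str
    vol_chain: TransformChain
    inverse_vol_chain: TransformChain
    reg: SphericalRegistration
    ribbon_mask: VolumeImage

    def __post_init__(self):
        if not np.any(self.ribbon_mask.data):
            raise ValidationError(f"subject {self.subject_id}: empty ribbon mask")


@dataclass
class VolToSurfMapping:
    """Averaged template-volume world coordinate per template-surface vertex."""

    coords: np.ndarray  # (V, 3) world mm
    n_subjects: int
    counts: np.ndarray | None = None  # contributing subjects per vertex

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("vol2surf coords must be (V, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("vol2surf coords must be finite")

    @property
    def n_vertices(self) -> int:
        return len(self.coords)


@dataclass
class SurfToVolMapping:
    """Averaged common-sphere coordinate, coverage and masks per template voxel.

    ``sphere_coords`` holds the renormalized mean unit vector per voxel
    (NaN where no subject contributed or the mean degenerated);
    ``vertex_index`` is -1 until :func:`finalize_surf2vol` assigns the
    nearest template-sphere vertex on the loose mask.
    """

    shape: tuple
    affine: np.ndarray
    sphere_coords: np.ndarray  # (X, Y, Z, 3)
    coverage: np.ndarray  # (X, Y, Z) in [0, 1]
    tight_mask: np.ndarray  # bool
    loose_mask: np.ndarray  # bool
    tight_thresh: float
    loose_thresh: float
    n_subjects: int
    vertex_index: np.ndarray | None = None  # (X, Y, Z) int32, -1 outside loose mask

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        self.affine = np.asarray(self.affine, dtype=float)
        if not (self.coverage.min() >= 0 and self.coverage.max() <= 1):
            raise ValidationError("coverage fraction must lie in [0, 1]")
        if np.any(self.tight_mask & ~self.loose_mask):
            raise ValidationError("tight mask must be a subset of the loose mask")

    def voxel_centers(self) -> np.ndarray:
        idx = np.stack(
            np.unravel_index(np.arange(int(np.prod(self.shape))), self.shape, order="F"), axis=1
        )
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


# ---------------------------------------------------------------------------
# volume -> surface direction
# ---------------------------------------------------------------------------


def per_subject_vertex_coords(
    bundle: SubjectBundle, template_sphere: TriangleMesh
) -> np.ndarray:
    """One subject's composed mapping: template-volume coordinate per
    template vertex; NaN rows where the vertex left the subject's field
    hull and the subject cannot contribute."""
    p = template_vertex_to_subject_point(bundle.reg, None, template_sphere=template_sphere)
    return bundle.inverse_vol_chain.map_points(p, oob="nan")


def build_vol2surf(
    cohort: list[SubjectBundle], template_sphere: TriangleMesh
) -> VolToSurfMapping:
    """Average the composed per-subject vertex mappings across the cohort."""
    if len(cohort) == 0:
        raise ValidationError("cohort must contain at least one subject")
    n_vertices = template_sphere.n_vertices
    total = np.zeros((n_vertices, 3), dtype=float)
    counts = np.zeros(n_vertices, dtype=np.int64)
    for bundle in cohort:
        q = per_subject_vertex_coords(bundle, template_sphere)
        valid = np.all(np.isfinite(q), axis=1)
        n_dropped = int((~valid).sum())
        if n_dropped:
            warnings.warn(
                f"subject {bundle.subject_id}: {n_dropped} vertices unmappable "
                "(outside field hull); excluded from the average",
                stacklevel=2,
            )
        total[valid] += q[valid]
        counts += valid
    if np.any(counts == 0):
        raise ValidationError(
            f"{int((counts == 0).sum())} template vertices received no contribution "
            "from any subject"
        )
    return VolToSurfMapping(total / counts[:, None], n_subjects=len(cohort), counts=counts)


def average_partial(
    cohort: list[SubjectBundle],
    template_sphere: TriangleMesh,
    indices: list[int] | np.ndarray,
) -> VolToSurfMapping:
    """The fusion mapping restricted to a cohort subset (deterministic in order)."""
    indices = list(indices)
    if len(indices) == 0:
        raise ValidationError("subset must be non-empty")
    return build_vol2surf([cohort[i] for i in indices], template_sphere)


# ---------------------------------------------------------------------------
# surface -> volume direction
# ---------------------------------------------------------------------------


def build_surf2vol(
    cohort: list[SubjectBundle],
    template_shape: tuple[int, int, int],
    template_affine: np.ndarray,
    tight_thresh: float = 0.50,
    loose_thresh: float = 0.15,
) -> SurfToVolMapping:
    """Accumulate per-voxel sphere coordinates and coverage over the cohort."""
    if len(cohort) == 0:
        raise ValidationError("cohort must contain at least one subject")
    if not (0 < loose_thresh <= tight_thresh <= 1):
        raise ValidationError(
            f"need 0 < loose_thresh <= tight_thresh <= 1, got loose={loose_thresh}, "
            f"tight={tight_thresh}"
        )
    template_affine = np.asarray(template_affine, dtype=float)
    shape = tuple(int(s) for s in template_shape)
    n_vox = int(np.prod(shape))
    idx = np.stack(np.unravel_index(np.arange(n_vox), shape, order="F"), axis=1)
    centers = idx @ template_affine[:3, :3].T + template_affine[:3, 3]

    acc = np.zeros((n_vox, 3), dtype=float)
    cnt = np.zeros(n_vox, dtype=np.int64)
    for bundle in cohort:
        y = bundle.vol_chain.map_points(centers, oob="clamp")
        rib = bundle.ribbon_mask
        vox = _world_to_voxel(rib.affine, y)
        nearest_idx = np.round(vox).astype(int)
        inside = np.all((nearest_idx >= 0) & (nearest_idx < np.array(rib.shape)), axis=1)
        in_ribbon = np.zeros(n_vox, dtype=bool)
        ii = nearest_idx[inside]
        in_ribbon[inside] = rib.data[ii[:, 0], ii[:, 1], ii[:, 2]] > 0.5
        if not np.any(in_ribbon):
            continue
        vi = nearest_with_ties(bundle.reg.subject_mesh.vertices, y[in_ribbon])
        acc[in_ribbon] += bundle.reg.sphere_coords[vi]
        cnt[in_ribbon] += 1

    if cnt.sum() == 0:
        raise ValidationError(
            "no template voxel landed in any subject's ribbon: cohort/template mismatch"
        )
    coverage = cnt / float(len(cohort))
    mean = np.full((n_vox, 3), np.nan)
    covered = cnt > 0
    mean[covered] = acc[covered] / cnt[covered, None]
    norms = np.linalg.norm(mean, axis=1)
    ok = covered & (norms > 1e-12)
    mean[ok] /= norms[ok, None]
    mean[covered & ~ok] = np.nan  # antipodal cancellation: flagged, not guessed

    sphere_coords = np.empty(shape + (3,), dtype=float)
    for c in range(3):
        sphere_coords[..., c] = mean[:, c].reshape(shape, order="F")
    coverage_vol = coverage.reshape(shape, order="F")
    return SurfToVolMapping(
        shape=shape,
        affine=template_affine,
        sphere_coords=sphere_coords,
        coverage=coverage_vol,
        tight_mask=coverage_vol >= tight_thresh,
        loose_mask=coverage_vol >= loose_thresh,
        tight_thresh=tight_thresh,
        loose_thresh=loose_thresh,
        n_subjects=len(cohort),
    )


def dilate_mapping(m: SurfToVolMapping) -> SurfToVolMapping:
    """Grow the tight-mask mapping outward to fill the loose mask.

    Every loose-but-not-tight voxel receives the sphere coordinate (and
    final vertex, if already assigned) of its Euclidean-nearest tight
    voxel, with distances measured between voxel centers in world mm;
    ties resolve to the lowest linear index (x fastest).  Tight-voxel
    assignments are untouched.
    """
    if not np.any(m.tight_mask):
        raise ValidationError("cannot dilate: tight mask is empty")
    centers = m.voxel_centers()
    tight_flat = m.tight_mask.ravel(order="F")
    loose_flat = m.loose_mask.ravel(order="F")
    grow = loose_flat & ~tight_flat
    sphere = np.array([m.sphere_coords[..., c].ravel(order="F") for c in range(3)]).T
    vertex = None if m.vertex_index is None else m.vertex_index.ravel(order="F").copy()

    tight_lin = np.nonzero(tight_flat)[0]  # ascending == lowest-linear-index order
    grow_lin = np.nonzero(grow)[0]
    if grow_lin.size:
        nearest = nearest_with_ties(centers[tight_lin], centers[grow_lin])
        src = tight_lin[nearest]
        sphere[grow_lin] = sphere[src]
        if vertex is not None:
            vertex[grow_lin] = vertex[src]

    new_sphere = np.empty_like(m.sphere_coords)
    for c in range(3):
        new_sphere[..., c] = sphere[:, c].reshape(m.shape, order="F")
    new_vertex = None
    if vertex is not None:
        new_vertex = vertex.reshape(m.shape, order="F")
    return replace(m, sphere_coords=new_sphere, vertex_index=new_vertex)


def finalize_surf2vol(m: SurfToVolMapping, template_sphere: TriangleMesh) -> SurfToVolMapping:
    """Assign each loose-mask voxel the template-sphere vertex nearest to
    its averaged (renormalized) sphere coordinate.

    Voxels whose average degenerated (antipodal cancellation) are
    excluded from the loose mask with a warning.
    """
    verts = normalize_rows(template_sphere.vertices)
    loose_flat = m.loose_mask.ravel(order="F")
    sphere = np.array([m.sphere_coords[..., c].ravel(order="F") for c in range(3)]).T
    loose_lin = np.nonzero(loose_flat)[0]
    valid = np.all(np.isfinite(sphere[loose_lin]), axis=1)
    if not np.all(valid):
        warnings.warn(
            f"{int((~valid).sum())} loose-mask voxels have no usable averaged sphere "
            "coordinate (degenerate average); excluded from the final mapping",
            stacklevel=2,
        )
    keep = loose_lin[valid]
    vertex = np.full(int(np.prod(m.shape)), -1, dtype=np.int32)
    if keep.size:
        vertex[keep] = nearest_with_ties(verts, sphere[keep]).astype(np.int32)
    new_loose = np.zeros_like(loose_flat)
    new_loose[keep] = True
    return replace(
        m,
        vertex_index=vertex.reshape(m.shape, order="F"),
        loose_mask=new_loose.reshape(m.shape, order="F"),
        tight_mask=m.tight_mask & new_loose.reshape(m.shape, order="F"),
    )


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


def build_affine_baseline(
    affine: AffineTransform,
    anatomical_surface: TriangleMesh,
    template_sphere: TriangleMesh,
    ribbon: VolumeImage,
    template_shape: tuple[int, int, int],
    template_affine: np.ndarray,
    tight_thresh: float = 0.50,
    loose_thresh: float = 0.15,
) -> tuple[VolToSurfMapping, SurfToVolMapping]:
    """Single-affine baseline: push the supplied vertex-to-volume table
    through the affine (and its inverse) and run the same mask/dilation
    machinery with the single "subject's" ribbon.

    ``affine`` maps template-volume space into the space the anatomical
    surface and ribbon live in (the surface-template volume).
    """
    bundle = SubjectBundle(
        subject_id="affine-baseline",
        vol_chain=TransformChain([affine]),
        inverse_vol_chain=TransformChain([affine.inverse()]),
        reg=SphericalRegistration(
            anatomical_surface, normalize_rows(template_sphere.vertices), template_sphere
        ),
        ribbon_mask=ribbon,
    )
    v2s = build_vol2surf([bundle], template_sphere)
    s2v = build_surf2vol(
        [bundle], template_shape, template_affine, tight_thresh, loose_thresh
    )
    return v2s, s2v


def build_single_registration_baseline(
    template_bundle: SubjectBundle,
    template_sphere: TriangleMesh,
    template_shape: tuple[int, int, int],
    template_affine: np.ndarray,
    tight_thresh: float = 0.50,
    loose_thresh: float = 0.15,
) -> tuple[VolToSurfMapping, SurfToVolMapping]:
    """One-registration baseline: the identical fusion pipeline with N = 1.

    The "subject" is the volumetric template itself, processed once
    through the surface pipeline (the MNIsurf-style construction).
    """
    v2s = build_vol2surf([template_bundle], template_sphere)
    s2v = build_surf2vol(
        [template_bundle], template_shape, template_affine, tight_thresh, loose_thresh
    )
    return v2s, s2v


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _sidecar(path: Path, payload: dict):
    payload = {"software": "volsurf", "version": _pkg_version, **payload}
    path.write_text(json.dumps(payload, indent=2) + "\n")


def save_vol2surf(m: VolToSurfMapping, directory, subject_ids: list[str] | None = None) -> Path:
    """Write the per-vertex coordinate table (CSV) plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = "x,y,z"
    np.savetxt(directory / "vol2surf_coords.csv", m.coords, fmt="%.17g", delimiter=",",
               header=header, comments="")
    _sidecar(
        directory / "vol2surf.json",
        {
            "direction": "vol2surf",
            "n_subjects": int(m.n_subjects),
            "n_vertices": int(m.n_vertices),
            "subject_ids": subject_ids,
        },
    )
    return directory


def load_vol2surf(directory) -> VolToSurfMapping:
    directory = Path(directory)
    coords = np.loadtxt(directory / "vol2surf_coords.csv", delimiter=",", skiprows=1)
    meta = json.loads((directory / "vol2surf.json").read_text())
    return VolToSurfMapping(coords, n_subjects=int(meta["n_subjects"]))


def save_surf2vol(m: SurfToVolMapping, directory, subject_ids: list[str] | None = None) -> Path:
    """Write coordinate/index/mask volumes (NIfTI) plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    import nibabel as nib  # local: only this writer needs the 4-D container

    img = nib.Nifti1Image(np.nan_to_num(m.sphere_coords, nan=0.0), m.affine)
    nib.save(img, str(directory / "surf2vol_sphere_coords.nii"))
    write_volume(VolumeImage(m.coverage, m.affine), directory / "surf2vol_coverage.nii")
    write_volume(
        VolumeImage(m.tight_mask.astype(np.uint8), m.affine), directory / "surf2vol_tight.nii"
    )
    write_volume(
        VolumeImage(m.loose_mask.astype(np.uint8), m.affine), directory / "surf2vol_loose.nii"
    )
    if m.vertex_index is not None:
        write_volume(
            VolumeImage(m.vertex_index.astype(np.int32), m.affine),
            directory / "surf2vol_vertex_index.nii",
        )
    _sidecar(
        directory / "surf2vol.json",
        {
            "direction": "surf2vol",
            "n_subjects": int(m.n_subjects),
            "tight_thresh": m.tight_thresh,
            "loose_thresh": m.loose_thresh,
            "finalized": m.vertex_index is not None,
            "subject_ids": subject_ids,
        },
    )
    return directory


def load_surf2vol(directory) -> SurfToVolMapping:
    directory = Path(directory)
    import nibabel as nib

    meta = json.loads((directory / "surf2vol.json").read_text())
    img = nib.load(str(directory / "surf2vol_sphere_coords.nii"))
    sphere = np.asanyarray(img.dataobj).astype(float)
    affine = np.asarray(img.affine)
    coverage = read_volume(directory / "surf2vol_coverage.nii").data.astype(float)
    tight = read_volume(directory / "surf2vol_tight.nii").data > 0
    loose = read_volume(directory / "surf2vol_loose.nii").data > 0
    sphere[~loose] = np.nan
    vertex = None
    if meta.get("finalized"):
        vertex = read_volume(directory / "surf2vol_vertex_index.nii").data.astype(np.int32)
    return SurfToVolMapping(
        shape=sphere.shape[:3],
        affine=affine,
        sphere_coords=sphere,
        coverage=coverage,
        tight_mask=tight,
        loose_mask=loose,
        tight_thresh=float(meta["tight_thresh"]),
        loose_thresh=float(meta["loose_thresh"]),
        n_subjects=int(meta["n_subjects"]),
        vertex_index=vertex,
    )
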