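"""Apply finished mappings to data: volume-to-surface and
surface-to-volume projection, probabilistic-map construction, and
winner-takes-all fusion.

Probabilistic maps are per-structure scalar fields (fraction of
subjects carrying the label at each location) and may be projected with
smooth interpolation; hard labels are always projected with nearest
assignment so no label is ever invented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import ValidationError
from .formats_io import LabelTable, TriangleMesh, VolumeImage
from .fusion import SurfToVolMapping, VolToSurfMapping
from .surfaces import barycentric_locate, normalize_rows
from .transforms import _world_to_voxel

__all__ = [
    "ProbabilisticMap",
    "Parcellation",
    "project_vol_to_surf",
    "project_surf_to_vol",
    "make_prob_maps",
    "winner_takes_all",
    "threshold_boundaries",
    "boundary_vertices",
]


@dataclass
class ProbabilisticMap:
    """Per-location probability per label (stacked along the first axis)."""

    probs: np.ndarray  # (L, *location_shape)
    label_ids: np.ndarray  # (L,), ascending positive ints
    n_subjects: int
    table: LabelTable | None = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.label_ids = np.asarray(self.label_ids, dtype=np.int64)
        if len(self.label_ids) != self.probs.shape[0]:
            raise ValidationError("one probability field per label required")
        if np.any(np.diff(self.label_ids) <= 0):
            raise ValidationError("label ids must be strictly ascending")
        if self.probs.size and (self.probs.min() < -1e-9 or self.probs.max() > 1 + 1e-9):
            raise ValidationError("probabilities must lie in [0, 1]")
        total = self.probs.sum(axis=0)
        if total.size and total.max(initial=0.0) > 1 + 1e-9:
            raise ValidationError("per-location probabilities must sum to at most 1")


@dataclass
class Parcellation:
    """Per-location integer labels; 0 means unlabeled."""

    labels: np.ndarray
    table: LabelTable | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("parcellation labels must be integers")


def _labels_of(parc) -> np.ndarray:
    return parc.labels if isinstance(parc, Parcellation) else np.asarray(parc)


def project_vol_to_surf(
    vol: VolumeImage, mapping: VolToSurfMapping, interp: str = "trilinear"
) -> np.ndarray:
    """Sample a template volume at every vertex's mapped coordinate.

    Coordinates outside the volume yield 0 and are counted in a single
    warning.  Integer (label) volumes require ``interp='nearest'``.
    """
    if interp not in ("trilinear", "nearest"):
        raise ValidationError(f"unknown interpolation {interp!r}")
    is_int = np.issubdtype(vol.data.dtype, np.integer) or vol.data.dtype == bool
    if is_int and interp != "nearest":
        raise ValidationError("label volumes must be projected with interp='nearest'")
    vox = _world_to_voxel(vol.affine, mapping.coords)
    shape = np.array(vol.shape, dtype=float)
    inside = np.all((vox >= -1e-9) & (vox <= shape - 1 + 1e-9), axis=1)
    n_out = int((~inside).sum())
    if n_out:
        warnings.warn(
            f"{n_out} of {len(vox)} mapped coordinates fall outside the volume; filled with 0",
            stacklevel=2,
        )
    out = ndi.map_coordinates(
        vol.data if is_int else vol.data.astype(float),
        vox.T,
        order=0 if interp == "nearest" else 1,
        mode="grid-constant",
        cval=0,
        prefilter=False,
    )
    return out


def project_surf_to_vol(
    data: np.ndarray,
    m: SurfToVolMapping,
    interp: str = "nearest",
    template_sphere: TriangleMesh | None = None,
) -> VolumeImage:
    """Project per-template-vertex data into the template volume.

    Nearest mode copies the datum of each loose-mask voxel's final
    vertex (the mapping must be finalized); barycentric mode blends the
    data of the sphere triangle containing the voxel's averaged sphere
    coordinate (scalar data only).  Voxels outside the loose mask are 0.
    """
    data = np.asarray(data)
    is_int = np.issubdtype(data.dtype, np.integer) or data.dtype == bool
    loose_flat = m.loose_mask.ravel(order="F")
    n_vox = int(np.prod(m.shape))
    out = np.zeros(n_vox, dtype=data.dtype if is_int else float)
    lin = np.nonzero(loose_flat)[0]
    if interp == "nearest":
        if m.vertex_index is None:
            raise ValidationError("mapping must be finalized before nearest projection")
        vi = m.vertex_index.ravel(order="F")[lin]
        out[lin] = data[vi]
    elif interp == "barycentric":
        if is_int:
            raise ValidationError("label data must be projected with interp='nearest'")
        if template_sphere is None:
            raise ValidationError("barycentric projection needs the template sphere mesh")
        sphere = np.array([m.sphere_coords[..., c].ravel(order="F")[lin] for c in range(3)]).T
        face_idx, w = barycentric_locate(
            TriangleMesh(normalize_rows(template_sphere.vertices), template_sphere.faces), sphere
        )
        corners = data[template_sphere.faces[face_idx]]
        out[lin] = np.einsum("nk,nk->n", w, corners)
    else:
        raise ValidationError(f"unknown interpolation {interp!r}")
    return VolumeImage(out.reshape(m.shape, order="F"), m.affine)


def make_prob_maps(
    parcellations: list,
    label_ids: np.ndarray | None = None,
    table: LabelTable | None = None,
) -> ProbabilisticMap:
    """Fraction of subjects carrying each label at each location."""
    if len(parcellations) == 0:
        raise ValidationError("need at least one parcellation")
    arrays = [_labels_of(p) for p in parcellations]
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise ValidationError("all parcellations must share the same shape")
    if label_ids is None:
        label_ids = np.unique(np.concatenate([np.unique(a) for a in arrays]))
        label_ids = label_ids[label_ids > 0]
    label_ids = np.asarray(label_ids, dtype=np.int64)
    probs = np.zeros((len(label_ids),) + shape, dtype=float)
    for a in arrays:
        for i, label in enumerate(label_ids):
            probs[i] += a == label
    probs /= len(arrays)
    return ProbabilisticMap(probs, label_ids, n_subjects=len(arrays), table=table)


def winner_takes_all(p: ProbabilisticMap) -> Parcellation:
    """Per location, the label with the highest probability.

    Unlabeled (0) never competes: a location wins 0 only when every
    structure probability is 0 there.  Ties resolve to the lowest id.
    """
    if len(p.label_ids) == 0:
        raise ValidationError("probabilistic map has no labels")
    best = np.argmax(p.probs, axis=0)  # first occurrence == lowest label id
    best_prob = np.take_along_axis(p.probs, best[None], axis=0)[0]
    labels = p.label_ids[best]
    labels = np.where(best_prob > 0, labels, 0).astype(np.int32)
    return Parcellation(labels, table=p.table)


def boundary_vertices(labels, mesh: TriangleMesh) -> np.ndarray:
    """Boolean mask of vertices with at least one differently-labeled neighbor."""
    labels = _labels_of(labels)
    if len(labels) != mesh.n_vertices:
        raise ValidationError("label array length must equal the vertex count")
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    differs = labels[edges[:, 0]] != labels[edges[:, 1]]
    out = np.zeros(mesh.n_vertices, dtype=bool)
    out[edges[differs].ravel()] = True
    return out


def threshold_boundaries(
    p: ProbabilisticMap, mesh: TriangleMesh
) -> tuple[Parcellation, np.ndarray]:
    """Winner-takes-all parcellation plus its boundary-vertex indicator."""
    parc = winner_takes_all(p)
    return parc, boundary_vertices(parc, mesh)
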