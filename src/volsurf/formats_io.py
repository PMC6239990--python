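"""Readers and writers for every on-disk artifact the toolkit touches.

Conventions, enforced at this boundary and assumed everywhere downstream:

* world coordinates are RAS millimetres; volumes read from disk are
  reoriented to the closest canonical (RAS) orientation on load;
* voxel indices are 0-based;
* label id 0 is background / unlabeled and never names a structure;
* displacement fields are exchanged as 4-D NIfTI images whose fourth
  axis holds exactly three scalar volumes: the x, y, z components of a
  world-space (mm) displacement sampled on the field's own grid;
* meshes are GIFTI (``.gii``) or a plain-text dialect (header line
  ``<n_vertices> <n_faces>``, then vertex rows, then 0-based face rows);
* affines are whitespace-separated 4x4 text files; label tables are CSV.

Integer payloads round-trip bit-exactly; float payloads round-trip to
the storage precision of the chosen container (GIFTI pointsets are
float32, the text dialect and NIfTI float64 volumes are exact).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError

__all__ = [
    "VolumeImage",
    "VectorField",
    "TriangleMesh",
    "LabelTable",
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
    "read_mesh",
    "write_mesh",
    "read_labels",
    "write_labels",
    "read_affine",
    "write_affine",
    "read_vertex_data",
    "write_vertex_data",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VolumeImage:
    """A scalar or integer 3-D grid with a voxel-to-world (RAS mm) affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"volume payload must be 3-D, got {self.data.ndim}-D")
        if self.affine.shape != (4, 4):
            raise FormatError("voxel-to-world affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("voxel-to-world affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_centers(self) -> np.ndarray:
        """World (mm) coordinates of all voxel centers, x-fastest order, (n, 3)."""
        idx = np.stack(
            np.unravel_index(np.arange(self.data.size), self.shape, order="F"), axis=1
        )
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class VectorField:
    """World-space mm displacement vectors sampled on the field's own grid.

    ``vectors`` has shape (X, Y, Z, 3); ``grid_affine`` maps the field's
    0-based voxel indices to world mm.
    """

    vectors: np.ndarray
    grid_affine: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.grid_affine = np.asarray(self.grid_affine, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[3] != 3:
            raise FormatError(
                f"vector field must have exactly 3 components per node, got shape {self.vectors.shape}"
            )
        if self.grid_affine.shape != (4, 4) or abs(np.linalg.det(self.grid_affine[:3, :3])) < 1e-12:
            raise FormatError("field grid affine must be an invertible 4x4 matrix")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]


@dataclass
class TriangleMesh:
    """Vertices (world mm) and 0-based triangular faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise FormatError("mesh vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise FormatError("mesh faces must be (m, 3)")
        if not np.issubdtype(self.faces.dtype, np.integer):
            if not np.all(self.faces == np.round(self.faces)):
                raise FormatError("face indices must be integers")
            self.faces = self.faces.astype(np.int64)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise FormatError("face indices out of range")
        if self.faces.size:
            f = self.faces
            degenerate = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            if degenerate.any():
                raise FormatError(f"{int(degenerate.sum())} degenerate faces (repeated vertex index)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def is_closed(self) -> bool:
        """True when every directed edge is matched by its reverse (closed, orientable)."""
        f = self.faces
        edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        fwd = set(map(tuple, edges))
        return all((b, a) in fwd for a, b in fwd)


@dataclass
class LabelTable:
    """Positive integer label ids mapped to names and display colors.

    Id 0 is reserved for background and may never appear as an entry.
    """

    entries: dict = field(default_factory=dict)  # id -> (name, color)

    def __post_init__(self):
        for label_id in self.entries:
            if int(label_id) <= 0:
                raise FormatError("label ids must be positive; 0 is reserved for background")

    @property
    def ids(self) -> list[int]:
        return sorted(int(k) for k in self.entries)

    def name(self, label_id: int) -> str:
        return self.entries[label_id][0]


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


def _load_nifti(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        # force the payload now so truncated files fail here, not downstream
        np.asanyarray(img.dataobj)
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path}: {exc}") from exc
    return img


def read_volume(path) -> VolumeImage:
    """Read a 3-D NIfTI-1 volume, reoriented to RAS."""
    img = _load_nifti(path)
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got {img.ndim}-D")
    img = nib.as_closest_canonical(img)
    return VolumeImage(np.asanyarray(img.dataobj), np.asarray(img.affine))


def write_volume(vol: VolumeImage, path) -> Path:
    """Write a volume as NIfTI-1. Integer data is stored as int32 (bit-exact)."""
    data = vol.data
    if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, vol.affine)
    img.set_sform(vol.affine, code=1)
    img.set_qform(vol.affine, code=1)
    path = Path(path)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# displacement fields
# ---------------------------------------------------------------------------


def read_field(path) -> VectorField:
    """Read a dense displacement field (4-D NIfTI with three component volumes)."""
    img = _load_nifti(path)
    if img.ndim != 4:
        raise FormatError(f"{path}: expected a 4-D vector image, got {img.ndim}-D")
    if img.shape[3] != 3:
        raise FormatError(
            f"{path}: vector payload must have exactly 3 components, got {img.shape[3]}"
        )
    # Reorienting permutes/flips the *grid* axes only; the fourth axis holds
    # world-space component volumes, which are orientation-invariant.
    img = nib.as_closest_canonical(img)
    return VectorField(np.asanyarray(img.dataobj), np.asarray(img.affine))


def write_field(fieldv: VectorField, path) -> Path:
    img = nib.Nifti1Image(fieldv.vectors.astype(np.float64), fieldv.grid_affine)
    img.set_sform(fieldv.grid_affine, code=1)
    img.set_qform(fieldv.grid_affine, code=1)
    path = Path(path)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# meshes and per-vertex data
# ---------------------------------------------------------------------------


def read_mesh(path) -> TriangleMesh:
    """Read a GIFTI (``.gii``) or plain-text mesh."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".gii":
        try:
            img = nib.load(str(path))
            verts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
            faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
        except IndexError as exc:
            raise FormatError(f"{path}: GIFTI file lacks pointset/triangle arrays") from exc
        except Exception as exc:
            raise FormatError(f"cannot read {path}: {exc}") from exc
        return TriangleMesh(np.asarray(verts, dtype=float), np.asarray(faces, dtype=np.int64))
    return _read_text_mesh(path)


def _read_text_mesh(path: Path) -> TriangleMesh:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: text mesh header must be '<n_vertices> <n_faces>'")
        try:
            nv, nf = int(header[0]), int(header[1])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed text mesh header") from exc
        rows = [line.split() for line in fh if line.strip()]
    if len(rows) != nv + nf:
        raise FormatError(f"{path}: expected {nv + nf} rows, found {len(rows)}")
    try:
        verts = np.array([[float(x) for x in r] for r in rows[:nv]], dtype=float)
        faces = np.array([[int(x) for x in r] for r in rows[nv:]], dtype=np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed mesh row") from exc
    if nv and verts.shape[1] != 3 or nf and faces.shape[1] != 3:
        raise FormatError(f"{path}: mesh rows must have 3 entries")
    return TriangleMesh(verts, faces)


def write_mesh(mesh: TriangleMesh, path) -> Path:
    """Write a mesh as GIFTI (float32 pointset) or exact plain text."""
    path = Path(path)
    if path.suffix == ".gii":
        darrays = [
            nib.gifti.GiftiDataArray(
                mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            nib.gifti.GiftiDataArray(
                mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
        nib.save(nib.gifti.GiftiImage(darrays=darrays), str(path))
        return path
    with open(path, "w") as fh:
        fh.write(f"{mesh.n_vertices} {len(mesh.faces)}\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"{f[0]} {f[1]} {f[2]}\n")
    return path


def write_vertex_data(values: np.ndarray, path) -> Path:
    """One value per line; integers verbatim, floats at full precision."""
    values = np.asarray(values)
    path = Path(path)
    fmt = "%d" if np.issubdtype(values.dtype, np.integer) else "%.17g"
    np.savetxt(path, values.reshape(len(values), -1), fmt=fmt)
    return path


def read_vertex_data(path, dtype=float) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        out = np.loadtxt(path, dtype=dtype, ndmin=1)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed per-vertex data") from exc
    return out


# ---------------------------------------------------------------------------
# label tables and affines
# ---------------------------------------------------------------------------


def write_labels(table: LabelTable, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "name", "color"])
        for label_id in table.ids:
            name, color = table.entries[label_id]
            writer.writerow([label_id, name, color])
    return path


def read_labels(path) -> LabelTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "name", "color"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: label CSV needs columns id,name,color")
        for row in reader:
            try:
                label_id = int(row["id"])
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer label id {row['id']!r}") from exc
            if label_id in entries:
                raise FormatError(f"{path}: duplicate label id {label_id}")
            entries[label_id] = (row["name"], row["color"])
    return LabelTable(entries)


def write_affine(matrix: np.ndarray, path) -> Path:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise FormatError("affine must be 4x4")
    np.savetxt(Path(path), matrix, fmt="%.17g")
    return Path(path)


def read_affine(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        matrix = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed affine file") from exc
    if matrix.shape != (4, 4):
        raise FormatError(f"{path}: affine must be 4 rows of 4 numbers, got {matrix.shape}")
    return matrix
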