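r"""Point-mapping algebra for affine and dense nonlinear transforms.

A transform maps world (RAS mm) points from a named source space to a
named target space.  Dense transforms are displacement fields: a point
``x`` maps to ``x + u(x)`` where the world-mm displacement ``u`` is
interpolated trilinearly on the field's own grid.  Chains apply their
steps sequentially (lazy composition); :func:`bake_chain` collapses a
chain to a single dense field on a stated grid for export.

Image resampling follows the pull-back convention throughout: to
resample an image from space A onto a grid in space B, the chain must
map B points to A points; each B voxel center is pushed through the
chain and the A image is sampled there.

Field inversion uses the standard fixed-point iteration for
displacement fields,

    v_{k+1}(x) = -u(x + v_k(x)),        v_0(x) = -u(x),

which converges for smooth, moderate-amplitude (invertible) fields and
stops when the max update falls below ``tol`` millimetres.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .errors import FieldInversionError, OutOfHullError, ValidationError
from .formats_io import (
    VectorField,
    VolumeImage,
    read_affine,
    read_field,
    write_affine,
    write_field,
)

__all__ = [
    "AffineTransform",
    "DenseTransform",
    "TransformChain",
    "sample_field",
    "invert_field",
    "resample_volume",
    "bake_chain",
    "save_chain",
    "load_chain",
]

_OOB_MODES = ("error", "zero", "nan", "clamp")


def _world_to_voxel(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return points @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class AffineTransform:
    """A world-to-world 4x4 affine (mm). Last row must be (0, 0, 0, 1)."""

    matrix: np.ndarray
    source: str | None = None
    target: str | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValidationError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-9):
            raise ValidationError("affine last row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValidationError("affine matrix is singular")

    def apply(self, points: np.ndarray, oob: str | None = None) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), source=self.target, target=self.source)


def sample_field(fieldv: VectorField, points: np.ndarray, oob: str = "error") -> np.ndarray:
    """Trilinearly interpolate world-mm displacement vectors at world points.

    Out-of-hull policy ``oob``: ``error`` (default), ``zero`` (zero
    displacement with a warning), ``nan`` (NaN rows, silent) or
    ``clamp`` (clamp to the nearest grid node, silent).
    """
    if oob not in _OOB_MODES:
        raise ValidationError(f"unknown out-of-hull policy {oob!r}")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    vox = _world_to_voxel(fieldv.grid_affine, points)
    shape = np.array(fieldv.grid_shape, dtype=float)
    eps = 1e-9
    inside = np.all((vox >= -eps) & (vox <= shape - 1 + eps), axis=1)
    n_out = int((~inside).sum())
    if n_out:
        if oob == "error":
            raise OutOfHullError(
                f"{n_out} of {len(points)} points fall outside the field grid hull"
            )
        if oob == "zero":
            warnings.warn(
                f"{n_out} points outside the field grid hull; zero displacement assumed",
                stacklevel=2,
            )
    disp = np.empty_like(points)
    coords = vox.T
    for c in range(3):
        disp[:, c] = ndi.map_coordinates(
            fieldv.vectors[..., c], coords, order=1, mode="nearest"
        )
    if n_out:
        if oob == "zero":
            disp[~inside] = 0.0
        elif oob == "nan":
            disp[~inside] = np.nan
    return disp


@dataclass
class DenseTransform:
    """A dense displacement-field transform: x -> x + u(x)."""

    field: VectorField
    source: str | None = None
    target: str | None = None
    residual: float | None = None  # achieved inversion residual (mm), if inverted

    def __post_init__(self):
        if not np.all(np.isfinite(self.field.vectors)):
            raise ValidationError("dense transform field must be finite everywhere")

    def apply(self, points: np.ndarray, oob: str = "error") -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points + sample_field(self.field, points, oob=oob)


Transform = AffineTransform | DenseTransform


@dataclass
class TransformChain:
    """An ordered list of transforms applied first-to-last."""

    steps: list = dc_field(default_factory=list)

    def __post_init__(self):
        for a, b in zip(self.steps, self.steps[1:]):
            if a.target is not None and b.source is not None and a.target != b.source:
                raise ValidationError(
                    f"inconsistent chain: step target {a.target!r} != next source {b.source!r}"
                )

    @property
    def source(self) -> str | None:
        return self.steps[0].source if self.steps else None

    @property
    def target(self) -> str | None:
        return self.steps[-1].target if self.steps else None

    def map_points(self, points: np.ndarray, oob: str = "error") -> np.ndarray:
        """Apply every step in order. The empty chain is the identity."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        for step in self.steps:
            points = step.apply(points, oob=oob)
        return points


def invert_field(
    transform: DenseTransform, tol: float = 0.01, max_iter: int = 50
) -> DenseTransform:
    """Invert a smooth displacement field by fixed-point iteration.

    Returns a :class:`DenseTransform` on the same grid with source and
    target swapped; ``result.residual`` reports the achieved max update
    (mm). Raises :class:`FieldInversionError` if the update is still
    above ``tol`` after ``max_iter`` iterations.
    """
    fieldv = transform.field
    shape = fieldv.grid_shape
    idx = np.stack(np.unravel_index(np.arange(np.prod(shape)), shape, order="F"), axis=1)
    x = idx @ fieldv.grid_affine[:3, :3].T + fieldv.grid_affine[:3, 3]
    u_flat = sample_field(fieldv, x, oob="clamp")
    v = -u_flat
    residual = float(np.abs(v).max(initial=0.0))
    if residual > 0:
        for _ in range(max_iter):
            v_new = -sample_field(fieldv, x + v, oob="clamp")
            residual = float(np.linalg.norm(v_new - v, axis=1).max())
            v = v_new
            if residual < tol:
                break
        else:
            raise FieldInversionError(
                f"field inversion did not reach tol={tol} mm in {max_iter} iterations "
                f"(residual {residual:.4g} mm); the field may be too large or non-invertible",
                residual=residual,
            )
    else:
        residual = 0.0
    inv_field = VectorField(_unflatten(v, shape), fieldv.grid_affine.copy())
    return DenseTransform(
        inv_field, source=transform.target, target=transform.source, residual=residual
    )


def _unflatten(flat: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Reshape (n, 3) rows in x-fastest order back to an (X, Y, Z, 3) grid."""
    out = np.empty(shape + (3,), dtype=flat.dtype)
    for c in range(3):
        out[..., c] = flat[:, c].reshape(shape, order="F")
    return out


def resample_volume(
    vol: VolumeImage,
    chain: TransformChain,
    target_shape: tuple[int, int, int] | None = None,
    target_affine: np.ndarray | None = None,
    interp: str = "trilinear",
    fill: float = 0.0,
) -> VolumeImage:
    """Resample ``vol`` onto a target grid through a pull-back chain.

    ``chain`` must map target-space points to source (``vol``) space.
    Each target voxel center is mapped through the chain and the source
    volume is sampled there; points outside the source volume get
    ``fill``. Integer (label) volumes require ``interp='nearest'``.
    """
    if interp not in ("trilinear", "nearest"):
        raise ValidationError(f"unknown interpolation {interp!r}")
    is_int = np.issubdtype(vol.data.dtype, np.integer) or vol.data.dtype == bool
    if is_int and interp != "nearest":
        raise ValidationError("integer (label) volumes must be resampled with interp='nearest'")
    if target_shape is None:
        target_shape = vol.shape
    if target_affine is None:
        target_affine = vol.affine
    target_affine = np.asarray(target_affine, dtype=float)
    idx = np.stack(
        np.unravel_index(np.arange(int(np.prod(target_shape))), target_shape, order="F"), axis=1
    )
    world = idx @ target_affine[:3, :3].T + target_affine[:3, 3]
    mapped = chain.map_points(world, oob="clamp")
    vox = _world_to_voxel(vol.affine, mapped)
    order = 0 if interp == "nearest" else 1
    flat = ndi.map_coordinates(
        vol.data.astype(float) if not is_int else vol.data,
        vox.T,
        order=order,
        mode="grid-constant",
        cval=fill,
        prefilter=False,
    )
    dtype = vol.data.dtype if is_int or order == 0 else float
    data = np.ascontiguousarray(flat.astype(dtype).reshape(target_shape, order="F"))
    return VolumeImage(data, target_affine)


def bake_chain(
    chain: TransformChain,
    grid_affine: np.ndarray,
    grid_shape: tuple[int, int, int],
    oob: str = "clamp",
) -> DenseTransform:
    """Collapse a chain to a single dense field sampled at grid nodes."""
    grid_affine = np.asarray(grid_affine, dtype=float)
    idx = np.stack(
        np.unravel_index(np.arange(int(np.prod(grid_shape))), grid_shape, order="F"), axis=1
    )
    x = idx @ grid_affine[:3, :3].T + grid_affine[:3, 3]
    disp = chain.map_points(x, oob=oob) - x
    return DenseTransform(
        VectorField(_unflatten(disp, tuple(grid_shape)), grid_affine),
        source=chain.source,
        target=chain.target,
    )


# ---------------------------------------------------------------------------
# chain serialization: an ordered text manifest plus affine/field files
# ---------------------------------------------------------------------------


def save_chain(chain: TransformChain, directory, stem: str = "chain") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, step in enumerate(chain.steps):
        if isinstance(step, AffineTransform):
            fname = f"{stem}_{i:02d}_affine.txt"
            write_affine(step.matrix, directory / fname)
            entries.append(
                {"kind": "affine", "file": fname, "source": step.source, "target": step.target}
            )
        else:
            fname = f"{stem}_{i:02d}_field.nii"
            write_field(step.field, directory / fname)
            entries.append(
                {"kind": "field", "file": fname, "source": step.source, "target": step.target}
            )
    manifest = directory / f"{stem}_manifest.json"
    manifest.write_text(json.dumps({"steps": entries}, indent=2) + "\n")
    return manifest


def load_chain(manifest_path) -> TransformChain:
    manifest_path = Path(manifest_path)
    spec = json.loads(manifest_path.read_text())
    steps: list = []
    for entry in spec["steps"]:
        path = manifest_path.parent / entry["file"]
        if entry["kind"] == "affine":
            steps.append(
                AffineTransform(read_affine(path), source=entry["source"], target=entry["target"])
            )
        elif entry["kind"] == "field":
            steps.append(
                DenseTransform(read_field(path), source=entry["source"], target=entry["target"])
            )
        else:
            raise ValidationError(f"unknown chain step kind {entry['kind']!r}")
    return TransformChain(steps)
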