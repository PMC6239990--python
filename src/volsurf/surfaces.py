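"""Spherical-mesh machinery: nearest-vertex queries, barycentric location
on the sphere, and resampling per-vertex data between a subject mesh and
the template mesh through their common spherical coordinates.

A spherical registration assigns every vertex of a subject's anatomical
mesh a position on the common unit sphere.  Locating a template-sphere
vertex inside the subject's spherical mesh (gnomonic projection onto the
candidate face plane) yields barycentric weights that transfer data in
either direction, or pull the template vertex to a concrete point on the
subject's anatomical surface.

Tie-breaks everywhere: the lowest index wins.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .formats_io import TriangleMesh

__all__ = [
    "SphericalRegistration",
    "nearest_vertex",
    "barycentric_locate",
    "resample_to_template",
    "template_vertex_to_subject_point",
]


def normalize_rows(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norms = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValidationError("cannot normalize zero-length sphere coordinates")
    return v / norms


class SphericalRegistration:
    """Per-vertex correspondence of a subject mesh to the common sphere.

    Parameters
    ----------
    subject_mesh:
        The subject's anatomical sampling surface (world mm).
    sphere_coords:
        Position of each subject vertex on the common sphere.  Any
        radius (e.g. the conventional 100 mm sphere) is accepted and
        normalized to unit length on construction.
    template_sphere:
        The template mesh on the same sphere (normalized likewise).
    """

    def __init__(
        self,
        subject_mesh: TriangleMesh,
        sphere_coords: np.ndarray,
        template_sphere: TriangleMesh,
    ):
        sphere_coords = np.asarray(sphere_coords, dtype=float)
        if sphere_coords.shape != (subject_mesh.n_vertices, 3):
            raise ValidationError(
                "need exactly one sphere position per subject vertex "
                f"({subject_mesh.n_vertices}), got shape {sphere_coords.shape}"
            )
        self.subject_mesh = subject_mesh
        self.sphere_coords = normalize_rows(sphere_coords)
        self.template_sphere = TriangleMesh(
            normalize_rows(template_sphere.vertices), template_sphere.faces
        )
        self._sphere_mesh = TriangleMesh(self.sphere_coords, subject_mesh.faces)

    @property
    def sphere_mesh(self) -> TriangleMesh:
        """The subject mesh's topology realized on the common sphere."""
        return self._sphere_mesh


def nearest_vertex(mesh, points: np.ndarray) -> np.ndarray:
    """Index of the Euclidean-nearest vertex per query point (ties: lowest index)."""
    verts = mesh.vertices if isinstance(mesh, TriangleMesh) else np.asarray(mesh, dtype=float)
    if len(verts) == 0:
        raise ValidationError("cannot query an empty mesh")
    return nearest_with_ties(verts, points)


def nearest_with_ties(ref_points: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Nearest reference index per query, resolving exact ties to the lowest index."""
    ref = np.asarray(ref_points, dtype=float)
    q = np.atleast_2d(np.asarray(query, dtype=float))
    tree = cKDTree(ref)
    if len(ref) == 1:
        return np.zeros(len(q), dtype=np.int64)
    d, i = tree.query(q, k=2)
    idx = i[:, 0].astype(np.int64)
    d0 = d[:, 0]
    maybe_tied = np.nonzero(d[:, 1] - d0 <= 1e-9 * (1.0 + d0))[0]
    for j in maybe_tied:
        candidates = tree.query_ball_point(q[j], r=d0[j] * (1 + 1e-9) + 1e-12)
        idx[j] = min(candidates)
    return idx


def _solve_face_weights(tri: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Solve p = w0*v0 + w1*v1 + w2*v2 for each (face, point) pair.

    ``tri`` is (n, 3, 3) vertex triples; ``pts`` is (n, 3).  Falls back
    to least squares when a face plane is (numerically) degenerate.
    """
    A = tri.transpose(0, 2, 1)  # columns are the face vertices
    try:
        return np.linalg.solve(A, pts[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.empty_like(pts)
        for k in range(len(pts)):
            try:
                out[k] = np.linalg.solve(A[k], pts[k])
            except np.linalg.LinAlgError:
                out[k] = np.linalg.lstsq(A[k], pts[k], rcond=None)[0]
        return out


def barycentric_locate(
    sphere: TriangleMesh, points: np.ndarray, n_candidates: int = 32
) -> tuple[np.ndarray, np.ndarray]:
    """Locate unit-sphere points inside a closed spherical triangulation.

    For each point the candidate faces nearest by centroid are tested in
    order; a face contains the point when the gnomonic projection onto
    its plane has weights all >= -1e-9 with a positive sum.  Negative
    weights within tolerance are clipped to 0 and the weights are
    renormalized to sum to 1.  Points that no candidate face contains
    fall back to their nearest face with clipped weights.

    Returns ``(face_indices, weights)`` with shapes (n,) and (n, 3).
    """
    verts = normalize_rows(sphere.vertices)
    faces = sphere.faces
    if len(faces) == 0:
        raise ValidationError("sphere mesh has no faces")
    pts = normalize_rows(np.atleast_2d(np.asarray(points, dtype=float)))
    centroids = normalize_rows(verts[faces].mean(axis=1))
    tree = cKDTree(centroids)
    k = min(n_candidates, len(faces))
    _, cand = tree.query(pts, k=k)
    cand = np.atleast_2d(cand)
    if k == 1:
        cand = cand.reshape(-1, 1)

    n = len(pts)
    face_idx = np.full(n, -1, dtype=np.int64)
    weights = np.zeros((n, 3), dtype=float)
    unresolved = np.arange(n)
    for rank in range(k):
        if unresolved.size == 0:
            break
        f = cand[unresolved, rank]
        w = _solve_face_weights(verts[faces[f]], pts[unresolved])
        s = w.sum(axis=1)
        ok = (s > 1e-12) & np.all(w >= -1e-9 * np.maximum(1.0, np.abs(s))[:, None], axis=1)
        hit = unresolved[ok]
        face_idx[hit] = f[ok]
        weights[hit] = w[ok] / s[ok, None]
        unresolved = unresolved[~ok]
    if unresolved.size:
        # nearest-face fallback: clip whatever weights the plane solve gives
        f = cand[unresolved, 0]
        w = _solve_face_weights(verts[faces[f]], pts[unresolved])
        s = w.sum(axis=1)
        bad = np.abs(s) <= 1e-12
        if bad.any():
            raise ValidationError(
                f"{int(bad.sum())} points could not be located on the sphere mesh"
            )
        face_idx[unresolved] = f
        weights[unresolved] = w / s[:, None]
    weights = np.clip(weights, 0.0, None)
    weights /= weights.sum(axis=1, keepdims=True)
    return face_idx, weights


def resample_to_template(
    reg: SphericalRegistration, subject_data: np.ndarray, interp: str = "barycentric"
) -> np.ndarray:
    """Resample per-vertex subject data onto the template sphere vertices.

    Scalars use barycentric interpolation inside the subject's spherical
    mesh; labels (integer data) must use ``interp='nearest'``.
    """
    subject_data = np.asarray(subject_data)
    if len(subject_data) != reg.subject_mesh.n_vertices:
        raise ValidationError(
            f"data length {len(subject_data)} != subject vertex count "
            f"{reg.subject_mesh.n_vertices}"
        )
    is_int = np.issubdtype(subject_data.dtype, np.integer) or subject_data.dtype == bool
    template_pts = reg.template_sphere.vertices
    if interp == "nearest":
        idx = nearest_with_ties(reg.sphere_coords, template_pts)
        return subject_data[idx]
    if interp != "barycentric":
        raise ValidationError(f"unknown interpolation {interp!r}")
    if is_int:
        raise ValidationError("label data must be resampled with interp='nearest'")
    face_idx, w = barycentric_locate(reg.sphere_mesh, template_pts)
    corner_data = subject_data[reg.subject_mesh.faces[face_idx]]
    return np.einsum("nk,nk...->n...", w, corner_data)


def template_vertex_to_subject_point(
    reg: SphericalRegistration,
    vertex_indices: np.ndarray | int | None = None,
    template_sphere: TriangleMesh | None = None,
    interp: str = "barycentric",
) -> np.ndarray:
    """Anatomical world point(s) on the subject surface corresponding to
    template-sphere vertices.

    The template vertex is located among the subject's sphere
    coordinates and its barycentric weights are applied to the subject's
    anatomical vertex positions (``interp='nearest'`` snaps to the
    nearest subject vertex instead).  ``vertex_indices=None`` maps every
    template vertex.
    """
    sphere = reg.template_sphere if template_sphere is None else TriangleMesh(
        normalize_rows(template_sphere.vertices), template_sphere.faces
    )
    scalar = np.isscalar(vertex_indices)
    if vertex_indices is None:
        pts = sphere.vertices
    else:
        indices = np.atleast_1d(np.asarray(vertex_indices, dtype=np.int64))
        if indices.min(initial=0) < 0 or indices.max(initial=-1) >= sphere.n_vertices:
            raise ValidationError("template vertex index out of range")
        pts = sphere.vertices[indices]
    if interp == "nearest":
        idx = nearest_with_ties(reg.sphere_coords, pts)
        out = reg.subject_mesh.vertices[idx]
    else:
        face_idx, w = barycentric_locate(reg.sphere_mesh, pts)
        corners = reg.subject_mesh.vertices[reg.subject_mesh.faces[face_idx]]
        out = np.einsum("nk,nkc->nc", w, corners)
    return out[0] if scalar else out
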