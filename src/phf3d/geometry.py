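"""Geometric domain types and least-squares primitives.

Everything downstream (anatomical frame construction, displacement
decomposition, shape modelling, fragment reduction) is built on the types
and fits defined here.  Conventions: all lengths are millimetres, all
angles exposed to callers are degrees, internal computation uses radians.
Points and vectors are numpy ``float64`` arrays of shape ``(3,)`` (single)
or ``(n, 3)`` (batched).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import trimesh as _trimesh
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

__all__ = [
    "DegenerateInputError",
    "FitFailureError",
    "NotRigidError",
    "FRAGMENT_LABELS",
    "TriangleMesh",
    "RigidTransform",
    "Plane",
    "Sphere",
    "CylinderAxis",
    "as_points",
    "unit",
    "fit_plane",
    "fit_sphere",
    "fit_cylinder_axis",
    "mesh_centroid",
    "project_onto_plane",
    "vector_norm3",
    "rigid_align",
]

_ORTHO_TOL = 1e-9

FRAGMENT_LABELS = (
    "head",
    "greater_tuberosity",
    "lesser_tuberosity",
    "shaft",
    "blueprint",
    "other",
)


class DegenerateInputError(ValueError):
    """Input point set cannot support the requested fit (too few points,
    collinear for a plane, coplanar for a sphere, ...)."""


class FitFailureError(RuntimeError):
    """A fit ran but the result is untrustworthy; carries residual diagnostics."""

    def __init__(self, message: str, residual_rms: float | None = None):
        super().__init__(message)
        self.residual_rms = residual_rms


class NotRigidError(ValueError):
    """A 4x4 matrix violates the rigid-transform invariants (scaling or
    reflection present, or malformed homogeneous row)."""


def as_points(points: Iterable[Sequence[float]] | np.ndarray) -> np.ndarray:
    """Coerce input to an (n, 3) float64 array, validating finiteness."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim == 1:
        pts = pts.reshape(1, 3)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) points, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite components")
    return pts


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize a 3-vector; raises on (near-)zero input."""
    v = np.asarray(v, dtype=np.float64).reshape(3)
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def vector_norm3(v: Sequence[float]) -> float:
    """Euclidean norm of a 3-vector (mm for displacement vectors)."""
    v = np.asarray(v, dtype=np.float64).reshape(3)
    if not np.all(np.isfinite(v)):
        raise ValueError("vector has non-finite components")
    return float(np.linalg.norm(v))


def project_onto_plane(v: Sequence[float], plane_normal: Sequence[float]) -> np.ndarray:
    """Orthogonal projection of ``v`` onto the plane with unit normal
    ``plane_normal``: ``v - (v.n) n``.  The result never exceeds ``|v|``."""
    v = np.asarray(v, dtype=np.float64).reshape(3)
    n = np.asarray(plane_normal, dtype=np.float64).reshape(3)
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise ValueError("plane normal must be a unit vector")
    return v - np.dot(v, n) * n


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """Triangle surface mesh in millimetres.

    The universal geometry carrier for fracture fragments and pre-fracture
    blueprints.  ``label`` identifies the fragment (one of
    :data:`FRAGMENT_LABELS`); arbitrary labels are allowed but the standard
    ones drive Neer part counting.
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices contain non-finite coordinates")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    # -- basic measures ----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def transformed(self, transform: "RigidTransform") -> "TriangleMesh":
        return TriangleMesh(transform.apply(self.vertices), self.faces.copy(), self.label)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.label)

    # -- interop / I/O -----------------------------------------------------
    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, mesh: _trimesh.Trimesh, label: str = "other") -> "TriangleMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), label)

    @classmethod
    def load(cls, path: str | Path, label: str | None = None) -> "TriangleMesh":
        """Load STL/PLY/OBJ.  Degenerate (zero-area) faces are dropped;
        label defaults to the file stem."""
        path = Path(path)
        raw = _trimesh.load_mesh(str(path), process=False)
        if isinstance(raw, _trimesh.Scene):
            raw = raw.to_mesh()
        mesh = cls.from_trimesh(raw, label or path.stem)
        areas = mesh.face_areas()
        keep = areas > 1e-12
        if not keep.all():
            mesh = cls(mesh.vertices, mesh.faces[keep], mesh.label)
        return mesh

    def save(self, path: str | Path) -> None:
        self.to_trimesh().export(str(path))


@dataclass(frozen=True)
class RigidTransform:
    """A 4x4 homogeneous rigid transform: rotation + translation, no scaling.

    The upper-left 3x3 block must be a proper rotation (RᵀR = I,
    det R = +1 within 1e-9) and the bottom row exactly (0, 0, 0, 1).
    The translation occupies the fourth column.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise NotRigidError(f"expected 4x4 matrix, got {m.shape}")
        object.__setattr__(self, "matrix", m)
        self.validate()

    def validate(self, tol: float = 1e-6) -> None:
        m = self.matrix
        if not np.all(np.isfinite(m)):
            raise NotRigidError("matrix has non-finite entries")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise NotRigidError("bottom row must be exactly (0, 0, 0, 1)")
        R = m[:3, :3]
        if np.abs(R.T @ R - np.eye(3)).max() > tol:
            raise NotRigidError("rotation block is not orthonormal (scaling/shear present)")
        if abs(np.linalg.det(R) - 1.0) > tol:
            raise NotRigidError("rotation block determinant != +1 (reflection present)")

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(
        cls, rotation: np.ndarray | Rotation, translation: Sequence[float]
    ) -> "RigidTransform":
        if isinstance(rotation, Rotation):
            R = rotation.as_matrix()
        else:
            R = np.asarray(rotation, dtype=np.float64)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = np.asarray(translation, dtype=np.float64).reshape(3)
        return cls(m)

    @classmethod
    def from_axis_angle(
        cls,
        axis: Sequence[float],
        angle_deg: float,
        translation: Sequence[float] = (0.0, 0.0, 0.0),
        center: Sequence[float] | None = None,
    ) -> "RigidTransform":
        """Rotation of ``angle_deg`` about ``axis`` (through ``center`` if
        given, else the origin), followed by ``translation``."""
        R = Rotation.from_rotvec(unit(axis) * np.deg2rad(angle_deg)).as_matrix()
        t = np.asarray(translation, dtype=np.float64).reshape(3)
        if center is not None:
            c = np.asarray(center, dtype=np.float64).reshape(3)
            t = t + c - R @ c
        return cls.from_rotation_translation(R, t)

    # -- algebra -----------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        single = pts.ndim == 1
        pts = pts.reshape(-1, 3)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def apply_vector(self, v: np.ndarray) -> np.ndarray:
        """Rotate a direction (no translation)."""
        return self.rotation @ np.asarray(v, dtype=np.float64).reshape(3)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Returns self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        R = self.rotation
        m = np.eye(4)
        m[:3, :3] = R.T
        m[:3, 3] = -R.T @ self.translation
        return RigidTransform(m)

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return bool(np.abs(self.matrix - other.matrix).max() <= tol)


@dataclass(frozen=True)
class Plane:
    """Plane through ``point`` with unit ``normal``."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=np.float64).reshape(3))
        object.__setattr__(self, "normal", unit(self.normal))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        return (pts - self.point) @ self.normal


@dataclass(frozen=True)
class Sphere:
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=np.float64).reshape(3))
        if not self.radius > 0:
            raise ValueError("sphere radius must be positive")


@dataclass(frozen=True)
class CylinderAxis:
    """Infinite-cylinder axis: a point on the axis, unit direction, radius."""

    point: np.ndarray
    direction: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=np.float64).reshape(3))
        object.__setattr__(self, "direction", unit(self.direction))
        if not self.radius > 0:
            raise ValueError("cylinder radius must be positive")

    def closest_point(self, p: Sequence[float]) -> np.ndarray:
        p = np.asarray(p, dtype=np.float64).reshape(3)
        return self.point + np.dot(p - self.point, self.direction) * self.direction


# ---------------------------------------------------------------------------
# Least-squares fits
# ---------------------------------------------------------------------------


def fit_plane(points: Iterable[Sequence[float]]) -> Plane:
    """Total-least-squares plane: minimizes squared orthogonal distances.

    The normal is the singular vector of the centered point matrix with the
    smallest singular value.  Its sign is unspecified at this level; callers
    with anatomical knowledge resolve orientation.
    """
    pts = as_points(points)
    if len(pts) < 3:
        raise DegenerateInputError(f"plane fit needs >= 3 points, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear points: second singular value vanishes relative to the first
    scale = s[0] if s[0] > 0 else 1.0
    if s[1] / scale < 1e-9:
        raise DegenerateInputError("points are collinear; plane is not determined")
    return Plane(centroid, vt[2])


def fit_sphere(points: Iterable[Sequence[float]]) -> Sphere:
    """Least-squares sphere through >= 4 non-coplanar points.

    Algebraic fit (linear system in center and radius) followed by a
    Gauss-Newton refinement of the geometric (orthogonal) residuals.
    """
    pts = as_points(points)
    if len(pts) < 4:
        raise DegenerateInputError(f"sphere fit needs >= 4 points, got {len(pts)}")
    # coplanarity check via the spread of the third principal direction
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    if s[2] / scale < 1e-9:
        raise DegenerateInputError("points are coplanar; sphere is not determined")
    # algebraic: |p|^2 = 2 c.p + (r^2 - |c|^2)
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + center0 @ center0, 1e-12)))

    def resid(x: np.ndarray) -> np.ndarray:
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    out = least_squares(resid, np.r_[center0, r0], method="lm", max_nfev=200)
    center, radius = out.x[:3], float(out.x[3])
    return Sphere(center, abs(radius))


def fit_cylinder_axis(
    points: Iterable[Sequence[float]],
    orientation_hint: Sequence[float] | None = None,
    max_relative_residual: float = 0.1,
) -> CylinderAxis:
    """Least-squares infinite cylinder fit to a point cloud.

    Initialized from the principal component of the points, then refined by
    nonlinear least squares over axis direction (two angles), axis offset
    and radius, minimizing squared radial residuals.  The direction sign is
    canonicalized to agree with ``orientation_hint`` (e.g. a distal-to-
    proximal vector) when provided.

    Raises :class:`FitFailureError` when the cloud is not cylindrical:
    the RMS radial residual exceeds ``max_relative_residual`` times the
    fitted radius (a sphere, for instance, is rejected).
    """
    pts = as_points(points)
    if len(pts) < 6:
        raise DegenerateInputError(f"cylinder fit needs >= 6 points, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d0 = vt[0]  # principal direction ~ cylinder axis for elongated clouds

    def frame_of(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = unit(np.cross(d, ref))
        return u, np.cross(d, u)

    def unpack(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        theta, phi, a, b, r = x
        d = np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        u, v = frame_of(d)
        return d, centroid + a * u + b * v, r

    def resid(x: np.ndarray) -> np.ndarray:
        d, p0, r = unpack(x)
        rel = pts - p0
        radial = rel - np.outer(rel @ d, d)
        return np.linalg.norm(radial, axis=1) - r

    theta0 = float(np.arccos(np.clip(d0[2], -1.0, 1.0)))
    phi0 = float(np.arctan2(d0[1], d0[0]))
    rel = centered - np.outer(centered @ d0, d0)
    r0 = float(np.linalg.norm(rel, axis=1).mean())
    if r0 < 1e-9:
        raise DegenerateInputError("points lie on a line; cylinder radius is zero")
    x0 = np.array([theta0, phi0, 0.0, 0.0, r0])
    out = least_squares(resid, x0, method="lm", max_nfev=500)
    d, p0, r = unpack(out.x)
    r = abs(float(r))
    rms = float(np.sqrt(np.mean(out.fun**2)))
    if not out.success or r < 1e-9 or rms > max_relative_residual * r:
        raise FitFailureError(
            f"point cloud is not cylindrical (RMS radial residual {rms:.3g} mm "
            f"vs radius {r:.3g} mm)",
            residual_rms=rms,
        )
    if orientation_hint is not None and np.dot(d, np.asarray(orientation_hint, float)) < 0:
        d = -d
    return CylinderAxis(p0, d, r)


def mesh_centroid(mesh: TriangleMesh, kind: str = "surface") -> np.ndarray:
    """Centroid of a triangle mesh.

    ``kind='surface'`` (default): area-weighted mean of face centroids —
    well defined for open fragment shells.  ``kind='volume'``: volume
    centroid via divergence theorem, valid only for closed meshes.
    Both are equivariant under rigid motion.
    """
    if mesh.n_faces < 1:
        raise ValueError("mesh has no faces; centroid undefined")
    if kind == "surface":
        areas = mesh.face_areas()
        total = areas.sum()
        if total <= 0:
            raise ValueError("mesh has zero total area")
        face_centroids = mesh.vertices[mesh.faces].mean(axis=1)
        return (areas[:, None] * face_centroids).sum(axis=0) / total
    if kind == "volume":
        tm = mesh.to_trimesh()
        if not tm.is_watertight:
            raise ValueError("volume centroid requires a watertight mesh")
        return np.asarray(tm.center_mass, dtype=np.float64)
    raise ValueError(f"unknown centroid kind {kind!r}")


def rigid_align(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Kabsch rigid alignment (rotation + translation, no scaling) of
    corresponded point sets, minimizing sum of squared distances
    |T(source_i) - target_i|^2."""
    src = as_points(source)
    tgt = as_points(target)
    if src.shape != tgt.shape:
        raise ValueError("source and target must have identical shapes")
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - cs).T @ (tgt - ct)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return RigidTransform.from_rotation_translation(R, ct - R @ cs)
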