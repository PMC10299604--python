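"""Virtual fragment reduction onto the pre-fracture blueprint.

The clinical workflow reduces each fragment manually; here the reduction is
automated by rigid surface registration — trimmed point-to-plane iterative
closest point (ICP) of the fragment's outer surface onto the blueprint.
Trimming discards the worst correspondences each iteration (fracture
surfaces have no blueprint counterpart), and an optional multi-start over
the 24 octahedral rotations guards against rotational local minima when no
initial transform is supplied.  Manually obtained transforms can be fed in
unchanged through :func:`accept_manual_transform`, preserving the manual
workflow.

The blueprint itself is positioned either by registering its shaft region
onto the observed unfractured shaft (default) or at a standard pose
relative to a user-supplied glenoid frame (0 deg flexion, neutral rotation,
30 deg abduction by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import (
    FitFailureError,
    RigidTransform,
    TriangleMesh,
    fit_cylinder_axis,
    mesh_centroid,
    unit,
)

__all__ = [
    "RejectedFragmentError",
    "PositioningFailureError",
    "ReductionSettings",
    "ReductionResult",
    "GlenoidFrame",
    "StandardPose",
    "reduce_fragment",
    "accept_manual_transform",
    "position_blueprint",
    "octahedral_rotations",
]


class RejectedFragmentError(ValueError):
    """Fragment too small to register reliably (vertex count or surface
    area below the configured floor)."""


class PositioningFailureError(RuntimeError):
    """Blueprint positioning did not reach an acceptable residual."""


@dataclass(frozen=True)
class ReductionSettings:
    """Registration settings.

    ``trim_fraction`` is the fraction of closest-point correspondences kept
    each iteration (fracture surfaces are discarded by the trim);
    ``area_floor_mm2`` rejects slivers below ~195 mm^2, the scale at which
    surface registration of fragments becomes unreliable.
    """

    trim_fraction: float = 0.7
    max_iterations: int = 200
    tolerance: float = 1e-6
    multistart: bool = True
    coarse_iterations: int = 10
    max_source_points: int = 600
    min_vertices: int = 50
    area_floor_mm2: float = 195.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.1 <= self.trim_fraction <= 1.0:
            raise ValueError("trim_fraction must lie in [0.1, 1]")


@dataclass(frozen=True)
class ReductionResult:
    label: str
    transform: RigidTransform
    residual_rms: float
    converged: bool
    n_iterations: int


def octahedral_rotations() -> list[np.ndarray]:
    """The 24 rotation matrices of the octahedral group (identity first)."""
    mats = []
    for g in Rotation.create_group("O"):
        m = np.round(g.as_matrix())
        mats.append(m)
    mats.sort(key=lambda m: float(np.rad2deg(np.linalg.norm(Rotation.from_matrix(m).as_rotvec()))))
    return mats


class _SurfaceTarget:
    """KD-tree over target surface samples with outward normals, supporting
    point-to-plane distance queries."""

    def __init__(self, mesh: TriangleMesh):
        tm = mesh.to_trimesh()
        self.points = np.asarray(tm.vertices, dtype=np.float64)
        self.normals = np.asarray(tm.vertex_normals, dtype=np.float64)
        self.tree = cKDTree(self.points)

    def closest(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        _, idx = self.tree.query(pts, k=1)
        return self.points[idx], self.normals[idx]


def _icp_point_to_plane(
    source: np.ndarray,
    target: _SurfaceTarget,
    init: RigidTransform,
    settings: ReductionSettings,
    max_iterations: int,
) -> tuple[RigidTransform, float, int, bool]:
    """Trimmed point-to-plane ICP.  Returns (transform, trimmed RMS,
    iterations, converged)."""
    T = init
    n_keep = max(6, int(np.ceil(settings.trim_fraction * len(source))))
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        moved = T.apply(source)
        q, n = target.closest(moved)
        d = np.einsum("ij,ij->i", moved - q, n)
        order = np.argsort(np.abs(d))[:n_keep]
        p, qn, nn, dd = moved[order], q[order], n[order], d[order]
        rms = float(np.sqrt(np.mean(dd**2)))
        # linearized rigid update: minimize sum (n.( (I+[w]x) p + t - q ))^2
        A = np.hstack([np.cross(p, nn), nn])
        b = -dd
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        w, t = x[:3], x[3:]
        angle = np.linalg.norm(w)
        R = Rotation.from_rotvec(w).as_matrix() if angle > 0 else np.eye(3)
        T = RigidTransform.from_rotation_translation(R, t).compose(T)
        if prev - rms < settings.tolerance * max(prev, 1.0):
            converged = True
            break
        prev = rms
    moved = T.apply(source)
    q, n = target.closest(moved)
    d = np.einsum("ij,ij->i", moved - q, n)
    d = np.sort(np.abs(d))[:n_keep]
    rms = float(np.sqrt(np.mean(d**2)))
    return T, rms, it, converged


def _residual_rms(
    points: np.ndarray, target: _SurfaceTarget, T: RigidTransform, keep_fraction: float
) -> float:
    moved = T.apply(points)
    q, n = target.closest(moved)
    d = np.abs(np.einsum("ij,ij->i", moved - q, n))
    d = np.sort(d)[: max(6, int(np.ceil(keep_fraction * len(d))))]
    return float(np.sqrt(np.mean(d**2)))


def _subsample(points: np.ndarray, n_max: int, seed: int) -> np.ndarray:
    if len(points) <= n_max:
        return points
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(points), size=n_max, replace=False)
    return points[idx]


def reduce_fragment(
    fragment: TriangleMesh,
    blueprint: TriangleMesh,
    init: RigidTransform | None = None,
    settings: ReductionSettings = ReductionSettings(),
) -> ReductionResult:
    """Register a displaced fragment onto the blueprint.

    With ``init`` given, a single trimmed point-to-plane ICP run refines
    it.  Without, and with ``settings.multistart`` on, the 24 octahedral
    rotations about the fragment centroid are each scored by a short
    coarse ICP on subsampled points; the best (ties broken by smallest
    rotation angle, guaranteed by the ordering of the start list) is then
    refined fully.  Deterministic for fixed settings.

    Non-convergence is reported in the result, not raised; fragments below
    the vertex or area floor raise :class:`RejectedFragmentError`.
    """
    if fragment.n_vertices < settings.min_vertices:
        raise RejectedFragmentError(
            f"fragment '{fragment.label}' has {fragment.n_vertices} vertices "
            f"(< {settings.min_vertices})"
        )
    area = fragment.area()
    if area < settings.area_floor_mm2:
        raise RejectedFragmentError(
            f"fragment '{fragment.label}' surface area {area:.0f} mm^2 is below "
            f"the {settings.area_floor_mm2:.0f} mm^2 floor"
        )
    target = _SurfaceTarget(blueprint)
    source_full = fragment.vertices
    source = _subsample(source_full, settings.max_source_points, settings.seed)

    if init is not None:
        starts = [init]
    elif settings.multistart:
        c = mesh_centroid(fragment)
        starts = [
            RigidTransform.from_axis_angle(
                axis, angle, center=c
            ) if angle > 0 else RigidTransform.identity()
            for axis, angle in (_rotation_axis_angle(m) for m in octahedral_rotations())
        ]
    else:
        starts = [RigidTransform.identity()]

    if len(starts) > 1:
        coarse_src = _subsample(source, 250, settings.seed + 1)
        scored = []
        for s_idx, T0 in enumerate(starts):
            Tc, _, _, _ = _icp_point_to_plane(
                coarse_src, target, T0, settings, settings.coarse_iterations
            )
            # rank candidates by near-untrimmed residual: a mis-rotated pose
            # of a locally symmetric fragment can look good under heavy
            # trimming but not once the distinctive regions count
            score = _residual_rms(coarse_src, target, Tc, keep_fraction=0.95)
            scored.append((score, s_idx, Tc))
        scored.sort(key=lambda x: (x[0], x[1]))  # tie -> smaller start rotation
        candidates = [Tc for _, _, Tc in scored[:3]]
    else:
        candidates = list(starts)

    finals = []
    for rank, T0 in enumerate(candidates):
        Tf, rms_f, iters_f, conv_f = _icp_point_to_plane(
            source, target, T0, settings, settings.max_iterations
        )
        finals.append(
            (_residual_rms(source, target, Tf, 0.95), rank, Tf, rms_f, iters_f, conv_f)
        )
    finals.sort(key=lambda x: (x[0], x[1]))
    _, _, T, rms, iters, converged = finals[0]
    return ReductionResult(
        label=fragment.label,
        transform=T,
        residual_rms=rms,
        converged=converged,
        n_iterations=iters,
    )


def _rotation_axis_angle(R: np.ndarray) -> tuple[np.ndarray, float]:
    rv = Rotation.from_matrix(R).as_rotvec()
    angle = float(np.rad2deg(np.linalg.norm(rv)))
    axis = rv / np.linalg.norm(rv) if angle > 1e-9 else np.array([0.0, 0.0, 1.0])
    return axis, angle


def accept_manual_transform(
    label: str,
    M: RigidTransform | np.ndarray,
    fragment: TriangleMesh | None = None,
    blueprint: TriangleMesh | None = None,
) -> ReductionResult:
    """Wrap an externally obtained (e.g. manual) reduction transform.

    Validates rigidity; when both fragment and blueprint are supplied, the
    post-reduction surface RMS residual is recomputed for the record."""
    if not isinstance(M, RigidTransform):
        M = RigidTransform(np.asarray(M, dtype=np.float64))
    residual = 0.0
    if fragment is not None and blueprint is not None:
        target = _SurfaceTarget(blueprint)
        moved = M.apply(fragment.vertices)
        q, n = target.closest(moved)
        d = np.einsum("ij,ij->i", moved - q, n)
        residual = float(np.sqrt(np.mean(d**2)))
    return ReductionResult(
        label=label, transform=M, residual_rms=residual, converged=True, n_iterations=0
    )


# ---------------------------------------------------------------------------
# Blueprint positioning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GlenoidFrame:
    """Abstract glenoid coordinate frame supplied by the user (the scapula
    is never segmented here): origin at the desired humeral head center,
    with superior, anterior and lateral unit directions."""

    origin: np.ndarray
    superior: np.ndarray
    anterior: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, float).reshape(3))
        object.__setattr__(self, "superior", unit(self.superior))
        object.__setattr__(self, "anterior", unit(self.anterior))

    @property
    def lateral(self) -> np.ndarray:
        return unit(np.cross(self.anterior, self.superior))


@dataclass(frozen=True)
class StandardPose:
    """Humeral pose relative to the glenoid: the neutral sling position is
    0 deg flexion, neutral axial rotation, 30 deg abduction."""

    abduction_deg: float = 30.0
    flexion_deg: float = 0.0
    rotation_deg: float = 0.0


def position_blueprint(
    predicted: TriangleMesh,
    observed_shaft: TriangleMesh | None = None,
    mode: str = "shaft_anchored",
    shaft_indices: np.ndarray | None = None,
    settings: ReductionSettings = ReductionSettings(),
    max_rms: float = 2.0,
    glenoid: GlenoidFrame | None = None,
    pose: StandardPose = StandardPose(),
    blueprint_frame=None,
) -> RigidTransform:
    """Position the predicted blueprint.

    ``shaft_anchored`` (default): rigid registration of the blueprint's
    shaft region (``shaft_indices`` into ``predicted``; all vertices when
    omitted) onto the observed unfractured shaft, initialized by aligning
    the two diaphyseal cylinder axes with a small multi-start over axial
    spin (the bicipital groove locks the azimuth).  Raises
    :class:`PositioningFailureError` above ``max_rms``.

    ``pose_anchored``: place the blueprint at the standard pose relative to
    a supplied :class:`GlenoidFrame` — abduction tilts the humeral axial
    axis away from the glenoid's superior axis — with the head center O at
    the glenoid origin.  Requires ``blueprint_frame`` (the blueprint's own
    :class:`~phf3d.frame.ReferenceFrame`).
    """
    if mode == "pose_anchored":
        if glenoid is None or blueprint_frame is None:
            raise ValueError("pose_anchored mode needs a glenoid frame and blueprint frame")
        f = blueprint_frame
        # target humeral axes in glenoid coordinates
        ab = np.deg2rad(pose.abduction_deg)
        fl = np.deg2rad(pose.flexion_deg)
        rot = np.deg2rad(pose.rotation_deg)
        R_ab = Rotation.from_rotvec(ab * glenoid.anterior).as_matrix()
        axial_t = R_ab @ glenoid.superior
        post_t = R_ab @ (-glenoid.anterior)
        if fl:
            R_fl = Rotation.from_rotvec(fl * unit(np.cross(axial_t, post_t))).as_matrix()
            axial_t, post_t = R_fl @ axial_t, R_fl @ post_t
        if rot:
            R_rot = Rotation.from_rotvec(rot * axial_t).as_matrix()
            post_t = R_rot @ post_t
        src = np.column_stack([f.axial, f.posterior_dir, np.cross(f.axial, f.posterior_dir)])
        tgt = np.column_stack([axial_t, post_t, np.cross(axial_t, post_t)])
        R = tgt @ src.T
        t = glenoid.origin - R @ f.origin_O
        return RigidTransform.from_rotation_translation(R, t)

    if mode != "shaft_anchored":
        raise ValueError(f"unknown positioning mode {mode!r}")
    if observed_shaft is None:
        raise ValueError("shaft_anchored mode needs the observed shaft mesh")

    src_pts = (
        predicted.vertices if shaft_indices is None else predicted.vertices[shaft_indices]
    )
    # initialize by aligning cylinder axes; azimuth resolved by multi-start
    try:
        ax_src = fit_cylinder_axis(src_pts)
        ax_tgt = fit_cylinder_axis(observed_shaft.vertices)
        v, w = ax_src.direction, ax_tgt.direction
        if np.dot(v, w) < 0:
            w = -w
        cross = np.cross(v, w)
        c = float(np.clip(np.dot(v, w), -1, 1))
        R0 = (
            Rotation.from_rotvec(unit(cross) * np.arccos(c)).as_matrix()
            if np.linalg.norm(cross) > 1e-12
            else np.eye(3)
        )
        # match axis positions, including the along-axis centroid stations
        s_src = float(np.mean((src_pts - ax_src.point) @ v))
        s_tgt = float(np.mean((observed_shaft.vertices - ax_tgt.point) @ w))
        t0 = (ax_tgt.point + s_tgt * w) - R0 @ (ax_src.point + s_src * v)
        base = RigidTransform.from_rotation_translation(R0, t0)
        spin_center = ax_tgt.point + s_tgt * w
        inits = [
            RigidTransform.from_axis_angle(w, spin, center=spin_center).compose(base)
            for spin in np.arange(0.0, 360.0, 45.0)
        ]
    except FitFailureError:
        inits = [RigidTransform.identity()]

    target = _SurfaceTarget(observed_shaft)
    source = _subsample(src_pts, settings.max_source_points, settings.seed)
    scored = []
    for i, T0 in enumerate(inits):
        Tc, _, _, _ = _icp_point_to_plane(
            source, target, T0, settings, settings.coarse_iterations
        )
        scored.append((_residual_rms(source, target, Tc, 0.95), i, Tc))
    scored.sort(key=lambda x: (x[0], x[1]))
    # fully refine the leading candidates; keep the best final residual
    finals = []
    for rank, (_, i, Tc) in enumerate(scored[:3]):
        T, rms, _, _ = _icp_point_to_plane(
            source, target, Tc, settings, settings.max_iterations
        )
        finals.append((_residual_rms(source, target, T, 0.95), rank, T, rms))
    finals.sort(key=lambda x: (x[0], x[1]))
    _, _, T, rms = finals[0]
    if rms > max_rms:
        raise PositioningFailureError(
            f"blueprint shaft registration RMS {rms:.2f} mm exceeds {max_rms:.2f} mm"
        )
    return T
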