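"""Humeral anatomical reference frame and proximal-humerus morphometry.

The frame is built on the pre-fracture blueprint in five steps:

1. the *axial* axis is the least-squares axis of the diaphyseal cylinder,
   oriented to point proximally;
2. a plane is fit (total least squares) to points picked on the anatomical
   neck;
3. the *anatneck* axis is that plane's normal, sign-resolved to point
   towards the glenoid;
4. *coro* = axial x anatneck (the coronal-plane normal, an antero-posterior
   direction);
5. *sag* = axial x coro (the sagittal-plane normal, a medio-lateral
   direction).

The frame origin O is the center of the sphere fit to the articular head
region of the blueprint.  Each named axis is the NORMAL of its named plane:
varus/valgus is rotation about *coro*, anterior/posterior tilt about *sag*,
anteversion/retroversion about *axial*.

Side convention: frames are built intrinsically from the bone, so axes are
chirality-dependent (on a right humerus *coro* points posteriorly, on a
left one anteriorly; *sag* points laterally on both).  Clinical signs
(varus, posterior tilt and retroversion positive) are made side-consistent
by the sign table :data:`SIDE_TWIST_SIGNS`: mirroring a humerus and
rebuilding the frame leaves all reported clinical signs unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import (
    CylinderAxis,
    Plane,
    TriangleMesh,
    as_points,
    fit_cylinder_axis,
    fit_plane,
    fit_sphere,
    unit,
)

__all__ = [
    "AmbiguousOrientationError",
    "ReferenceFrame",
    "AnatomyParameters",
    "SIDE_TWIST_SIGNS",
    "GROOVE_REFERENCE_OFFSET_DEG",
    "build_reference_frame",
    "measure_anatomy",
]

# Conventional angular offset (degrees) from the bicipital groove to the
# neck-reference direction in the axial plane: the groove lies this far
# anterior of the medial reference axis from which retroversion is measured.
GROOVE_REFERENCE_OFFSET_DEG = 60.0

# Multipliers applied to raw twist angles about (coro, sag, axial) so that
# positive always means (varus, posterior tilt, retroversion).  Derived by
# mirror conjugation of rotations: reflection flips the handedness of twists
# about the axial and sagittal axes but not about the coronal axis (whose
# direction itself flips with side).
SIDE_TWIST_SIGNS = {
    "right": np.array([1.0, 1.0, 1.0]),
    "left": np.array([1.0, -1.0, -1.0]),
}


class AmbiguousOrientationError(ValueError):
    """The glenoid hint cannot resolve the anatomical-neck normal sign."""


@dataclass(frozen=True)
class ReferenceFrame:
    """Humeral reference frame: origin O (pre-fracture humeral head center)
    plus the three orthonormal plane normals and the anatomical-neck axis.

    ``diaphyseal_axis``, ``neck_plane`` and ``head_radius`` retain the fitted
    primitives for morphometry; they are derived context, not part of the
    orthonormal triad.
    """

    origin_O: np.ndarray
    axial: np.ndarray
    anatneck: np.ndarray
    coro: np.ndarray
    sag: np.ndarray
    side: str = "right"
    diaphyseal_axis: CylinderAxis | None = None
    neck_plane: Plane | None = None
    head_radius: float | None = None

    def __post_init__(self) -> None:
        for name in ("origin_O", "axial", "anatneck", "coro", "sag"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=np.float64).reshape(3)
            )
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        for name in ("axial", "anatneck", "coro", "sag"):
            v = getattr(self, name)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} is not a unit vector")
        for a, b in (("axial", "coro"), ("axial", "sag"), ("coro", "sag")):
            if abs(np.dot(getattr(self, a), getattr(self, b))) > 1e-9:
                raise ValueError(f"{a} and {b} are not orthogonal")

    @property
    def plane_normals(self) -> dict[str, np.ndarray]:
        """Normals of the coronal, sagittal and axial planes."""
        return {"coronal": self.coro, "sagittal": self.sag, "axial": self.axial}

    @property
    def twist_signs(self) -> np.ndarray:
        return SIDE_TWIST_SIGNS[self.side]

    @property
    def medial_dir(self) -> np.ndarray:
        """Unit vector pointing medially (side-consistent)."""
        return -self.sag

    @property
    def posterior_dir(self) -> np.ndarray:
        """Unit vector pointing posteriorly (side-consistent)."""
        return self.coro if self.side == "right" else -self.coro

    def transformed(self, transform) -> "ReferenceFrame":
        """The frame of the rigidly transformed bone."""
        R = transform.rotation
        axis = self.diaphyseal_axis
        if axis is not None:
            axis = CylinderAxis(transform.apply(axis.point), R @ axis.direction, axis.radius)
        plane = self.neck_plane
        if plane is not None:
            plane = Plane(transform.apply(plane.point), R @ plane.normal)
        return ReferenceFrame(
            transform.apply(self.origin_O),
            R @ self.axial,
            R @ self.anatneck,
            R @ self.coro,
            R @ self.sag,
            self.side,
            axis,
            plane,
            self.head_radius,
        )


@dataclass(frozen=True)
class AnatomyParameters:
    """Standard proximal-humerus anatomical parameters.

    retroversion/inclination in degrees, lengths in mm.  ``retroversion``
    is NaN when no bicipital-groove landmarks are available.
    """

    retroversion: float
    inclination: float
    head_height: float
    radius_of_curvature: float
    posterior_offset: float
    medial_offset: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.retroversion,
                self.inclination,
                self.head_height,
                self.radius_of_curvature,
                self.posterior_offset,
                self.medial_offset,
            ]
        )

    FIELDS = (
        "retroversion",
        "inclination",
        "head_height",
        "radius_of_curvature",
        "posterior_offset",
        "medial_offset",
    )


def _axes_from_axial_anatneck(
    axial: np.ndarray, anatneck: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    coro = unit(np.cross(axial, anatneck))
    sag = unit(np.cross(axial, coro))
    return coro, sag


def build_reference_frame(
    blueprint: TriangleMesh,
    neck_points: Iterable[Sequence[float]],
    shaft_points: Iterable[Sequence[float]],
    glenoid_hint: Sequence[float],
    side: str = "right",
    head_margin: float = 1.0,
) -> ReferenceFrame:
    """Build the humeral reference frame from the blueprint.

    Parameters
    ----------
    blueprint : TriangleMesh
        Pre-fracture proximal humerus.
    neck_points : array-like (n, 3), n >= 3 (10 recommended)
        Points on the anatomical neck; a plane is fit by total least squares.
    shaft_points : array-like (n, 3)
        Points sampling the diaphyseal cylinder.
    glenoid_hint : vector
        Any vector with a positive dot product with the true medial
        (toward-glenoid) direction; resolves the anatneck sign.  The hint
        must not be near-orthogonal to the neck normal.
    side : 'left' | 'right'
    head_margin : float
        Blueprint vertices farther than this (mm) on the articular side of
        the neck plane are used for the head-sphere fit of the origin O.
    """
    neck_pts = as_points(neck_points)
    shaft_pts = as_points(shaft_points)
    hint = unit(glenoid_hint)

    # axial axis: diaphyseal cylinder, oriented distal -> proximal (the neck
    # lies proximal to the shaft sample).
    proximal_hint = neck_pts.mean(axis=0) - shaft_pts.mean(axis=0)
    axis = fit_cylinder_axis(shaft_pts, orientation_hint=proximal_hint)

    neck_plane = fit_plane(neck_pts)
    n = neck_plane.normal
    d = float(np.dot(n, hint))
    if abs(d) < 0.1:
        raise AmbiguousOrientationError(
            "glenoid hint is nearly orthogonal to the anatomical-neck normal; "
            "cannot resolve the toward-glenoid direction"
        )
    anatneck = n if d > 0 else -n
    neck_plane = Plane(neck_plane.point, anatneck)

    coro, sag = _axes_from_axial_anatneck(axis.direction, anatneck)

    # origin O: center of the sphere fit to the articular-side vertices.
    sd = neck_plane.signed_distance(blueprint.vertices)
    head_vertices = blueprint.vertices[sd > head_margin]
    if len(head_vertices) < 4:
        raise ValueError(
            "too few blueprint vertices on the articular side of the neck plane"
        )
    head_sphere = fit_sphere(head_vertices)

    return ReferenceFrame(
        origin_O=head_sphere.center,
        axial=axis.direction,
        anatneck=anatneck,
        coro=coro,
        sag=sag,
        side=side,
        diaphyseal_axis=axis,
        neck_plane=neck_plane,
        head_radius=head_sphere.radius,
    )


def _signed_angle_about(axis: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Signed angle (radians) from a to b about axis (right-hand rule),
    after projecting both into the plane normal to axis."""
    a = a - np.dot(a, axis) * axis
    b = b - np.dot(b, axis) * axis
    return float(np.arctan2(np.dot(np.cross(a, b), axis), np.dot(a, b)))


def measure_anatomy(
    blueprint: TriangleMesh,
    frame: ReferenceFrame,
    groove_points: Iterable[Sequence[float]] | None = None,
) -> AnatomyParameters:
    """Measure the six standard anatomical parameters on a blueprint.

    Definitions (fixed here, documented in the methods note):

    * inclination: clinical neck-shaft angle — the supplement of the angle
      between the axial axis (proximal) and the anatneck axis, degrees in
      (90, 180) for normal anatomy;
    * retroversion: signed axial-plane angle from the neck-reference
      direction (bicipital-groove direction rotated by the conventional
      offset) to the anatneck projection, positive posterior; NaN without
      groove points;
    * radius_of_curvature: radius of the head sphere;
    * head_height: head sphere radius minus the distance from the head
      center to the anatomical-neck plane (the height of the articular cap);
    * posterior/medial offset: components of (O - nearest point on the
      diaphyseal axis) along the side-consistent posterior and medial
      directions.
    """
    if frame.diaphyseal_axis is None or frame.neck_plane is None or frame.head_radius is None:
        raise ValueError("frame lacks fitted primitives; build it with build_reference_frame")
    axis = frame.diaphyseal_axis
    O = frame.origin_O
    r = float(frame.head_radius)

    # clinical neck-shaft angle: supplement of the axial/anatneck angle, so
    # normal anatomy lands in (90, 180) degrees (135 typical)
    inclination = 180.0 - float(
        np.rad2deg(np.arccos(np.clip(np.dot(frame.axial, frame.anatneck), -1.0, 1.0)))
    )
    head_height = r - abs(float(frame.neck_plane.signed_distance(O)[0]))

    offset_vec = O - axis.closest_point(O)
    posterior_offset = float(np.dot(offset_vec, frame.posterior_dir))
    medial_offset = float(np.dot(offset_vec, frame.medial_dir))

    retroversion = float("nan")
    if groove_points is not None:
        groove = as_points(groove_points)
        if len(groove) >= 1:
            side_sign = 1.0 if frame.side == "right" else -1.0
            g_dir = groove.mean(axis=0) - axis.closest_point(groove.mean(axis=0))
            g_dir = g_dir - np.dot(g_dir, frame.axial) * frame.axial
            g_dir = unit(g_dir)
            ref = Rotation.from_rotvec(
                frame.axial * np.deg2rad(side_sign * GROOVE_REFERENCE_OFFSET_DEG)
            ).apply(g_dir)
            retroversion = side_sign * np.rad2deg(
                _signed_angle_about(frame.axial, ref, frame.anatneck)
            )

    return AnatomyParameters(
        retroversion=retroversion,
        inclination=inclination,
        head_height=head_height,
        radius_of_curvature=r,
        posterior_offset=posterior_offset,
        medial_offset=medial_offset,
    )
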