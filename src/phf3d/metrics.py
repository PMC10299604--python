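"""Fragment displacement metrics and Neer classification.

The reduction transform M (4x4, rigid) records the path of a fragment from
its displaced (injury) pose back to its anatomic pose on the pre-fracture
blueprint.  This module decomposes M into

* a translation measured between the fragment centroid before (GP) and
  after (GR) reduction, with its 3D norm and the 2D projections onto the
  coronal, sagittal and axial planes, and
* a rotation in axis-angle form plus signed per-plane clinical angles
  (varus/valgus, anterior/posterior tilt, anteversion/retroversion)
  extracted by swing-twist decomposition about the frame axes,

then applies Neer's displacement criteria (>= 10 mm translation or >= 45
degrees of angulation) and the standard reporting bins, and aggregates
cohorts (rotation cross-tabs, bin histograms, and the paired comparison of
2D projected vs 3D translations).

Sign convention: clinical angles describe the *displacement* of the
fragment, not the correcting motion, so signed twists are extracted from
the inverse of M's rotation; a head displaced 30 degrees into varus reports
``coronal_angle = +30``.  Positive means varus, posterior tilt and
retroversion respectively; left-side frames flip signs where mirror
symmetry requires it (see :mod:`phf3d.frame`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .frame import ReferenceFrame
from .geometry import (
    RigidTransform,
    TriangleMesh,
    mesh_centroid,
    project_onto_plane,
    vector_norm3,
)

__all__ = [
    "NEER_TRANSLATION_MM",
    "NEER_ANGLE_DEG",
    "TRANSLATION_BINS",
    "TRANSLATION_FINE_BINS",
    "ROTATION_CLASSES",
    "TranslationReport",
    "RotationReport",
    "NeerAssessment",
    "DisplacementReport",
    "CohortSummary",
    "decompose_transform",
    "twist_angle_deg",
    "translation_report",
    "rotation_report",
    "assess_neer",
    "measure_displacement",
    "count_neer_parts",
    "summarize_cohort",
]

# Neer's reference thresholds, inclusive.
NEER_TRANSLATION_MM = 10.0
NEER_ANGLE_DEG = 45.0

# Reporting bins for translation norms (mm).  Binning is on the raw value;
# display rounding never promotes 9.95-9.99 into the >=10 bin.
TRANSLATION_BINS = ("<5", "5-9.9", ">=10")
TRANSLATION_FINE_BINS = ("<5", "5-9", "10-15", ">15")

# Per-plane rotation classes, ordered negative-extreme to positive-extreme.
# Positive direction per plane: varus (coronal), posterior tilt (sagittal),
# retroversion (axial).
_CLASS_DIRECTIONS = {
    "coronal": ("valgus", "varus"),
    "sagittal": ("anterior_tilt", "posterior_tilt"),
    "axial": ("anteversion", "retroversion"),
}
ROTATION_CLASSES = {
    plane: (
        f"{neg}>45",
        f"{neg} 5-45",
        "<5",
        f"{pos} 5-45",
        f"{pos}>45",
    )
    for plane, (neg, pos) in _CLASS_DIRECTIONS.items()
}


@dataclass(frozen=True)
class TranslationReport:
    """Translation of one fragment: centroid before (GP) and after (GR)
    reduction, the vector between them, its 3D norm and the (unsigned)
    norms of its projections onto the three reference planes.
    ``axis_components`` additionally stores the signed components along
    each frame axis for transparency."""

    GP: np.ndarray
    GR: np.ndarray
    trans_vector: np.ndarray
    norm_3d: float
    proj_coronal: float
    proj_sagittal: float
    proj_axial: float
    axis_components: dict = field(default_factory=dict)

    def projections(self) -> dict[str, float]:
        return {
            "coronal": self.proj_coronal,
            "sagittal": self.proj_sagittal,
            "axial": self.proj_axial,
        }


@dataclass(frozen=True)
class RotationReport:
    """Rotation of one fragment: axis-angle of the 3D displacement rotation
    plus signed per-plane clinical angles (degrees)."""

    axis: np.ndarray
    angle_3d: float
    coronal_angle: float
    sagittal_angle: float
    axial_angle: float

    def plane_angles(self) -> dict[str, float]:
        return {
            "coronal": self.coronal_angle,
            "sagittal": self.sagittal_angle,
            "axial": self.axial_angle,
        }


@dataclass(frozen=True)
class NeerAssessment:
    displaced: bool
    translation_bin: str
    translation_fine_bin: str
    coronal_rotation_class: str
    sagittal_rotation_class: str
    axial_rotation_class: str


@dataclass(frozen=True)
class DisplacementReport:
    label: str
    transform: RigidTransform
    translation: TranslationReport
    rotation: RotationReport
    neer: NeerAssessment


# ---------------------------------------------------------------------------
# Transform decomposition
# ---------------------------------------------------------------------------


def decompose_transform(
    M: RigidTransform | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Decompose a rigid transform into (translation, rotation axis, angle).

    The translation is the fourth column (a14, a24, a34); the rotation is
    returned in axis-angle form with the angle in [0, 180] degrees.  A zero
    rotation reports the conventional axis (0, 0, 1).  Non-rigid input
    (scaling, shear or reflection) raises :class:`NotRigidError`.
    """
    if not isinstance(M, RigidTransform):
        M = RigidTransform(np.asarray(M, dtype=np.float64))
    t = M.translation.copy()
    R = M.rotation
    # axis-angle: angle from the trace, axis from the skew-symmetric part
    cos_a = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.arccos(cos_a))
    if angle < 1e-12:
        return t, np.array([0.0, 0.0, 1.0]), 0.0
    skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if np.linalg.norm(skew) > 1e-9:
        axis = skew / np.linalg.norm(skew)
    else:
        # angle ~ 180 degrees: axis from the symmetric part R + I
        B = R + np.eye(3)
        axis = B[:, int(np.argmax(np.linalg.norm(B, axis=0)))]
        axis = axis / np.linalg.norm(axis)
    return t, axis, float(np.rad2deg(angle))


def twist_angle_deg(R: np.ndarray, axis: Sequence[float]) -> float:
    """Signed twist of rotation matrix ``R`` about unit ``axis`` (degrees,
    in (-180, 180]).

    The twist is the rotation about ``axis`` in the swing-twist
    factorization R = R_swing R_twist (swing axis orthogonal to ``axis``);
    equivalently the rotation about ``axis`` closest to R.  Closed form from
    the matrix entries: theta = atan2(a . skew(R), trace(R) - a^T R a).
    """
    a = np.asarray(axis, dtype=np.float64).reshape(3)
    R = np.asarray(R, dtype=np.float64)
    A = float(np.trace(R) - a @ R @ a)
    skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    B = float(a @ skew)
    return float(np.rad2deg(np.arctan2(B, A)))


# ---------------------------------------------------------------------------
# Per-fragment reports
# ---------------------------------------------------------------------------


def translation_report(
    fragment: TriangleMesh, M: RigidTransform, frame: ReferenceFrame
) -> TranslationReport:
    """Translation analysis: GP = fragment centroid before reduction,
    GR = M applied to GP; the GP->GR vector's 3D norm and per-plane
    projected norms."""
    GP = mesh_centroid(fragment)
    GR = M.apply(GP)
    v = GR - GP
    norm_3d = vector_norm3(v)
    projections = {
        plane: float(np.linalg.norm(project_onto_plane(v, normal)))
        for plane, normal in frame.plane_normals.items()
    }
    components = {
        "coronal": float(np.dot(v, frame.coro)),
        "sagittal": float(np.dot(v, frame.sag)),
        "axial": float(np.dot(v, frame.axial)),
    }
    return TranslationReport(
        GP=GP,
        GR=GR,
        trans_vector=v,
        norm_3d=norm_3d,
        proj_coronal=projections["coronal"],
        proj_sagittal=projections["sagittal"],
        proj_axial=projections["axial"],
        axis_components=components,
    )


def rotation_report(M: RigidTransform, frame: ReferenceFrame) -> RotationReport:
    """Rotation analysis: axis-angle of the fragment's displacement rotation
    (the inverse of M's rotation) and signed per-plane twists about the
    frame axes, side-aware."""
    _, axis_red, angle = decompose_transform(M)
    # displacement rotation = inverse of the reduction rotation
    R_disp = M.rotation.T
    axis = -axis_red if angle > 0 else axis_red
    signs = frame.twist_signs
    coronal = signs[0] * twist_angle_deg(R_disp, frame.coro)
    sagittal = signs[1] * twist_angle_deg(R_disp, frame.sag)
    axial = signs[2] * twist_angle_deg(R_disp, frame.axial)
    return RotationReport(
        axis=axis,
        angle_3d=angle,
        coronal_angle=coronal,
        sagittal_angle=sagittal,
        axial_angle=axial,
    )


# ---------------------------------------------------------------------------
# Neer criteria and bins
# ---------------------------------------------------------------------------


def _translation_bin(norm_mm: float) -> str:
    if norm_mm < 5.0:
        return TRANSLATION_BINS[0]
    if norm_mm < NEER_TRANSLATION_MM:
        return TRANSLATION_BINS[1]
    return TRANSLATION_BINS[2]


def _translation_fine_bin(norm_mm: float) -> str:
    if norm_mm < 5.0:
        return TRANSLATION_FINE_BINS[0]
    if norm_mm < 10.0:
        return TRANSLATION_FINE_BINS[1]
    if norm_mm <= 15.0:
        return TRANSLATION_FINE_BINS[2]
    return TRANSLATION_FINE_BINS[3]


def _rotation_class(angle_deg: float, plane: str) -> str:
    neg_hi, neg_lo, neutral, pos_lo, pos_hi = ROTATION_CLASSES[plane]
    if angle_deg <= -NEER_ANGLE_DEG:
        return neg_hi
    if angle_deg <= -5.0:
        return neg_lo
    if angle_deg < 5.0:
        return neutral
    if angle_deg < NEER_ANGLE_DEG:
        return pos_lo
    return pos_hi


def assess_neer(translation: TranslationReport, rotation: RotationReport) -> NeerAssessment:
    """Neer criteria: a fragment is displaced at >= 10 mm 3D translation or
    >= 45 degrees of rotation in any reference plane (both inclusive)."""
    max_angle = max(abs(a) for a in rotation.plane_angles().values())
    displaced = translation.norm_3d >= NEER_TRANSLATION_MM or max_angle >= NEER_ANGLE_DEG
    return NeerAssessment(
        displaced=bool(displaced),
        translation_bin=_translation_bin(translation.norm_3d),
        translation_fine_bin=_translation_fine_bin(translation.norm_3d),
        coronal_rotation_class=_rotation_class(rotation.coronal_angle, "coronal"),
        sagittal_rotation_class=_rotation_class(rotation.sagittal_angle, "sagittal"),
        axial_rotation_class=_rotation_class(rotation.axial_angle, "axial"),
    )


def measure_displacement(
    fragment: TriangleMesh, M: RigidTransform, frame: ReferenceFrame
) -> DisplacementReport:
    """Full per-fragment displacement report for reduction transform M."""
    tr = translation_report(fragment, M, frame)
    rot = rotation_report(M, frame)
    return DisplacementReport(
        label=fragment.label,
        transform=M,
        translation=tr,
        rotation=rot,
        neer=assess_neer(tr, rot),
    )


def count_neer_parts(
    assessments: Mapping[str, NeerAssessment] | Iterable[NeerAssessment],
) -> int:
    """Neer part count: 1 plus the number of displaced fragments, capped at
    4.  A fracture with no displaced fragment is 1-part by definition."""
    values = list(assessments.values()) if isinstance(assessments, Mapping) else list(assessments)
    if not values:
        raise ValueError("at least one fragment assessment is required")
    return min(1 + sum(a.displaced for a in values), 4)


# ---------------------------------------------------------------------------
# Cohort aggregation
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    """Cohort-level aggregation of displacement reports.

    * ``crosstab_axial`` / ``crosstab_sagittal``: axial (resp. sagittal)
      rotation class by coronal rotation class, with marginal totals;
    * ``coronal_class_counts`` / ``translation_fine_counts``: histogram
      tables;
    * ``underestimation``: per plane, the paired comparison of the 3D
      translation norm against its 2D in-plane projection — mean difference
      (mm), 95% CI and paired-t p-value.  Projection can only shorten a
      vector, so the mean difference is non-negative by construction.
    """

    n: int
    crosstab_axial: pd.DataFrame
    crosstab_sagittal: pd.DataFrame
    coronal_class_counts: pd.Series
    translation_fine_counts: pd.Series
    underestimation: pd.DataFrame
    displaced_fraction: float

    def to_csv_dir(self, outdir) -> list[str]:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, obj in [
            ("crosstab_coronal_by_axial.csv", self.crosstab_axial),
            ("crosstab_coronal_by_sagittal.csv", self.crosstab_sagittal),
            ("coronal_class_counts.csv", self.coronal_class_counts),
            ("translation_fine_counts.csv", self.translation_fine_counts),
            ("underestimation_2d_vs_3d.csv", self.underestimation),
        ]:
            path = outdir / name
            obj.to_csv(path)
            written.append(str(path))
        return written


def _crosstab(rows: pd.Series, cols: pd.Series, row_order, col_order) -> pd.DataFrame:
    tab = pd.crosstab(rows, cols, margins=True, margins_name="Total")
    tab = tab.reindex(index=list(row_order) + ["Total"], fill_value=0)
    tab = tab.reindex(columns=list(col_order) + ["Total"], fill_value=0)
    return tab


def summarize_cohort(reports: Sequence[DisplacementReport]) -> CohortSummary:
    """Aggregate a cohort of displacement reports."""
    if not reports:
        raise ValueError("cannot summarize an empty cohort")
    n = len(reports)
    df = pd.DataFrame(
        {
            "coronal_class": [r.neer.coronal_rotation_class for r in reports],
            "sagittal_class": [r.neer.sagittal_rotation_class for r in reports],
            "axial_class": [r.neer.axial_rotation_class for r in reports],
            "fine_bin": [r.neer.translation_fine_bin for r in reports],
            "displaced": [r.neer.displaced for r in reports],
            "norm_3d": [r.translation.norm_3d for r in reports],
            "proj_coronal": [r.translation.proj_coronal for r in reports],
            "proj_sagittal": [r.translation.proj_sagittal for r in reports],
            "proj_axial": [r.translation.proj_axial for r in reports],
        }
    )
    coronal_order = ROTATION_CLASSES["coronal"]
    crosstab_axial = _crosstab(
        df["axial_class"], df["coronal_class"], ROTATION_CLASSES["axial"], coronal_order
    )
    crosstab_sagittal = _crosstab(
        df["sagittal_class"], df["coronal_class"], ROTATION_CLASSES["sagittal"], coronal_order
    )
    coronal_counts = (
        df["coronal_class"].value_counts().reindex(coronal_order, fill_value=0)
    )
    fine_counts = df["fine_bin"].value_counts().reindex(TRANSLATION_FINE_BINS, fill_value=0)

    rows = {}
    for plane in ("coronal", "sagittal", "axial"):
        diffs = df["norm_3d"].to_numpy() - df[f"proj_{plane}"].to_numpy()
        mean = float(diffs.mean())
        if n > 1 and diffs.std(ddof=1) > 0:
            sem = diffs.std(ddof=1) / np.sqrt(n)
            half = stats.t.ppf(0.975, n - 1) * sem
            tt = stats.ttest_rel(df["norm_3d"], df[f"proj_{plane}"])
            p = float(tt.pvalue)
        else:
            half, p = 0.0, float("nan")
        rows[plane] = {
            "mean_diff_mm": mean,
            "ci95_low": mean - half,
            "ci95_high": mean + half,
            "p_value": p,
        }
    underest = pd.DataFrame(rows).T

    return CohortSummary(
        n=n,
        crosstab_axial=crosstab_axial,
        crosstab_sagittal=crosstab_sagittal,
        coronal_class_counts=coronal_counts,
        translation_fine_counts=fine_counts,
        underestimation=underest,
        displaced_fraction=float(df["displaced"].mean()),
    )
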