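"""Statistical shape model of the proximal humerus.

A PCA model over densely corresponded meshes (fixed topology, as emitted by
:mod:`phf3d.synthetic`): mean vertex coordinates plus orthonormal principal
modes of per-vertex displacement.  The model predicts the full pre-fracture
proximal humerus "blueprint" from a partial observation — the most proximal
segment (nominally 6 cm) of the unfractured diaphysis — by rigidly aligning
the observation to the model's shaft region (no scaling) and solving a
Tikhonov-regularized linear least-squares problem for the mode
coefficients, penalized in units of per-mode standard deviations.

Real-data correspondence (registration of clinical CT meshes onto the
model topology) is out of scope; this is the documented integration point
for a clinically trained model with the same interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .frame import AnatomyParameters
from .geometry import RigidTransform, TriangleMesh, rigid_align

__all__ = [
    "PredictionFailureError",
    "ShapeModel",
    "PartialObservation",
    "PredictionDiagnostics",
    "build_shape_model",
    "predict_prefracture",
    "prediction_error_report",
    "MIN_OBSERVATION_LENGTH_MM",
]

# predictions from less shaft than this are refused (the clinical method
# uses 6 cm; below 4 cm the fit is considered unreliable)
MIN_OBSERVATION_LENGTH_MM = 40.0


class PredictionFailureError(RuntimeError):
    """The observation cannot support a blueprint prediction (too short,
    or no usable correspondence with the model's shaft region)."""


@dataclass
class ShapeModel:
    """PCA shape model: mean shape, orthonormal modes, per-mode variances.

    ``modes`` has shape (k, 3V) with mutually orthonormal rows;
    ``mode_variances`` is non-increasing.  ``shaft_indices`` defines the
    model's shaft region (vertex ids) used for partial-observation fitting.
    """

    mean_vertices: np.ndarray
    faces: np.ndarray
    modes: np.ndarray
    mode_variances: np.ndarray
    n_training: int
    shaft_indices: np.ndarray
    total_variance: float
    retained_fraction: float
    version: str = "phf3d-ssm-1"

    @property
    def n_modes(self) -> int:
        return len(self.mode_variances)

    @property
    def mean_shape(self) -> TriangleMesh:
        return TriangleMesh(self.mean_vertices.copy(), self.faces.copy(), "blueprint")

    def synthesize(self, coefficients: Sequence[float]) -> TriangleMesh:
        """Mesh at the given mode coefficients (natural units, i.e. the
        coefficients multiply the unit-norm mode vectors)."""
        c = np.asarray(coefficients, dtype=np.float64)
        if len(c) != self.n_modes:
            raise ValueError(f"expected {self.n_modes} coefficients, got {len(c)}")
        v = self.mean_vertices.reshape(-1) + c @ self.modes
        return TriangleMesh(v.reshape(-1, 3), self.faces.copy(), "blueprint")

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Persist as an .npz archive with a JSON metadata entry."""
        meta = {
            "version": self.version,
            "n_training": int(self.n_training),
            "total_variance": float(self.total_variance),
            "retained_fraction": float(self.retained_fraction),
        }
        np.savez_compressed(
            Path(path),
            mean_vertices=self.mean_vertices,
            faces=self.faces,
            modes=self.modes,
            mode_variances=self.mode_variances,
            shaft_indices=self.shaft_indices,
            meta=json.dumps(meta),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ShapeModel":
        data = np.load(Path(path), allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        return cls(
            mean_vertices=data["mean_vertices"],
            faces=data["faces"],
            modes=data["modes"],
            mode_variances=data["mode_variances"],
            n_training=meta["n_training"],
            shaft_indices=data["shaft_indices"],
            total_variance=meta["total_variance"],
            retained_fraction=meta["retained_fraction"],
            version=meta["version"],
        )


@dataclass(frozen=True)
class PartialObservation:
    """The observed unfractured shaft segment, corresponded to the model.

    ``vertex_indices`` maps each observation vertex to a model vertex id
    (correspondence by construction for synthetic meshes).  The observation
    must span at least :data:`MIN_OBSERVATION_LENGTH_MM` along its long
    axis.
    """

    mesh: TriangleMesh
    vertex_indices: np.ndarray
    groove_points: np.ndarray | None = None

    def length_mm(self) -> float:
        """Extent along the principal axis of the observed points."""
        pts = self.mesh.vertices
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[0]
        return float(proj.max() - proj.min())


@dataclass(frozen=True)
class PredictionDiagnostics:
    coefficients: np.ndarray
    shaft_rms_mm: float
    pose: RigidTransform  # model frame -> observation frame
    observation_length_mm: float


def build_shape_model(
    training: Sequence[TriangleMesh],
    variance_to_retain: float = 0.98,
    shaft_indices: np.ndarray | None = None,
    min_training: int = 10,
) -> ShapeModel:
    """Build the PCA model from a corresponded training population.

    All meshes must share vertex count and face array.  Retains the
    smallest number of leading modes explaining at least
    ``variance_to_retain`` of the total vertex-coordinate variance.
    A zero-variance population (identical meshes) yields zero modes.
    """
    meshes = [m.mesh if hasattr(m, "mesh") else m for m in training]  # accept SyntheticHumerus
    if len(meshes) < min_training:
        raise ValueError(f"need >= {min_training} training meshes, got {len(meshes)}")
    faces0 = meshes[0].faces
    nv = meshes[0].n_vertices
    for m in meshes[1:]:
        if m.n_vertices != nv or not np.array_equal(m.faces, faces0):
            raise ValueError("training meshes are not corresponded (topology mismatch)")
    X = np.stack([m.vertices.reshape(-1) for m in meshes])
    mean = X.mean(axis=0)
    Xc = X - mean
    # thin SVD of the (n, 3V) data matrix
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    variances = s**2 / (len(meshes) - 1) if len(meshes) > 1 else s * 0.0
    total = float(variances.sum())
    if total <= 1e-12:
        modes = np.empty((0, X.shape[1]))
        variances = np.empty(0)
        retained = 1.0
    else:
        frac = np.cumsum(variances) / total
        k = int(np.searchsorted(frac, variance_to_retain - 1e-12) + 1)
        k = min(k, int((variances > 1e-12 * total).sum()))
        modes = Vt[:k]
        retained = float(frac[k - 1])
        variances = variances[:k]
    if shaft_indices is None:
        shaft_indices = np.arange(nv)
    return ShapeModel(
        mean_vertices=mean.reshape(-1, 3),
        faces=faces0.copy(),
        modes=modes,
        mode_variances=variances,
        n_training=len(meshes),
        shaft_indices=np.asarray(shaft_indices, dtype=np.int64),
        total_variance=total,
        retained_fraction=retained,
    )


def predict_prefracture(
    model: ShapeModel,
    obs: PartialObservation,
    regularization: float = 1.0,
) -> tuple[TriangleMesh, PredictionDiagnostics]:
    """Predict the full pre-fracture proximal humerus from a shaft segment.

    The observation is rigidly aligned (Kabsch, no scaling) onto the
    corresponding model vertices; mode coefficients then minimize

        || A c - b ||^2  +  lambda * sum_i (c_i / sigma_i)^2

    where A restricts the modes to the observed vertices, b is the aligned
    observation residual to the mean shape, and sigma_i are per-mode
    standard deviations.  The predicted mesh is returned posed in the
    observation's coordinates; diagnostics carry the coefficients and the
    shaft-region RMS residual.
    """
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    length = obs.length_mm()
    if length < MIN_OBSERVATION_LENGTH_MM:
        raise PredictionFailureError(
            f"observed shaft segment spans {length:.1f} mm "
            f"(< {MIN_OBSERVATION_LENGTH_MM:.0f} mm); cannot predict the blueprint"
        )
    idx = np.asarray(obs.vertex_indices, dtype=np.int64)
    if len(idx) != obs.mesh.n_vertices:
        raise PredictionFailureError("observation/model correspondence is incomplete")
    if len(idx) < 10:
        raise PredictionFailureError("too few corresponded observation vertices")

    mean_obs = model.mean_vertices[idx]
    # pose: observation frame -> model frame (rigid only, honoring the
    # no-resizing constraint)
    to_model = rigid_align(obs.mesh.vertices, mean_obs)
    aligned = to_model.apply(obs.mesh.vertices)
    b = (aligned - mean_obs).reshape(-1)

    if model.n_modes == 0:
        coeffs = np.empty(0)
        predicted_vertices = model.mean_vertices.copy()
    else:
        cols = (idx[:, None] * 3 + np.arange(3)).reshape(-1)
        A = model.modes[:, cols].T  # (3m, k)
        if regularization == 0:
            # unpenalized: minimum-norm solution guards against modes with
            # (numerically) no expression in the observed region
            coeffs, *_ = np.linalg.lstsq(A, b, rcond=None)
        else:
            sigma2 = np.maximum(model.mode_variances, 1e-18)
            lhs = A.T @ A + regularization * np.diag(1.0 / sigma2)
            coeffs = np.linalg.solve(lhs, A.T @ b)
        predicted_vertices = (
            model.mean_vertices.reshape(-1) + coeffs @ model.modes
        ).reshape(-1, 3)

    # residual over the observed region, in model pose
    fitted_obs = predicted_vertices[idx]
    rms = float(np.sqrt(np.mean(np.sum((aligned - fitted_obs) ** 2, axis=1))))

    to_obs = to_model.inverse()
    predicted = TriangleMesh(to_obs.apply(predicted_vertices), model.faces.copy(), "blueprint")
    diag = PredictionDiagnostics(
        coefficients=coeffs,
        shaft_rms_mm=rms,
        pose=to_obs,
        observation_length_mm=length,
    )
    return predicted, diag


def prediction_error_report(
    predicted: TriangleMesh,
    truth: TriangleMesh,
    measure_fn,
) -> dict[str, float]:
    """Absolute differences of the six anatomical parameters between a
    predicted blueprint and the true bone.  ``measure_fn`` maps a mesh to
    :class:`~phf3d.frame.AnatomyParameters` (for fixed-topology synthetic
    meshes use :func:`phf3d.synthetic.make_anatomy_measurer`)."""
    a = measure_fn(predicted)
    b = measure_fn(truth)
    return {
        name: abs(getattr(a, name) - getattr(b, name))
        for name in AnatomyParameters.FIELDS
    }
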