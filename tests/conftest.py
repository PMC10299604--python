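"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from hypothesis import settings as hyp_settings
from scipy.spatial.transform import Rotation

import phf3d as p

hyp_settings.register_profile("ci", derandomize=True, max_examples=200)
hyp_settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the implementation paths they check)
# ---------------------------------------------------------------------------


def quaternion_twist_deg(R: np.ndarray, axis: np.ndarray) -> float:
    """Swing-twist oracle: project the rotation quaternion onto the twist
    axis and renormalize.  Independent of the matrix closed form used by
    the implementation."""
    q = Rotation.from_matrix(R).as_quat()  # (x, y, z, w)
    v, w = q[:3], q[3]
    if w < 0:
        v, w = -v, -w
    proj = float(np.dot(v, axis))
    return float(np.rad2deg(2.0 * np.arctan2(proj, w)))


def algebraic_sphere_fit(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Sphere fit oracle: solve |p|^2 = 2 c.p + k as a linear system."""
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def brute_force_neer(norm_3d, coronal, sagittal, axial):
    """Literal threshold evaluation of the Neer displacement rule."""
    return norm_3d >= 10.0 or max(abs(coronal), abs(sagittal), abs(axial)) >= 45.0


def random_frame(rng: np.random.Generator) -> p.ReferenceFrame:
    """A valid random reference frame from a random (axial, anatneck) pair
    (rejecting near-parallel pairs, which have no defined coronal axis)."""
    while True:
        axial = rng.normal(size=3)
        axial /= np.linalg.norm(axial)
        anatneck = rng.normal(size=3)
        anatneck /= np.linalg.norm(anatneck)
        if np.abs(np.cross(axial, anatneck)).max() > 1e-3:
            break
    coro = np.cross(axial, anatneck)
    coro /= np.linalg.norm(coro)
    sag = np.cross(axial, coro)
    sag /= np.linalg.norm(sag)
    return p.ReferenceFrame(
        origin_O=rng.normal(0, 30, 3),
        axial=axial,
        anatneck=anatneck,
        coro=coro,
        sag=sag,
        side="right",
    )


@pytest.fixture(scope="session")
def oracles():
    class Oracles:
        quaternion_twist_deg = staticmethod(quaternion_twist_deg)
        algebraic_sphere_fit = staticmethod(algebraic_sphere_fit)
        brute_force_neer = staticmethod(brute_force_neer)
        random_frame = staticmethod(random_frame)

    return Oracles


# ---------------------------------------------------------------------------
# Shared geometry fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def humerus():
    """Default synthetic humerus at moderate resolution."""
    return p.generate_humerus(resolution=36)


@pytest.fixture(scope="session")
def humerus_frame(humerus):
    """Reference frame built (not copied from ground truth) on the default
    humerus."""
    return p.build_reference_frame(
        humerus.mesh,
        humerus.landmarks["neck_points"],
        humerus.mesh.vertices[humerus.shaft_mask],
        humerus.landmarks["glenoid_hint"],
        side="right",
    )


@pytest.fixture(scope="session")
def synthetic_settings():
    """Registration settings for synthetic fragments: these are cut from
    the intact surface and carry no fracture-surface outliers, so the
    appropriate trim keeps nearly all correspondences."""
    return p.ReductionSettings(trim_fraction=0.95)
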