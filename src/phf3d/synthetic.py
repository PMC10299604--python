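"""Parametric synthetic proximal humerus: meshes, populations, fractures.

This module is the package's test bed: it generates watertight
fixed-topology humerus meshes with exact ground-truth landmarks and
reference frames, samples anatomically dispersed populations for shape
model training, and cuts simulated fractures whose fragment displacements
are known exactly.

Geometry (canonical right-side frame, mm): +x medial, +y posterior,
+z proximal.  The bone is a surface of stacked vertex rings:

* a cylindrical diaphysis (radius ``shaft_radius``) carrying a shallow
  bicipital-groove sulcus at azimuth ``groove_angle``,
* a metaphysis blending the shaft circle into the anatomical-neck rim,
  carrying greater- and lesser-tuberosity prominences,
* a spherical articular cap (radius ``head_radius``) centred on the head
  center O, bounded by the anatomical-neck plane whose normal (*anatneck*)
  points supero-medially toward the glenoid.

The neck-shaft inclination is the clinical angle: ``inclination`` =
180 deg - angle(axial, anatneck), default 135.  Retroversion rotates
anatneck posteriorly about the axial axis.  All rings share one azimuth
parametrization, so meshes generated at the same resolution are densely
corresponded by construction.

Fragment cutting uses smooth parametric regions (bands of the ring
lattice), not irregular fracture lines — sufficient for transform-recovery
testing, a stated realism limitation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .frame import ReferenceFrame
from .geometry import CylinderAxis, Plane, RigidTransform, TriangleMesh, mesh_centroid, unit

__all__ = [
    "HumerusParams",
    "MeshResolution",
    "SyntheticHumerus",
    "FragmentDisplacement",
    "FractureSpec",
    "SyntheticFracture",
    "CohortDistributions",
    "DEFAULT_DISPERSIONS",
    "generate_humerus",
    "sample_population",
    "simulate_fracture",
    "sample_cohort",
    "shaft_observation",
    "make_anatomy_measurer",
]


@dataclass(frozen=True)
class HumerusParams:
    """Anatomical parameters of the synthetic humerus (mm / degrees).

    Defaults are typical adult values: 24 mm head radius, 135 deg
    neck-shaft inclination, 20 deg retroversion, ~2.5 mm posterior and
    ~6.5 mm medial head-center offset.
    """

    shaft_radius: float = 12.0
    shaft_length: float = 100.0
    head_radius: float = 24.0
    inclination: float = 135.0
    retroversion: float = 20.0
    posterior_offset: float = 2.5
    medial_offset: float = 6.5
    groove_angle: float = -60.0  # azimuth of the bicipital groove, from medial toward posterior
    head_center_height: float = 19.0  # height of O above the shaft top
    cap_half_angle: float = 75.0  # articular cap half-angle about anatneck
    gt_prominence: float = 4.0  # greater tuberosity radial bump
    lt_prominence: float = 2.5  # lesser tuberosity radial bump
    groove_depth: float = 1.2
    side: str = "right"

    def __post_init__(self) -> None:
        if min(self.shaft_radius, self.head_radius, self.head_center_height) <= 0:
            raise ValueError("lengths must be positive")
        if self.shaft_length < 80.0:
            raise ValueError("shaft_length must be >= 80 mm")
        if not 110.0 < self.inclination < 160.0:
            raise ValueError("inclination must lie in (110, 160) degrees")
        if not 0 < self.cap_half_angle < 90:
            raise ValueError("cap_half_angle must lie in (0, 90) degrees")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    def replace(self, **kw) -> "HumerusParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class MeshResolution:
    """Ring lattice resolution.  ``from_theta`` scales the band counts from
    the azimuthal sample count."""

    n_theta: int = 48
    n_shaft: int = 16
    n_meta: int = 12
    n_cap: int = 12

    @classmethod
    def from_theta(cls, n_theta: int) -> "MeshResolution":
        return cls(
            n_theta=n_theta,
            n_shaft=max(8, n_theta // 3),
            n_meta=max(6, n_theta // 4),
            n_cap=max(6, n_theta // 4),
        )


# angular half-widths (degrees) of the tuberosity bumps and groove
_GT_AZIMUTH = 180.0  # lateral
_GT_SIGMA = 22.0
_LT_AZIMUTH = -95.0  # anterior, just lateral of the groove
_LT_SIGMA = 14.0
_GROOVE_SIGMA = 8.0

# Diaphyseal signatures of the proximal anatomy: each head parameter leaves
# a small, distinct trace on the shaft surface (a taper for head size and
# mutually orthogonal circumferential harmonics for the others), emulating
# the anatomical covariation that lets the unfractured diaphysis predict the
# pre-fracture head.  Amplitudes are ~0.3 mm per population SD — subtle
# against the 12 mm shaft radius, and chosen with zero mean and no first
# harmonic so least-squares cylinder fits stay unbiased.
_SHAFT_COUPLING = {
    "head_radius": ("taper", 0.15),  # mm of proximal flare per mm of head radius
    "inclination": ("cos2", 0.06),  # mm per degree
    "retroversion": ("sin2", 0.04),
    "posterior_offset": ("cos3", 0.30),  # mm per mm
    "medial_offset": ("sin3", 0.20),
}


def _shaft_signature(p: "HumerusParams", t: np.ndarray) -> tuple[np.ndarray, float]:
    """Circumferential signature (per-azimuth mm) and taper coefficient
    encoding the deviation of the head parameters from the reference
    anatomy.  The taper term scales with height as (z + L) / L."""
    ref = HumerusParams()
    sig = np.zeros_like(t)
    taper = 0.0
    for name, (kind, amp) in _SHAFT_COUPLING.items():
        dev = getattr(p, name) - getattr(ref, name)
        if kind == "taper":
            taper += amp * dev
        elif kind == "cos2":
            sig = sig + amp * dev * np.cos(2 * t)
        elif kind == "sin2":
            sig = sig + amp * dev * np.sin(2 * t)
        elif kind == "cos3":
            sig = sig + amp * dev * np.cos(3 * t)
        elif kind == "sin3":
            sig = sig + amp * dev * np.sin(3 * t)
    return sig, taper


@dataclass
class SyntheticHumerus:
    """A generated humerus: mesh, exact landmarks, ground-truth frame and
    the lattice bookkeeping needed for correspondence and fragment cutting."""

    mesh: TriangleMesh
    params: HumerusParams
    resolution: MeshResolution
    frame: ReferenceFrame
    landmarks: dict
    seed: int
    # per-vertex lattice coordinates
    vertex_band: np.ndarray  # 0 bottom pole, 1 shaft, 2 metaphysis, 3 cap, 4 apex
    vertex_s: np.ndarray  # band parameter: z for shaft, s for meta, polar angle for cap
    vertex_t: np.ndarray  # azimuth parameter (radians)
    shaft_mask: np.ndarray = field(default=None)
    cap_mask: np.ndarray = field(default=None)
    neck_ring_indices: np.ndarray = field(default=None)

    def shaft_vertex_indices(self, length_mm: float = 60.0) -> np.ndarray:
        """Indices of shaft-band vertices within ``length_mm`` of the shaft
        top (the 'most proximal X cm of the unfractured shaft')."""
        sel = (self.vertex_band == 1) & (self.vertex_s >= -length_mm - 1e-9)
        return np.nonzero(sel)[0]

    def anchor_vertex_indices(self, meta_s_max: float = 0.2) -> np.ndarray:
        """Indices of the blueprint-anchoring region: the whole shaft plus
        the lower metaphyseal flare (below the typical surgical-neck cut).
        The flare breaks the axial-slide invariance of a plain cylinder, so
        shaft-anchored registration is well posed."""
        sel = (self.vertex_band == 1) | (
            (self.vertex_band == 2) & (self.vertex_s <= meta_s_max)
        )
        return np.nonzero(sel)[0]


def _minimal_rotation_frame(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane basis (u, v) of the plane with normal n, obtained by the
    minimal rotation carrying z to n applied to (x, y); keeps the azimuth
    parametrization continuous across bands."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, n))
    if c > 1.0 - 1e-12:
        R = np.eye(3)
    else:
        axis = np.cross(z, n)
        R = Rotation.from_rotvec(unit(axis) * np.arccos(np.clip(c, -1, 1))).as_matrix()
    return R @ np.array([1.0, 0.0, 0.0]), R @ np.array([0.0, 1.0, 0.0])


def _wrapped_gauss(t: np.ndarray, center_deg: float, sigma_deg: float) -> np.ndarray:
    d = np.rad2deg(t) - center_deg
    d = (d + 180.0) % 360.0 - 180.0
    return np.exp(-0.5 * (d / sigma_deg) ** 2)


def generate_humerus(
    params: HumerusParams = HumerusParams(),
    resolution: MeshResolution | int = 48,
    seed: int = 0,
) -> SyntheticHumerus:
    """Generate a watertight synthetic proximal humerus.

    Deterministic for a given (params, resolution, seed); the mesh topology
    depends only on the resolution, so meshes of a population are densely
    corresponded by construction.  Returns the mesh together with exact
    landmarks (10 anatomical-neck points on the neck rim, bicipital-groove
    points, head center, glenoid hint) and the construction reference frame.
    """
    if isinstance(resolution, int):
        resolution = MeshResolution.from_theta(resolution)
    p = params
    res = resolution
    nt = res.n_theta
    t = 2.0 * np.pi * np.arange(nt) / nt  # azimuth from +x (medial) toward +y (posterior)
    cos_t, sin_t = np.cos(t), np.sin(t)

    alpha = np.deg2rad(180.0 - p.inclination)  # anatneck polar angle from +z
    retro = np.deg2rad(p.retroversion)
    anatneck = np.array(
        [np.sin(alpha) * np.cos(retro), np.sin(alpha) * np.sin(retro), np.cos(alpha)]
    )
    # offsets are defined in the anatomical frame's own basis (the coronal
    # plane rotates with retroversion), so measurement round-trips exactly
    z_axis = np.array([0.0, 0.0, 1.0])
    coro0 = unit(np.cross(z_axis, anatneck))
    sag0 = unit(np.cross(z_axis, coro0))
    O = (
        p.medial_offset * (-sag0)
        + p.posterior_offset * coro0
        + p.head_center_height * z_axis
    )
    phi_cap = np.deg2rad(p.cap_half_angle)
    rim_center = O + p.head_radius * np.cos(phi_cap) * anatneck
    rim_radius = p.head_radius * np.sin(phi_cap)
    u_n, v_n = _minimal_rotation_frame(anatneck)

    # groove modulation with its mean and first circular harmonic removed:
    # the local sulcus survives (it locks the azimuth in registrations) but
    # the least-squares cylinder of the shaft keeps the nominal axis/radius
    groove = p.groove_depth * _wrapped_gauss(t, p.groove_angle, _GROOVE_SIGMA)
    groove = groove - groove.mean()
    for harmonic in (np.cos(t - np.deg2rad(p.groove_angle)), np.sin(t - np.deg2rad(p.groove_angle))):
        denom = float(harmonic @ harmonic)
        if denom > 0:
            groove = groove - (float(groove @ harmonic) / denom) * harmonic
    gt_bump = p.gt_prominence * _wrapped_gauss(t, _GT_AZIMUTH, _GT_SIGMA)
    lt_bump = p.lt_prominence * _wrapped_gauss(t, _LT_AZIMUTH, _LT_SIGMA)

    vertices: list[np.ndarray] = []
    band: list[np.ndarray] = []
    sparam: list[np.ndarray] = []
    tparam: list[np.ndarray] = []

    def add_ring(pts: np.ndarray, b: int, s: float) -> None:
        vertices.append(pts)
        band.append(np.full(nt, b))
        sparam.append(np.full(nt, s))
        tparam.append(t)

    # bottom pole
    vertices.append(np.array([[0.0, 0.0, -p.shaft_length - p.shaft_radius * 0.4]]))
    band.append(np.array([0]))
    sparam.append(np.array([-p.shaft_length]))
    tparam.append(np.array([0.0]))

    signature, taper = _shaft_signature(p, t)

    # shaft rings, z from -L to 0
    for z in np.linspace(-p.shaft_length, 0.0, res.n_shaft + 1):
        rho = p.shaft_radius - groove + signature + taper * (z + p.shaft_length) / p.shaft_length
        ring = np.column_stack([rho * cos_t, rho * sin_t, np.full(nt, z)])
        add_ring(ring, 1, z)

    # metaphysis rings, s in (0, 1]; s=1 is the anatomical-neck rim
    for s in np.linspace(0.0, 1.0, res.n_meta + 1)[1:]:
        h = s * s * (3.0 - 2.0 * s)  # smoothstep
        center = h * rim_center
        base = (1.0 - h) * p.shaft_radius + h * rim_radius
        normal = unit((1.0 - h) * np.array([0.0, 0.0, 1.0]) + h * anatneck)
        u, v = _minimal_rotation_frame(normal)
        env = np.sin(np.pi * s) ** 2
        rho = base + env * (gt_bump + lt_bump) + (1.0 - h) * (signature + taper - groove)
        ring = center + rho[:, None] * (np.outer(cos_t, u) + np.outer(sin_t, v))
        add_ring(ring, 2, s)

    # articular cap rings, polar angle from phi_cap down toward the apex
    for phi in np.linspace(phi_cap, 0.0, res.n_cap + 1)[1:-1]:
        center = O + p.head_radius * np.cos(phi) * anatneck
        rho = p.head_radius * np.sin(phi)
        ring = center + rho * (np.outer(cos_t, u_n) + np.outer(sin_t, v_n))
        add_ring(ring, 3, float(phi))
    # apex
    vertices.append((O + p.head_radius * anatneck)[None, :])
    band.append(np.array([4]))
    sparam.append(np.array([0.0]))
    tparam.append(np.array([0.0]))

    V = np.vstack(vertices)
    band_arr = np.concatenate(band)
    s_arr = np.concatenate(sparam)
    t_arr = np.concatenate(tparam)

    # faces: bottom fan, quad strips between consecutive rings, top fan
    n_rings = res.n_shaft + 1 + res.n_meta + res.n_cap - 1
    faces: list[tuple[int, int, int]] = []
    ring_start = lambda r: 1 + r * nt  # noqa: E731
    # bottom fan (outward = downward): wind so normals point away from the bone
    for k in range(nt):
        faces.append((0, ring_start(0) + (k + 1) % nt, ring_start(0) + k))
    for r in range(n_rings - 1):
        a0, b0 = ring_start(r), ring_start(r + 1)
        for k in range(nt):
            k1 = (k + 1) % nt
            faces.append((a0 + k, a0 + k1, b0 + k))
            faces.append((a0 + k1, b0 + k1, b0 + k))
    apex = len(V) - 1
    top0 = ring_start(n_rings - 1)
    for k in range(nt):
        faces.append((top0 + k, top0 + (k + 1) % nt, apex))
    F = np.asarray(faces, dtype=np.int64)

    # exact landmarks
    psi = 2.0 * np.pi * np.arange(10) / 10
    neck_points = rim_center + rim_radius * (
        np.outer(np.cos(psi), u_n) + np.outer(np.sin(psi), v_n)
    )
    tg = np.deg2rad(p.groove_angle)
    groove_dir = np.array([np.cos(tg), np.sin(tg), 0.0])
    groove_rho = p.shaft_radius - p.groove_depth
    groove_z = np.linspace(-55.0, -5.0, 8)
    groove_points = groove_rho * groove_dir + np.outer(groove_z, [0.0, 0.0, 1.0])
    glenoid_hint = np.array([1.0, 0.0, 0.0])  # medial

    axial = np.array([0.0, 0.0, 1.0])

    if p.side == "left":
        # mirror medial-lateral and flip winding to keep outward normals
        M = np.diag([-1.0, 1.0, 1.0])
        V = V @ M
        F = F[:, [0, 2, 1]]
        neck_points = neck_points @ M
        groove_points = groove_points @ M
        glenoid_hint = M @ glenoid_hint
        anatneck = M @ anatneck
        O = M @ O
        rim_center = M @ rim_center

    coro = unit(np.cross(axial, anatneck))
    sag = unit(np.cross(axial, coro))
    frame = ReferenceFrame(
        origin_O=O,
        axial=axial,
        anatneck=anatneck,
        coro=coro,
        sag=sag,
        side=p.side,
        diaphyseal_axis=CylinderAxis(np.zeros(3), axial, p.shaft_radius),
        neck_plane=Plane(rim_center, anatneck),
        head_radius=p.head_radius,
    )

    mesh = TriangleMesh(V, F, label="blueprint")
    landmarks = {
        "neck_points": neck_points,
        "groove_points": groove_points,
        "head_center": O.copy(),
        "glenoid_hint": glenoid_hint,
        "side": p.side,
    }
    neck_ring = 1 + (res.n_shaft + res.n_meta) * nt + np.arange(nt)
    return SyntheticHumerus(
        mesh=mesh,
        params=p,
        resolution=res,
        frame=frame,
        landmarks=landmarks,
        seed=seed,
        vertex_band=band_arr,
        vertex_s=s_arr,
        vertex_t=t_arr,
        shaft_mask=band_arr == 1,
        cap_mask=(band_arr == 3) | (band_arr == 4),
        neck_ring_indices=neck_ring,
    )


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

# sampling standard deviations for anatomical variation (mm / degrees)
DEFAULT_DISPERSIONS: dict[str, float] = {
    "head_radius": 2.0,
    "inclination": 5.0,
    "retroversion": 8.0,
    "posterior_offset": 1.0,
    "medial_offset": 1.5,
    "shaft_radius": 1.0,
}


def _tangent_basis(
    base: HumerusParams, names: Sequence[str], resolution: MeshResolution | int
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Base vertices and per-parameter vertex-displacement fields (central
    finite differences of the generator)."""
    v0 = generate_humerus(base, resolution=resolution).mesh.vertices
    fields = {}
    for name in names:
        eps = 0.01
        lo = generate_humerus(
            base.replace(**{name: getattr(base, name) - eps}), resolution=resolution
        ).mesh.vertices
        hi = generate_humerus(
            base.replace(**{name: getattr(base, name) + eps}), resolution=resolution
        ).mesh.vertices
        fields[name] = (hi - lo) / (2.0 * eps)
    return v0, fields


def sample_population(
    base: HumerusParams = HumerusParams(),
    dispersions: Mapping[str, float] | None = None,
    n: int = 50,
    seed: int = 0,
    resolution: MeshResolution | int = 48,
    max_resample: int = 50,
    linearize: bool = True,
) -> list[SyntheticHumerus]:
    """Sample ``n`` humeri with normally dispersed anatomical parameters
    (means = ``base``, standard deviations = ``dispersions``).  All meshes
    share one topology.  Invalid draws are resampled up to
    ``max_resample`` times.

    With ``linearize`` (default), vertices are drawn from the linear shape
    space tangent to the parametric generator at ``base`` — the population
    then spans exactly the low-dimensional linear space a PCA shape model
    assumes, and every latent factor is observable in the diaphysis through
    the generator's shaft signatures.  Landmarks and frames come from the
    exact generator at the drawn parameters (consistent with the linearized
    vertices to second order in the dispersions).  With
    ``linearize=False`` meshes are exact nonlinear generator output."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    disp = DEFAULT_DISPERSIONS if dispersions is None else dict(dispersions)
    rng = np.random.default_rng(seed)
    names = list(disp)
    basis = _tangent_basis(base, names, resolution) if linearize else None
    out = []
    for i in range(n):
        for attempt in range(max_resample + 1):
            deltas = {k: rng.normal(0.0, s) for k, s in disp.items()}
            try:
                params = base.replace(
                    **{k: getattr(base, k) + d for k, d in deltas.items()}
                )
                break
            except ValueError:
                if attempt == max_resample:
                    raise ValueError(
                        "could not draw valid humerus parameters; dispersions too wide"
                    )
        humerus = generate_humerus(params, resolution=resolution, seed=seed + i)
        if linearize:
            v0, fields = basis
            v = v0.copy()
            for k, d in deltas.items():
                v = v + d * fields[k]
            humerus.mesh = TriangleMesh(v, humerus.mesh.faces, humerus.mesh.label)
        out.append(humerus)
    return out


# ---------------------------------------------------------------------------
# Fractures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentDisplacement:
    """Displacement of one fragment from its anatomic pose: a rotation of
    ``angle_deg`` about ``axis`` through the fragment centroid, then a
    ``translation`` (mm)."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    angle_deg: float = 0.0


@dataclass(frozen=True)
class FractureSpec:
    """Which fracture lines exist and how each fragment is displaced."""

    pattern: tuple[str, ...] = ("surgical_neck",)
    displacements: Mapping[str, FragmentDisplacement] = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        valid = {"surgical_neck", "greater_tuberosity", "lesser_tuberosity"}
        if not self.pattern:
            raise ValueError("fracture pattern must not be empty")
        unknown = set(self.pattern) - valid
        if unknown:
            raise ValueError(f"unknown fracture lines: {sorted(unknown)}")


@dataclass
class SyntheticFracture:
    """Fragments in displaced pose, the intact bone, and per-fragment exact
    reduction transforms (displaced -> anatomic, stored before noise)."""

    fragments: dict[str, TriangleMesh]
    anatomic_fragments: dict[str, TriangleMesh]
    intact: SyntheticHumerus
    ground_truth: dict[str, RigidTransform]
    spec: FractureSpec
    seed: int


def _face_regions(humerus: SyntheticHumerus, pattern: Sequence[str], neck_cut_s: float) -> np.ndarray:
    """Assign each face to a fragment label by the lattice coordinates of
    its vertices.  Priority: tuberosities, then head, else shaft."""
    mesh = humerus.mesh
    fb = humerus.vertex_band[mesh.faces]
    fs = humerus.vertex_s[mesh.faces]
    ft = humerus.vertex_t[mesh.faces]
    # face-level parameters
    band_max = fb.max(axis=1)
    in_meta = (fb == 2).any(axis=1)
    n_meta_v = (fb == 2).sum(axis=1)
    s_face = np.where(fb == 2, fs, 0.0).sum(axis=1) / np.maximum(n_meta_v, 1)
    s_face[n_meta_v == 0] = np.nan
    # circular mean azimuth over ring vertices (bands 1-3)
    ring_v = fb >= 1
    cx = np.where(ring_v, np.cos(ft), 0.0).sum(axis=1)
    sx = np.where(ring_v, np.sin(ft), 0.0).sum(axis=1)
    # lattice azimuth is anatomical azimuth (medial -> posterior positive)
    # on both sides: mirroring flips world x but also the lattice winding.
    az = np.rad2deg(np.arctan2(sx, cx))

    def near(az_deg: np.ndarray, center: float, half_width: float) -> np.ndarray:
        d = (az_deg - center + 180.0) % 360.0 - 180.0
        return np.abs(d) < half_width

    labels = np.full(mesh.n_faces, "shaft", dtype=object)
    head_region = (band_max >= 3) | (in_meta & (s_face > neck_cut_s))
    if "surgical_neck" in pattern:
        labels[head_region] = "head"
    tuber_band = in_meta & (s_face > 0.12) & (s_face < 0.9) & (band_max < 3)
    if "greater_tuberosity" in pattern:
        labels[tuber_band & near(az, _GT_AZIMUTH, 2.0 * _GT_SIGMA)] = "greater_tuberosity"
    if "lesser_tuberosity" in pattern:
        labels[tuber_band & near(az, _LT_AZIMUTH, 1.8 * _LT_SIGMA)] = "lesser_tuberosity"
    return labels


def _submesh(mesh: TriangleMesh, face_mask: np.ndarray, label: str) -> TriangleMesh:
    faces = mesh.faces[face_mask]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(mesh.vertices[used], remap[faces], label)


def simulate_fracture(
    humerus: SyntheticHumerus,
    spec: FractureSpec = FractureSpec(),
    neck_cut_s: float = 0.25,
) -> SyntheticFracture:
    """Cut the humerus into the requested fragments and displace each one.

    Fragments are open shells cut from the intact surface along lattice
    bands (the surgical-neck cut sits at metaphysis parameter
    ``neck_cut_s``).  Each fragment listed in ``spec.displacements`` is
    moved by its :class:`FragmentDisplacement` (rotation about its own
    anatomic centroid, then translation); independent Gaussian vertex
    jitter of ``spec.noise_sigma`` mm is added afterwards.  The stored
    ground-truth transform is the exact noise-free reduction
    (displaced -> anatomic); composing displacement then reduction is the
    identity to machine precision.
    """
    labels_per_face = _face_regions(humerus, spec.pattern, neck_cut_s)
    rng = np.random.default_rng(spec.seed)

    fragment_labels = ["shaft"]
    if "surgical_neck" in spec.pattern:
        fragment_labels.append("head")
    if "greater_tuberosity" in spec.pattern:
        fragment_labels.append("greater_tuberosity")
    if "lesser_tuberosity" in spec.pattern:
        fragment_labels.append("lesser_tuberosity")

    fragments: dict[str, TriangleMesh] = {}
    anatomic: dict[str, TriangleMesh] = {}
    ground_truth: dict[str, RigidTransform] = {}
    for label in fragment_labels:
        mask = labels_per_face == label
        if not mask.any():
            raise ValueError(f"fracture cut produced an empty fragment: {label}")
        frag = _submesh(humerus.mesh, mask, label)
        anatomic[label] = frag
        disp = spec.displacements.get(label, FragmentDisplacement())
        centroid = mesh_centroid(frag)
        if disp.angle_deg == 0.0 and not any(disp.translation):
            D = RigidTransform.identity()
        else:
            D = RigidTransform.from_axis_angle(
                disp.axis, disp.angle_deg, translation=disp.translation, center=centroid
            )
        moved = frag.transformed(D)
        if spec.noise_sigma > 0:
            moved = TriangleMesh(
                moved.vertices + rng.normal(0.0, spec.noise_sigma, moved.vertices.shape),
                moved.faces,
                label,
            )
        fragments[label] = moved
        ground_truth[label] = D.inverse()

    return SyntheticFracture(
        fragments=fragments,
        anatomic_fragments=anatomic,
        intact=humerus,
        ground_truth=ground_truth,
        spec=spec,
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortDistributions:
    """Sampling distributions for simulated fracture cohorts.

    Defaults are loosely shaped like the fracture-pattern frequencies and
    displacement magnitudes observed clinically: the surgical neck is
    fractured in ~90% of cases, the greater tuberosity in ~91%, the lesser
    tuberosity in ~44%; head rotation is drawn per plane (varus-skewed
    coronal, posterior-skewed sagittal, retroversion-skewed axial) and
    tuberosity translation components are isotropic normal.
    """

    p_surgical_neck: float = 0.90
    p_greater_tuberosity: float = 0.91
    p_lesser_tuberosity: float = 0.44
    head_coronal_mean: float = 2.0
    head_coronal_sd: float = 25.0
    head_sagittal_mean: float = 10.0
    head_sagittal_sd: float = 17.0
    head_axial_mean: float = 8.0
    head_axial_sd: float = 24.0
    head_translation_sd: float = 3.0
    gt_translation_sd: float = 5.5
    lt_translation_sd: float = 6.5
    tuberosity_rotation_sd: float = 10.0
    noise_sigma: float = 0.0


def _head_displacement(
    dist: CohortDistributions, frame: ReferenceFrame, rng: np.random.Generator
) -> FragmentDisplacement:
    """Draw a head displacement with per-plane rotations composed about the
    frame axes (coronal, then sagittal, then axial twist order)."""
    signs = frame.twist_signs
    c = rng.normal(dist.head_coronal_mean, dist.head_coronal_sd)
    s = rng.normal(dist.head_sagittal_mean, dist.head_sagittal_sd)
    a = rng.normal(dist.head_axial_mean, dist.head_axial_sd)
    R = (
        Rotation.from_rotvec(np.deg2rad(signs[0] * c) * frame.coro)
        * Rotation.from_rotvec(np.deg2rad(signs[1] * s) * frame.sag)
        * Rotation.from_rotvec(np.deg2rad(signs[2] * a) * frame.axial)
    )
    rotvec = R.as_rotvec()
    angle = float(np.rad2deg(np.linalg.norm(rotvec)))
    axis = tuple(unit(rotvec)) if angle > 1e-9 else (0.0, 0.0, 1.0)
    translation = tuple(rng.normal(0.0, dist.head_translation_sd, 3))
    return FragmentDisplacement(translation=translation, axis=axis, angle_deg=angle)


def sample_cohort(
    n: int,
    dist: CohortDistributions = CohortDistributions(),
    seed: int = 0,
    base: HumerusParams = HumerusParams(),
    resolution: MeshResolution | int = 32,
    vary_anatomy: bool = True,
) -> list[SyntheticFracture]:
    """Sample ``n`` synthetic fractures with logged, reproducible draws.

    Each case draws its anatomy (optionally), its fracture pattern
    (Bernoulli per fracture line, resampled if empty) and per-fragment
    displacements from ``dist``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        if vary_anatomy:
            humerus = sample_population(
                base, n=1, seed=int(rng.integers(1 << 31)), resolution=resolution
            )[0]
        else:
            humerus = generate_humerus(base, resolution=resolution, seed=seed + i)
        while True:
            pattern = tuple(
                name
                for name, p in (
                    ("surgical_neck", dist.p_surgical_neck),
                    ("greater_tuberosity", dist.p_greater_tuberosity),
                    ("lesser_tuberosity", dist.p_lesser_tuberosity),
                )
                if rng.random() < p
            )
            if pattern:
                break
        displacements: dict[str, FragmentDisplacement] = {}
        if "surgical_neck" in pattern:
            displacements["head"] = _head_displacement(dist, humerus.frame, rng)
        for label, sd in (
            ("greater_tuberosity", dist.gt_translation_sd),
            ("lesser_tuberosity", dist.lt_translation_sd),
        ):
            if label in pattern:
                axis = rng.normal(size=3)
                displacements[label] = FragmentDisplacement(
                    translation=tuple(rng.normal(0.0, sd, 3)),
                    axis=tuple(unit(axis)),
                    angle_deg=abs(rng.normal(0.0, dist.tuberosity_rotation_sd)),
                )
        spec = FractureSpec(
            pattern=pattern,
            displacements=displacements,
            noise_sigma=dist.noise_sigma,
            seed=int(rng.integers(1 << 31)),
        )
        cohort.append(simulate_fracture(humerus, spec))
    return cohort


def shaft_observation(humerus: SyntheticHumerus, length_mm: float = 60.0):
    """The partial observation used for blueprint prediction: the most
    proximal ``length_mm`` of the unfractured shaft as a submesh, with its
    model vertex correspondence."""
    from .ssm import PartialObservation

    idx = humerus.shaft_vertex_indices(length_mm)
    mesh = humerus.mesh
    fmask = np.isin(mesh.faces, idx).all(axis=1)
    faces = mesh.faces[fmask]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = TriangleMesh(mesh.vertices[used], remap[faces], "shaft")
    return PartialObservation(sub, used)


# ---------------------------------------------------------------------------
# Fixed-topology morphometry helper
# ---------------------------------------------------------------------------


def make_anatomy_measurer(template: SyntheticHumerus):
    """Build a measurement function for meshes sharing the template's
    topology (e.g. shape-model predictions): it extracts shaft, neck-rim
    and groove points by vertex index and runs the standard frame build and
    morphometry.  Returns ``callable(TriangleMesh) -> AnatomyParameters``."""
    from .frame import build_reference_frame, measure_anatomy

    shaft_idx = np.nonzero(template.shaft_mask)[0]
    neck_idx = template.neck_ring_indices
    tg = np.deg2rad(template.params.groove_angle)
    d = (template.vertex_t - tg + np.pi) % (2 * np.pi) - np.pi
    groove_sel = (np.abs(d) < np.deg2rad(4.0)) & template.shaft_mask & (
        template.vertex_s > -60.0
    )
    groove_idx = np.nonzero(groove_sel)[0]
    side = template.params.side

    def measure(mesh: TriangleMesh):
        v = mesh.vertices
        shaft_pts = v[shaft_idx]
        neck_pts = v[neck_idx]
        hint = neck_pts.mean(axis=0) - shaft_pts.mean(axis=0)
        frame = build_reference_frame(mesh, neck_pts, shaft_pts, hint, side=side)
        return measure_anatomy(mesh, frame, v[groove_idx])

    return measure
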