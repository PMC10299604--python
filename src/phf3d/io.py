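"""Serialization: landmarks, manifests, displacement reports, bundles.

All serialized quantities are millimetres and degrees; transforms are
row-major 4x4 arrays with the translation in the fourth column.  Every
written report carries a provenance block (schema version, package
version, seed and config hash) so runs can be traced and reproduced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__ as _pkg_version
from .geometry import RigidTransform, TriangleMesh
from .metrics import (
    DisplacementReport,
    NeerAssessment,
    RotationReport,
    TranslationReport,
)

__all__ = [
    "REPORT_SCHEMA",
    "transform_to_list",
    "transform_from_list",
    "save_landmarks",
    "load_landmarks",
    "report_to_dict",
    "report_from_dict",
    "save_reports",
    "load_reports",
    "provenance_block",
    "write_fracture_bundle",
    "read_fracture_bundle",
]

REPORT_SCHEMA = "phf3d-report-1"


def transform_to_list(M: RigidTransform) -> list[list[float]]:
    return [[float(x) for x in row] for row in M.matrix]


def transform_from_list(rows: Any) -> RigidTransform:
    return RigidTransform(np.asarray(rows, dtype=np.float64))


def _vec(v) -> list[float]:
    return [float(x) for x in np.asarray(v).reshape(-1)]


def provenance_block(seed: int | None = None, config: Mapping | None = None) -> dict:
    block = {"schema": REPORT_SCHEMA, "package_version": _pkg_version}
    if seed is not None:
        block["seed"] = int(seed)
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()
        block["config_sha256"] = digest
    return block


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------


def save_landmarks(path: str | Path, landmarks: Mapping[str, Any]) -> None:
    """Write named landmark arrays (mm) to JSON: point lists, vectors and
    the side string are supported values."""
    out = {}
    for key, value in landmarks.items():
        if isinstance(value, str):
            out[key] = value
        else:
            arr = np.asarray(value, dtype=np.float64)
            out[key] = arr.tolist()
    Path(path).write_text(json.dumps(out, indent=1))


def load_landmarks(path: str | Path) -> dict[str, Any]:
    raw = json.loads(Path(path).read_text())
    out: dict[str, Any] = {}
    for key, value in raw.items():
        out[key] = value if isinstance(value, str) else np.asarray(value, dtype=np.float64)
    return out


# ---------------------------------------------------------------------------
# Displacement reports
# ---------------------------------------------------------------------------


def report_to_dict(report: DisplacementReport) -> dict:
    t, r, n = report.translation, report.rotation, report.neer
    return {
        "label": report.label,
        "transform": transform_to_list(report.transform),
        "translation": {
            "GP_mm": _vec(t.GP),
            "GR_mm": _vec(t.GR),
            "vector_mm": _vec(t.trans_vector),
            "norm_3d_mm": float(t.norm_3d),
            "proj_coronal_mm": float(t.proj_coronal),
            "proj_sagittal_mm": float(t.proj_sagittal),
            "proj_axial_mm": float(t.proj_axial),
            "axis_components_mm": {k: float(v) for k, v in t.axis_components.items()},
        },
        "rotation": {
            "axis": _vec(r.axis),
            "angle_3d_deg": float(r.angle_3d),
            "coronal_deg": float(r.coronal_angle),
            "sagittal_deg": float(r.sagittal_angle),
            "axial_deg": float(r.axial_angle),
        },
        "neer": asdict(n),
    }


def report_from_dict(d: Mapping) -> DisplacementReport:
    t = d["translation"]
    r = d["rotation"]
    translation = TranslationReport(
        GP=np.asarray(t["GP_mm"]),
        GR=np.asarray(t["GR_mm"]),
        trans_vector=np.asarray(t["vector_mm"]),
        norm_3d=t["norm_3d_mm"],
        proj_coronal=t["proj_coronal_mm"],
        proj_sagittal=t["proj_sagittal_mm"],
        proj_axial=t["proj_axial_mm"],
        axis_components=dict(t["axis_components_mm"]),
    )
    rotation = RotationReport(
        axis=np.asarray(r["axis"]),
        angle_3d=r["angle_3d_deg"],
        coronal_angle=r["coronal_deg"],
        sagittal_angle=r["sagittal_deg"],
        axial_angle=r["axial_deg"],
    )
    return DisplacementReport(
        label=d["label"],
        transform=transform_from_list(d["transform"]),
        translation=translation,
        rotation=rotation,
        neer=NeerAssessment(**d["neer"]),
    )


def save_reports(
    path: str | Path,
    reports: list[DisplacementReport],
    seed: int | None = None,
    config: Mapping | None = None,
    extra: Mapping | None = None,
) -> None:
    doc = {
        "provenance": provenance_block(seed=seed, config=config),
        "fragments": [report_to_dict(r) for r in reports],
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1))


def load_reports(path: str | Path) -> list[DisplacementReport]:
    doc = json.loads(Path(path).read_text())
    return [report_from_dict(d) for d in doc["fragments"]]


# ---------------------------------------------------------------------------
# Fracture bundles (simulate output / measure input)
# ---------------------------------------------------------------------------


def write_fracture_bundle(outdir: str | Path, fracture, fmt: str = "ply") -> Path:
    """Write a simulated fracture as mesh files plus a JSON manifest
    (labels, seed, ground-truth reduction matrices, landmarks).  Returns
    the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for label, mesh in fracture.fragments.items():
        fname = f"fragment_{label}.{fmt}"
        mesh.save(outdir / fname)
        entries.append({"label": label, "path": fname})
    intact_name = f"intact.{fmt}"
    fracture.intact.mesh.save(outdir / intact_name)
    landmarks_name = "landmarks.json"
    save_landmarks(outdir / landmarks_name, fracture.intact.landmarks)
    manifest = {
        "provenance": provenance_block(seed=fracture.seed),
        "fragments": entries,
        "blueprint": intact_name,
        "blueprint_anchor_indices": fracture.intact.anchor_vertex_indices().tolist(),
        "landmarks": landmarks_name,
        "ground_truth": {
            label: transform_to_list(M) for label, M in fracture.ground_truth.items()
        },
        "pattern": list(fracture.spec.pattern),
        "noise_sigma": fracture.spec.noise_sigma,
        "seed": fracture.seed,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_fracture_bundle(manifest_path: str | Path) -> dict:
    """Read a bundle manifest; meshes are loaded, ground-truth transforms
    reconstructed.  Raises FileNotFoundError for missing mesh files."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    fragments = {}
    for entry in manifest["fragments"]:
        mesh_path = root / entry["path"]
        if not mesh_path.exists():
            raise FileNotFoundError(f"manifest references missing mesh: {mesh_path}")
        fragments[entry["label"]] = TriangleMesh.load(mesh_path, entry["label"])
    blueprint = None
    if manifest.get("blueprint"):
        bp_path = root / manifest["blueprint"]
        if not bp_path.exists():
            raise FileNotFoundError(f"manifest references missing mesh: {bp_path}")
        blueprint = TriangleMesh.load(bp_path, "blueprint")
    landmarks = None
    if manifest.get("landmarks"):
        landmarks = load_landmarks(root / manifest["landmarks"])
    ground_truth = {
        label: transform_from_list(rows)
        for label, rows in manifest.get("ground_truth", {}).items()
    }
    anchor = manifest.get("blueprint_anchor_indices")
    return {
        "fragments": fragments,
        "blueprint": blueprint,
        "blueprint_anchor_indices": None if anchor is None else np.asarray(anchor, dtype=np.int64),
        "landmarks": landmarks,
        "ground_truth": ground_truth,
        "manifest": manifest,
    }
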