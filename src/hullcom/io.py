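"""Body manifests: read/write bodies as mesh files plus a YAML index.

A manifest is a YAML file listing, per taxon: status, locomotor class,
hip reference, optional sternum landmarks, and per-segment mesh paths
(relative to the manifest) with joint centres and side.  Meshes are
OBJ/PLY/STL; the manifest declares their unit (mm|cm|m) and everything is
converted to metres on load.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .body import BodyModel, BodySegment
from .mesh import load_mesh, save_mesh


def _point(x):
    return None if x is None else [float(v) for v in np.asarray(x).ravel()]


def write_bodies(bodies, directory, units: str = "m") -> Path:
    """Write meshes and a ``manifest.yaml`` for a list of bodies; returns
    the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for body in bodies:
        segs = []
        for seg in body.segments:
            rec = {
                "name": seg.name,
                "side": seg.side,
                "proximal_joint": _point(seg.proximal_joint),
                "distal_joint": _point(seg.distal_joint),
            }
            for attr, tag in (("skin_mesh", "skin"), ("skeleton_hull", "hull")):
                mesh = getattr(seg, attr)
                if mesh is not None:
                    fname = f"{body.taxon}_{seg.key}_{tag}.obj"
                    save_mesh(mesh, directory / fname)
                    rec[attr] = fname
            segs.append(rec)
        entries.append(
            {
                "taxon": body.taxon,
                "status": body.status,
                "locomotor_class": body.locomotor_class,
                "hip_reference": _point(body.hip_reference),
                "sternum_landmarks": None
                if body.sternum_landmarks is None
                else {k: _point(v) for k, v in body.sternum_landmarks.items()},
                "segments": segs,
            }
        )
    manifest = directory / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"units": units, "bodies": entries}, fh, sort_keys=False)
    return manifest


def read_bodies(manifest_path) -> list:
    """Load bodies from a manifest written by :func:`write_bodies` (or by
    hand, same schema)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        doc = yaml.safe_load(fh)
    units = doc.get("units", "m")
    root = manifest_path.parent
    bodies = []
    for entry in doc["bodies"]:
        segments = []
        for rec in entry["segments"]:
            segments.append(
                BodySegment(
                    name=rec["name"],
                    side=rec.get("side", "axial"),
                    skin_mesh=load_mesh(root / rec["skin_mesh"], units)
                    if rec.get("skin_mesh")
                    else None,
                    skeleton_hull=load_mesh(root / rec["skeleton_hull"], units)
                    if rec.get("skeleton_hull")
                    else None,
                    proximal_joint=rec.get("proximal_joint"),
                    distal_joint=rec.get("distal_joint"),
                )
            )
        bodies.append(
            BodyModel(
                taxon=entry["taxon"],
                status=entry["status"],
                locomotor_class=entry["locomotor_class"],
                segments=segments,
                hip_reference=entry["hip_reference"],
                sternum_landmarks=None
                if entry.get("sternum_landmarks") is None
                else {
                    k: np.asarray(v, dtype=float)
                    for k, v in entry["sternum_landmarks"].items()
                },
            )
        )
    return bodies
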