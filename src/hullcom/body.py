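"""Assemble posed body segments into whole-body mass properties.

A body is a set of posed segments (head, neck, torso, tail, plus the
three-segment forelimb and four-segment hindlimb), each carrying a skin
mesh and/or a skeletal convex hull, a density, and proximal/distal joint
centres.  Whole-body centre of mass is the mass-weighted mean of segment
CoMs; its position is reported relative to the hip in the cranio-caudal
(CC) and dorso-ventral (DV) directions and normalised by body mass^(1/3)
for size-independent comparison.

Coordinate convention (fixed package-wide): +x cranial, +y left, +z dorsal.
``cc_com = com_x - hip_x`` (positive cranial to the hip) and
``dv_com = hip_z - com_z`` (positive ventral to the hip).  The hip
reference is the midpoint of the left and right acetabular joint centres.
"""

from __future__ import annotations

import copy as _copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import TriMesh, mass_properties

logger = logging.getLogger(__name__)

AXIAL_SEGMENTS = ("head", "neck", "torso", "tail")
FORELIMB_SEGMENTS = ("humerus", "forearm", "manus")
HINDLIMB_SEGMENTS = ("thigh", "shank", "metatarsus", "pes")
SEGMENT_NAMES = AXIAL_SEGMENTS + FORELIMB_SEGMENTS + HINDLIMB_SEGMENTS
PAIRED_SEGMENTS = FORELIMB_SEGMENTS + HINDLIMB_SEGMENTS

LOCOMOTOR_CLASSES = ("HLD", "FLD", "non-avian sauropsid")

#: Normalisation exponent for lengths and CoM offsets: mass^(1/3) gives the
#: dimensionally consistent length scale of an isometrically scaled body.
NORMALISATION_EXPONENT = 1.0 / 3.0


class BodyError(ValueError):
    """Raised for ill-formed bodies or unresolvable density scenarios."""


@dataclass
class BodySegment:
    name: str
    side: str = "axial"  # left | right | axial
    skin_mesh: TriMesh | None = None
    skeleton_hull: TriMesh | None = None
    density: float | None = None
    proximal_joint: np.ndarray | None = None
    distal_joint: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.name not in SEGMENT_NAMES:
            raise BodyError(f"unknown segment name {self.name!r}")
        if self.side not in ("left", "right", "axial"):
            raise BodyError(f"unknown side {self.side!r}")
        if self.skin_mesh is None and self.skeleton_hull is None:
            raise BodyError(f"segment {self.name}: no geometry supplied")
        for attr in ("proximal_joint", "distal_joint"):
            val = getattr(self, attr)
            if val is not None:
                setattr(self, attr, np.asarray(val, dtype=float))

    def mesh(self, source: str) -> TriMesh | None:
        if source == "skin":
            return self.skin_mesh
        if source in ("hull", "expanded_hull", "skeleton"):
            return self.skeleton_hull
        raise ValueError(f"unknown mesh source {source!r}")

    @property
    def key(self) -> str:
        return f"{self.name}_{self.side}" if self.side != "axial" else self.name


@dataclass
class BodyModel:
    taxon: str
    status: str  # extant | extinct
    locomotor_class: str
    segments: list
    hip_reference: np.ndarray = None
    sternum_landmarks: dict | None = None  # keys: cranial, caudal, ventral

    def __post_init__(self) -> None:
        keys = [s.key for s in self.segments]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise BodyError(f"duplicate segments: {dupes}")
        if self.hip_reference is None:
            raise BodyError("hip_reference is required")
        self.hip_reference = np.asarray(self.hip_reference, dtype=float)
        if not np.all(np.isfinite(self.hip_reference)):
            raise BodyError("hip_reference must be finite")

    def segment(self, name: str, side: str = "axial") -> BodySegment:
        for s in self.segments:
            if s.name == name and s.side == side:
                return s
        raise KeyError(f"no segment {name} ({side})")

    def copy(self) -> "BodyModel":
        return _copy.deepcopy(self)


@dataclass
class DensityScenario:
    """Map segment names (optionally keyed by locomotor class) to densities
    in kg m^-3.  ``densities`` may be flat {segment: rho} or nested
    {class: {segment: rho}}; ``default`` fills unlisted segments."""

    name: str
    densities: dict
    default: float = 1000.0

    def resolve(self, segment_name: str, locomotor_class: str) -> float:
        table = self.densities
        if table and isinstance(next(iter(table.values())), dict):
            if locomotor_class not in table:
                raise BodyError(
                    f"scenario {self.name!r} has no entry for locomotor class "
                    f"{locomotor_class!r}"
                )
            table = table[locomotor_class]
        unknown = set(table) - set(SEGMENT_NAMES)
        if unknown:
            raise BodyError(f"scenario {self.name!r}: unknown segments {sorted(unknown)}")
        rho = table.get(segment_name, self.default)
        if rho <= 0:
            raise BodyError(f"non-positive density for {segment_name}")
        return float(rho)


def standard_scenario() -> DensityScenario:
    """Heterogeneous reference densities: 1000 kg m^-3 throughout except the
    neck (800) and torso (850), which are lightened for the respiratory
    air-sac system."""
    return DensityScenario("standard", {"neck": 800.0, "torso": 850.0})


def homogeneous_scenario() -> DensityScenario:
    """Uniform 1000 kg m^-3: isolates the pure effect of segment volume."""
    return DensityScenario("homogeneous", {})


def group_varying_scenario() -> DensityScenario:
    """Neck/torso densities graded by locomotor group, emulating increased
    skeletal pneumaticity along the bird line and in volant taxa."""
    return DensityScenario(
        "group_varying",
        {
            "non-avian sauropsid": {"neck": 850.0, "torso": 900.0},
            "HLD": {"neck": 825.0, "torso": 875.0},
            "FLD": {"neck": 800.0, "torso": 850.0},
        },
    )


def default_scenarios() -> list:
    return [standard_scenario(), homogeneous_scenario(), group_varying_scenario()]


def apply_density_scenario(body: BodyModel, scenario: DensityScenario) -> BodyModel:
    """Return a copy of ``body`` with segment densities set from the
    scenario; the input body is untouched."""
    out = body.copy()
    for seg in out.segments:
        seg.density = scenario.resolve(seg.name, body.locomotor_class)
    return out


@dataclass
class CoMResult:
    taxon: str
    body_mass: float
    com_absolute: np.ndarray
    cc_com: float
    dv_com: float
    cc_com_norm: float
    dv_com_norm: float
    iteration_tag: str = ""


@dataclass
class SegmentRow:
    name: str
    length: float | None
    mass: float
    length_norm: float | None
    mass_fraction: float


@dataclass
class SegmentSummary:
    taxon: str
    body_mass: float
    rows: list
    sternum_depth: float | None = None
    sternum_length: float | None = None

    def as_dict(self) -> dict:
        out = {}
        for r in self.rows:
            out[f"{r.name}_length"] = r.length
            out[f"{r.name}_length_norm"] = r.length_norm
            out[f"{r.name}_mass"] = r.mass
            out[f"{r.name}_mass_fraction"] = r.mass_fraction
        out["sternum_depth"] = self.sternum_depth
        out["sternum_length"] = self.sternum_length
        out["body_mass"] = self.body_mass
        return out


def _mirror_mesh(mesh: TriMesh) -> TriMesh:
    R = np.diag([1.0, -1.0, 1.0])
    return mesh.transformed(R)


def _mirror_point(p):
    return None if p is None else p * np.array([1.0, -1.0, 1.0])


def mirror_segment(seg: BodySegment) -> BodySegment:
    """Reflect a unilateral segment across the sagittal (y = 0) plane."""
    return BodySegment(
        name=seg.name,
        side="right" if seg.side == "left" else "left",
        skin_mesh=None if seg.skin_mesh is None else _mirror_mesh(seg.skin_mesh),
        skeleton_hull=None
        if seg.skeleton_hull is None
        else _mirror_mesh(seg.skeleton_hull),
        density=seg.density,
        proximal_joint=_mirror_point(seg.proximal_joint),
        distal_joint=_mirror_point(seg.distal_joint),
    )


def effective_segments(body: BodyModel, mirror_missing: bool = True) -> list:
    """Segments used in aggregation: paired segments present on only one
    side are mirrored across the sagittal plane (standard practice for
    bilaterally preserved fossils); each mirror is logged."""
    segs = list(body.segments)
    if not mirror_missing:
        return segs
    for name in PAIRED_SEGMENTS:
        sides = {s.side for s in segs if s.name == name}
        if sides == {"left"} or sides == {"right"}:
            (orig,) = [s for s in segs if s.name == name]
            segs.append(mirror_segment(orig))
            logger.info(
                "%s: mirrored %s (%s) across sagittal plane",
                body.taxon, name, orig.side,
            )
    return segs


def whole_body_com(
    body: BodyModel, source: str = "skin", iteration_tag: str = ""
) -> CoMResult:
    """Mass-weighted whole-body CoM: body mass is the sum of segment
    masses and the CoM is Sum(m_i * com_i) / Sum(m_i)."""
    segs = effective_segments(body)
    missing = [s.key for s in segs if s.mesh(source) is None]
    if missing:
        raise BodyError(f"segments missing {source!r} mesh: {missing}")
    no_density = [s.key for s in segs if s.density is None]
    if no_density:
        raise BodyError(f"segments missing density: {no_density}")

    masses = []
    coms = []
    for seg in segs:
        mp = mass_properties(seg.mesh(source), density=seg.density)
        masses.append(mp.mass)
        coms.append(mp.com)
    masses = np.asarray(masses)
    coms = np.asarray(coms)
    body_mass = float(masses.sum())
    com = (masses[:, None] * coms).sum(axis=0) / body_mass

    hip = body.hip_reference
    cc = float(com[0] - hip[0])
    dv = float(hip[2] - com[2])
    norm = body_mass ** NORMALISATION_EXPONENT
    return CoMResult(
        taxon=body.taxon,
        body_mass=body_mass,
        com_absolute=com,
        cc_com=cc,
        dv_com=dv,
        cc_com_norm=cc / norm,
        dv_com_norm=dv / norm,
        iteration_tag=iteration_tag,
    )


def ga_length(body: BodyModel) -> float:
    """Gleno-acetabular length: shoulder (proximal humerus joint) to hip
    reference — the standard torso-length proxy for scaling CoM errors."""
    for side in ("left", "right"):
        try:
            seg = body.segment("humerus", side)
        except KeyError:
            continue
        if seg.proximal_joint is not None:
            return float(np.linalg.norm(seg.proximal_joint - body.hip_reference))
    raise BodyError(f"{body.taxon}: no humerus joint centre for GA length")


def segment_lengths(body: BodyModel) -> dict:
    """Euclidean joint-centre to joint-centre distance per segment key;
    segments with a missing joint centre are omitted with a warning."""
    out = {}
    for seg in body.segments:
        if seg.proximal_joint is None or seg.distal_joint is None:
            logger.warning(
                "%s: segment %s missing joint centre, length omitted",
                body.taxon, seg.key,
            )
            continue
        out[seg.key] = float(np.linalg.norm(seg.distal_joint - seg.proximal_joint))
    return out


def sternum_distances(landmarks: dict | None):
    """(depth, length) of the sternum from its three landmarks: length is
    the cranial-to-caudal chord, depth the ventral keel point's distance
    from that chord's midpoint."""
    if not landmarks:
        return None, None
    cranial = np.asarray(landmarks["cranial"], dtype=float)
    caudal = np.asarray(landmarks["caudal"], dtype=float)
    ventral = np.asarray(landmarks["ventral"], dtype=float)
    length = float(np.linalg.norm(cranial - caudal))
    depth = float(np.linalg.norm(ventral - 0.5 * (cranial + caudal)))
    return depth, length


def segment_summary(body: BodyModel, source: str = "skin") -> SegmentSummary:
    """Per-segment lengths (raw and mass^(1/3)-normalised), masses and
    mass fractions, plus sternum depth/length when landmarks are present.
    Paired segments are pooled (left + right, mirrored when one-sided)."""
    segs = effective_segments(body)
    missing = [s.key for s in segs if s.mesh(source) is None]
    if missing:
        raise BodyError(f"segments missing {source!r} mesh: {missing}")
    masses = {}
    for seg in segs:
        mp = mass_properties(seg.mesh(source), density=seg.density)
        masses[seg.name] = masses.get(seg.name, 0.0) + mp.mass
    body_mass = sum(masses.values())
    norm = body_mass ** NORMALISATION_EXPONENT

    lengths = segment_lengths(body)
    # paired limb segments: one representative side's length
    by_name: dict[str, float] = {}
    for key, L in lengths.items():
        name = key.split("_")[0]
        by_name.setdefault(name, L)

    rows = []
    for name in SEGMENT_NAMES:
        if name not in masses:
            continue
        L = by_name.get(name)
        rows.append(
            SegmentRow(
                name=name,
                length=L,
                mass=masses[name],
                length_norm=None if L is None else L / norm,
                mass_fraction=masses[name] / body_mass,
            )
        )
    depth, slen = sternum_distances(body.sternum_landmarks)
    return SegmentSummary(
        taxon=body.taxon,
        body_mass=body_mass,
        rows=rows,
        sternum_depth=depth,
        sternum_length=slen,
    )
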