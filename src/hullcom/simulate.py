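"""Synthetic digital taxa, phylogenies and Brownian-motion traits.

Real specimens enter this kind of analysis as CT-derived segment meshes;
here every input is generated instead, with known ground truth, so the
whole pipeline — hull construction, expansion-model fitting, fossil
reconstruction, comparative statistics — is testable end to end.

Bodies are multi-segment and bilaterally organised (head, neck, torso,
tail, three-segment forelimbs, four-segment hindlimbs) built from convex
primitives (ellipsoids, capsules, frusta) whose analytic volumes and
centroids are known.  Each segment's "skeleton" is its skin surface
shrunk by a factor ``s`` about the segment CoM, so the skeletal convex
hull has exactly ``s^3`` times the skin volume: the hull:skin expansion
factor — the quantity the reconstruction method estimates — is
controllable per segment and known exactly.

Two locomotor archetypes caricature the contrast the comparative tests
need: an HLD-like (hindlimb-dominated, terrestrial) plan with a long tail
and long hindlimbs, and an FLD-like (forelimb-dominated, volant) plan
with enlarged forelimbs and head and a reduced tail.  A third,
tail-heavy plan stands in for non-avian sauropsids.  Per-taxon segment
dimensions are modulated by log-proportions evolved under Brownian motion
on a simulated pure-birth tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh as _trimesh

from .body import (
    BodyModel,
    BodySegment,
    FORELIMB_SEGMENTS,
    HINDLIMB_SEGMENTS,
    apply_density_scenario,
    standard_scenario,
    whole_body_com,
)
from .mesh import TriMesh, convex_hull, mass_properties
from .phylo import Phylogeny

logger = logging.getLogger(__name__)

#: Mesh resolutions: icosphere subdivisions / capsule sections / frustum ring
#: sides.  Volume deficit of the inscribed discretisation (worst case, the
#: sphere): coarse ~2.7%, medium ~0.7%, fine ~0.2%.
RESOLUTIONS = {
    "coarse": {"subdiv": 1, "capsule": (8, 12), "ring": 12},
    "medium": {"subdiv": 2, "capsule": (16, 24), "ring": 24},
    "fine": {"subdiv": 3, "capsule": (32, 48), "ring": 48},
}

#: Default per-segment hull:skin expansion factors (skin volume / hull
#: volume).  Fleshy proximal segments carry more soft tissue than distal
#: ones; all exceed 1 so skin encloses skeleton.
DEFAULT_EXPANSION = {
    "head": 1.6, "neck": 2.2, "torso": 1.5, "tail": 2.5,
    "humerus": 2.0, "forearm": 1.8, "manus": 1.4,
    "thigh": 2.4, "shank": 2.0, "metatarsus": 1.4, "pes": 1.3,
}

ARCHETYPES = ("HLD", "FLD", "non-avian sauropsid")

#: Archetype dimension multipliers (qualitative caricatures, not calibrated
#: to any real species): tail / forelimb / hindlimb / head length factors.
_ARCHETYPE_MULTS = {
    "HLD": {"tail": 1.6, "forelimb": 0.6, "hindlimb": 1.35, "head": 0.9, "neck": 1.1},
    "FLD": {"tail": 0.6, "forelimb": 1.5, "hindlimb": 0.9, "head": 1.1, "neck": 1.0},
    "non-avian sauropsid": {
        "tail": 2.0, "forelimb": 0.8, "hindlimb": 1.1, "head": 1.0, "neck": 0.9,
    },
}


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Primitive meshes with analytic mass properties
# ---------------------------------------------------------------------------


def _frame(axis) -> np.ndarray:
    """Rotation matrix sending +z to ``axis`` (unit)."""
    z = np.asarray(axis, dtype=float)
    z = z / np.linalg.norm(z)
    ref = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(ref, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def ellipsoid_mesh(radii, centre, resolution: str = "medium") -> tuple:
    """Ellipsoid as a scaled icosphere; returns (TriMesh, analytic dict)."""
    sub = RESOLUTIONS[resolution]["subdiv"]
    ico = _trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
    radii = np.asarray(radii, dtype=float)
    centre = np.asarray(centre, dtype=float)
    verts = np.asarray(ico.vertices) * radii + centre
    mesh = TriMesh(verts, np.asarray(ico.faces))
    analytic = {
        "volume": 4.0 / 3.0 * np.pi * radii.prod(),
        "com": centre.copy(),
    }
    return mesh, analytic


def capsule_mesh(radius, length, start, axis, resolution: str = "medium") -> tuple:
    """Capsule (cylinder of ``length`` with hemispherical caps) from
    ``start`` along ``axis``; returns (TriMesh, analytic dict)."""
    counts = RESOLUTIONS[resolution]["capsule"]
    cap = _trimesh.creation.capsule(height=length, radius=radius, count=counts)
    verts = np.asarray(cap.vertices)
    # normalise trimesh's axial placement: symmetric capsule, centre at origin
    zmid = 0.5 * (verts[:, 2].min() + verts[:, 2].max())
    verts = verts - np.array([0.0, 0.0, zmid])
    R = _frame(axis)
    axis = np.asarray(axis, dtype=float) / np.linalg.norm(axis)
    centre = np.asarray(start, dtype=float) + 0.5 * length * axis
    mesh = TriMesh(verts @ R.T + centre, np.asarray(cap.faces))
    analytic = {
        "volume": np.pi * radius**2 * length + 4.0 / 3.0 * np.pi * radius**3,
        "com": centre.copy(),
    }
    return mesh, analytic


def frustum_mesh(r_base, r_tip, length, start, axis, resolution: str = "medium") -> tuple:
    """Conical frustum from ``start`` (radius ``r_base``) along ``axis``
    to radius ``r_tip``; returns (TriMesh, analytic dict).

    The analytic values are for the circular frustum; the inscribed
    polygonal mesh is smaller by the ring discretisation factor.
    """
    m = RESOLUTIONS[resolution]["ring"]
    theta = np.linspace(0.0, 2 * np.pi, m, endpoint=False)
    ring = np.column_stack([np.cos(theta), np.sin(theta)])
    base = np.column_stack([r_base * ring, np.zeros(m)])
    top = np.column_stack([r_tip * ring, np.full(m, length)])
    verts = np.vstack([base, top, [[0, 0, 0.0]], [[0, 0, length]]])
    cb, ct = 2 * m, 2 * m + 1
    faces = []
    for i in range(m):
        j = (i + 1) % m
        faces.append([i, j, m + i])          # side lower triangle
        faces.append([j, m + j, m + i])      # side upper triangle
        faces.append([cb, j, i])             # base cap (normal -z)
        faces.append([ct, m + i, m + j])     # top cap (normal +z)
    mesh0 = TriMesh(np.asarray(verts), np.asarray(faces))
    R2 = r_base * r_base
    r2 = r_tip * r_tip
    Rr = r_base * r_tip
    vol = np.pi * length * (R2 + Rr + r2) / 3.0
    zbar = length * (R2 + 2 * Rr + 3 * r2) / (4.0 * (R2 + Rr + r2))
    Rm = _frame(axis)
    axis = np.asarray(axis, dtype=float) / np.linalg.norm(axis)
    start = np.asarray(start, dtype=float)
    mesh = TriMesh(mesh0.vertices @ Rm.T + start, mesh0.faces)
    analytic = {"volume": vol, "com": start + zbar * axis}
    return mesh, analytic


_PRIMITIVES = {
    "ellipsoid": ellipsoid_mesh,
    "capsule": capsule_mesh,
    "frustum": frustum_mesh,
}


# ---------------------------------------------------------------------------
# Body plans
# ---------------------------------------------------------------------------


@dataclass
class BodyPlanParams:
    """Fully resolved plan for one digital taxon."""

    taxon: str
    status: str
    locomotor_class: str
    archetype: str
    segments: dict          # key -> primitive spec dict
    hip_reference: np.ndarray
    sternum_landmarks: dict | None
    expansion: dict         # segment name -> hull:skin factor k (> 1)


def archetype_plan(
    taxon: str,
    archetype: str,
    status: str = "extant",
    size_scale: float = 1.0,
    trait_mults: dict | None = None,
    expansion: dict | None = None,
) -> BodyPlanParams:
    """Resolve a full body plan for an archetype.

    ``size_scale`` multiplies every linear dimension; ``trait_mults`` may
    carry per-module multipliers (keys tail/forelimb/hindlimb/head/neck)
    stacked on top of the archetype's own, e.g. from BM-evolved
    log-proportions.
    """
    if archetype not in _ARCHETYPE_MULTS:
        raise SimulationError(f"unknown archetype {archetype!r}")
    mult = dict(_ARCHETYPE_MULTS[archetype])
    for k, v in (trait_mults or {}).items():
        mult[k] = mult.get(k, 1.0) * v
    B = 0.3 * size_scale  # torso length scale, metres

    tail = mult["tail"]
    fl = mult["forelimb"]
    hl = mult["hindlimb"]
    head = mult["head"]
    neck = mult["neck"]

    shoulder = {s: np.array([0.35 * B, s * 0.20 * B, 0.05 * B]) for s in (+1, -1)}
    hip = {s: np.array([-0.40 * B, s * 0.12 * B, -0.05 * B]) for s in (+1, -1)}
    hip_ref = 0.5 * (hip[+1] + hip[-1])

    neck_len = 0.5 * B * neck
    neck_start = np.array([0.48 * B, 0.0, 0.10 * B])
    neck_end = neck_start + np.array([neck_len, 0.0, 0.0])
    head_centre = neck_end + np.array([0.16 * B * head, 0.0, 0.0])

    segs: dict[str, dict] = {
        "torso": {
            "primitive": "ellipsoid",
            "args": {"radii": (0.50 * B, 0.25 * B, 0.30 * B), "centre": (0, 0, 0)},
            "proximal": np.array([0.50 * B, 0.0, 0.0]),
            "distal": np.array([-0.50 * B, 0.0, 0.0]),
        },
        "neck": {
            "primitive": "capsule",
            "args": {
                "radius": 0.08 * B, "length": neck_len,
                "start": neck_start, "axis": (1, 0, 0),
            },
            "proximal": neck_start, "distal": neck_end,
        },
        "head": {
            "primitive": "ellipsoid",
            "args": {
                "radii": (0.18 * B * head, 0.10 * B, 0.10 * B),
                "centre": head_centre,
            },
            "proximal": neck_end,
            "distal": head_centre + np.array([0.18 * B * head, 0, 0]),
        },
        "tail": {
            "primitive": "frustum",
            "args": {
                "r_base": 0.16 * B, "r_tip": 0.04 * B,
                "length": 0.9 * B * tail,
                "start": np.array([-0.50 * B, 0.0, 0.0]), "axis": (-1, 0, 0),
            },
            "proximal": np.array([-0.50 * B, 0.0, 0.0]),
            "distal": np.array([-0.50 * B - 0.9 * B * tail, 0.0, 0.0]),
        },
    }

    def chain(names, lengths, radii, origin, direction, side):
        direction = np.asarray(direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
        p = origin
        for name, L, r in zip(names, lengths, radii):
            q = p + L * direction
            segs[f"{name}_{side}"] = {
                "primitive": "capsule",
                "args": {"radius": r, "length": L, "start": p, "axis": direction},
                "proximal": p, "distal": q,
            }
            p = q
        return p

    for s, side in ((+1, "left"), (-1, "right")):
        chain(
            FORELIMB_SEGMENTS,
            [0.35 * B * fl, 0.30 * B * fl, 0.22 * B * fl],
            [0.055 * B, 0.040 * B, 0.030 * B],
            shoulder[s],
            (0.10, s * 0.30, -0.95),
            side,
        )
        ankle = chain(
            HINDLIMB_SEGMENTS[:3],
            [0.40 * B * hl, 0.35 * B * hl, 0.25 * B * hl],
            [0.065 * B, 0.045 * B, 0.030 * B],
            hip[s],
            (0.0, s * 0.10, -1.0),
            side,
        )
        # pes: horizontal, pointing cranially from the ankle
        segs[f"pes_{side}"] = {
            "primitive": "capsule",
            "args": {
                "radius": 0.025 * B, "length": 0.20 * B * hl,
                "start": ankle, "axis": (1, 0, 0),
            },
            "proximal": ankle,
            "distal": ankle + np.array([0.20 * B * hl, 0, 0]),
        }

    keel = 0.12 * B * (1.5 if archetype == "FLD" else 1.0)
    sternum = {
        "cranial": np.array([0.35 * B, 0.0, -0.22 * B]),
        "caudal": np.array([0.05 * B, 0.0, -0.26 * B]),
        "ventral": np.array([0.20 * B, 0.0, -0.26 * B - keel]),
    }

    return BodyPlanParams(
        taxon=taxon,
        status=status,
        locomotor_class=archetype,
        archetype=archetype,
        segments=segs,
        hip_reference=hip_ref,
        sternum_landmarks=sternum,
        expansion=dict(expansion or DEFAULT_EXPANSION),
    )


def build_body(params: BodyPlanParams, resolution: str = "medium"):
    """Materialise a body plan into a :class:`BodyModel` plus ground truth.

    Skin meshes discretise the primitives; each skeleton hull is the
    convex hull of the skin surface shrunk by ``k^(-1/3)`` about the
    segment's (mesh) CoM, so hull volume = skin volume / k exactly.
    Returns ``(body, truth)`` where ``truth`` holds per-segment analytic
    and mesh-exact volumes/CoMs and the true expansion factors.
    """
    if resolution not in RESOLUTIONS:
        raise SimulationError(f"unknown resolution {resolution!r}")
    segments = []
    truth_segments = {}
    for key, spec in params.segments.items():
        name, _, side = key.partition("_")
        side = side or "axial"
        builder = _PRIMITIVES[spec["primitive"]]
        mesh, analytic = builder(resolution=resolution, **spec["args"])
        mp = mass_properties(mesh)
        k = params.expansion[name]
        if k <= 0.0:
            raise SimulationError(f"expansion factor must be positive, got {k}")
        if k <= 1.0:
            logger.warning(
                "%s/%s: expansion factor %.3f <= 1 (skin does not enclose "
                "skeleton)", params.taxon, key, k,
            )
        s = k ** (-1.0 / 3.0)
        shrunk = mp.com + s * (mesh.vertices - mp.com)
        hull = convex_hull(shrunk)
        segments.append(
            BodySegment(
                name=name,
                side=side,
                skin_mesh=mesh,
                skeleton_hull=hull,
                proximal_joint=spec["proximal"],
                distal_joint=spec["distal"],
            )
        )
        rel_err = abs(mp.volume - analytic["volume"]) / analytic["volume"]
        truth_segments[key] = {
            "analytic_volume": analytic["volume"],
            "analytic_com": analytic["com"],
            "mesh_volume": mp.volume,
            "mesh_com": mp.com,
            "expansion_factor": k,
            "discretisation_error": rel_err,
        }
    body = BodyModel(
        taxon=params.taxon,
        status=params.status,
        locomotor_class=params.locomotor_class,
        segments=segments,
        hip_reference=params.hip_reference,
        sternum_landmarks=params.sternum_landmarks,
    )
    truth = {
        "segments": truth_segments,
        "max_discretisation_error": max(
            t["discretisation_error"] for t in truth_segments.values()
        ),
    }
    return body, truth


def analytic_whole_body(params: BodyPlanParams, truth: dict, scenario=None):
    """Whole-body mass and CoM from the primitives' closed-form volumes
    and centroids under a density scenario (default: the standard
    heterogeneous scenario)."""
    scenario = scenario or standard_scenario()
    masses, coms = [], []
    for key, t in truth["segments"].items():
        name = key.partition("_")[0]
        rho = scenario.resolve(name, params.locomotor_class)
        masses.append(rho * t["analytic_volume"])
        coms.append(t["analytic_com"])
    masses = np.asarray(masses)
    coms = np.asarray(coms)
    mass = float(masses.sum())
    com = (masses[:, None] * coms).sum(axis=0) / mass
    hip = params.hip_reference
    cc = float(com[0] - hip[0])
    dv = float(hip[2] - com[2])
    return {
        "body_mass": mass, "com": com,
        "cc_com": cc, "dv_com": dv,
        "cc_com_norm": cc / mass ** (1 / 3),
        "dv_com_norm": dv / mass ** (1 / 3),
    }


# ---------------------------------------------------------------------------
# Trees and traits
# ---------------------------------------------------------------------------


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Ultrametric pure-birth (Yule) tree with ``n_tips`` labelled
    ``t1..tn``; reproducible under ``seed``."""
    if n_tips < 2:
        raise SimulationError("need n_tips >= 2")
    rng = np.random.default_rng(seed)

    def new_node(t):
        return {"birth": t, "children": []}

    root = new_node(0.0)
    a, b = new_node(0.0), new_node(0.0)
    root["children"] = [a, b]
    active = [a, b]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        c1, c2 = new_node(t), new_node(t)
        active[i]["children"] = [c1, c2]
        active[i] = c1
        active.append(c2)
    depth = t + rng.exponential(1.0 / (birth_rate * n_tips))

    labels = iter(f"t{i+1}" for i in range(n_tips))

    def newick(node):
        if not node["children"]:
            return f"{next(labels)}:{depth - node['birth']:.10f}"
        # a node's branch ends where its children were born (its split time)
        end = node["children"][0]["birth"]
        parts = ",".join(newick(c) for c in node["children"])
        if node is root:
            return f"({parts});"
        return f"({parts}):{end - node['birth']:.10f}"

    return Phylogeny.from_newick(newick(root))


def simulate_traits(
    tree: Phylogeny,
    rates: dict,
    root_values: dict | None = None,
    seed: int = 0,
    include_nodes: bool = False,
):
    """Independent Brownian motion per trait along the tree's branches.

    ``rates`` maps trait name to the BM rate sigma^2 (variance per unit
    branch length).  Returns the tip table, or ``(tips, nodes)`` when
    ``include_nodes`` — the internal-node values are the simulation truth
    against which ancestral-state estimates can be scored.
    """
    rng = np.random.default_rng(seed)
    root_values = root_values or {}
    n = len(tree.node_ids)
    cols_t, cols_n = {}, {}
    for trait in rates:
        sigma2 = rates[trait]
        x = np.zeros(n)
        x[0] = root_values.get(trait, 0.0)
        for i in range(1, n):
            p = tree.parent[i]
            x[i] = x[p] + rng.normal(0.0, np.sqrt(sigma2 * tree.edge_length[i]))
        cols_t[trait] = pd.Series(
            x[tree.tip_indices], index=tree.tip_labels
        )
        cols_n[trait] = pd.Series(
            x[tree.internal_indices], index=tree.internal_ids
        )
    tips = pd.DataFrame(cols_t)
    if include_nodes:
        return tips, pd.DataFrame(cols_n)
    return tips


# ---------------------------------------------------------------------------
# Fixture sets
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions for a full fixture set.

    Defaults mirror the study design the package emulates: 50 extant taxa
    (13 HLD + 20 FLD birds, 17 non-avian sauropsids) and 14 fossil taxa,
    with no noise on the per-segment expansion factors.
    """

    n_extant: int = 50
    n_fossil: int = 14
    birth_rate: float = 1.0
    trait_rate: float = 0.01      # BM rate of log10 module proportions
    size_rate: float = 0.02       # BM rate of log10 body size
    ratio_noise_sd: float = 0.0   # lognormal SD on expansion factors
    resolution: str = "coarse"
    seed: int = 0

    def __post_init__(self):
        if self.n_extant < 1 or self.n_fossil < 1:
            raise SimulationError("counts must be >= 1")


@dataclass
class FixtureSet:
    extant: list
    fossils: list
    tree: Phylogeny
    traits: pd.DataFrame
    answers: pd.DataFrame       # hidden fossil ground truth
    truths: dict                # taxon -> build_body truth dict
    plans: dict                 # taxon -> BodyPlanParams


def _archetype_allocation(n_extant: int) -> list:
    """Split extant taxa into HLD / FLD / non-avian archetypes in the
    study's 13:20:17 proportions."""
    if n_extant < 3:
        return ["HLD", "FLD", "non-avian sauropsid"][:n_extant]
    n_hld = max(1, round(n_extant * 13 / 50))
    n_fld = max(1, round(n_extant * 20 / 50))
    while n_hld + n_fld >= n_extant:  # keep at least one non-avian slot
        if n_fld >= n_hld and n_fld > 1:
            n_fld -= 1
        elif n_hld > 1:
            n_hld -= 1
        else:
            break
    n_nav = n_extant - n_hld - n_fld
    return ["HLD"] * n_hld + ["FLD"] * n_fld + ["non-avian sauropsid"] * n_nav


def make_fixture_set(config: SimConfig) -> FixtureSet:
    """Generate a full study: extant bodies with both geometries, fossil
    bodies with hulls only, the tree, the BM trait table, and an answers
    table holding each fossil's true mass and CoM (standard densities).
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_extant + config.n_fossil
    tree = simulate_tree(n_total, config.birth_rate, seed=config.seed + 1)
    rates = {
        "log_size": config.size_rate,
        "log_tail": config.trait_rate,
        "log_forelimb": config.trait_rate,
        "log_hindlimb": config.trait_rate,
        "log_head": config.trait_rate,
        "log_neck": config.trait_rate,
    }
    traits = simulate_traits(tree, rates, seed=config.seed + 2)

    labels = tree.tip_labels
    extant_labels = labels[: config.n_extant]
    fossil_labels = labels[config.n_extant:]
    archetypes = _archetype_allocation(config.n_extant)

    extant, fossils = [], []
    truths, plans = {}, {}
    answer_rows = []

    def resolve(taxon, archetype, status):
        row = traits.loc[taxon]
        mults = {
            "tail": 10.0 ** row["log_tail"],
            "forelimb": 10.0 ** row["log_forelimb"],
            "hindlimb": 10.0 ** row["log_hindlimb"],
            "head": 10.0 ** row["log_head"],
            "neck": 10.0 ** row["log_neck"],
        }
        expansion = {
            name: k * float(np.exp(rng.normal(0.0, config.ratio_noise_sd)))
            if config.ratio_noise_sd > 0 else k
            for name, k in DEFAULT_EXPANSION.items()
        }
        plan = archetype_plan(
            taxon, archetype, status=status,
            size_scale=10.0 ** row["log_size"],
            trait_mults=mults, expansion=expansion,
        )
        return build_body(plan, resolution=config.resolution), plan

    for taxon, archetype in zip(extant_labels, archetypes):
        (body, truth), plan = resolve(taxon, archetype, "extant")
        extant.append(body)
        truths[taxon] = truth
        plans[taxon] = plan

    scenario = standard_scenario()
    for taxon in fossil_labels:
        (body, truth), plan = resolve(taxon, "non-avian sauropsid", "extinct")
        true_com = whole_body_com(
            apply_density_scenario(body, scenario), source="skin"
        )
        answer_rows.append(
            {
                "taxon": taxon,
                "true_body_mass": true_com.body_mass,
                "true_cc_com_norm": true_com.cc_com_norm,
                "true_dv_com_norm": true_com.dv_com_norm,
            }
        )
        # strip the skin: the pipeline sees hulls only
        for seg in body.segments:
            seg.skin_mesh = None
        fossils.append(body)
        truths[taxon] = truth
        plans[taxon] = plan

    traits = traits.copy()
    traits["locomotor_class"] = [
        plans[t].locomotor_class for t in traits.index
    ]
    traits["status"] = ["extinct" if t in set(fossil_labels) else "extant"
                        for t in traits.index]
    return FixtureSet(
        extant=extant,
        fossils=fossils,
        tree=tree,
        traits=traits,
        answers=pd.DataFrame(answer_rows).set_index("taxon")
        if answer_rows else pd.DataFrame(),
        truths=truths,
        plans=plans,
    )
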