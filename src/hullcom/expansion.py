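"""Segment-specific hull-to-skin expansion models and fossil reconstruction.

The minimum convex hull (MCH) of a body segment's skeleton underestimates
the fleshed-out skin volume by a segment-specific factor.  Fitting that
relationship on extant animals — for which both skeleton hulls and skin
volumes are measurable — gives per-segment predictive models that can
inflate a fossil's skeletal hulls to estimated skin volumes, from which
whole-body mass and centre of mass follow.

Three model families are supported per segment:

* ``mean_ratio`` — the arithmetic mean over training taxa of the per-taxon
  skin:hull volume ratio (size-independent by construction);
* ``ols_loglog`` — ordinary least squares of log10(skin volume) on
  log10(hull volume), capturing allometry in the fleshing-out;
* ``pgls_loglog`` — the same regression with Brownian-motion phylogenetic
  covariance among training taxa.

Fossil reconstruction runs the full grid of volume models x density
scenarios (4 x 3 = 12 iterations with the standard configuration), scaling
each segment hull isotropically about its own centre of mass — so a
segment's CoM is invariant to its expansion — and aggregating with
:func:`hullcom.body.whole_body_com`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .body import (
    BodyError,
    BodyModel,
    BodySegment,
    DensityScenario,
    apply_density_scenario,
    effective_segments,
    whole_body_com,
)
from .mesh import mass_properties, scale_to_volume
from .phylo import Phylogeny, pgls

logger = logging.getLogger(__name__)

METHODS = ("mean_ratio", "ols_loglog", "pgls_loglog")
SCOPES = ("all_taxa", "birds_only", "non_avian_only")


class ExpansionError(ValueError):
    pass


@dataclass
class SegmentParams:
    """Fitted hull->skin parameters for one segment: either a mean
    expansion factor ``k`` or log10-log10 intercept/slope ``a``, ``b``."""

    n: int
    k: float | None = None
    a: float | None = None
    b: float | None = None
    resid_se: float = 0.0


@dataclass
class ExpansionModel:
    method: str
    training_scope: str
    segments: dict  # name -> SegmentParams

    def to_json(self) -> str:
        payload = {
            "method": self.method,
            "training_scope": self.training_scope,
            "segments": {
                name: {
                    "n": p.n, "k": p.k, "a": p.a, "b": p.b,
                    "resid_se": p.resid_se,
                }
                for name, p in self.segments.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExpansionModel":
        d = json.loads(text)
        return cls(
            method=d["method"],
            training_scope=d["training_scope"],
            segments={
                name: SegmentParams(**params)
                for name, params in d["segments"].items()
            },
        )

    @property
    def label(self) -> str:
        return f"{self.method}:{self.training_scope}"


def _in_scope(body: BodyModel, scope: str) -> bool:
    if scope == "all_taxa":
        return True
    is_bird = body.locomotor_class in ("HLD", "FLD")
    if scope == "birds_only":
        return is_bird
    if scope == "non_avian_only":
        return not is_bird
    raise ValueError(f"unknown scope {scope!r}")


def segment_volumes(body: BodyModel, source: str) -> dict:
    """Per-segment-name volume (m^3), pooling left+right for paired
    segments (mirroring a one-sided limb first)."""
    out: dict[str, float] = {}
    for seg in effective_segments(body):
        mesh = seg.mesh(source)
        if mesh is None:
            continue
        out[seg.name] = out.get(seg.name, 0.0) + mass_properties(mesh).volume
    return out


def fit_expansion_models(
    training,
    method: str,
    scope: str = "all_taxa",
    tree: Phylogeny | None = None,
) -> ExpansionModel:
    """Fit per-segment hull->skin models on extant training bodies.

    Every in-scope body must carry both a skeleton hull and a skin mesh
    for the segments being fitted; a segment with fewer than 3 usable taxa
    is unfittable and raises, naming the offending segments.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if method == "pgls_loglog" and tree is None:
        raise ExpansionError("pgls_loglog requires a tree")
    bodies = [b for b in training if _in_scope(b, scope)]
    if not bodies:
        raise ExpansionError(f"no training bodies in scope {scope!r}")

    per_segment: dict[str, dict[str, tuple[float, float]]] = {}
    for body in bodies:
        hulls = segment_volumes(body, "hull")
        skins = segment_volumes(body, "skin")
        for name in hulls:
            if name in skins:
                per_segment.setdefault(name, {})[body.taxon] = (
                    hulls[name], skins[name]
                )

    unfittable = sorted(n for n, d in per_segment.items() if len(d) < 3)
    if unfittable:
        raise ExpansionError(
            f"segments with < 3 taxa having both volumes: {unfittable}"
        )

    params: dict[str, SegmentParams] = {}
    for name, by_taxon in sorted(per_segment.items()):
        taxa = sorted(by_taxon)
        hull = np.array([by_taxon[t][0] for t in taxa])
        skin = np.array([by_taxon[t][1] for t in taxa])
        ratios = skin / hull
        if np.any(ratios <= 1.0):
            logger.warning(
                "segment %s: %d training ratios <= 1 (skin volume not "
                "exceeding hull volume)", name, int((ratios <= 1).sum()),
            )
        if method == "mean_ratio":
            k = float(ratios.mean())
            params[name] = SegmentParams(
                n=len(taxa), k=k, resid_se=float(ratios.std(ddof=1))
            )
            continue
        lx = pd.Series(np.log10(hull), index=taxa)
        ly = pd.Series(np.log10(skin), index=taxa)
        if method == "ols_loglog":
            A = np.column_stack([np.ones(len(taxa)), lx.to_numpy()])
            beta, *_ = np.linalg.lstsq(A, ly.to_numpy(), rcond=None)
            resid = ly.to_numpy() - A @ beta
            dof = max(len(taxa) - 2, 1)
            params[name] = SegmentParams(
                n=len(taxa), a=float(beta[0]), b=float(beta[1]),
                resid_se=float(np.sqrt(resid @ resid / dof)),
            )
        else:  # pgls_loglog
            on_tree = [t for t in taxa if t in tree.tip_labels]
            dropped = sorted(set(taxa) - set(on_tree))
            if dropped:
                logger.warning(
                    "segment %s: dropping taxa missing from tree: %s",
                    name, dropped,
                )
            if len(on_tree) < 3:
                raise ExpansionError(
                    f"segment {name}: < 3 tree-matched taxa for pGLS"
                )
            sub = tree.prune_to(on_tree)
            fit = pgls(ly.loc[on_tree], lx.loc[on_tree].rename("log_hull"), sub)
            params[name] = SegmentParams(
                n=len(on_tree),
                a=float(fit.coef["intercept"]),
                b=float(fit.coef["log_hull"]),
                resid_se=float(np.sqrt(fit.sigma2)),
            )
    return ExpansionModel(method=method, training_scope=scope, segments=params)


def predict_skin_volume(
    hull_volume: float, segment: str, model: ExpansionModel
) -> float:
    """Predicted skin volume (m^3) for a segment hull volume."""
    if hull_volume <= 0:
        raise ValueError("hull volume must be positive")
    if segment not in model.segments:
        raise ExpansionError(
            f"segment {segment!r} not in model {model.label}"
        )
    p = model.segments[segment]
    if p.k is not None:
        return p.k * hull_volume
    return float(10.0 ** (p.a + p.b * np.log10(hull_volume)))


@dataclass
class ReconstructionGrid:
    taxon: str
    results: list  # CoMResult per (volume model, density scenario) cell
    skipped: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "taxon": r.taxon,
                    "iteration_tag": r.iteration_tag,
                    "body_mass": r.body_mass,
                    "com_x": r.com_absolute[0],
                    "com_y": r.com_absolute[1],
                    "com_z": r.com_absolute[2],
                    "cc_com": r.cc_com,
                    "dv_com": r.dv_com,
                    "cc_com_norm": r.cc_com_norm,
                    "dv_com_norm": r.dv_com_norm,
                }
            )
        return pd.DataFrame(rows)


def expand_body(fossil: BodyModel, model: ExpansionModel) -> BodyModel:
    """Inflate every segment hull of a fossil to its predicted skin
    volume, writing the expanded hull into ``skin_mesh``.

    Paired segments are predicted from the pooled (left+right) hull volume
    and the predicted total is distributed across sides in proportion to
    each side's hull volume, keeping prediction consistent with the pooled
    fitting convention.  Each hull is scaled isotropically about its own
    CoM.
    """
    out = fossil.copy()
    out.segments = effective_segments(out)
    pooled = segment_volumes(fossil, "hull")
    missing = [s.key for s in out.segments if s.skeleton_hull is None]
    if missing:
        raise BodyError(f"fossil segments missing hulls: {missing}")
    for seg in out.segments:
        hull_vol_pooled = pooled[seg.name]
        pred_pooled = predict_skin_volume(hull_vol_pooled, seg.name, model)
        mp = mass_properties(seg.skeleton_hull)
        target = pred_pooled * mp.volume / hull_vol_pooled
        seg.skin_mesh = scale_to_volume(seg.skeleton_hull, target, mp.com)
    return out


def reconstruct_taxon(
    fossil: BodyModel,
    volume_models,
    density_scenarios,
) -> ReconstructionGrid:
    """Run the full volume-model x density-scenario grid on one fossil.

    Each cell expands the hulls under one volume model, applies one
    density scenario, and computes whole-body CoM; body mass is the sum of
    the expanded segment masses.  A cell that cannot be computed is
    skipped with a logged reason; if no cell succeeds the reconstruction
    is a hard error.
    """
    results = []
    skipped = []
    for vm in volume_models:
        try:
            expanded = expand_body(fossil, vm)
        except (BodyError, ExpansionError) as exc:
            for ds in density_scenarios:
                skipped.append((f"{vm.label}|{ds.name}", str(exc)))
            logger.warning("%s: skipping volume model %s: %s",
                           fossil.taxon, vm.label, exc)
            continue
        for ds in density_scenarios:
            tag = f"{vm.label}|{ds.name}"
            try:
                with_density = apply_density_scenario(expanded, ds)
                res = whole_body_com(with_density, source="skin",
                                     iteration_tag=tag)
            except BodyError as exc:
                skipped.append((tag, str(exc)))
                logger.warning("%s: skipping cell %s: %s",
                               fossil.taxon, tag, exc)
                continue
            results.append(res)
    if not results:
        raise ExpansionError(
            f"{fossil.taxon}: no reconstructable grid cells "
            f"({len(skipped)} skipped)"
        )
    return ReconstructionGrid(taxon=fossil.taxon, results=results, skipped=skipped)


# ---------------------------------------------------------------------------
# Validation on extant taxa
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    mode: str
    table: pd.DataFrame  # per taxon x model: predicted vs true values


def _true_com(body: BodyModel, scenario: DensityScenario):
    return whole_body_com(apply_density_scenario(body, scenario), source="skin")


def validate_on_extant(
    models,
    extant,
    mode: str = "apply_to_self",
    scenario: DensityScenario | None = None,
    tree: Phylogeny | None = None,
) -> ValidationReport:
    """Measure CoM prediction error of expansion models on extant bodies
    that have both geometries.

    * ``apply_to_self`` — apply already-fitted models to each body's hulls;
    * ``leave_one_out`` — refit each model without the focal taxon before
      predicting it (requires >= 4 in-scope training taxa);
    * ``equal_volume_hull`` — scale each hull to the TRUE skin volume
      (identical densities), isolating pure hull-shape error.
    """
    from .body import standard_scenario

    scenario = scenario or standard_scenario()
    if isinstance(models, ExpansionModel):
        models = [models]
    rows = []
    for body in extant:
        truth = _true_com(body, scenario)
        if mode == "equal_volume_hull":
            expanded = body.copy()
            expanded.segments = effective_segments(expanded)
            skins = segment_volumes(body, "skin")
            pooled_hulls = segment_volumes(body, "hull")
            for seg in expanded.segments:
                mp = mass_properties(seg.skeleton_hull)
                target = skins[seg.name] * mp.volume / pooled_hulls[seg.name]
                seg.skin_mesh = scale_to_volume(seg.skeleton_hull, target, mp.com)
            pred = whole_body_com(
                apply_density_scenario(expanded, scenario), source="skin"
            )
            rows.append(_error_row(body, "equal_volume_hull", pred, truth))
            continue
        for model in models:
            if mode == "apply_to_self":
                fitted = model
            elif mode == "leave_one_out":
                rest = [b for b in extant if b.taxon != body.taxon
                        and _in_scope(b, model.training_scope)]
                if len(rest) < 4:
                    raise ExpansionError(
                        "leave_one_out needs >= 4 in-scope training taxa"
                    )
                fitted = fit_expansion_models(
                    rest, method=model.method, scope=model.training_scope,
                    tree=tree,
                )
            else:
                raise ValueError(f"unknown mode {mode!r}")
            expanded = expand_body(body, fitted)
            pred = whole_body_com(
                apply_density_scenario(expanded, scenario), source="skin"
            )
            rows.append(_error_row(body, model.label, pred, truth))
    return ValidationReport(mode=mode, table=pd.DataFrame(rows))


def _error_row(body, model_label, pred, truth):
    return {
        "taxon": body.taxon,
        "model": model_label,
        "true_body_mass": truth.body_mass,
        "pred_body_mass": pred.body_mass,
        "mass_error": pred.body_mass - truth.body_mass,
        "true_cc_com_norm": truth.cc_com_norm,
        "pred_cc_com_norm": pred.cc_com_norm,
        "cc_error": pred.cc_com_norm - truth.cc_com_norm,
        "true_dv_com_norm": truth.dv_com_norm,
        "pred_dv_com_norm": pred.dv_com_norm,
        "dv_error": pred.dv_com_norm - truth.dv_com_norm,
    }


def default_volume_models(training, tree: Phylogeny | None = None) -> list:
    """The four standard volume-model variants: allometric equations fit on
    all taxa, birds only, and non-birds only, plus the raw mean expansion
    factor over all training taxa."""
    method = "pgls_loglog" if tree is not None else "ols_loglog"
    return [
        fit_expansion_models(training, method=method, scope="all_taxa", tree=tree),
        fit_expansion_models(training, method=method, scope="birds_only", tree=tree),
        fit_expansion_models(training, method=method, scope="non_avian_only", tree=tree),
        fit_expansion_models(training, method="mean_ratio", scope="all_taxa"),
    ]
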