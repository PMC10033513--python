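"""End-to-end orchestration: bodies -> CoM tables -> expansion fits ->
fossil reconstruction grid -> comparative statistics.

``run_pipeline`` drives the whole study from a single config and writes
tabular outputs (CSV/JSON) plus a run log into an output directory;
``summarise`` renders a Markdown digest of a finished run.  All
randomness flows from one master seed, with per-stage seeds derived
deterministically from it and recorded in the log.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .body import (
    apply_density_scenario,
    default_scenarios,
    segment_summary,
    whole_body_com,
)
from .expansion import (
    default_volume_models,
    reconstruct_taxon,
    validate_on_extant,
)
from .phylo import (
    allometry_classify,
    ancestral_states_table,
    pgls,
    phylo_anova,
    phylo_pca,
    phylomorphospace,
    spearman_matrix,
)
from .simulate import SimConfig, make_fixture_set

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.9g"


@dataclass
class StatsConfig:
    traits: tuple = ("cc_com_norm", "dv_com_norm")
    group_column: str = "locomotor_class"
    n_perm: int = 999
    isometric_slope: float = 1.0 / 3.0


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    drop_taxa: dict = field(default_factory=dict)  # label -> [taxon, ...]

    def __post_init__(self):
        # single-seed policy: the master seed drives the simulation too
        self.sim.seed = self.seed

    def to_dict(self) -> dict:
        return {
            "sim": asdict(self.sim),
            "stats": {**asdict(self.stats), "traits": list(self.stats.traits)},
            "seed": self.seed,
            "drop_taxa": self.drop_taxa,
        }


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, float_format=_FLOAT_FMT, index=index)


def _extant_trait_table(extant, scenarios) -> tuple:
    """Per-taxon CoM rows for every density scenario plus the trait table
    (standard-scenario values) used by the comparative statistics."""
    com_rows = []
    trait_rows = {}
    for body in extant:
        for scn in scenarios:
            res = whole_body_com(
                apply_density_scenario(body, scn),
                source="skin",
                iteration_tag=f"skin|{scn.name}",
            )
            com_rows.append(
                {
                    "taxon": body.taxon,
                    "locomotor_class": body.locomotor_class,
                    "status": body.status,
                    "iteration_tag": res.iteration_tag,
                    "body_mass": res.body_mass,
                    "cc_com": res.cc_com,
                    "dv_com": res.dv_com,
                    "cc_com_norm": res.cc_com_norm,
                    "dv_com_norm": res.dv_com_norm,
                }
            )
            if scn.name == "standard":
                summ = segment_summary(apply_density_scenario(body, scn))
                row = {
                    "locomotor_class": body.locomotor_class,
                    "status": body.status,
                    "body_mass": res.body_mass,
                    "log10_body_mass": np.log10(res.body_mass),
                    "cc_com": res.cc_com,
                    "dv_com": res.dv_com,
                    "cc_com_norm": res.cc_com_norm,
                    "dv_com_norm": res.dv_com_norm,
                }
                row.update(summ.as_dict())
                trait_rows[body.taxon] = row
    return pd.DataFrame(com_rows), pd.DataFrame(trait_rows).T


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run the complete analysis and write all outputs under ``outdir``.

    Outputs: extant CoM table, expansion-model JSONs, fossil
    reconstruction grid, ancestral states, pGLS/allometry table,
    pANOVA/phylANCOVA table, phylogenetic PCA scores/loadings,
    phylomorphospace coordinates, Spearman matrices (tips and nodes),
    validation report, and a JSON run log.  Configured drop-taxon reruns
    are written to ``drop_<label>/`` subdirectories.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    fixtures = make_fixture_set(config.sim)
    log = {
        "seed": config.seed,
        "package_version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "stages": {},
    }

    _run_study(fixtures, config, outdir, log, drop=None)
    for label, taxa in config.drop_taxa.items():
        subdir = outdir / f"drop_{label}"
        subdir.mkdir(parents=True, exist_ok=True)
        sublog = dict(log, stages={})
        _run_study(fixtures, config, subdir, sublog, drop=list(taxa))
        with open(subdir / "run_log.json", "w") as fh:
            json.dump(sublog, fh, indent=2, sort_keys=True)

    log["elapsed_s"] = round(time.time() - t_start, 3)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    with open(outdir / "config_effective.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
    return outdir


def _run_study(fixtures, config, outdir, log, drop=None):
    def stage(name):
        log["stages"][name] = round(time.time() - t0, 3)

    drop = set(drop or ())
    extant = [b for b in fixtures.extant if b.taxon not in drop]
    fossils = [b for b in fixtures.fossils if b.taxon not in drop]
    keep = [b.taxon for b in extant] + [b.taxon for b in fossils]
    tree = fixtures.tree.prune_to(keep) if drop else fixtures.tree
    scenarios = default_scenarios()

    t0 = time.time()
    try:
        # (1) extant CoM / trait tables
        com_table, trait_table = _extant_trait_table(extant, scenarios)
        _write(com_table, outdir / "com_table.csv", index=False)
        stage("com_table")

        # (2) expansion models
        models = default_volume_models(extant, tree=tree)
        for m in models:
            fname = f"expansion_{m.method}_{m.training_scope}.json"
            (outdir / fname).write_text(m.to_json() + "\n")
        stage("expansion_fits")

        # (3) fossil reconstruction grid
        grids = [reconstruct_taxon(f, models, scenarios) for f in fossils]
        grid_df = (
            pd.concat([g.to_frame() for g in grids], ignore_index=True)
            if grids else pd.DataFrame()
        )
        _write(grid_df, outdir / "fossil_grid.csv", index=False)
        stage("fossil_grid")

        # fossil rows for comparative statistics: the size-robust choice is
        # the mean-ratio volume model with standard densities
        stats_tag = "mean_ratio:all_taxa|standard"
        fossil_traits = {}
        for g in grids:
            for r in g.results:
                if r.iteration_tag == stats_tag:
                    fossil_traits[r.taxon] = {
                        "locomotor_class": "non-avian sauropsid",
                        "status": "extinct",
                        "body_mass": r.body_mass,
                        "log10_body_mass": np.log10(r.body_mass),
                        "cc_com": r.cc_com,
                        "dv_com": r.dv_com,
                        "cc_com_norm": r.cc_com_norm,
                        "dv_com_norm": r.dv_com_norm,
                    }
        all_traits = pd.concat(
            [trait_table, pd.DataFrame(fossil_traits).T]
        )
        _write(all_traits, outdir / "trait_table.csv")

        stats_traits = list(config.stats.traits)
        numeric = all_traits[stats_traits + ["log10_body_mass"]].astype(float)

        # (4) ancestral states
        anc = ancestral_states_table(tree, numeric[stats_traits])
        _write(anc, outdir / "ancestral_states.csv")
        stage("ancestral_states")

        # (5) pGLS allometry of raw CoM offsets vs body mass in birds
        birds = all_traits[all_traits["locomotor_class"].isin(["HLD", "FLD"])]
        pgls_rows = []
        for group, sub in (
            ("all_birds", birds),
            ("HLD", birds[birds["locomotor_class"] == "HLD"]),
            ("FLD", birds[birds["locomotor_class"] == "FLD"]),
        ):
            for trait, iso in (
                ("cc_com", config.stats.isometric_slope),
                ("dv_com", config.stats.isometric_slope),
            ):
                vals = sub[trait].astype(float)
                if len(vals) < 4 or (vals <= 0).any():
                    continue  # log-log slope undefined for non-positive offsets
                y = np.log10(vals)
                X = sub["log10_body_mass"].astype(float).rename("log10_body_mass")
                fit = pgls(y, X, tree)
                cls = allometry_classify(fit, iso)
                pgls_rows.append(
                    {
                        "group": group,
                        "trait": f"log10_{trait}",
                        "n": fit.n,
                        "slope": fit.coef["log10_body_mass"],
                        "se": fit.se["log10_body_mass"],
                        "ci_low": cls["ci_low"],
                        "ci_high": cls["ci_high"],
                        "isometric_slope": iso,
                        "classification": cls["classification"],
                        "sigma2": fit.sigma2,
                        "loglik": fit.loglik,
                        "aicc": fit.aicc,
                    }
                )
        _write(pd.DataFrame(pgls_rows), outdir / "pgls_allometry.csv", index=False)
        stage("pgls")

        # (6) pANOVA / phylANCOVA between HLD and FLD birds
        rng = np.random.default_rng(config.seed + 101)
        anova_rows = []
        bird_groups = birds["locomotor_class"]
        for trait in stats_traits + ["log10_body_mass"]:
            seed_t = int(rng.integers(2**31 - 1))
            res = phylo_anova(
                birds[trait].astype(float), bird_groups, tree,
                n_perm=config.stats.n_perm, seed=seed_t,
            )
            anova_rows.append(
                {"trait": trait, "test": "group", "F": res.statistic,
                 "p": res.p_value, "n_perm": res.n_permutations,
                 "seed": res.seed}
            )
            res2 = phylo_anova(
                birds[trait].astype(float), bird_groups, tree,
                covariate=birds["log10_body_mass"].astype(float),
                n_perm=config.stats.n_perm,
                seed=int(rng.integers(2**31 - 1)), test="slopes",
            )
            anova_rows.append(
                {"trait": trait, "test": "slopes", "F": res2.statistic,
                 "p": res2.p_value, "n_perm": res2.n_permutations,
                 "seed": res2.seed}
            )
        _write(pd.DataFrame(anova_rows), outdir / "panova.csv", index=False)
        stage("panova")

        # (7) phylogenetic PCA with node projection
        pca_cols = stats_traits + ["log10_body_mass"]
        ppca = phylo_pca(numeric[pca_cols], tree, project_nodes=True)
        _write(ppca.scores, outdir / "ppca_scores.csv")
        _write(ppca.node_scores, outdir / "ppca_node_scores.csv")
        _write(ppca.loadings, outdir / "ppca_loadings.csv")
        _write(
            pd.DataFrame(
                {
                    "eigenvalue": ppca.eigenvalues,
                    "percent_variance": ppca.percent_variance,
                },
                index=[f"PC{i+1}" for i in range(len(ppca.eigenvalues))],
            ),
            outdir / "ppca_variance.csv",
        )
        stage("ppca")

        # (8) phylomorphospace of the two focal traits
        pm = phylomorphospace(tree, numeric, stats_traits[0], stats_traits[1])
        _write(pm["tips"], outdir / "morpho_tips.csv")
        _write(pm["nodes"], outdir / "morpho_nodes.csv")
        _write(pm["edges"], outdir / "morpho_edges.csv", index=False)
        stage("phylomorphospace")

        # (9) Spearman matrices on tip values and node values separately
        _write(spearman_matrix(numeric), outdir / "spearman_tips.csv")
        node_vals = anc[stats_traits]
        node_full = node_vals.join(
            ancestral_states_table(tree, numeric[["log10_body_mass"]])[
                ["log10_body_mass"]
            ]
        )
        _write(spearman_matrix(node_full), outdir / "spearman_nodes.csv")
        stage("spearman")

        # (10) validation on extant taxa
        rep_self = validate_on_extant(models, extant, mode="apply_to_self")
        rep_shape = validate_on_extant(models, extant, mode="equal_volume_hull")
        validation = pd.concat(
            [rep_self.table.assign(mode="apply_to_self"),
             rep_shape.table.assign(mode="equal_volume_hull")],
            ignore_index=True,
        )
        _write(validation, outdir / "validation.csv", index=False)
        stage("validation")

        tree.write(outdir / "tree_used.nwk")
    except Exception as exc:
        failed_stage = len(log["stages"])
        raise RuntimeError(
            f"pipeline aborted after stage {failed_stage}: {exc}"
        ) from exc


def summarise(outdir) -> str:
    """Render a Markdown digest of a finished run: group contrasts,
    allometry classifications, and per-fossil CoM ranges across the model
    iterations.  Writes ``summary.md`` and returns the text."""
    outdir = Path(outdir)
    lines = ["# Run summary", ""]

    grid_path = outdir / "fossil_grid.csv"
    grid = pd.read_csv(grid_path) if grid_path.exists() else pd.DataFrame()
    traits = pd.read_csv(outdir / "trait_table.csv", index_col=0)

    anova = pd.read_csv(outdir / "panova.csv")
    lines.append("## Group contrasts (HLD vs FLD, permutation tests)")
    for _, r in anova.iterrows():
        lines.append(
            f"- {r['trait']} ({r['test']}): F = {r['F']:.3f}, P = {r['p']:.4f}"
        )
    lines.append("")

    pgls_path = outdir / "pgls_allometry.csv"
    lines.append("## Allometry (pGLS slope vs isometry)")
    if pgls_path.exists():
        pg = pd.read_csv(pgls_path)
        for _, r in pg.iterrows():
            lines.append(
                f"- {r['group']} {r['trait']}: slope {r['slope']:.3f} "
                f"[{r['ci_low']:.3f}, {r['ci_high']:.3f}] -> {r['classification']}"
            )
    lines.append("")

    lines.append("## Fossil reconstructions")
    if grid.empty:
        lines.append("no fossil reconstructions")
    else:
        extant = traits[traits["status"] == "extant"]
        ranges = {
            grp: (
                extant.loc[extant["locomotor_class"] == grp, "cc_com_norm"]
                .astype(float)
                .agg(["min", "max"])
            )
            for grp in ("HLD", "FLD")
            if (extant["locomotor_class"] == grp).any()
        }
        for taxon, sub in grid.groupby("taxon"):
            vals = sub["cc_com_norm"].astype(float)
            med = vals.median()
            inside = [
                grp
                for grp, r in ranges.items()
                if r["min"] <= med <= r["max"]
            ]
            where = " and ".join(inside) if inside else "neither extant"
            lines.append(
                f"- {taxon}: cc_com_norm min/median/max = "
                f"{vals.min():.4f}/{med:.4f}/{vals.max():.4f} "
                f"({len(sub)} iterations); median falls in {where} range"
            )
    text = "\n".join(lines) + "\n"
    (outdir / "summary.md").write_text(text)
    return text
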