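# hullcom

Volumetric centre-of-mass (CoM) reconstruction and phylogenetic
comparative statistics for multi-segment vertebrate bodies — built for
the question of how body shape and mass distribution evolved along the
bird line, where extant taxa provide full skin-volume models but fossils
preserve only skeletons.

## The problem

Whole-body mass and CoM position govern posture and locomotion in bipeds
and fliers, but fossils preserve no soft tissue.  The minimum convex hull
(MCH) approach works around this: for living animals, the convex hull of
each body segment's skeleton has a measurable volume that the skin volume
exceeds by a segment-specific *expansion factor*.  Fitting that
hull-to-skin relationship on extant taxa lets you inflate a fossil's
segment hulls to estimated skin volumes, assign tissue densities, and
compute its body mass and CoM.

`hullcom` implements the whole chain:

1. **Mesh geometry** (`hullcom.mesh`) — exact mass properties of closed
   triangle meshes by signed-tetrahedron decomposition (divergence
   theorem): volume `V = (1/6) Σ a·(b × c)` over faces, CoM as the
   signed-volume-weighted tetrahedron centroid mean.  Convex hulls
   (Quickhull), watertightness/orientation validation, volume-targeted
   isotropic scaling, and an independent ray-parity Monte-Carlo
   containment check.
2. **Body assembly** (`hullcom.body`) — posed segments (head, neck,
   torso, tail, 3-segment forelimbs, 4-segment hindlimbs) with densities;
   whole-body CoM as `Σ mᵢxᵢ / Σ mᵢ`; cranio-caudal (CC) and
   dorso-ventral (DV) CoM offsets from the hip, normalised by
   body-mass^(1/3); three density scenarios (standard heterogeneous,
   homogeneous, group-varying).
3. **Hull expansion** (`hullcom.expansion`) — per-segment hull→skin
   models: mean expansion ratio, OLS and phylogenetic GLS regressions in
   log₁₀–log₁₀ space; fossil reconstruction under the full 4 volume-model
   × 3 density-scenario grid (12 iterations per fossil); validation modes
   on extant taxa including the pure hull-shape test.
4. **Comparative statistics** (`hullcom.phylo`) — Brownian-motion
   ancestral states with 95% CIs, pGLS with AICc and isometry
   classification (slope vs 1/3), residual-randomisation phylogenetic
   ANOVA/ANCOVA, phylogenetic PCA, phylomorphospace coordinates, Spearman
   rank correlations on tips and nodes.
5. **Synthetic data** (`hullcom.simulate`) — digital taxa built from
   convex primitives with exactly controllable hull:skin ratios, pure-birth
   trees, BM-evolved proportions, and withheld fossil ground truth, so
   the entire pipeline is testable without any specimen download.
6. **Pipeline** (`hullcom.pipeline`) — one-config orchestration of the
   full study with deterministic seeding, driven by the numbered scripts
   in `analysis/`.

## Worked example

Reconstruct one synthetic fossil from its skeletal hulls under all 12
model iterations:

```python
from hullcom.simulate import SimConfig, make_fixture_set
from hullcom.expansion import default_volume_models, reconstruct_taxon
from hullcom.body import default_scenarios

fx = make_fixture_set(SimConfig(n_extant=10, n_fossil=1,
                                resolution="coarse", seed=42))
models = default_volume_models(fx.extant, tree=fx.tree)
grid = reconstruct_taxon(fx.fossils[0], models, default_scenarios())
df = grid.to_frame()
print(df[["iteration_tag", "body_mass", "cc_com_norm"]].head(3))
```

prints

```
                     iteration_tag  body_mass  cc_com_norm
     pgls_loglog:all_taxa|standard  10.574676     0.015703
  pgls_loglog:all_taxa|homogeneous  11.669347     0.021604
pgls_loglog:all_taxa|group_varying  10.926144     0.017629
```

Across the 12 iterations this fossil's normalised CC_CoM spans 0.0157 to
0.0216 m·kg^(−1/3) (median 0.0176); the generator's withheld truth is
0.0157 with body mass 10.57 kg, which the standard-density iteration
recovers exactly — with no noise on the expansion ratios the method is
exact by construction, so the spread across iterations isolates the
effect of the model choices themselves.

The full study lives in `analysis/`:

```bash
python analysis/01_simulate_taxa.py        # 50 extant + 14 fossil taxa
python analysis/02_run_reconstruction.py   # CoM tables, fits, grid, stats
python analysis/03_summarise_results.py    # Markdown digest
```

Tables land under `results/study/run/`; the digest reports, per fossil,
where its reconstructed CC_CoM falls relative to the extant
hindlimb-dominated (HLD) and forelimb-dominated (FLD) ranges.

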