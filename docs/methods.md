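# Methods

This note documents the models, conventions and numerical choices behind
`hullcom`, and what the synthetic experiments do and do not demonstrate.

## Coordinate and normalisation conventions

All geometry is in metres with a fixed anatomical frame: **+x cranial,
+y left, +z dorsal**.  The hip reference is the midpoint of the left and
right acetabular joint centres.  The cranio-caudal CoM offset is
`cc_com = com_x − hip_x` (positive cranial) and the dorso-ventral offset
is `dv_com = hip_z − com_z` (positive ventral).  Lengths and CoM offsets
are normalised by body mass to the power **exactly 1/3** — the
dimensionally consistent exponent for comparing linear dimensions across
isometrically scaled bodies (a printed "0.33" is read as a rounding of
1/3).  Mesh files may be declared in mm/cm/m and are converted on load;
all internal tolerances are relative to bounding-box scale so unit choice
cannot change behaviour.

## Mass properties

Volume and CoM of a closed triangle mesh come from signed-tetrahedron
decomposition (the divergence theorem), which is exact for polyhedra and
independent of tessellation.  The decomposition reference point is the
vertex mean, not the global origin: the result is analytically
origin-independent, but a far origin makes the signed tetrahedra huge and
nearly cancelling, and property-based testing showed CoM errors of order
10⁻² for meshes translated ~10⁴ body lengths from the origin under the
origin-based fan.  A globally inverted mesh (consistent winding, negative
signed volume) is repaired by flipping all faces and logging; mixed
winding and non-manifold edges are hard errors, because silently
repairing them risks wrong signed volumes.  An independent ray-crossing
(Möller–Trumbore parity) containment test supports Monte-Carlo volume
estimation; it shares no code path or mathematics with the
divergence-theorem route, so the two cross-check each other in the test
suite (agreement within Monte-Carlo standard error, and zero
disagreements against exact half-space tests on convex meshes).

Convex hulls are delegated to Quickhull (scipy's qhull bindings) with
facets re-oriented outward; correctness is enforced in tests by
brute-force facet-by-facet half-space containment of every input point
and by volume idempotence, not assumed from the library.

## Densities

The standard heterogeneous scenario assigns 1000 kg·m⁻³ to all segments
except the neck (800) and torso (850), lightened for the respiratory
air-sac system.  Two sensitivity scenarios bracket this choice: a
homogeneous 1000 kg·m⁻³ scenario (pure volume signal, no investigator
density choice) and a group-varying scenario grading neck/torso density
by locomotor class (non-avian sauropsids 850/900, HLD birds 825/875, FLD
birds 800/850), emulating increased pneumaticity along the bird line.

## Hull expansion models

Per segment, three model families map hull volume to skin volume:

* **mean_ratio** — arithmetic mean over training taxa of per-taxon
  skin:hull ratios.  Size-independent; the variant of choice when a
  fossil lies outside the training body-size range, where an allometric
  slope would extrapolate.
* **ols_loglog / pgls_loglog** — `log₁₀(skin) = a + b·log₁₀(hull)` by
  OLS, or GLS with Brownian-motion covariance from the tree.  Volume–
  volume allometries are conventionally fit in log–log space; no
  back-transform (smearing) correction is applied by default.

Paired limb segments pool left+right volumes before fitting; at
prediction time the pooled estimate is distributed across sides in
proportion to each side's hull volume, keeping fitting and application
consistent.  Segment hulls are expanded **isotropically about their own
CoM**, so a segment's CoM is invariant to its expansion — any other
centre would inject an arbitrary directional shift into the
reconstruction.  Four volume models (all-taxa, birds-only,
non-avian-only allometric equations, plus the all-taxa mean ratio)
crossed with the three density scenarios give 12 reconstruction
iterations per fossil.

## Comparative statistics

Everything runs under Brownian motion (BM): trait covariance between two
taxa is σ² times the depth of their most recent common ancestor.
Pagel's λ (off-diagonal shrinkage of C, ML-estimated by grid search plus
bounded refinement) is available where a weaker phylogenetic signal is
suspected.

* **Ancestral states** are the joint GLS/ML solution; point estimates are
  the conditional expectations given the tips with the GLS root mean, and
  variances are kriging variances including root-mean uncertainty, with
  σ² at its ML value.  CIs are estimate ± 1.96·SD.  Tests verify the
  estimates against direct numerical maximisation of the BM likelihood
  over all node states.
* **pGLS** is fit by ML (comparability of AICc across fixed-effect
  structures); AICc counts the regression coefficients plus σ² (plus λ
  when estimated).  Coefficient SEs use the unbiased residual variance
  with n − p degrees of freedom, so a star tree reproduces OLS exactly.
  AICc is reported as infinite when n − k − 1 ≤ 0 rather than erroring,
  so tiny training scopes degrade gracefully.
* **Allometry classification** compares the slope's 95% CI against the
  isometric expectation (1/3 for a length against mass): wholly below →
  negative, containing → isometric, wholly above → positive; the CI
  bounds are always reported so borderline cases are visible.
* **Phylogenetic ANOVA/ANCOVA** follows residual randomisation (RRPP):
  the model is fit after premultiplication by C^(−1/2) (Cholesky factor,
  triangular solves — stabler than eigen-inversion for ultrametric C),
  the F statistic for the group term (or group × covariate interaction
  for the slopes test) is referenced to permutations of reduced-model
  residuals, and p = (1 + #{F* ≥ F}) / (1 + n_perm).  Default n_perm =
  999; a seed is mandatory, and permutations are vectorised so null
  calibration experiments run in seconds.  Degenerate responses (zero
  residual variance) report F = 0, p = 1.
* **Phylogenetic PCA** eigendecomposes the evolutionary covariance
  (C⁻¹-weighted cross-product about the phylogenetic mean); tip scores
  project centred raw data, node scores project ancestral-state
  estimates.  Eigenvector signs are fixed (largest-magnitude loading
  positive) for deterministic output.
* **Spearman** uses average ranks for ties and the t approximation for
  p-values; exact permutation enumeration is available for n ≤ 8 (the
  factorial blow-up makes larger exact enumeration pointless when the t
  approximation is already adequate at n = 9).
* **Tree uncertainty**: `across_trees` applies any scalar analysis over a
  list of topologies and reports per-tree values with the median and
  2.5/97.5 percentiles; ancestral-state variance and across-tree spread
  are therefore available separately, never conflated.
* No multiple-testing correction is applied; raw P values are reported.

## Synthetic data generator

Bodies are assembled from convex primitives — ellipsoids (head, torso),
capsules (neck, limb segments), frusta (tail) — whose analytic volumes
and centroids are known.  The "skeleton" of each segment is its skin
surface shrunk by s = k^(−1/3) about the segment CoM, so the skeletal
convex hull has **exactly** 1/k times the skin volume and the same CoM:
the expansion factor, the quantity the method estimates, is controlled
per segment without modelling osteology.  Default per-segment factors
range 1.3 (pes) to 2.5 (tail), larger for fleshier proximal segments.
Archetypes are qualitative caricatures — HLD-like (long tail and
hindlimbs, reduced forelimbs), FLD-like (enlarged forelimbs and head,
reduced tail, deeper sternal keel), and a tail-heavy non-avian plan —
whose only purpose is to make group-contrast and morphospace analyses
exercisable.  Per-taxon dimensions are modulated by log-proportions
evolved under BM on a simulated pure-birth (Yule) tree; expansion
factors optionally carry per-segment lognormal noise.

Default study conditions are 50 extant taxa (13 HLD, 20 FLD, 17
non-avian sauropsids) and 14 fossils, mirroring the study design the
package emulates; tests and calibration experiments use smaller
configurations (typically 8–20 extant taxa, 5–50-tip trees, coarse mesh
resolution) chosen to keep the suite fast while leaving every check
statistically meaningful at its stated tolerance.

Mesh resolutions trade speed for discretisation error: inscribed
discretisations underestimate curved-primitive volumes by ~13% (coarse),
~3% (medium), ~0.3% (fine) in the worst case (the sphere).  This bias is
*shared* between skin mesh and skeleton hull, so hull:skin ratios and
recovery tests are exact at any resolution; only comparisons against the
closed-form primitive volumes need the documented tolerance.

What passing tests show — and what they do not: the generator's hulls are
exactly similar in shape to its skins, so hull-shape error (the
difference between a convex hull and a real animal's concave outline) is
near zero by construction here, and the equal-volume validation mode
measures the pipeline's handling of that limit, not the biological shape
effect.  Real skeletons also violate the constant-ratio-within-segment
assumption in ways lognormal ratio noise only approximates.  Recovery
results on synthetic data therefore validate the estimator and the
plumbing, not the anatomical fidelity of convex-hull reconstruction.

## Error metrics

Exact-recovery checks are relative to the true values.  Noisy-recovery
CoM error is reported as a fraction of **gleno-acetabular length**
(shoulder-to-hip distance, the standard torso-length proxy): the CC_CoM
offset itself passes through zero across body plans, so error relative
to the offset is ill-conditioned and seed-dependent, while error
relative to body length is stable and is the convention used for CoM
accuracy in this literature.

## Determinism

One master seed drives everything: the simulation config adopts it, and
per-stage seeds (permutation tests) are derived deterministically from
it and recorded in the run log.  Output CSVs are written with 9
significant digits and fixed orderings, so identical config + seed gives
byte-identical tables; the acceptance script reseeds all generators from
its `--seed` argument.

## Known limitations

* No inertia tensors, non-isotropic ("sculpted") expansions, feather or
  integument volumes, or soft-tissue density maps.
* Posture is taken as given in the input meshes; no re-posing.
* Mesh repair is limited to the global orientation flip; non-manifold
  surgery is out of scope.
* The pipeline consumes time-calibrated trees; it does not build or date
  them.
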