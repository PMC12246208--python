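# Methods

## Landmark template and coordinate conventions

All configurations live on a fixed template of 526 named points: 12
thoracic vertebrae × 4 vertebral-body corner points
(anterior-superior/inferior, posterior-superior/inferior; 48 points), 24
ribs × 19 points (head, tubercle, sternal end plus 16 curve
semilandmarks equally spaced in arc angle; 456 points), and 22 midline
sternal points. The published template this emulates is only known by
its total count, so this per-structure breakdown is a stand-in chosen to
supply the vertebral corner points the TVBHD ratio needs and dense rib
curves for the PLS blocks. The analysis subset removes ribs 11–12
bilaterally (4 × 19 points), leaving 450.

Units are mm. Axes are right-handed with +x left lateral, +y ventral,
+z cranial; the midsagittal plane is x = 0 and the anatomical mirror is
x → −x combined with swapping bilaterally paired labels (an involution on
the template). Fixing one convention makes symmetrization and mirroring
exactly testable. Semilandmarks are treated as fixed points after
digitization; no sliding is performed (none is part of the emulated
protocol as far as it is documented).

Missing data are representable in the long-format CSV interchange only;
TPS export (LM3 dialect, optional ID lines, no CURVES blocks) is
restricted to complete configurations because TPS has no missing-data
convention.

## Superimposition

Generalized Procrustes analysis iterates rotation-to-consensus until the
consensus RMS change falls below 1e-12, capped at 1000 iterations.
Mutually similar configurations (any realistic sample) converge in under
five iterations; the high cap only matters for mutually random shapes,
whose consensus contracts slowly (~0.93 per iteration) — with a lower cap
the aligned coordinates would still carry ~1e-5 of drift. Rotations are
proper (determinant +1); reflection enters only through symmetrization.

Two spaces are supported. *Shape space* scales every configuration to
centroid size 1 (an invariant checked to 1e-9). *Form space*
(size-and-shape space) removes translation and rotation only, so
centroid size is preserved exactly; the PLS completion operates here
because it must predict absolute rib dimensions in mm. A ln(CS)
augmentation of shape space would be a reasonable alternative but is not
the default, which keeps predictions dimensionally transparent.

Symmetrization orients the configuration so the best-fit plane through
the midline points is x = 0 (smallest-angle rotation of the fitted
normal onto +x, applied about the midline centroid), superimposes the
relabeled mirror image onto the original by rigid OPA, averages the two,
and finally averages the result with its own in-place mirror. The last
step is a linear projection onto the mirror-symmetric subspace, so the
output is *exactly* symmetric under the template pairing; it is the
identity when the input is already symmetric, and the whole operation is
idempotent to machine precision. The pre-orientation matters: the
projection is only shape-preserving when the symmetry plane is at x = 0.

## Reconstruction stack

**Metamer increments.** Control spines (complete vertebral columns) are
superimposed by one form-space GPA on the whole 48-point column; the
per-level means are taken in that common frame and the increment for
transition l→l+1 is the difference of consecutive mean metamers. The
column is aligned as a unit rather than level-by-level because the
increments consist mostly of the inter-level translation, which per-level
(centered) superimposition would destroy. With constant-increment,
noise-free controls the estimator is exact to machine precision, and a
single control returns its own level differences. When a target level is
estimated, the increment chain starts at the nearest preserved level
(ties resolved cranially) and is rotated into the specimen's frame when
at least two preserved levels allow estimating the orientation; preserved
levels are never overwritten.

**Kyphosis.** The TVBHD ratio is ΣA/ΣP over T1–T12, with A and P
measured as the corner-point distances. The regression from ratio to
angle ships with *no default coefficients*: the published regression is
protocol-specific and unavailable, so the model refuses to run
unconfigured rather than silently inventing numbers. Angles outside
(0°, 90°) trigger a warning. Synthetic runs state their coefficients in
the pipeline config (the analysis scripts use intercept 10°, slope
30°/unit ratio, which puts the synthetic spines near 39–40°, a normal
adult thoracic kyphosis).

**Spine assembly.** The 12 levels are placed with their centroids on a
circular arc in the midsagittal plane, preserving consecutive centroid
(chord) spacing, each level rigidly rotated to the local arc tangent.
The arc curvature is solved (Brent's method on the curvature, bracketed
tolerance 1e-15) so that the *polyline* turning angle of the centroids
equals the requested kyphosis angle to better than 1e-6 degrees; a zero
angle degenerates to a straight caudal stack. This is a deliberate
landmark-level simplification of facet-contiguity (zygapophyseal)
articulation, which requires surface meshes and is out of scope.

**Two-block PLS.** Reference specimens are superimposed per block (full
ribcage; partial point set) by form-space GPA. With X and Y the
centered flattened blocks (n × 3p, n × 3q), the leading singular pair
u₁, v₁ of C = XᵀY/(n−1) is computed via economy QR of each block's
transpose, reducing the SVD to n × n (the dense SVD of C is the
independent oracle in tests). β is the least-squares slope of Y-scores
on X-scores. Only the first latent variable is used for prediction;
higher singular values are stored for diagnostics. A case is aligned to
the frozen partial-block consensus by OPA (the reference fit is not
re-run), scored as t = ⟨x − x̄, u₁⟩, and completed as ŷ = ȳ + β t v₁.
Prediction is equivariant under rigid motion of the case. The partial
point set must contain ≥4 non-coplanar points so the alignment is
well-posed. Prediction is whole-complement (one model for everything
missing) rather than rib-by-rib; with a single latent variable the
rib-by-rib decomposition would only lose the covariance between
elements.

**Splicing and provenance.** Observed points are rigidly superimposed
(no scaling — the fossil's material has true size) onto the prediction
over the shared labels and overwrite it; at least 3 non-collinear shared
points are required. Every reconstructed configuration carries per-label
provenance (`observed`, `pls`, `metamer+spine`, `spine`), recorded in the
reconstruction report together with the TVBHD ratio, kyphosis angle, PLS
score and β. A complete input passes through unchanged. Masking
granularity is whole anatomical elements; sub-element fragments are out
of scope.

## Group statistics

The permutation test statistic is |mean_a − mean_b| with the observed
statistic included in the null set: p = (#{perm ≥ obs} + 1)/(n + 1), so
p > 0 always and the smallest attainable p is 1/(n+1). Singleton groups
(individual fossils) are allowed. Raw p-values are reported by default
(mirroring how such tables are usually published); Benjamini–Hochberg
adjustment is available by flag. Permutation counts default to 10,000.

The dendrogram distance between groups g and h is the mean over
replicates of |mean*_g − mean*_h| where each replicate resamples values
*within* each group (bootstrap). A pooled label permutation — the other
reading of "permuted" — would drive all distances toward the same null
scale regardless of separation and could not approximate the plain mean
difference for well-separated groups; within-group resampling degrades
gracefully to the plain |mean difference| for singleton groups. UPGMA is
implemented directly (merge height = average inter-cluster distance / 2,
ties broken by the lexicographically smallest pair of cluster minima) so
that tie-breaking is deterministic; scipy's average linkage is the
independent oracle in tests. Trees are ultrametric and serialized as
Newick with quoted labels (plain Newick would turn underscores into
spaces).

Shape PCA is covariance PCA of the aligned coordinates with a
deterministic sign convention (largest-magnitude loading positive);
variance fractions are over the nonzero spectrum. Samples with no
variation return a flagged degenerate result.

The analysis stage enforces the preprocessing order: symmetrization and
removal of ribs 11–12 always precede superimposition.

## Synthetic thorax generator

The generator is the package's study-conditions module, not a test
convenience. Each specimen is built as:

* twelve planar elliptical rib arcs with half-width ρ·bᵢ·C and depth
  bᵢ·C, where bᵢ is a fixed barrel profile peaking mid-thorax and
  C = 180 mm; the arc spans head (0.06π) → tubercle (0.18π) → sternal
  end (0.96π) in ellipse angle with 16 equally spaced curve points,
  then tilts caudally by the declination angle about the rib head;
* a vertebral column stacked with a constant per-level increment
  (default (0, −3, −26) mm) and fixed body dimensions (height 20 mm,
  depth 25 mm, equal anterior/posterior — the TVBHD ratio of noise-free
  specimens is exactly 1);
* 22 sternal points interpolated between the first and seventh sternal
  rib ends, displaced 10 mm ventrally.

The noise-free configuration is exactly mirror-symmetric and is rescaled
so its centroid size equals the specimen's size draw S exactly.
Measurement error is decomposed into a *symmetric* field (drawn on
midline and left-side points, mirrored to the right; zero x-component on
the midline) scaled by `noise_sd_mm`, plus an *antisymmetric*
(fluctuating-asymmetry) field scaled by `asymmetry_sd_mm`. This makes
"asymmetry off ⇒ exactly symmetric output" a testable invariant and
mirrors the symmetric/asymmetric variance decomposition of
object-symmetric morphometrics. Draw order per specimen (one generator
per call, seeded): S, ρ, declination, symmetric field, antisymmetric
field — documented so outputs stay stable across versions.

Defaults are the study-like conditions: group sizes 12 cold /
29 temperate / 18 warm (the comparative-sample composition, total 59);
group centroid-size means 2642.2 / 2662.6 / 2470.8 mm with
CV 0.065 (the coefficient of variation implied by the published group
dispersions); width/depth ratio ρ means 0.75 / 0.70 / 0.65 with
SD 0.03; declination 30° ± 3°; noise and asymmetry 1 mm each. Group
effects enter only through S, ρ and declination — the interpretive axes
of the analysis (size; width vs depth on PC1; declination on PC2).
Representative mean annual temperatures (0, 15, 26 °C) keep metadata
consistent with the climate thresholds (cold ≤ 7, temperate ≤ 23,
warm > 23 °C; boundaries belong to the colder class).

Built-in preservation patterns emulate four fossil states: `complete`
(everything but the rib-12 pair), `oetzi` (same retention; ribs flagged
as taphonomically perturbed — the dorso-ventral bending of the mummy's
ribs is only flagged, since no correction protocol is documented),
`nazlet_khater_2` (vertebrae T1–T5 plus a configurable rib subset,
default ribs 1–10; sternum absent), and `ohalo_2` (ribs 1, 7, 9–12 as
present in the template plus vertebrae T1, T2, T3, T8; sternum absent).

The `one_factor_sample` helper generates a noise-free sample varying
along a single latent direction projected orthogonal to the rigid
motions of both the full configuration and its restriction to the
partial point set; form-space superimposition is then exactly inert and
the cross-covariance is exactly rank one, giving the PLS stage a
machine-precision recovery case.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: true rib cross-sectional geometry and
torsion, costal cartilage, vertebral wedging and the resulting nonunit
TVBHD ratios, spatially correlated digitization error, allometric shape
change beyond uniform scaling, and taphonomic deformation. Results on
synthetic data validate the *machinery* (alignment, estimation,
inference), not anatomical conclusions.

## Validation experiments and problem sizes

`thoraxgm.experiments` packages the repeatable experiments; chosen sizes
are a deliberate compromise between statistical resolution and a
laptop-scale run:

* **Calibration**: 400 null replicates (n = 10/group, 999 permutations)
  — the type-I error at α = 0.05 sits inside the 99% binomial interval
  (0.022–0.078). **Power**: 200 replicates at n = 15/group against a
  1.5-pooled-SD shift exceed 0.8 by a wide margin (~0.96).
* **PLS recovery**: the one-factor holdout (n = 30) recovers a masked
  specimen to ~1e-17 of centroid size; the noisy paired comparison runs
  20 replicates at the full 59-specimen reference composition. The
  per-replicate win probability against mean substitution is ~0.93–0.94:
  losses are confined to held-out specimens that happen to lie near the
  reference mean, where both completions share the same noise floor and
  the single-latent-variable prediction has nothing to add. The mean
  error contrast is unambiguous (~2.3 vs ~5.2 mm RMS).
* **End-to-end recovery** configures an explicit monotone ecogeographic
  gradient (cold 2800 / temperate 2650 / warm 2470 mm) rather than the
  default group means, whose cold–temperate contrast is non-monotone and
  whose cold–warm separation is marginal at the study's group sizes; the
  experiment is a sensitivity check of the full pipeline, so its
  configured effect is chosen to be unambiguous. Two specimens are
  masked to the Ohalo-like and Nazlet-Khater-like patterns,
  reconstructed, and analyzed with 10,000 permutations.

## Known limitations

* Mesh-level steps of the emulated protocol (surface warping, volume
  estimation, facet articulation, rib placement at functional residual
  capacity) are replaced by landmark-level analogues or omitted.
* The kyphosis regression must be supplied by the user; the package
  cannot validate its coefficients beyond a range warning.
* The UPGMA distance and the permutation statistic are specific readings
  of ambiguous published wording (documented above); alternatives (e.g.
  median-based statistics) are not implemented.
* Reconstruction assumes whole-element preservation; partial ribs or
  vertebral fragments cannot be expressed in the mask model.
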