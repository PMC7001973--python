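# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.

## Claw-angle geometry

A measured surface is reduced to landmarks *A* (proximal end of the
surface), *B* (claw tip) and *X* (apex). *X* is constructed, not digitized:
it is the intersection of the perpendicular bisector of chord *AB* with the
digitized outline polyline, with segments linearly interpolated. When the
bisector crosses the polyline more than once — possible for wavy or noisy
outlines — the crossing farthest from the chord is taken, i.e. the apex of
the convex surface. No crossing at all raises an error naming the metric,
since it means the landmarks are inconsistent with the outline.

The claw angle is the central angle ∠AOB of the circumcircle of *A*, *B*,
*X*, measured for the arc that contains *X*. Because *X* lies on the
measured surface, this arc is the surface's arc; for strongly hooked claws
it exceeds 180°, and the equivalent inscribed-angle form
θ = 360° − 2·∠AXB is used as an independent oracle in the tests. The
angle is invariant under translation, rotation, reflection and uniform
scaling, so outline coordinates are unit-free; angles are always reported
in degrees.

Numerical choices:

* Circumcenter computation centres the three points on their centroid
  first; this removes catastrophic cancellation for small, distant
  triangles and keeps the similarity-invariance error below ~1e-7°.
* Collinearity: landmarks are flat when the implied circumradius exceeds
  1e6 × |AB| (relative area tolerance). Flat returns the value 0°, not an
  error — genuinely flat unguals occur in ground-dwelling birds and are
  data, not failures.
* Endpoint order is canonicalized before computing, so the A↔B symmetry is
  bit-exact.

## Group statistics

* **Allometry check:** OLS of cos θ (normalising transform for angles) on
  log(body mass) per behavioural category, skipping categories with fewer
  than 3 complete records. Log base 10 by default and configurable; slope
  p-values and R² are base-invariant, slopes are not.
* **Pairwise Wilcoxon rank-sum** per metric: exact null distribution when
  both samples have ≤ 10 observations and no ties, otherwise the normal
  approximation with mid-ranks and tie-corrected variance (scipy's
  `mannwhitneyu`). Bonferroni over the category pairs, capped at 1.
* **Pairwise PERMANOVA:** each unordered category pair gets its own
  two-group permutation test of the pseudo-F
  F = [SS_between/(g−1)] / [SS_within/(N−g)], g = 2, from squared
  Euclidean distances between raw angle vectors. p = (1 + #{F_perm ≥
  F_obs}) / (1 + n_perm); the default n_perm = 9999 puts the attainable
  minimum Bonferroni-adjusted p over six pairs at 6 × 1e-4 = 0.0006.
  Permutations are vectorized over label indicators and seeded, so results
  are reproducible bit for bit. The pseudo-F agrees with scikit-bio's
  PERMANOVA to ~1e-14 (test-suite cross-check).
* **Box summaries:** Tukey statistics — quartiles by linear interpolation,
  whiskers to the most extreme point within 1.5·IQR, the rest outliers.

Pairwise two-group tests (rather than one global test with post-hoc
contrasts) match the tabular pairwise reporting the package produces; with
heteroscedastic groups the two-group form is also the more conservative
layout.

## Discriminant lifestyle model

Raw angles in degrees enter the LDA; the cosine transform is used only for
the regression step. The model estimates class means, pooled within-class
covariance **W** (divisor N − g), and priors (class frequencies by default,
uniform or explicit available — classification of rare classes is
sensitive to this choice). Discriminant scalings solve the symmetric
generalized eigenproblem **B**v = λ**W**v, with **B** the class-size-
weighted between-class scatter; `scipy.linalg.eigh(B, W)` returns
eigenvectors with Vᵀ**W**V = I, i.e. the within-class sphering convention,
under which Euclidean distance in the full discriminant space equals
pooled-covariance Mahalanobis distance. Proportion of trace is the
normalized eigenvalue share per axis; the sign of each axis is arbitrary
and comparisons across software are made up to per-column sign. A pooled
covariance with condition number above 1e12 raises a degenerate-data error
naming the metric set.

Posteriors are π_g·N(x; μ_g, **W**) normalized across classes, computed in
log space. Projection centres on the grand mean of the training rows and
multiplies by the scalings.

**Bootstrap accuracy.** Each of n_iterations (default 2000) draws a
resample of the records with replacement, refits the LDA, and classifies
the out-of-bag records. Resamples that lose a class, leave a class with
≤ p records, or leave no out-of-bag records are redrawn (counted in the
report). Per-class accuracy is pooled out-of-bag recall; total accuracy
weights the per-class recalls by the class frequencies of the training
sample. Per-class "accuracy" is not standardised terminology; recall is
this package's documented definition. At 2000 iterations two different
seeds agree to < 0.02 on the default synthetic sample.

**Morphospace ellipses** are normal-theory: the bivariate normal fitted to
a group's (LD1, LD2) scores, drawn at the χ²(2 df) quantile of the
confidence level (95% default), axes from the covariance
eigendecomposition.

**Fossil classification** uses the bone-only model M1 (IU, OU) for every
claw and the bone+sheath model M2 (IU, OU, IS2, OS) where both sheath
angles are present (IS2 is preferred over IS for fossils because it needs
no toe-pad reconstruction); the report flags agreement between the two
predictions. Left and right claws of one specimen are treated as
independent observations and may legitimately disagree.

## Synthetic data

The generator emulates the qualitative structure of real PD-III claw
samples, with all values chosen once as configuration:

* four behavioural groups with mean angle vectors ordered terrestrial <
  perching ≈ predatory < scansorial on every metric; ungual angles lower
  and tighter than sheath angles; the predatory group narrowest
  (SD 7° ungual / 11–12° sheath vs 11–12° / 16–18° elsewhere);
  within-claw correlation 0.6 between metrics;
* IU zero-inflated at 10% in the terrestrial group, emulating the exactly
  flat unguals seen in some ground-dwelling birds;
* body masses log-uniform on 36–1930 g (the envelope a dental-radiography
  acquisition protocol imposes on claw size);
* angle vectors drawn from a truncated multivariate normal (rejection
  sampling on [0°, 360°); the truncation biases low-mean groups slightly
  upward, visible only for terrestrial IU and accounted for in the tests);
* noisy arcs: points uniformly spaced on an arc of known central angle
  with isotropic Gaussian jitter on interior points; endpoints exact.

A `separation` dial scales the spread of group means about their common
centre, used to verify that fossil-category recovery rises monotonically
with separation. Everything is driven by `numpy.random.default_rng` seeds;
identical seeds give byte-identical CSV output.

What passing tests on these data do **not** show: real claw samples have
phylogenetic covariance among taxa (deliberately not simulated, and no
phylogenetic correction is applied anywhere), unbalanced and much smaller
predatory classes, measurement error correlated within observer and
instrument, and behavioural categories that are simplifications of mixed
behaviour. Accuracy numbers on synthetic data characterize the machinery,
not any real fauna.

## Pipeline

`run_full_analysis` runs the four standard metric subsets — (IU, OU),
(IS, OS), (IU, OU, IS, OS), (IU, OU, IS2, OS) — through statistics,
model fitting, bootstrap, morphospace export and fossil classification.
One run seed fans out to per-stage seeds through
`numpy.random.SeedSequence.spawn`, so a single integer reproduces the whole
bundle; outputs carry a configuration hash and the seed map, and reruns are
byte-identical.

Problem sizes in the shipped acceptance script — 30 claws per group, 100
noisy arcs, 500 null replicates at 99 permutations, 999 permutations for
the observed contrasts, 2000 bootstrap iterations per subset, 100 synthetic
fossils — were chosen as the package's default demonstration scale: large
enough that Monte-Carlo error is small against the effects measured, small
enough to run in well under a minute on one core.

## Known limitations

* The apex-selection rule (farthest crossing) assumes a convex measured
  surface; deeply waisted outlines could defeat it.
* PERMANOVA is implemented for the two-group pairwise design only; a
  global g-group test would need the same machinery with g > 2 but is not
  exposed.
* LDA assumes a shared covariance; strongly different group spreads (the
  narrow predatory group) are modelled only through their means.
* Bootstrap redraw on class-losing resamples slightly biases the resample
  distribution for very small classes; the redraw count is reported.
* XLSX reading trusts the first sheet and a flat header row.
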