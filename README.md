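# clawcurve

Claw-curvature ecomorphology: landmark-based claw-angle measurement, group
statistics, and linear-discriminant lifestyle inference for avian and
theropod pedal claws.

## The problem

The shape of a claw tracks how it is used. Ground-dwelling birds have
relatively flat pedal claws, perching and raptorial birds intermediate ones,
and climbers the most strongly hooked — and the same signal survives in the
ungual bone (the terminal phalanx inside the claw), which, unlike the
keratinous sheath, is routinely preserved in fossils. `clawcurve` packages
the full analysis chain that exploits this: it measures claw curvature from
digitized 2-D outlines, compares curvature across behavioural categories,
fits discriminant models of lifestyle on extant samples, and assigns
posterior lifestyle probabilities to fossil theropod and early-bird claws.

It is aimed at comparative morphologists and palaeontologists working with
pedal digit III (PD-III) claws, but nothing in the code is specific to that
digit.

## The measurement and the model

**Claw angle.** A claw surface is summarised by three landmarks: *A* at the
proximal end of the measured surface, *B* at the claw tip, and *X* at the
apex — the intersection of the perpendicular bisector of chord *AB* with the
digitized outline. The circle centre *O* is the circumcenter of *A*, *B*,
*X*, and the claw angle is the central angle ∠AOB of the arc containing *X*.
Flat claws measure exactly 0°; strongly hooked claws can exceed 180°. Five
metrics differ only in landmark placement: IU/OU (inner = ventral and outer
= dorsal curvature of the ungual bone) and IS/IS2/OS (sheath curvatures,
IS2 starting distal to the toe pad).

**Group statistics.** Per behavioural category (terrestrial, perching,
predatory, scansorial), the package fits OLS of cos θ on log₁₀(body mass) to
check allometry, runs pairwise Wilcoxon rank-sum tests per metric and
pairwise two-group PERMANOVAs (pseudo-F on Euclidean distances, permutation
p-values) on metric subsets, all Bonferroni-corrected, and computes Tukey
box-plot summaries.

**Lifestyle model.** A Gaussian LDA on raw angles (degrees): class means
μ_g, pooled within-class covariance **W**, priors π_g, and discriminant
axes solving the generalized eigenproblem **B**v = λ**W**v, normalized so
each discriminant has unit pooled within-class variance. Posteriors are
π_g · N(x; μ_g, **W**) normalized over classes. Predictive accuracy is
estimated by out-of-bag bootstrap (resample, refit, classify the records
left out of the resample), reported per class (recall) and as a
class-frequency-weighted total. Fossils are classified by the bone-only
model M1 (IU, OU) and, when the sheath is preserved, also by the
bone+sheath model M2 (IU, OU, IS2, OS).

A seeded synthetic-data generator with known group structure (truncated
multivariate normal angles, log-uniform masses 36–1930 g, occasional exactly
flat terrestrial unguals) makes every stage testable end to end.

## Worked example

```python
from clawcurve import LifestyleModel, classify_fossil_set, fit_lda
from clawcurve import generate_extant, generate_fossils

data = generate_extant(seed=42)               # 120 claws, 4 categories
res = LifestyleModel(data, metrics=["IU", "OU"]).fit()
print(res.summary())
```

```
Linear discriminant lifestyle model
===================================
Metrics:            IU, OU
Records:            120
Class counts:       terrestrial=30, perching=30, predatory=30, scansorial=30
Priors:             terrestrial=0.2500, perching=0.2500, predatory=0.2500, scansorial=0.2500

Group means (degrees):
                   IU        OU
terrestrial    33.131    60.552
perching       60.315    87.605
predatory      73.091    89.754
scansorial     89.119   112.951

Coefficients of linear discriminants (within-class sphered):
             LD1       LD2
metric
IU     -0.051779  0.096371
OU     -0.039733 -0.106768

Proportion of trace: LD1=0.9530, LD2=0.0470
```

LD1 carries 95% of the between-group separation and orders the groups from
flat (terrestrial) to hooked (scansorial); the sign of each axis is
arbitrary.

```python
acc = res.bootstrap_accuracy(n_iterations=2000, seed=7)
print(acc.total_accuracy)                      # 0.7311
print(acc.per_class_accuracy)                  # terrestrial 0.93, perching 0.44, ...
```

Out-of-bag bootstrap accuracy of the bone-only model is 0.73 on this
synthetic sample — perching claws are the hardest class, as their angles
overlap both the predatory and scansorial ranges.

```python
fossils, truth = generate_fossils(n_per_category=3, seed=43)
m2 = fit_lda(data, ["IU", "OU", "IS2", "OS"])
table = classify_fossil_set(res, m2, fossils)
print(table[["taxon", "M1_terrestrial", "M1_perching",
             "M1_predatory", "M1_scansorial", "M1_predicted"]].head(3))
```

```
           taxon   M1_terrestrial  M1_perching  M1_predatory  M1_scansorial M1_predicted
Fossilis terr001            0.805        0.180         0.016            0.0  terrestrial
Fossilis terr002            0.637        0.284         0.078            0.0  terrestrial
Fossilis terr003            0.682        0.246         0.073            0.0  terrestrial
```

Each row is one fossil claw; the four M1 columns are posterior probabilities
under the bone-only model and sum to 1.

The same workflow is available from the shell
(`clawcurve simulate / measure / stats / train / predict / morphospace /
run-all`); `clawcurve run-all` writes the complete set of tidy CSV outputs
(regressions, pairwise tests, accuracies, loadings, morphospace scores and
95% ellipses, fossil posteriors) with a provenance stamp, and reruns with
the same configuration are byte-identical.

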