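# Methods

## Superimposition

All analyses operate on partial Procrustes superimpositions: every
configuration is centred, scaled to unit centroid size, and rotated to the
consensus; no per-specimen rescaling is applied during rotation and
reflections are disallowed (specimens are assumed digitized in a
consistent orientation, so an apparent reflection indicates an error
rather than a valid alignment). The consensus is initialised from the
first specimen and the rotate/average cycle repeats until the summed
squared change in the consensus drops below `tol = 1e-10`
(`max_iter = 100`; typical convergence is 3–5 iterations). The consensus
is stored rescaled to unit centroid size; the raw coordinate-wise mean of
the aligned specimens is proportional to it with a factor just below 1.

Shape statistics use the superimposed coordinates directly, without
projection to a tangent space. At the shape variation typical of
intraspecific cranial data (Procrustes distances ≪ 0.2) the difference is
far below the effects measured; the choice is recorded here for
reproducibility, and a tangent-space projection is deliberately not
offered rather than half-supported.

Centroid sizes are recorded from the raw coordinates before any scaling,
so they are identical whether or not semilandmarks slide.

## Thin-plate spline and sliding

The TPS uses the 2D fundamental solution `U(r) = r² log r`. The
bending-energy matrix is the upper-left k×k block of the inverse of the
bordered system matrix; it is symmetric positive semidefinite and
annihilates affine deformations exactly, which the tests assert.

Semilandmarks slide along the unit chord from their "before" to their
"after" neighbour (secant tangents — robust for sparse curves, standard
practice). Per specimen, all sliders are solved jointly: the bending
energy of the specimen-to-consensus deformation is quadratic in the vector
of sliding displacements, so its minimiser is one linear solve. The
reference for the energy is the current consensus (one bending-energy
matrix per pass, not per specimen). After each pass the configurations are
re-centred, re-scaled, re-rotated, and the consensus recomputed;
`slide_passes = 5` by default. Because each pass minimises the quadratic
objective exactly against a fixed consensus, within-pass energy is
mathematically non-increasing. Sliding is repeated inside every
rarefaction subsample's GPA (toggleable), treating each subsample as a
self-contained study.

## Statistical layer

**Procrustes ANOVA (RRPP).** Sequential (type I) sums of squares on
flattened coordinates over an ordered covariate list, size entered before
group factors (`shape ~ log10 CS + sex`), no interaction terms. Each
term's significance comes from randomizing reduced-model residuals:
permute the residual rows of the model containing only the preceding
terms, add them back to the reduced fit, recompute the term's F (full
n_perm arrangements including the observed one, so `p ≥ 1/n_perm`;
`n_perm = 1000` default). Effect size is the z-score of the observed F in
its permutation distribution. With a scalar response and one factor this
reduces exactly to the classical one-way F, which the tests check.

**Dispersion.** Group dispersion is Procrustes variance (mean squared
flattened-coordinate distance to the group mean); the pairwise statistic
is the absolute variance difference with labels permuted globally.

**Two-block PLS.** rPLS is the correlation of the first paired singular
axis scores of the cross-block covariance, sign-fixed to be non-negative
(singular-vector signs are arbitrary); the null permutes block-2 rows.

**Tukey HSD.** Pairwise studentized-range tests with the harmonic mean of
each pair's sample sizes in the standard error (the Tukey–Kramer form;
identical to classical HSD when balanced). With two groups it reduces to
the unadjusted two-sample t test. The rarefaction summaries apply ANOVA +
Tukey treating each permuted subsample as an observation — deliberate,
acknowledged pseudo-replication, replicated as a procedure under study
rather than endorsed; interpret those p-values accordingly. Two
degenerate cases are handled explicitly: zero residual variance with
equal means reports p = 1, with unequal means p = 0, both with warnings.

A reporting filter (`ShapePCA.n_above`) counts PCs explaining more than
10% of variance; it never truncates any downstream statistic.

## Rarefaction experiment

Fractions default to (1.0, 0.75, 0.5, 0.25, 0.1); bin sizes round half-up
(n = 72 → 7 specimens in the 10% bin; n = 81 → 8), with a hard minimum of
3. Each (fraction, iteration) draw is seeded as
`base_seed·10⁶ + bin_index·10⁴ + iteration` and the seed stored in the
record, so any single draw reproduces in isolation. The 100% bin reuses
the full-sample consensus, making its distance to the true mean exactly
zero in every iteration — it anchors the distance ANOVA, from whose Tukey
contrasts it is excluded as perfectly degenerate (all-zero variance).

Subsample mean shapes are re-aligned (OPA) to the full consensus before
projection into the full-sample PCA space: each subsample GPA carries an
arbitrary orientation, and convex hulls on (PC1, PC2) only make sense in
a common frame. The same rotation (plus PC1 sign alignment to the
full-sample axis) is applied before comparing PC1 deformation-grid
displacement fields across subsamples.

Under the isotropic generator, the expected squared distance between a
subsample mean of m and the full mean of n is proportional to
`1/m − 1/n`; the acceptance battery checks the regression of mean squared
distance on that predictor (R² > 0.9) and the strict growth of mean
distance as fractions shrink.

One caveat measured during development: the omnibus F comparing mean
log10 centroid size across bins is mildly liberal (~10% rejections at
α = 0.05 instead of 5%), because subsample-mean variances differ ~28-fold
between the 10% and 75% bins. This heteroscedasticity is structural to
the procedure being replicated (equal per-bin counts keep the inflation
modest), not a property of the generator; the unbiasedness conclusion —
no systematic centroid-size differences between bins — is unaffected.

## Synthetic data generator

The generator emulates an intraspecific 2D cranial study on small
mammals. Specimen i of group g is built as

```
coords = CS · R(θ) · (template + effect_g + β·(log10 CS − mean)·a + ε) + t
```

with isotropic Gaussian landmark noise ε, a uniform random rotation θ,
and a random translation t, so superimposition has real work to undo.
Three deterministic templates mirror common skull views: lateral cranium
(14 fixed landmarks + one 15-point sliding curve), ventral cranium
(19 + 6), and mandible (10 + three curves of 6/6/18); curves are
quadratic arcs between fixed anchor landmarks, divided equidistantly in
parameter. A generic polygon template (any k, no semilandmarks) serves
calibration studies.

Every effect vector — allometry `a`, group offsets — is orthogonalized
against the template's similarity directions (translation, rotation,
scale), so generator truth lives in the shape space that Procrustes
analysis estimates.

Defaults (units of template centroid size unless noted), chosen once as
the study conditions:

| parameter | default | rationale |
|---|---|---|
| landmark noise sd | 0.008 | <1% of CS: combined digitization + individual variation |
| log10 CS sd | 0.04 | ~9% coefficient of variation in size, typical intraspecific |
| allometry slope β | 0.8 | allometry carries ~20% of shape variance and dominates PC1 |
| sex shape offset norm | 0.024 | puts the sex term's ANOVA R² in the few-percent band typical of subtle sexual shape dimorphism |
| sex log10 CS offset | 0.03 | females ~7% larger, detectable but not overwhelming |
| congener shape offset | 0.004 | half the per-landmark noise sd: a morphologically cryptic species pair with heavily overlapping hulls |

Study designs: 48 F / 24 M (n = 72), 39 F / 42 M (n = 81), and an
overlapping congener sample (n = 22).

What the generator does **not** emulate: correlated (anatomically
structured) noise, digitizer bias, curve-resampling artefacts, outliers,
within-species geographic structure, or any 3D-to-2D projection error.
Passing tests therefore demonstrate the correctness and calibration of
the machinery under clean assumptions, not robustness of conclusions on
real museum data.

## Ground-truth recovery protocol

Recovery checks (allometry direction/slope) run GPA without sliding and
rotate the estimated coefficient vector into the template frame before
comparison: sliding legitimately removes along-curve components of any
injected vector, and a GPA frame is defined only up to rotation. With
defaults at n = 80 the direction cosine is ≈ 0.98 and the slope error a
few percent.

## Problem sizes used in tests and the acceptance script

Calibration batteries run 500 null simulations (n = 40, k = 10,
n_perm = 200). The main rarefaction run uses T = 200 iterations over all
five bins at n = 72; the centroid-size unbiasedness battery runs 50
replicate experiments (centroid-size-only fast path, which skips
per-subsample GPA since sizes do not depend on it); the dispersion
battery runs 20 replicates at T = 100 over the 75% and 10% bins, where
the variance contrast is strongest. The balanced-resampling dimorphism
count uses T = 200 resamples at n_perm = 200. These sizes are the
package's chosen experiment scale; all are parameters.

## Known limitations

- 2D landmarks only; no 3D rotation, no surface semilandmarks.
- Bending-energy sliding only (no minimum-Procrustes-distance criterion).
- TPS reader covers the tpsDIG dialect (LM/CURVES/POINTS/IMAGE/ID/SCALE,
  case-insensitive); NTS and Morphologika formats are out of scope.
- SCALE factors, when present in TPS files, are always applied and
  logged; there is no option to ignore them.
- Permutation tests shuffle complete rows; no restricted/blocked
  permutation schemes.
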