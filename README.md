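# morphosample

2D geometric morphometrics with a focus on **how sample size affects what
you can estimate**: mean shape, shape variance, and centroid size.

Morphometric studies of museum material rarely get to choose their sample
size — specimen availability does. This package implements the full
analysis stack needed to quantify the consequences: Generalized Procrustes
Analysis (GPA) with bending-energy sliding of semilandmarks, shape PCA,
Procrustes ANOVA with residual-randomization (RRPP) significance,
dispersion (Procrustes variance) permutation tests, two-block partial least
squares, and a seeded rarefaction experiment that repeatedly subsamples a
dataset into fraction bins (100/75/50/25/10%) and measures how far each
subsample's mean shape drifts from the full-sample ("true") mean. A
synthetic landmark generator with known ground truth (template shape,
isotropic landmark noise, allometry, group shape/size offsets) makes every
stage testable end to end.

## Core quantities

- **Centroid size** `CS = sqrt(Σᵢ ‖xᵢ − x̄‖²)` — the standard size measure,
  geometrically independent of shape.
- **Partial Procrustes distance** `d(A, B)` — root summed squared
  coordinate differences after centring, unit-size scaling, and optimal
  rotation (no reflections).
- **GPA** — iterative rotate/average superimposition to a consensus;
  semilandmarks slide along their curve tangents to minimize the
  thin-plate-spline bending energy of each specimen-to-consensus
  deformation (solved jointly per specimen as a linear system).
- **Procrustes ANOVA / RRPP** — sequential (type I) sums of squares of
  flattened shape coordinates over an ordered covariate list (e.g.
  `shape ~ log10 CS + sex`); each term's F is tested by permuting its
  reduced-model residuals, with `p ≥ 1/n_perm` and effect size
  `Z = (F_obs − mean F_perm)/sd F_perm`.
- **Two-block PLS** — first singular axes of the cross-block covariance;
  `rPLS` is the correlation of the paired axis scores, tested by permuting
  one block's rows.
- **Rarefaction** — for every bin fraction `f` and iteration `t`, a seeded
  draw of `round(f·n)` specimens gets its own self-contained GPA (sliding
  included); records hold member IDs, mean shape, mean log10 CS, and the
  Procrustes distance to the full-sample consensus. Under isotropic
  sampling error the expected squared distance scales as `1/m − 1/n`.

## Worked example

```python
import morphosample as ms

# a study-structured synthetic sample: 48 F / 24 M, 14 fixed landmarks
# + 15 sliding semilandmarks, isotropic noise, allometry, sex dimorphism
ds, truth = ms.generate_dataset(ms.study_spec(seed=7))
res = ms.gpa(ds, slide=True)
print(f"n = {ds.n}, k = {ds.k}, GPA iterations = {res.iterations}")

records, full = ms.run_rarefaction(ds, T=50, base_seed=7)
df = ms.records_to_dataframe(records)
print(df.groupby("fraction").dist_to_true.mean().round(4))

summary = ms.summarize_rarefaction(records, full, n_perm=500, seed=7)
print("CS ANOVA p =", round(summary.cs_anova.p[0], 3))
```

prints

```
n = 72, k = 29, GPA iterations = 3
fraction
0.10    0.0527
0.25    0.0311
0.50    0.0195
0.75    0.0118
1.00    0.0000
Name: dist_to_true, dtype: float64
CS ANOVA p = 0.547
```

Mean shape error grows steadily as the subsample shrinks (a 10% subsample
of 7 specimens sits ~0.05 Procrustes units from the true mean; the 100%
bin is exactly at it), while mean centroid size stays statistically
indistinguishable across bins — size can be estimated well from few
specimens, mean shape cannot. The accompanying dispersion tests flag the
10% bin's mean shapes as significantly more variable than every other
bin's (p ≈ 0.002 at 500 permutations).

## Command line

```bash
morphosample simulate --out data/ --seed 1          # synthetic TPS + tables
morphosample gpa --tps data/landmarks.tps --sliders data/sliders.csv --out gpa/
morphosample rarefy --simulate --seed 1 -T 200 --out raref/
morphosample concordance --config views.yaml --out pls/
morphosample dimorphism --tps ... --classifiers ... --balanced-t 1000 --out dim/
```

Every command writes a `manifest.json` (config hash, seeds, version) so
runs are reproducible bit-for-bit. Real tpsDIG-dialect TPS files, slider
CSVs (`before,slide,after`, 1-based), and classifier CSVs
(`id,species,sex,view`) are accepted anywhere the synthetic data is.

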