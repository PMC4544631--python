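# gsel

Genomic selection for multi-family populations of fully inbred breeding
lines (doubled haploids and recombinant inbred lines), built for plant
breeders and quantitative geneticists who want to study — at desk scale,
with full control of the truth — why genomic prediction works within a
breeding population and fails across them.

Genomic selection predicts a line's genetic merit (its genomic estimated
breeding value, GEBV) from genome-wide markers: marker effects
**β** are estimated on a *training* population with genotypes **X** and
phenotypes **y**, and candidates are ranked by **X**<sub>new</sub>**β̂**
without being phenotyped. Accuracy is the Pearson correlation *r* between
GEBVs and observed values in held-out lines, and it depends on the linkage
disequilibrium between markers and QTLs and on the relatedness between
training and target material — both of which decay when the two sets come
from different breeding programs.

## What's in the package

* **Simulation** (`gsel.simulate`) — inbred founder pools with a U-shaped
  allele-frequency spectrum, Haldane-model meiosis on a cM map, DH (one
  meiosis, genome doubled) and RIL (single-seed descent, ~2x map
  expansion) multi-family populations, additive 100-QTL traits at a
  controlled heritability, and partially shared architectures between two
  populations.
* **Phenotype adjustment** (`gsel.phenotype`) — the unreplicated-trial
  model `Y_ij = μ + G_i + B_j + e_ij` (sub-block effects identified by
  repeated control cultivars), the across-location ANOVA
  `Y_il = μ + G_i + Location_l + e_il` with variance components, and
  line-mean heritability `h² = σ²_g / (σ²_g + σ²_e/ℓ)`.
* **Five GEBV methods** (`gsel.predictors`), all scikit-learn compatible
  estimators: ridge regression BLUP (`β̂ = (X'X + λI)⁻¹X'y`, λ tied to
  heritability), Bayesian ridge regression and the Bayesian LASSO (Gibbs
  samplers, numba-compiled), GBLUP on a marker kinship with spectral REML,
  Gaussian-kernel (RKHS) regression, and random-forest regression.
* **Relatedness and LD** (`gsel.relatedness`) — identity-by-state kinship
  with diagonal normalization, within/between-group summaries, and LD as
  the squared correlation r² of marker columns.
* **Evaluation** (`gsel.evaluation`) — single-, composite- and
  cross-population cross-validation (80/20 resampling, refit every
  iteration), and the QTL-sharing experiment measuring how
  cross-population accuracy decays as the two populations' architectures
  share fewer QTLs.
* A `gsel` command line (`simulate`, `adjust`, `kinship`, `ld`, `fit`,
  `cv`, `qtl-share`, `run`) operating on plain TSV/JSON files, plus a
  strict YAML-configured pipeline with a reproducibility manifest.

## Worked example

```python
import numpy as np
from gsel import (
    study_populations, intersect_markers, draw_architecture, simulate_trait,
    CVScheme, run_cv, qtl_sharing_experiment,
)

# two ~350-line populations (one DH, one RIL) from overlapping parent pools
dh, ril, founders = study_populations(seed=7)
print(f"{dh.n_lines} lines x {dh.n_markers} markers "
      f"({dh.polymorphic_mask().sum()} polymorphic)")
print("polymorphic in both:", (dh.polymorphic_mask() & ril.polymorphic_mask()).sum())

# a 100-QTL additive trait at h2 = 0.82 in the DH population
arch = draw_architecture(np.flatnonzero(dh.polymorphic_mask()),
                         n_qtl=100, sigma_a=1.0, seed=1, h2=0.82)
y, g = simulate_trait(dh, arch, seed=2)
print(f"realized h2 = {np.var(g, ddof=1)/np.var(y, ddof=1):.3f}")

# within-population cross-validation, 80/20, ridge
scheme = CVScheme(kind="single", training_populations=["popA"],
                  n_iterations=50, seed=3)
res = run_cv(scheme, "RIDGE", {"popA": (dh, y)})
print(f"single-population CV: r = {res.mean_r:.3f} +/- {res.sd_r:.3f}")

# cross-population accuracy versus shared-QTL fraction
dh_c, ril_c = intersect_markers([dh, ril])
table = qtl_sharing_experiment(dh_c, ril_c, fractions=[0.1, 0.5, 1.0],
                               h2_levels=(0.6,), n_reps=20, seed=4)
print(table[["fraction", "h2", "mean_r", "sd_r"]].round(3).to_string(index=False))
```

prints

```
350 lines x 2520 markers (1257 polymorphic)
polymorphic in both: 1177
realized h2 = 0.811
single-population CV: r = 0.638 +/- 0.060
 fraction  h2  mean_r  sd_r
      0.1 0.6   0.024 0.113
      0.5 0.6   0.244 0.114
      1.0 0.6   0.432 0.056
```

Read: within one population, markers predict the trait well (r ≈ 0.64 at
h² ≈ 0.8). Across populations, even with *identical* architectures
(fraction 1.0) accuracy drops to r ≈ 0.43, and it decays roughly linearly
as the shared fraction of QTLs shrinks — at 10% sharing the accuracy is
statistically indistinguishable from zero. Family structure behaves as
expected too: mean identity-by-state kinship is 0.943 within full-sib
families versus 0.888 between families of the same population
(`kinship_group_summary(ibs_kinship(dh, group_labels=...))`).

The same study from the shell:

```bash
gsel simulate --seed 7 --out-dir run1
gsel adjust --phenotypes run1/phenotypes_popA.tsv --trait simtrait --out-prefix run1/adj
gsel cv --scheme single --method RIDGE \
     --train run1/genotypes_popA.tsv:run1/trait_popA.tsv --out-prefix run1/cv
gsel qtl-share --train run1/genotypes_popA.tsv --validation run1/genotypes_popB.tsv \
     --reps 20 --out run1/sharing.tsv
```

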