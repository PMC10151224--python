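# wingmorph

Landmark-based wing geometric morphometrics for separating and identifying
closely related fly species — built around the two *Haematobosca* species
that co-occur in Thailand (*H. sanguinolenta* and *H. aberrans*), whose
adults are hard to tell apart once diagnostic setae are damaged in the
field.  The package implements the full analysis chain a wing-morphometrics
study runs on digitized landmarks: Procrustes superimposition, size and
shape statistics with permutation inference, cross-validated classification,
UPGMA clustering, digitization repeatability, and identification of new
specimens against reference data.  It is aimed at medical/veterinary
entomologists and anyone who needs a scripted, reproducible alternative to
interactive morphometrics GUIs.

## The method

Each wing is a configuration of k homologous landmarks **x**₁…**x**ₖ ∈ ℝ².
Size and shape are separated classically:

- **Centroid size**: CS = √Σᵢ‖**x**ᵢ − x̄‖², the scale measure.
- **Generalized Procrustes analysis (GPA)**: every configuration is
  translated to the origin, scaled to unit CS, and rotated onto an
  iteratively refined consensus; aligned configurations are projected
  orthogonally onto the tangent plane at the consensus (projection
  I − **cc**ᵀ for the unit consensus vector **c**), giving Euclidean
  *shape variables* of rank ≤ 2k − 4.
- **Inference**: one-way ANOVA on CS and pairwise |mean differences| with
  permutation p-values, p = (b + 1)/(B + 1), Bonferroni-corrected;
  pairwise Mahalanobis distances D = √(δᵀS⁻¹δ) on retained PC scores with
  the same permutation machinery; canonical variate (discriminant) axes
  from eigenvectors of W⁻¹B.
- **Classification**: leave-one-out, per-group normal maximum likelihood on
  CS (size) and closest group by Mahalanobis distance (shape).
- **Clustering**: UPGMA on Euclidean distances between shape variables.
- **Repeatability**: Procrustes ANOVA over replicate digitizations;
  R = s²ₐ/(s²ₐ + MS_w)·100 with s²ₐ = (MS_a − MS_w)/m.
- **Allometry**: r² of the OLS regression of the first shape PC on CS.

Because the original study's landmark coordinates were never published (only
wing images are deposited), the package ships a synthetic-data generator
(`wingmorph.synthetic_data`) that reproduces the study's statistical design:
four groups (2 species × 2 sexes, n = 50/50/20/20), group centroid sizes
drawn from the published normal distributions (3.94/3.93/2.99/3.07 mm),
mean-shape offsets concentrated at the anterior and posterior wing-margin
landmarks, optional allometric coupling, and replicate digitization error.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
wings and write tables under `results/`:

```sh
python analysis/01_simulate_wings.py --seed 1
python analysis/02_repeatability.py
python analysis/03_size_analysis.py
python analysis/05_classification.py
```

`02` prints the digitization-precision check:

```
intra-user repeatability: 98.9% (error 1.1%), passes the 90% threshold
inter-user repeatability: 98.3% (error 1.7%), passes the 90% threshold
```

`03` prints the size analysis — species differ in wing size, sexes within a
species do not (shared letters):

```
         species    sex  n     mean      max      min  variance       sd letter
     H. aberrans female 20 3.091142 3.813528 2.772277  0.048684 0.220645      a
     H. aberrans   male 20 2.986011 3.190244 2.812502  0.010384 0.101901      a
H. sanguinolenta female 50 3.899434 4.794138 3.119942  0.150429 0.387852      b
H. sanguinolenta   male 50 3.906339 4.497527 3.180875  0.070643 0.265787      b
omnibus one-way ANOVA F = 81.36, permutation p = 0.000999
```

and `05` shows the study's central contrast — wing shape identifies the
flies nearly perfectly while overlapping wing sizes cannot:

```
overall: size 53.6% vs shape 100.0% — shape dominates
```

The same steps are available programmatically:

```python
from wingmorph import (generalized_procrustes, shape_pca, loo_classify_shape,
                       simulate_reference_dataset)
from wingmorph.synthetic_data import study_design_spec

ds = simulate_reference_dataset(study_design_spec(seed=1))
aligned = generalized_procrustes(ds)       # consensus, CS, shape variables
conf = loo_classify_shape(aligned, shape_pca(aligned))
print(conf.summary_table())
```

and from the shell via the `wingmorph` CLI (`simulate`, `gpa`, `size`,
`shape`, `classify`, `cluster`, `repeatability`, `identify`, `all`).

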