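# illposed

Linear ill-posed classification experiments on synthetic gray-matter
volumes: three linear classifiers (a Moore-Penrose pseudo-inverse
linear regression classifier, elastic-net regularized logistic
regression by coordinate descent, and a soft/hard-margin linear kernel
SVM) evaluated across a sample-size × dimension grid, with SVD-based
conditioning diagnostics of the linear kernel matrices and PCA-space
counterparts.

A seeded synthetic cohort generator produces 3D gray-matter density
volumes (NIfTI) with a smooth probability template, nested analysis
masks at four thresholds, a spatially localized class effect with
per-subject severity, and spatially smoothed noise — standing in for
restricted clinical data.

## Layout

| module | contents |
| --- | --- |
| `illposed.synthetic_cohort` | template + cohort simulation, NIfTI I/O |
| `illposed.template_masking` | threshold → mask → vectorize → standardize |
| `illposed.kernel_conditioning` | Gram matrices, SVD rank/condition reports, spectrum aggregation |
| `illposed.classifiers` | LRC (dual pseudo-inverse), RLR (coordinate descent), SVM (precomputed-kernel dual) |
| `illposed.model_selection` | fixed held-out split, stratified 10-fold CV grid search, accuracy |
| `illposed.pca_space` | PCA projection + incremental component selection |
| `illposed.experiments` | experiment grids 1-3 + hard/soft-margin supplement, aggregation |

## CLI

```sh
# simulate a cohort to NIfTI volumes + participants.csv
illposed simulate --config cohort.yaml --out cohort_dir --seed 1

# run an experiment grid (exp1 | exp2 | exp3 | supp)
illposed run exp1 --config experiment.yaml --out results/ --seed 1
```

`experiment.yaml` is a serialized `ExperimentConfig`
(`ExperimentConfig().to_yaml(path)` writes the default desk-scale
configuration: 32³ grid, size ladder 20-210, four mask thresholds
0.86/0.65/0.2/0.0021, 20 iterations). Outputs are long-format per-cell
CSV plus a mean/sd/quartile summary CSV.

## Reproducibility

Every experiment cell is seeded from the master seed through
`numpy.random.SeedSequence` tuple entropy keyed by (experiment, size
index, threshold index, iteration), so any subset of the grid, run in
any order, reproduces the same numbers.
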