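# neurodct

Joint three-class classification of Alzheimer's disease (AD), Parkinson's
disease (PD) and normal controls (NC) from volumetric functional neuroimaging
(PET and SPECT), implemented as a fully tested pipeline: synthetic cohort
generation, spatial- and DCT-frequency-domain learning with a fixed five-block
3D CNN, volumetric training-set augmentation, subject-level k-fold
cross-validation over a 20-method benchmark grid, and five-metric evaluation
with dense-rank aggregation.

Real AD/PD imaging cohorts (ADNI PET, PPMI SPECT) are access-restricted, so
the package ships a synthetic cohort generator with controllable class
separation — every stage of the pipeline is testable with known ground truth —
plus the published per-method metric values of the 20-method benchmark, from
which the derived average and ranking tables are reproduced exactly.

## The model

Volumes of shape 79 × 95 × 69 enter either as raw intensities (*spatial
domain*) or as their full orthonormal 3D DCT-II coefficient grid (*frequency
domain*), z-scored over all voxels. The network is five blocks of

    3×3×3 conv (11 filters, stride 1, same padding) → batch-norm → ELU
    → 2×2×2 max-pool (stride 2, ceil-mode)

followed by FC 300 → FC 100 → FC 3 → dropout(0.1) → softmax. Ceil-mode pooling
maps n → ⌈n/2⌉, so the five pools reduce 79 × 95 × 69 to a 3 × 3 × 3 map with
11 channels. Training uses Adam (lr 0.001, batch 2) with cross-entropy loss
and L2 weight decay on conv/FC weights. Two training-set augmentations are
provided: isotropic Gaussian blur (σ = 1.5 voxels) and random zoom with scale
drawn from {0.99, 1.03}; evaluation volumes are never augmented.

Each method (task × domain × augmentation × fold count) is scored on the
pooled cross-validation confusion matrix C (rows = true class, columns =
predicted) by five metrics:

- **RCI** = I(T;P) / H(T) — mutual information between true and predicted
  labels over the true-label entropy;
- **CEN**_j — confusion entropy of class j's misclassification probabilities,
  log base 2(K−1);
- **IBA**_j = (1 + α(TPR−TNR))·TPR·TNR with α = 0.1, one-vs-rest;
- **GM**_j = √(TPR·TNR), one-vs-rest;
- **MCC**_j — Matthews correlation of the one-vs-rest 2×2 table.

Per-class values are averaged with equal class weight; each metric column is
dense-ranked across methods (best = 1, ties share, no gaps), the five ranks
are summed into an overall score, and scores are dense-ranked into the overall
ranking.

## Worked example

Reproduce the benchmark average/ranking tables from the bundled per-method
reference values:

```python
from neurodct import tables

metrics = tables.load_reference_metrics()        # 20 methods, per-class values
print(tables.compute_ranking(metrics).head(3).to_string(index=False))
```

```
 method_id  rank_rci  rank_cen  rank_iba  rank_gm  rank_mcc  overall_score  overall_ranking
         1         1         1         1        1         1              5                1
         2         2         2         2        2         2             10                2
         3         2         2         2        2         2             10                2
```

Method 1 (spatial domain, Gaussian-blur augmentation, 5-fold CV) tops every
metric column, giving the minimum possible overall score of 5; method 20
(PET-task, frequency domain, no augmentation, 10-fold) sums to 84, the worst
overall ranking (18).

Run that best-ranked configuration end to end on a reduced-scale synthetic
cohort (32³ voxels, 20 subjects per class, regional effect five times the
voxel noise s.d., 10 epochs):

```python
import neurodct as nd
from neurodct import cnn, ranking

spec = nd.CohortSpec(n_per_class=20, effect_size=2.5, noise_sd=0.5,
                     seed=7, shape=(32, 32, 32))
cohort = nd.generate_cohort(spec)
result = ranking.run_method(nd.enumerate_methods()[0], cohort,
                            cnn.TrainConfig(max_epochs=10, seed=1))
print(result.confusion.counts)
print(result.metrics[["rci", "gm_ad", "gm_nc_spect", "gm_pd"]])
```

```
[[11  0  0]
 [ 1 10  0]
 [ 0  0 11]]
rci            0.905058
gm_ad          0.977008
gm_nc_spect    0.953463
gm_pd          1.000000
```

The pooled 5-fold confusion matrix is nearly diagonal: with a class signal
five times the noise level the pipeline recovers all three groups (per-class
GM ≥ 0.95); on an `effect_size=0` cohort the same run scores at chance.

The same pipeline is scriptable from the shell: `neurodct cohort`,
`neurodct preprocess`, `neurodct augment`, `neurodct metrics`,
`neurodct rank`, `neurodct experiment` (see `neurodct --help`).

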