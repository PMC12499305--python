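# conngat

Brain-age prediction from multi-task functional connectomes, combining joint
non-negative matrix factorization with graph attention networks, plus a
mask-learning explainer that identifies the functional connections driving
the prediction.

## Who this is for

Researchers with per-subject, per-task ROI×ROI functional-connectivity
matrices (Pearson correlations of regional BOLD time series on an atlas such
as the 264-node Power parcellation) who want to (1) regress a continuous
target such as chronological age from several fMRI paradigms jointly, and
(2) know *which* connections and functional networks carry the signal.
Real developmental cohorts of this kind are typically access-restricted, so
the package ships a synthetic-cohort generator with planted latent structure
that exercises the entire pipeline end to end.

## The model

**Stage 1 — shared-basis factorization.** Positive-thresholded connectivity
matrices X_k (one per subject and task) are factorized jointly,

    X_k ≈ W H_k,   W ≥ 0, H_k ≥ 0,
    min Σ_k ‖X_k − W H_k‖²_F + α(‖W‖²_F + Σ_k ‖H_k‖²_F),

by multiplicative updates. The shared basis W (N×R) captures group-level
connectivity patterns; the per-(subject, task) coefficients H_k provide
individualized node features (column i of H_k is node i's feature vector).

**Stage 2 — graph attention regression.** A brain graph is built by keeping
the top 10% of node pairs by cosine similarity of connectivity profiles.
Two attention layers per task,

    e_ij = LeakyReLU(aᵀ[Wh_i ‖ Wh_j]),  α_ij = softmax_j(e_ij),
    h′_i = σ(Σ_j α_ij W h_j),

followed by two dense layers, are trained with Adam on

    L = L_JNMF + λ Σ_ij α_ij ‖h_i − h_j‖² + μ·MSE(ŷ, y),

a combined loss of reconstruction (fixed after stage 1), graph smoothness,
and age-prediction error.

**Explanation.** Per subject, soft edge and feature masks are optimized
(five weighted loss components: prediction, feature size/element, population
size/element) so that the masked model reproduces its own prediction with as
little of the graph as possible; edges marked consistently across subjects
are tabulated by functional network. Everything runs on a small in-package
reverse-mode autodiff engine over numpy — no deep-learning framework is
required.

## Worked example

```python
import numpy as np
from conngat import (ConnectomeGATRegressor, ExplainerConfig, GNNExplainer,
                     SyntheticSpec, cohort_to_dataset, generate_cohort,
                     stratified_split, metrics, common_connections,
                     network_tabulation)

spec = SyntheticSpec(n_subjects=80, n_rois=30, n_tasks=2, rank=3,
                     effect_factors=(1,), effect_size=1.0, timepoints=80,
                     noise_sd=1.0, seed=7)
data = cohort_to_dataset(generate_cohort(spec))
plan = stratified_split(data.ages, (0.8, 0.1, 0.1), n_bins=5, seed=0)

model = ConnectomeGATRegressor(rank=3, nmf_alpha=0.1, nmf_iters=200,
                               epochs=200, learning_rate=3e-3,
                               weight_decay=1e-4, hidden_dim=8,
                               head_hidden=32, seed=0)
model.fit(data, train_idx=plan.train)
pred = model.predict(data, idx=plan.test)
m = metrics(data.ages[plan.test], pred)
print(f"test RMSE {m.rmse:.3f}  MAE {m.mae:.3f}  r {m.pearson_r:.3f}")

cfg = ExplainerConfig(pop_size_w=200.0)   # edge-size pressure -> sparse explanations
explainer = GNNExplainer(config=cfg, seed=0)
masks = [explainer.explain(model, data, s) for s in data.subjects[:5]]
table = common_connections(masks, fraction=0.05, atlas=data.atlas)
print(table.to_string(index=False))
print(network_tabulation(table, data.atlas).to_string())
```

prints

```
test RMSE 0.619  MAE 0.480  r 0.996
 roi_i  roi_j network_i network_j  frequency  mean_weight
     4      6      NET1      NET1        1.0     0.000036
    23     28      NET3      NET3        0.6     0.200023
    22     24      NET3      NET3        0.6     0.000036
      NET1  NET2  NET3
NET1     1     0     0
NET2     0     0     0
NET3     0     0     2
```

The cohort plants an age-dependent signal in factor 1 (labeled NET1 in the
synthetic atlas). The model recovers the target almost perfectly from the
held-out subjects (ages span 8–22 years, so an RMSE of 0.62 years is a
tight fit), and the most consistently flagged connection — marked by every
explained subject — lies inside NET1, the network whose connectivity
actually varies with age. `frequency` is the share of subjects whose
top-5% mask set contains the edge; `mean_weight` is the average mask value,
which under strong sparsity pressure is near zero even for edges that are
consistently ranked first.

A command-line interface mirrors the library (`conngat simulate`,
`fit-jnmf`, `train`, `predict`, `explain`, `evaluate`, `compare`), driven by
YAML configs; cohorts are stored as plain delimited matrices plus atlas and
target tables.

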