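# Methods

## Problem setting

The package predicts a continuous per-subject target (chronological age, in
years) from multi-task functional connectomes. Each subject contributes one
ROI-by-ROI Pearson-correlation matrix per fMRI task (e.g. an emotion-
identification and a working-memory paradigm), computed from mean regional
BOLD time series on a fixed parcellation (264 nodes by default; any square
parcellation is accepted). Alongside prediction, the package identifies the
functional connections most responsible for the prediction and tabulates
them by functional network.

## Stage 1 — joint non-negative matrix factorization

Each connectivity matrix is first thresholded to its positive part (negative
correlations set to zero), giving non-negative inputs X_k, one per
(subject, task). All X_k are factorized jointly with a single shared basis:

    X_k ≈ W H_k,   W ≥ 0, H_k ≥ 0,   k = 1 … K

minimising  Σ_k ‖X_k − W H_k‖²_F + α(‖W‖²_F + Σ_k ‖H_k‖²_F).

W (N × R) captures group-level connectivity structure common to all subjects
and tasks; H_k (R × N) carries the individual variation. Column i of H_k is
node i's R-dimensional feature vector for that subject and task
(`feature_mode="H"`, the default; `"WH"` uses rows of the reconstruction
instead, and `"fc"` bypasses the factorization for the ablation arm).

Design choices that the problem statement leaves open, fixed here:

- **Update rule.** Lee–Seung multiplicative updates extended to the shared
  basis and the Tikhonov penalty:
  W ← W ⊙ (Σ_k X_k H_kᵀ) ⊘ (W Σ_k H_k H_kᵀ + αW + ε),
  H_k ← H_k ⊙ (Wᵀ X_k) ⊘ (WᵀW H_k + αH_k + ε), ε = 1e-10. The W update is
  applied first, then all H_k against the new W. These updates never
  increase the objective and preserve non-negativity exactly, which
  gradient steps would not.
- **Form of α.** A squared-Frobenius penalty on W and every H_k — the
  simplest penalty compatible with multiplicative updates and a scalar α.
- **Granularity.** Every (subject, task) pair contributes its own X_k; W is
  shared across all of them. This yields per-subject node features while
  keeping the basis common across subjects and modalities.
- **Initialisation.** Entries uniform(0,1) scaled by √(mean(X)/R), seeded.
  One H initialisation is drawn and replicated across k (the H_k
  subproblems are independent given W, so identical inputs evolve
  identically).
- **Defaults.** Rank R = 5, α = 0.1. Note an ambiguity in the source
  experiments: the ablation table's best row is (rank 5, α = 0.5) while the
  reproducibility settings and the prose name α = 0.1; the defaults follow
  the latter without asserting which produced the headline numbers.
- **Held-out subjects** are projected onto the fitted basis by running the
  H-side update alone with W fixed.

## Stage 2 — graph attention regression

**Graph construction.** Node-pair weights are cosine similarities between
connectivity profiles (matrix rows with the self-correlation zeroed); the
top 10% of pairs by weight form the edge set (density configurable). By
default one group-level topology is built per task from the mean training
connectivity, with subject-specific node features; a per-subject topology is
available (`topology="subject"`). Cosine weights select edges only — they do
not enter the attention computation, which follows the printed equations
exactly; a weighted variant is deliberately not the default.

**Attention layer.** For node i and neighbor j,

    e_ij = LeakyReLU(aᵀ [W h_i ‖ W h_j]),   α_ij = softmax_j(e_ij),
    h′_i = σ( Σ_{j∈N(i)} α_ij W h_j ),

with a single head (multi-head was never indicated for this architecture;
the layer supports uniform-weight mode as the attention-free comparator).
Self-loops are enabled by default so every node attends to itself — standard
practice, and it prevents empty neighborhoods after sparsification. The
LeakyReLU negative slope is 0.2 (the original convention for this layer
type). Softmax is computed with per-neighborhood max-subtraction.

**Architecture.** Two attention layers per task branch ("branch" wiring,
default: each task has its own stack and the flattened node embeddings are
merged through the activation before the head; "concat" runs one stack on
features concatenated across tasks). The head is two dense layers: a
nonlinear hidden layer (100 units by default, matching the reported layer
size) and a scalar output. The flattened per-node representation feeding
the head mirrors the reported first-layer size of 69,696 = 264² for the
full parcellation.

**Loss.** Training minimises

    L = L_JNMF + λ Σ_i Σ_{j∈N(i)} α_ij ‖h_i − h_j‖² + μ · MSE(ŷ, y)

where the smoothness term (squared Euclidean distances between final node
embeddings, weighted by the last layer's attention) is averaged per subject,
and L_JNMF enters the reported per-epoch loss as a constant: the
factorization is solved first by multiplicative updates, then the network is
trained by Adam. This two-stage scheme preserves the non-negativity
guarantees of stage 1; an optional outer loop (`refit_h_every`) re-fits H_k
during training but is off by default. λ = 0.1 and μ = 1.0 by default
(no values were reported; prediction is the primary task and a small λ
favors the task-specific objective).

**Optimisation.** Adam, learning rate 1e-5, weight decay 0.2, 6000 epochs
by default (the reported settings; 3000 is also named in the source and
reachable via config). The activation is LeakyReLU by default; ReLU is
available because the experimental text names both — the conflict is
surfaced here rather than resolved. Training is full-batch and exactly
reproducible under a seed. All gradients come from a small in-package
reverse-mode autodiff engine on numpy arrays, validated against central
finite differences (max relative error < 1e-4 on the combined loss; ~1e-9
observed).

Numerical notes: node features are divided by one per-branch scalar (the
training-split standard deviation) so feature modes with very different
scales train comparably; the output bias is initialised at the mean training
age; softmax denominators carry a 1e-30 floor; the final-layer output is the
prediction (no clipping).

## Explanation stage

A soft edge mask and feature mask, parameterized through sigmoids, are
optimized per subject by Adam (learning rate 0.5, 150 epochs, weight decay
0 — the reported hyperparameters) to minimise the weighted sum of five
components with weights (prediction 1, feature size 200, feature element
20, population size 0, population element 1000): the squared error of the
masked prediction against the model's own unmasked prediction, mean mask
values (size terms), and mean binary entropies (element terms, which vanish
as masks saturate at 0 or 1). Using the model's own prediction rather than
the label is the regression analogue of the usual cross-entropy objective
and keeps the explanation faithful to the model.

Mask injection points (not specified in the source): the edge mask
multiplies the attention softmax numerators before renormalisation, and the
feature mask multiplies node-feature columns; self-loops are never masked.
Mask logits are initialised near zero (masks near 0.5, the entropy saddle),
so the prediction term decides which edges escape toward 1.

"Common connections" across subjects: each subject's top fraction of edges
by mask value is marked; edges are ranked by the share of subjects marking
them (ties: mean mask weight, then lexicographic) and truncated to the same
fraction. Network tabulation counts intra- (diagonal) and inter-network
(off-diagonal, symmetric) connections against the atlas; the upper triangle
plus diagonal sums to the table's row count. Developmental-stage analyses
are per-age-group reruns of the same procedure with caller-supplied bins,
since the stage boundaries are not printed in the source text.

## Synthetic cohorts

The generator emulates the cohort conditions the method targets: two tasks,
ages uniform on 8–22 years, 124 time points, and by default 622 subjects on
a 264-node parcellation. A non-negative block basis W_true (contiguous
ROI blocks per factor, 10% overlap) plants latent networks; per subject s
and task, the T × N time series is S = Z Λ_sᵀ + E with Z standard-normal
latent signals, Λ_s = W_true · diag(scales_s) and Gaussian noise (sd 1.0 by
default). A subset of factors has scales 1 + effect_size · (age_s −
midpoint)/(half-range), clipped at 0 — a common-cause mechanism, so the
connectivity is genuinely correlation-valued and the full pipeline
(correlation → positive thresholding → factorization → attention) is
exercised rather than having the signal pasted into the matrices. The
planted informative edge set (pairs co-loading on age-modulated factors) and
a block-aligned synthetic atlas give ground truth for recovery and
tabulation checks.

What the generator does **not** emulate: hemodynamics, head motion,
physiological noise, scanner drift, or realistic network topology beyond
block structure. Passing tests therefore demonstrate that the
implementation is correct and that the method can extract a planted
age-dependent signal end to end — not that it attains any particular
accuracy on real cohort data, which is access-restricted.

## Evaluation protocol

80/10/10 train/validation/test splits stratified over equal-width age bins
(5 by default, mirroring the five adolescent stages; configurable), with
largest-remainder allocation so every bin's shares are within one subject of
the ratios. Metrics are RMSE, MAE and Pearson r, aggregated as mean ± sd
over repeated seeded experiments; a 10-fold CV protocol is available because
the source describes both, and the choice is explicit at the CLI. Pairwise
model comparison reports the paired t-test and a bootstrap p-value side by
side; the bootstrap resamples paired differences to build the empirical
distribution of the paired t statistic (studentized bootstrap, add-one
smoothed), which is well calibrated at 10 repeats (~3–5% rejections at the
5% level under a true null).

Baselines: mean predictor; linear regression and an MLP on z-scored,
top-10%-edge features; the attention model on raw connectivity rows
(no-factorization arm); and the same stack with uniform neighbor weights
(attention-free arm).

## Problem sizes used in shipped checks

The acceptance script and heavy tests run the full pipeline at 200 subjects,
50 ROIs, two tasks, planted rank 5, effect size 1, three training seeds,
with 300 Adam epochs at learning rate 3e-3, weight decay 1e-4, hidden width
8 and head width 64 — a desk-scale configuration chosen so each training
run converges in about a minute on one CPU while preserving every
structural property of the full-size setting. Factorization recovery is
checked at N = 30, rank 3, 20,000 multiplicative updates. These sizes are
the package's own verification choices; full-size defaults remain as
documented above.

## Known limitations

- Static connectivity only; no dynamic or time-varying graphs.
- The factorization and the network are optimized in two stages; fully
  joint optimization would require projected-gradient handling of the
  non-negativity constraints.
- NMF is not identifiability-guaranteed: planted-basis recovery is checked
  via permutation-matched correlation after Hungarian assignment, and can
  fail for small, dense, low-rank instances where the non-negative cone
  admits rotations.
- The explainer's population-size weight is 0 in the reported
  hyperparameters, so background edges binarize by initialisation rather
  than being driven to zero; rankings across subjects (frequency of
  top-fraction membership) remain informative, and a positive size weight
  is available via config.
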