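# Methods

## Problem and model

The package predicts the synergy score of a drug pair in a cancer cell line.
The input is a triplet (drug A, drug B, cell line); the output is a scalar
ŷ trained by mean squared error against observed scores (Loewe-style or
ComboScore-style units — the model is agnostic to the metric).

The architecture has four stages.

**Featurization.** Drugs enter as token-level embedding matrices
(N_d × D_in) produced by any pretrained molecular encoder, or — for the
ablated variants — as per-character one-hot SMILES matrices.  Cell lines
enter as an enriched gene matrix G whose row i is g_i = E_i · P_i: the
gene's scalar expression value times its protein-sequence embedding
(L × D_P).  The ablated cell path uses raw expression as an L × 1 matrix,
which is exactly the D_P = 1 degenerate enrichment, so downstream shapes
are uniform.

**CCF encoder (DPC–KNN).**  For each cell line, the L gene rows are
compressed to |C| cluster rows.  Local density of gene i is
ρ_i = exp(−(1/k)·Σ_{j∈KNN(i)} ‖g_i − g_j‖²) with the self excluded from the
k nearest neighbours (including it adds a constant zero and is degenerate).
The separation δ_i is the plain Euclidean distance to the nearest strictly
denser gene, or the maximum distance to any gene when no gene is denser —
density is computed with squared distances, separation with plain
distances, deliberately.  The |C| genes with the largest ρ·δ scores become
cluster centers (ties to the lower index).  Every gene then joins the
cluster whose centroid is closest: assignment is seeded at the nearest
center and refined Lloyd-style against the evolving cluster means until
stable, with each center anchored to its own cluster so no cluster can
empty.  Clusters are summarized by their mean enriched row (a center-row
mode exists behind `representative="center"`).  Clustering depends only on
the cell line, so results are cached per cell-line id.

Defaults: k = 8 neighbours, |C| = 32 clusters (the desk-scale test
configuration uses k = 4, |C| = 8).  Downstream behaviour is insensitive to
|C| over a broad range because the projector and fusion layers operate
row-wise on whatever sequence length they receive.

**Projectors.**  Drug tokens pass token-wise through three
[linear → layer-norm → GELU] stages into the shared width D; one parameter
set serves both drugs, so the two branches are a single function applied
twice.  The compressed cell rows pass through the same motif.  Layer norm
uses ε = 1e-5 with learned affine initialized to (1, 0); GELU is the exact
Gaussian-CDF form x·Φ(x).

**Bridge fusion.**  Global max-, mean- and attention-poolings (a learned
per-token scalar score, softmaxed) of each of the three projected sequences
are concatenated (9 vectors) and linearly mapped to N_b data-dependent
bridge tokens of width D.  Each fusion layer applies four Bridge Attention
Units in parallel: H' = MHCA(LN(H_m), LN([H_n; H_m])) + H_m followed by
FFN(LN(H')) + H', where the keys/values concatenate the context with the
query sequence.  The drug and cell sequences attend to the bridge tokens;
the bridge tokens attend to [H_c, H_d2, H_d1].  All four updates read
layer-i inputs only (parallel semantics).  Because cross-modal exchange is
mediated by the N_b tokens, per-layer attention cost is linear in
N_b·(N_d1 + N_d2 + N_c) plus small self terms, and the package instruments
the exact score-entry count to verify it.  Defaults: N_b = 8 bridge tokens,
L_f = 3 layers, 8 heads, FFN ratio 4, dropout 0.2; an ablation flag
provides constant learned tokens instead of data-dependent ones, and a
plain pre-norm transformer over the concatenated sequence replaces the
mechanism entirely for the fusion ablation.

**Prediction head.**  The fused sequences are mean-pooled; the three entity
vectors concatenate to g_entity ∈ R^{3D} and the bridge tokens pool to
g_bridge ∈ R^D.  Each passes through a Global Representation Refiner: a
stack of residual blocks x₁ = x + Mix(LN(x)),
out = x₁ + DropPath(γ ⊙ SwiGLU(LN(x₁))), with channel mixing implemented
as a single linear layer, SwiGLU inner width 4D, LayerScale γ initialized
to 1e-4 and DropPath rate 0.1 (identity at evaluation).  Since g_entity is
3D wide while g_bridge is D wide, the entity branch starts with a 3D → D
linear projection so the two branch outputs can be summed before the
linear scalar head.  Under plain-transformer fusion there are no bridge
tokens; the bridge branch contributes a zero vector so the head stays
well-typed.

## Training and evaluation

AdamW is the default optimizer (a pluggable registry accepts others);
learning rate 1e-4, batch 256, dropout 0.2 and early-stopping patience 25
are the full-scale defaults.  The desk-scale experiments in the tests use
D = 64, N_b = 4, L_f = 2, |C| = 8 with learning rate 1.5e-3, batch 128 and
at most 25 epochs — sizes chosen so a complete study (three seeds, full and
ablated variants) runs on a single CPU.  Early stopping monitors validation
MSE and restores the best-epoch parameters.

Synergy is symmetric in the two drugs, but tables commonly list each pair
in one canonical order, so a model trained on the raw rows never sees the
swapped order and can drift from symmetry.  The training loop therefore
randomly swaps the drug order of half of each mini-batch
(`TrainConfig.swap_augment`, on by default, seeded); this costs nothing,
leaves accuracy unchanged, and raises the order-sensitivity correlation of
the trained model substantially.

Splits: a 10% triplet-level hold-out is drawn first and never enters any
fold.  The remainder is partitioned five ways at the protocol's grouping
level — triplets (random), whole cell lines (leave-cell-out) or unordered
drug pairs (leave-combination-out); (A,B) and (B,A) always share a fold.
Validation sets are carved out of each training fold at that same grouping
level, a choice the protocols leave open.  Metrics are RMSE,
R² = 1 − SS_res/SS_tot and the Pearson correlation; undefined values
(constant vectors, groups with fewer than two members) are reported as
explicit missing values, never as zero.  Per-cell-line PCCs can be
aggregated by tissue (mean and SD within tissue).

## Attribution

Perturbation contributions replace one drug's token matrix by a null
baseline — all zeros, or the token-averaged mean drug broadcast to all
rows — and report ΔS = S(full) − S(perturbed) for each drug.  Integrated
gradients attribute S along a straight path from the baseline pair to the
input pair (cell features fixed), using a midpoint Riemann sum (default 64
steps; a right-endpoint rule is available).  Per-drug aggregates sum the
token-level attributions over tokens and channels; with the joint path the
aggregates satisfy the completeness identity against S(x) − S(baseline)
as steps grow.  A practical note: the zero baseline sits at the layer-norm
singularity (the derivative of LN near a constant token scales like
1/√ε), so completeness converges slowly from zero; the mean baseline is
recommended when the completeness diagnostic matters.  Order sensitivity
predicts every triplet in both drug orders and reports the Pearson
correlation between the two sets.

## Synthetic benchmark

The generator emulates all four external inputs with a known ground truth.
Each drug carries a latent effect vector u_d (one entry per gene module)
embedded in the leading coordinates of its token rows plus feature noise;
each cell line has a positive module-activity vector v_c; gene protein
embeddings sit around module centroids that are pairwise equidistant
(orthogonal directions, norm-capped within-module offsets so a stated
separation bounds overlap); expression is the module activity plus noise.
Labels follow

    y = a·(f(u_a) + f(u_b)) + b·⟨u_a ⊙ u_b, v_c⟩ + ε,   f(u) = Σ tanh(u)

with a = 1, b the interaction strength (default 1), and ε Gaussian.  The
bilinear drug×drug×cell term was chosen because the architecture can
express it while purely additive baselines cannot, making the ablation
ordering checkable in spirit.  The signal-to-noise ratio is specified as an
amplitude ratio, SNR = sd(signal)/sd(ε), default 4 (so the Bayes-optimal
held-out R² is about SNR²/(1+SNR²) ≈ 0.94).  All randomness descends from
one root seed through spawned generator streams, so regeneration is
bitwise reproducible.  Defaults: 30 drugs, 10 cell lines, 120 genes in 6
modules, 8 tokens per drug, 2000 triplets.

What the generator does not emulate: real synergy-score distributions
(heavy tails, batch effects), dose–response structure, correlated gene
modules, or chemically meaningful SMILES (variant strings are random over
a small alphabet, so the one-hot ablation mainly encodes drug identity).
Passing tests therefore demonstrate that the implementation is faithful
and that the architecture can recover a recoverable signal — not that it
will match benchmark performance on laboratory data.

## Numerical core

The model runs on a compact float64 reverse-mode automatic-differentiation
engine over numpy arrays written for this package (tape-based, cycle-free
graphs, gradients available for inputs as integrated gradients requires).
Evaluation mode is bitwise deterministic; fixed-seed simulate→train→eval
runs reproduce loss curves and predictions exactly.  Linear layers flatten
leading axes into a single BLAS call; attention is batched per head.

## Design choices on open points

- The one-hot SMILES tokenizer is per-character, with an optional flag for
  the two-character elements Cl/Br; sequences are padded/truncated to a
  configurable maximum (128 by default; 12 in the desk-scale ablation runs
  to keep the plain-transformer baseline affordable).
- Exact density ties in DPC fall to the otherwise-branch only when no gene
  is strictly denser, the standard density-peaks convention.
- The bridge update in the layer recurrence targets the bridge tokens (the
  recurrence's last line is read as updating B).
- Drug projectors operate on token sequences, not pooled vectors (a pooled
  mode is not provided; the complexity accounting presumes token counts).
- The width mismatch in the head (3D entity vs D bridge) is resolved by an
  initial linear projection in the entity branch.

## Known limitations

- No GPU path; the engine targets desk-scale studies and correctness, not
  throughput at the benchmark datasets' scale.
- The Muon optimizer named in the original hyperparameter table is not
  implemented (its algorithm is unpublished in the source); AdamW is the
  default and the optimizer registry accepts alternatives.
- DBSCAN as a comparator needs tuned eps/min_samples; an all-noise result
  raises with guidance rather than guessing parameters.
- Cluster-count sensitivity is exercised indirectly (monotone within-cluster
  sum of squares; row-wise downstream operators); a full sweep of |C| with
  retraining at each value is left to the user.
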