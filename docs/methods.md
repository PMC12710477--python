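# Methods

## Problem setting

Drug synergy — the departure of a drug pair's joint effect from additive
expectation in a given cell line — is measured on a continuous, here
standardized, scale. Cell lines with few labeled pairs are treated as
few-shot regression tasks: from K labeled (drug A, drug B, score) samples
in a new line, predict scores for its remaining pairs. The model transfers
structure shared across cell lines through a meta-learned initialization
and captures the cell-specific residual through task adaptation.

## Architecture

**Drug encoder.** Heavy-atom molecular graphs with a 78-dimensional node
encoding: element one-hot over 43 common elements + reserved "other" (44),
heavy-neighbor count 0–10 (11), implicit valence 0–10 (11), total bonded
hydrogens 0–10 (11), one aromaticity bit. Counts above 10 clamp to the top
slot. "Hydrogen count" is read as total bonded hydrogens, not donor/
acceptor counts. Bonds carry connectivity only (edge weight 1); bond
orders are not used. Three graph-convolution layers aggregate with the
symmetric normalization e_vu/√(D̂_v·D̂_u), D̂_u = 1 + Σ_v e_vu, the self
term added inside the layer (graphs store no self-loops), followed by
ReLU; the readout is a coordinate-wise max over atoms. Node relabeling
leaves the embedding invariant up to float summation order (≈1e−12
relative; exact in exact arithmetic).

**Cell-line encoder.** Each line's 900 marker-gene values are arranged
30×30 in the order of the user-supplied (or generated) marker list — no
biological ordering is imposed, for reproducibility. Two conv layers
(3×3 valid, 16/32 channels by default) apply conv → batch norm → ReLU →
2×2 max pool, then flatten. Batch norm uses the current activations'
spatial statistics in training-mode forwards (pretraining and
meta-training, where running buffers are also updated) and frozen running
statistics during inner-loop adaptation, fine-tuning and evaluation, so
adaptation can never silently alter θ_E state. Profiles missing listed
genes are zero-filled after per-gene standardization; extra genes are
dropped.

**Integration and head.** A shared two-layer transform f_d =
FC2(ReLU(Dropout(FC1(·)))) maps each drug embedding (the printed operator
order, dropout before ReLU, is kept even though the conventional order is
reversed); sharing f_d across both drugs makes the pair treatment
symmetric. A single linear f_c maps the cell embedding. Their
concatenation z feeds the two-layer head ŷ = ReLU(zW₁+b₁)W₂+b₂. The
parameter partition θ_E (everything up to z) vs. θ_p (the head) is
explicit in parameter names and asserted.

Default widths (GCN 78→156→312→624, f_d→128, f_c→128, head hidden 256)
follow common graph-DTA-scale practice; a smaller `desk_config` (GCN
32/32/64, 4/8 channels, 24-dim transforms) is used for the CPU-scale
experiments. No test depends on the defaults.

## Training strategy

**Pretraining** minimizes ½Σ(ŷ−y)² (half-sum, as distinct from the mean
MSE used at task level) over all base-line samples; Adam, batch 128, 1e−3
by default.

**Cross-tier meta-optimization.** Per episode, N cell lines are sampled
without replacement, and per line K support + Q query samples with
pair-disjoint support/query. The inner tier takes one gradient step (step
count configurable) on the support MSE, updating the head only:
θ'_j = (θ_E, θ_p − α∇L_s). The outer tier updates all parameters by plain
gradient descent on Σ_j L_query(f_{θ'_j}), differentiating *through* the
inner step (exact second-order; a first-order flag exists). Defaults
α = 0.01, β = 0.001; never load-bearing in tests. The outer update is
plain gradient descent by default, matching the update rule as written; an
adaptive (Adam) outer optimizer is available and is what the benchmark
experiments use, because at desk scale plain SGD leaves the episodic query
loss essentially flat within a few hundred episodes while Adam converges
(0.34 → 0.10 on the default world). Dropout and
training-mode batch norm apply to the embedding pass of meta-training;
inner adaptation itself uses eval-mode embeddings (dropout noise inside a
task's gradient step would make the adapted head depend on a single mask
draw). The "50 K-shot tasks per episode" convention is read as N = 50
tasks from 50 distinct lines; desk-scale runs use N = 5.

**Fine-tuning / zero-shot.** Fine-tuning applies the same selective inner
step to a new line's support set and predicts its queries; the shared
state is never mutated (asserted by hashing in the harness). Zero-shot
mode disables the inner loop in training and at test; prediction is a pure
forward pass.

**Ablations.** `no_ml`: supervised training only (twice the pretraining
epoch budget, approximating training to convergence), fine-tuning still
applied at test; `no_ft`: no test-time adaptation; `no_so`: the inner tier
updates θ_E and θ_p; `no_pt`: meta-optimization from random init.

**Randomness.** Every stage draws from named substreams of one root seed
(episode sampling, batching, dropout, initialization); identical seeds
give bit-identical parameters.

## Autodiff core

No GPU deep-learning framework is assumed; the networks run on a compact
numpy reverse-mode engine whose vector-Jacobian products are built from
the same differentiable ops, so gradients can be differentiated again —
the second-order outer update is exact rather than approximated. ReLU and
max use detached subgradient masks (ties split equally), the standard
convention for piecewise-linear ops; convolution is im2col/col2im, a
mutually adjoint linear pair. First- and second-order gradients are
validated against central finite differences in the test suite.

## Synthetic benchmark

The generator emulates a synergy screen's *structure*, not its
pharmacology. Drugs are valid molecules built from ring/chain scaffolds ×
substituents (RDKit-validated, canonicalized, deduplicated). Cell-line
latent factors t_c = √ρ·u0 + √(1−ρ)·v_c (unit vectors, v_c ⊥ u0) have
pairwise correlation ρ = `cellline_similarity`; 900 gene values are a
fixed linear readout plus noise. Synergy is

    y = w·g_shared(φ_A, φ_B) + (1−w)·g_cell(φ_A, φ_B; t_c) + ε,

with φ random projections of graph-level summaries of the same atom
features the encoder sees (so the GCN path carries real signal), g_*
smooth symmetric tanh forms (functions of φ_A+φ_B and φ_A⊙φ_B), both
components standardized over the world, w = `shared_weight`, and
ε ~ N(0, noise_sd²). When `dispersion_range` is set, each line's noiseless
signal is rescaled to evenly spaced target SDs across the range; scores
are then globally standardized (per-line SDs shift by a few percent).
Per-line dispersion targeting is mutually exclusive with exact cross-line
score identity at w = 1, so `dispersion_range=None` disables it; the
default world keeps (0.5, 1.5).

Default study conditions: 40 drugs, 15 cell lines, 120 samples/line,
shared_weight 0.8, noise_sd 0.1 — a regime with strong transferable
structure and a real cell-specific component, which is what the
meta-learning benefit claim is about. What passing tests on this world do
*not* show: robustness to real expression covariance structure, assay
batch effects, heavy-tailed score noise, or chemically diverse
pharmacology (no dose–response or Loewe/Bliss surfaces are modeled).

## Evaluation protocols

Metrics: MSE, Spearman correlation (average-rank ties), R², and — after
thresholding true scores at a configurable value (default 0 on the
standardized scale; no claim of fidelity to any particular screen's
threshold) — ROC AUC and average-precision AUPR; single-class repeats are
NaN-flagged. Metrics are pooled per repeat, then mean ± SD across repeats.

The random split of 106 lines at 0.8 yields 85/21. The low-similarity
split clusters lines by average-linkage on (1 − Pearson correlation) of
expression vectors and moves whole clusters (least-similar-to-outside
first) to the test side until it holds n_test lines; its achieved
train–test similarity range sits below the random split's.

The per-line analysis samples tasks per meta-test line and correlates
per-line mean MSE with per-line score dispersion (range by default, SD
optionally). On dispersion-spread worlds this correlation is strongly
positive: lines with wider score ranges are intrinsically harder.

## Desk-scale problem sizes

Experiments run on one CPU core: pretraining 15–30 epochs, 150–300
episodes of N = 5 tasks (K = Q = 10), evaluation over 10–20 repeats of 10
tasks; the ablation comparison trains all five variants under identical
seeds and episode counts and evaluates on identical task draws. These
sizes are where the qualitative properties stabilize; all are config
fields.

## Known limitations

- Single-instance batch norm: training-mode statistics are per-grid
  spatial statistics, so train/eval BN behavior differs more than it would
  with large batches.
- The inner tier defaults to one gradient step; multi-step adaptation is
  supported but the fast shared-embedding path still applies only to
  head-only adaptation.
- The ablation ordering (full model best) is a statistical tendency of
  the training strategy, not a theorem; at very small episode counts the
  supervised variant can be competitive before meta-optimization has
  converged, and the selective-vs-full adaptation comparison (`no_so`) is
  seed-dependent at desk scale — one mild full-network adaptation step on
  a small network does not reliably overfit, so the advantage of
  restricting adaptation to the head only emerges at larger model and
  data scales than this benchmark exercises.
- Expression input assumes exactly the 900-gene marker list; no
  feature selection is performed.
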