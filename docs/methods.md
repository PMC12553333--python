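# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind protbench, in the spirit of a model-description
appendix. Nothing here states an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task model

Every dataset is described by a `TaskSpec` (arity × level × objective),
which fully determines featurization, head width, loss and metric set:

| task shape | head output | loss | headline metrics |
|---|---|---|---|
| single regression | `(B,)` | MSE | MSE, MAE, Spearman ρ, R² |
| single binary / multiclass | `(B, C)` logits | softmax + CE | ROC-AUC, PR-AUC, macro F1 / accuracy, macro F1 |
| pair regression | `(B,)` | MSE | R², MAE |
| pair binary | `(B,)` logit | sigmoid + BCE | ROC-AUC, PR-AUC, macro F1 |
| residue classification | `(B, L, C)` logits | per-token CE / true length T | pooled AUCs and macro F1 |

The single-vs-pair binary asymmetry (softmax+CE vs sigmoid+BCE) is kept
deliberately: it mirrors the training formulation this harness implements,
and the two are not interchangeable when class priors drift.

Residue-level tasks are single-arity by construction; residue-level
metrics pool all real (non-pad) positions across sequences before
computing ("micro" pooling). Per-sequence averaging is the main
alternative; pooling is the determinate choice when sequence lengths vary
widely and is what the residue kernels here implement.

## Architectures

**Sequence-based** (float32): input is one-hot over the 21-symbol residue
vocabulary (pad excluded), truncated to 300 residues from the N-terminus.

* **CNN** — three same-padding convolution stages with 32/64/96 filters
  and kernel sizes 4/8/12, ReLU, activations re-masked after every stage
  so padding never leaks; masked max-pool over positions; one-hidden-layer
  MLP head (hidden 256). The fourth "layer" of the stack is that head.
* **CNN-GRU** — the same three convolution stages followed by a two-layer
  bidirectional GRU (hidden 64 per direction), masked-mean pooled.
* **Transformer** — token + learned positional embeddings (dim 64), two
  encoder blocks with 4 attention heads, ReLU after self-attention,
  post-LayerNorm after the MLP sub-block. The feed-forward inner width is
  4× the embedding dim and sequence pooling is a masked mean — both are
  this package's choices where the configuration table is silent.

**Structure-based** (float64 — these models are small and exact
permutation invariance of the readout is part of their contract): the
sequence is condensed into the linear peptide's heavy-atom graph via
residue templates (RDKit), one water removed per peptide bond. Atom
features are one-hot element over {C, N, O, S} ⊕ degree/4; bond features
are one-hot over {single, double, aromatic}. Hydrogens are implicit; no
3D coordinates anywhere.

* **GCN** — 3 layers of symmetric-normalized propagation with self-loops.
* **GAT** — 3 layers, attention over N(i) ∪ {i}; 4 heads of width 16
  (the source table lists no head count for GAT; multi-headed is the
  canonical form). Edge features are not used by GCN/GAT.
* **MPNN** — 6 layers; messages condition on bond features,
  `m_v = Σ_u M(h_u, e_vu)`, with a learned linear update `U` (a linear
  update in place of a GRU cell keeps the layer shallow; documented
  simplification).
* **NeuralFP** — a GCN-derived fingerprint (per-layer softmax
  contributions summed over atoms) whose parameters are frozen after the
  seeded initial pass, followed by a trainable 3-layer MLP with BatchNorm.
  No unlabeled pretraining corpus is in scope, so the "initial pass" is
  the seeded initialization.
* **AttentiveFP** — 3 edge-aware attention layers with a gated attentive
  readout.
* **PAGTN** — 5 layers, LeakyReLU; attention over node pairs within 3
  hops, pair features = bond features summed along one shortest path.
* **Graphormer** — 1 dense attention layer, 8 heads, with degree
  (centrality) embeddings (capped at 4), a learned shortest-path spatial
  bias capped at distance 5, and a bond-feature edge bias for adjacent
  pairs; max-pool readout.

Readouts: weighted-sum + max (gated), sum + max, gated attentive pooling,
and max — all permutation-invariant by construction.

**Fixed-embedding head**: an upstream provider maps a sequence to a fixed
vector; only an MLP head trains, and the provider never receives
gradients. The default provider is the exact 1..2-mer composition (420
coordinates, collision-free); a hashed variant and a lookup-table wrapper
for externally computed embeddings exist. These are deterministic
synthetic stand-ins for frozen protein-language-model embeddings, not
trained models. For pair tasks the head consumes
`[u, v, |u − v|, u ⊙ v]`: shared-signal labels of the min/AND family are
linear in `|u − v|` and `u + v`, and validation showed a plain
concatenation leaves a small head unable to recover them (validation R²
plateaued near 0.55 on the shared-k-mer task, vs ≈ 0.99 for the same head
on the two exact count features). All other architectures keep the plain
concatenation `X_i ‖ X_j` of the pair formulation.

## Training

Adam (β = 0.9/0.999, ε = 1e-8) with batch size 32; default learning rate
1e-4 for sequence-based models and 1e-5 for structure-based models (the
graph models diverge at 1e-4); up to 100 epochs; dropout 0.1. Mini-batches
are seeded and length-bucketed: records are shuffled, grouped into buckets
of eight batches, sorted by length within a bucket, and the batch order is
reshuffled — composition stays randomized while padded length (and hence
attention/convolution cost) drops. Everything is bit-deterministic given
(data, config, seed).

By default training runs to `max_epochs` and returns the final-epoch
model, with per-epoch validation metrics recorded so best-epoch selection
is a post-hoc decision. `TrainConfig.early_stop_patience` enables
validation-based early stopping with best-epoch weight restore, watching
the task's headline metric.

Weight initialization is uniform fan-in, `U(±1/√fan_in)`, seeded.
Pad positions are excluded from the residue-loss denominator (the loss
normalizes by the true length `T`). The BCE is computed from logits in
the stable `max(z,0) − z·y + log(1+e^{−|z|})` form.

## Evaluation and comparison

ROC-AUC is the Mann–Whitney pair statistic computed from average ranks
(exact under ties, invariant under monotone score transforms). PR-AUC is
step-wise average precision; trapezoidal interpolation is biased for PR
curves and is only available behind an explicit flag. Macro F1 averages
one-vs-rest F1 over all declared classes, counting absent classes as 0.
Precision/recall use the zero-denominator convention "0 with a flag".
Spearman ρ of a constant prediction vector is reported as 0 (no ranking
information); a constant *truth* vector raises instead.

Methods are compared on replicate seeds (default 3) with a two-sided
two-sample Student's t-test (equal variances; Welch behind a flag).
The default significance level is 0.05, configurable to 0.01 — the two
conventional choices; both appear in the benchmark protocol this harness
mirrors, so the level is explicit in every `ComparisonResult`. Identical
zero-variance replicates short-circuit to t = 0, p = 1. No
multiple-testing correction is applied.

## Synthetic data: what it emulates, and what it does not

The generators produce the *statistical shape* of protein benchmark
tasks: short local motifs (binding sites, active positions) carried by
otherwise unstructured sequences, with labels derived from the planted
signal and corrupted by independent noise.

* single regression — label = Σ_m w_m · count(motif_m) + N(0, σ);
* single classification — class-specific motifs, balanced to ±1, labels
  flipped with probability f;
* pair regression — label = Σ_m w_m · min(count_a, count_b), a symmetric
  shared-k-mer score (study conditions use the 2-mers "WK"/"CH");
* pair classification — positives carry a complementary motif pair;
* residue — label 1 exactly at (disjointly) inserted motif positions,
  positionwise flips.

Defaults: lengths uniform on 50–200 (below the 300-residue truncation, so
truncation only enters dedicated tests), 0–3 insertions per motif,
classification flip probability 0.05 where noise is wanted. Records keep
the pre-noise truth (`clean_label`): with symmetric label flips at rate f
the best possible ROC-AUC against *observed* labels is exactly 1 − f, so
recovery of the planted signal is scored against the planted truth while
models train on the noisy observations — the standard planted-signal
recovery question, with a ceiling of 1 instead of a noise-set ceiling.

What passing these tests does **not** show: real proteins have
phylogenetic correlation, composition bias, long-range structural
couplings and label noise that is anything but independent — none of
which the generators emulate. Results here characterize optimization and
architecture behavior under known signal, not biological performance.

## Problem sizes used by the shipped checks

The acceptance checks train at desk scale, chosen so the full pipeline
(not a stub) runs on one CPU: binary planted-motif task n = 2000 with
motifs "WKWF"/"CHCP" and flip 0.05, CNN and transformer at their default
configurations for ≤ 20 epochs (patience 3) over three seeds;
residue-level CNN at n = 1000, lengths 50–100, noise-free "WKWFH" motifs,
lr 1e-3 (the small-dataset rate that converges equivalently for the
sequence models) for ≤ 15 epochs; fixed-embedding pair regression at
n = 2000, lr 1e-3, ≤ 200 epochs (patience 20). Metric kernels are checked
against brute-force oracles on 200 random instances of size ≤ 50
including tied scores.

## Known limitations

* The autodiff core is compact by design: no GPU, no fused kernels beyond
  conv1d/softmax, Python-loop recurrence for the GRU. Graph transformers
  run dense per-graph attention — fine for peptides, quadratic in atoms.
* NeuralFP's fingerprint is frozen at seeded initialization rather than
  after unsupervised pretraining.
* Graphormer's edge encoding only biases adjacent pairs; PAGTN uses one
  (arbitrary) shortest path per pair.
* The peptide graph is the linear chain: no disulfide bridges,
  stereochemistry, protonation states or post-translational modification.
* Ambiguous residues (B, Z, U, O) all map to one unknown token.
* The LLM prompt module renders strings only; nothing is sent anywhere.
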