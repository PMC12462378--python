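# Methods

## Problem setting

Protein–protein interaction site (PPIS) prediction is residue-level binary
classification: given one chain of a 3-D structure, label each residue as
interacting (1) or non-interacting (0) with a partner protein. Interacting
residues form contiguous surface segments, so a label string along the chain
contains characteristic local patterns: *edge structures* "01"/"10" (segment
boundaries) and *singular structures* "010"/"101" (isolated residues of one
class inside the other). Plain per-residue classifiers tend to fragment these
patterns; this package couples a residue-graph network with a structured
objective that penalizes pattern mismatch directly.

## Residue graph

A chain becomes an undirected graph G(X, E, A). Each residue is located at
its **side-chain centroid** (mean of side-chain heavy atoms; Cα for glycine
or side-chain-less residues), and two residues are adjacent iff their
centroid distance is **strictly below 14 Å**. Self-loops are included — the
rule `distance < cutoff` holds at distance 0, and positive degrees guarantee
D^{-1/2} exists. Ties at exactly 14.0 Å are excluded (configurable cutoff).

Node features X are 62-dimensional per residue, read from precomputed
tables: PSSM (20), HMM profile (20), DSSP secondary structure/accessibility
(14), mean atomic properties (5: mass, B-factor, side-chain membership,
charge, van der Waals radius), and centered centroid coordinates (3).
A 1024-d protein-language-model embedding may replace the handcrafted
blocks. Features are min–max scaled to [0, 1] per column *per protein*;
constant columns map to 0. Producing PSSM/HMM/DSSP/embedding inputs is out
of scope — only coordinate extraction and assembly happen here.

Edge features are [distance/14, min(|i−j|, 64)/64]: the spatial relation the
edges encode plus capped sequence separation for chain context. Both lie in
[0, 1], are symmetric in (i, j), and are [0, 0] on self-loops. The width is
configurable so richer recipes can be swapped in.

## Network

A shared linear projection (62 → d_hidden, default 128) followed by ReLU
gives the initial embedding H(0); each channel then keeps its own H(0).

**Subgraph channel.** Learnable top-k pooling scores residues by
s = H·w/‖w‖, keeps the top ⌈ρn⌉ (ρ default 0.5, ties to the lower index, at
least one node), gates kept rows by sigmoid(s) so w stays trainable, and
induces the subgraph adjacency (self-loops retained). On the pooled graph,
layers update as

    H(l+1) = σ( ((1−α) P′ H(l) + α H(0)) ((1−β_l) I + β_l W(l)) ),

with P′ = D^{-1/2} A′ D^{-1/2}, σ = ReLU, initial-residual weight α
(default 0.7), and identity-map weight β_l = ln(λ/l + 1) (λ default 1.5).
β_l decays with depth so deep stacks stay near identity maps — the standard
counter to over-smoothing in the GCNII family. An increasing variant
ln(λl + 1) is available behind `printed_beta_form`. Default depth: 2 layers.

**Attention channel (AGAT).** Each layer first aggregates with edge-aware
multi-head attention — logits LeakyReLU(aᵀ[W_h h_i ‖ W_h h_j ‖ W_e ε_ij]),
softmax over N(i) including self, 2 heads averaged (slope 0.2) — then
combines with the initial embedding:

    H(l+1) = σ( (1−β_l)((1−α) H_in + α H(0)) + β_l (H_in ‖ H(0)) W(l) ),

W(l) of shape [2d × d]. Default depth: 8 layers. Dropout (default 0.1) is
applied between layers and disabled in eval mode.

**Fusion and head.** The pooled-channel output is scattered back to all n
residues (zeros elsewhere) and fuses with the attention channel by scaled
dot-product attention, softmax(H_sub H_subᵀ/√d_sub)·H_AGAT. The fused and
attention embeddings are concatenated into a 3-layer MLP
(2d → d → d/2 → 2) with row-wise softmax. Per-residue calls threshold the
positive-class probability at 0.5.

Ablation switches: no fusion (plain concatenation of the scattered subgraph
and attention embeddings), attention-only, subgraph-only.

## Structured objective

For predicted positive-class probabilities p and true labels T (both length
n, sequence order), the loss is

    L_total = L_correctness + λ_sol (0.5 L_edge + 0.5 L_singular),

λ_sol default 0.2; λ_sol = 0 recovers plain cross-entropy training.
L_correctness is mean categorical cross-entropy with log clamped at 1e-12.
L_edge and L_singular each sum, over three 1-D kernels, the MSE between the
kernel's response on p and on T. Kernels are zero-sum (zero response on
constant signals): edge family {[−1,1], [−1,0,1], [−1,−1,0,1,1]/2} (widths
2/3/5, difference-of-step boundary detectors) and singular family
{[−1,2,−1], [−1,−1,4,−1,−1]/2, [−1,−1,−1,6,−1,−1,−1]/3} (widths 3/5/7,
discrete-Laplacian isolated-site detectors). Convolution is "same"
zero-padded cross-correlation along **sequence order** (even kernels
anchored left of center), applied to the continuous probability so the loss
stays differentiable; MSE averages over the n positions so the loss scale is
length-invariant; per-protein losses are averaged across a batch. Kernels
and weights are fully overridable through `SOLConfig`.

## Metrics

Seven pooled residue-level metrics (ACC, Precision, Recall, F1, MCC, AUROC,
AUPRC; AUROC/AUPRC via scikit-learn, NA with a warning on single-class
input; MCC and F1 use the 0-on-degenerate-marginal convention) plus pattern
accuracy for "01", "10", "010", "101": occurrences are exact overlapping
window matches in the *true* label string, hits require the predicted calls
to reproduce the window exactly, and dataset aggregation pools counts
(micro) before dividing; a macro variant averages per-protein accuracies.
A pattern with zero occurrences reports NA.

## Synthetic data

The generator produces desk-scale protein-like fixtures. Backbone: a
persistent self-avoiding random walk, 3.8 Å steps (Cα–Cα spacing), 3.0 Å
clash floor by rejection — at the 14 Å cutoff this yields ~10–30 neighbors
per residue, matching real contact counts. Labels: Poisson(segment_rate ·
L/100) segments placed uniformly without overlap; a segment has length 1
with probability singular_rate (supplying "010" patterns), else
1 + Geometric(1/segment_length_mean). Features: a fixed random direction μ
in feature space (one per dataset — a per-protein direction would make
cross-protein generalization impossible by construction), scaled by
snr · smoothed(T), where smoothed blends the residue's own label (1/2) with
one neighborhood-averaging pass over the cutoff graph (1/2) so the signal
is partly contextual without being washed out; unit Gaussian noise is added
and columns are min–max normalized. snr = 0 gives label-independent
features. Splits are 70/15/15 by protein, deterministic per seed.

What passing tests on this generator show: the architecture, loss and
metrics behave as specified and planted signal of known strength is
recovered. What they do not show: performance on real evolutionary-profile
features, real fold geometry, or real interface chemistry.

## Training

Adam (lr 1e-3, weight decay 1e-5), one protein per optimization step, early
stopping on validation MCC (patience 10), best-validation parameters
restored. These are exposed defaults, not tuned claims. Training aborts on
non-finite loss with the epoch/step location. Runs are reproducible per
seed; an optional positive-class weight in the cross-entropy is off by
default. The acceptance script uses 40 proteins of 60–120 residues (30
epochs) for signal/null runs and 18 boundary-rich proteins of 50–90
residues (15 epochs) for the paired structured-objective comparison — sizes
chosen so the whole pipeline runs on a laptop-class single core in minutes.

## Numerical choices and limitations

All arithmetic is float64 on a compact in-repo reverse-mode autograd engine
over numpy (gradients verified against central finite differences). Softmax
subtracts a detached per-row/segment max for stability. Top-k ties break to
the lower residue index; pooling keeps at least one node. The graph
container is a single .npz with a JSON header and refuses mismatched format
versions, as do checkpoints with mismatched configs.

Limitations: one chain at a time (no complex assembly, no mmCIF); features
are consumed precomputed; the pattern-accuracy definition (window match in
the true string, full-window hit) is one reasonable formalization among
several; CPU-scale training only.
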