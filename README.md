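# ppisite

Residue-level prediction of protein–protein interaction sites (PPIS) with a
dual-view graph network and a structured, pattern-aware training objective.

Interaction sites are the residues of a chain that contact a partner protein.
Along the sequence they form contiguous segments, so the binary label string
contains characteristic local patterns: boundary transitions `01`/`10` and
isolated sites `010`/`101`. Per-residue classifiers optimize each position
independently and tend to fragment exactly these patterns. `ppisite` targets
them directly, for structural bioinformaticians who want a trainable,
inspectable residue-graph model and an evaluation harness that scores
structural pattern reproduction as well as the usual residue metrics.

## Model

A chain becomes a graph G(X, E, A): nodes are residues at their side-chain
centroids, adjacency is `distance < 14 Å` (self-loops included), node
features are 62-d precomputed blocks (PSSM 20 | HMM 20 | DSSP 14 | atomic 5 |
centered centroid 3, min–max scaled per protein) or a 1024-d language-model
embedding, and each edge carries normalized distance and capped sequence
separation.

Two channels read a shared projected embedding H(0):

- **Subgraph channel** — learnable top-k pooling (score s = Hw/‖w‖, sigmoid
  gating), then propagation on the induced subgraph with initial residual
  and identity mapping:
  `H(l+1) = σ(((1−α) P′H(l) + α H(0)) ((1−β_l)I + β_l W(l)))`,
  P′ = D^{−1/2}A′D^{−1/2}, β_l = ln(λ/l + 1).
- **Attention channel (AGAT)** — edge-aware multi-head graph attention
  (logits `LeakyReLU(aᵀ[W_h h_i ‖ W_h h_j ‖ W_e ε_ij])`, softmax over
  neighbors), then
  `H(l+1) = σ((1−β_l)((1−α)H_in + α H(0)) + β_l (H_in ‖ H(0)) W(l))`.

The pooled output, scattered back to all residues, fuses with the attention
channel by scaled dot-product attention
`softmax(H_sub H_subᵀ/√d_sub) H_AGAT`; the concatenation feeds a 3-layer MLP
with softmax over {non-interacting, interacting}.

Training minimizes

    L_total = L_correctness + λ_sol (0.5 L_edge + 0.5 L_singular),

where L_correctness is cross-entropy and the structural terms compare
multi-scale zero-sum 1-D kernel responses (boundary and isolated-site
detectors) of the predicted probability signal against the true label
signal, by MSE along the sequence. λ_sol defaults to 0.2; λ_sol = 0 recovers
plain cross-entropy. See `docs/methods.md` for every definition and default.

The package includes a synthetic generator (backbone-like self-avoiding
walks, planted label segments with controllable boundary/singular supply,
label-correlated features at a chosen signal-to-noise ratio) so the whole
pipeline trains and evaluates at desk scale with no external data.

## Worked example

```python
from ppisite import SyntheticSpec, TrainConfig, generate_dataset, train, evaluate

spec = SyntheticSpec(n_proteins=12, length_range=(60, 90), snr=2.0,
                     segment_rate=6.0, singular_rate=0.3, seed=7)
train_set, val_set, test_set = generate_dataset(spec)
result = train(train_set, TrainConfig(epochs=12, seed=7), val_dataset=val_set)
report = evaluate(test_set, result.model)
print(f"held-out MCC   {report['MCC']:.3f}")
print(f"held-out F1    {report['F1']:.3f}")
print(f"held-out AUPRC {report['AUPRC']:.3f}")
for pat in ("01", "10", "010"):
    s = report["patterns"][pat]
    print(f"'{pat}' windows reproduced: {s['hits']}/{s['occurrences']}")
```

Output:

```
held-out MCC   0.914
held-out F1    0.929
held-out AUPRC 0.995
'01' windows reproduced: 5/7
'10' windows reproduced: 6/7
'010' windows reproduced: 3/4
```

Twelve synthetic proteins with a weak planted signal (snr 2) suffice to
recover held-out interaction sites almost perfectly (MCC 0.914), and most
true boundary (`01`/`10`) and isolated-site (`010`) windows are reproduced
exactly by the thresholded calls — the quantity the structured objective is
designed to protect.

The same pipeline is scriptable from the shell:

```bash
ppisite simulate --spec spec.yaml --out data/
ppisite train --config cfg.yaml --data data/ --out run/
ppisite predict --graph data/synth000.graph --checkpoint run/model.ckpt --out preds.tsv
ppisite evaluate --preds preds.tsv --labels labels.tsv --out report.json
ppisite build-graph --pdb 1abc.pdb --chain A --features feats.tsv --out 1abcA.graph
ppisite ablate --spec spec.yaml --out ablation/   # SOL / fusion / channel variants
```

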