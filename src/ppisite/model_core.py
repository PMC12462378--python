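"""Dual-view residue-graph network for interaction-site prediction.

Two channels read the same projected node embeddings:

* a **subgraph channel** — learnable top-k graph pooling followed by a stack
  of GCNII-style propagation layers on the induced subgraph,
  ``H(l+1) = sigma(((1-a) P' H(l) + a H(0)) ((1-b_l) I + b_l W(l)))``;
* an **attention channel (AGAT)** — edge-aware graph attention aggregation
  followed by a GCNII-style combine with the initial embedding,
  ``H(l+1) = sigma((1-b_l)((1-a) H_in + a H(0)) + b_l (H_in || H(0)) W(l))``.

The pooled-channel output is scattered back to all residues and fused with
the full-graph channel by scaled dot-product attention
(``softmax(H_sub H_sub^T / sqrt(d_sub)) H_AGAT``); the fused and full-graph
embeddings are concatenated and classified by a three-layer MLP with a
row-wise softmax over the two classes (interacting / non-interacting).

Propagation strength ``a`` (initial-residual weight) and the layer-wise
identity-map weight ``b_l = ln(lambda/l + 1)`` follow the GCNII lineage:
``b_l`` decays with depth so that deep stacks stay close to identity maps,
which is what counters over-smoothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autograd import (
    Tensor,
    concatenate,
    gather_rows,
    scatter_rows,
    segment_sum,
    softmax,
)
from .residue_graph import ResidueGraph

__all__ = [
    "ModelConfig",
    "PredictionResult",
    "SiteModel",
    "normalized_propagation",
    "beta_schedule",
    "graph_pool",
    "subgraph_conv_layer",
    "agat_attention_layer",
    "gcnii_layer",
    "att_fusion",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are exposed choices in the GCNII family, not tuned claims:
    ``alpha_prop`` is the initial-residual weight of both channel updates,
    ``lambda_decay`` sets the identity-map schedule b_l = ln(lambda/l + 1),
    ``pool_ratio`` the fraction of residues the subgraph channel keeps.
    ``printed_beta_form`` switches to the increasing schedule ln(lambda*l + 1).
    """

    d_hidden: int = 128
    n_layers_sub: int = 2
    n_layers_agat: int = 8
    alpha_prop: float = 0.7
    lambda_decay: float = 1.5
    pool_ratio: float = 0.5
    n_classes: int = 2
    dropout: float = 0.1
    seed: int = 0
    d_sub: int | None = None  # defaults to d_hidden
    n_heads: int = 2
    leaky_slope: float = 0.2
    printed_beta_form: bool = False

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0.0 < self.pool_ratio <= 1.0:
            raise ValueError("pool_ratio must be in (0, 1]")
        if self.d_hidden < 1 or self.n_classes < 1:
            raise ValueError("widths must be >= 1")
        if self.d_sub is None:
            self.d_sub = self.d_hidden


@dataclass
class PredictionResult:
    """Per-residue class probabilities and thresholded calls."""

    probs: np.ndarray  # [n, 2] row-stochastic
    calls: np.ndarray  # [n] 0/1
    threshold: float = 0.5

    @classmethod
    def from_probs(cls, probs: np.ndarray, threshold: float = 0.5):
        probs = np.asarray(probs, dtype=float)
        calls = (probs[:, 1] >= threshold).astype(int)
        return cls(probs=probs, calls=calls, threshold=threshold)


# ---------------------------------------------------------------------------
# Functional building blocks (pure, oracle-testable)


def normalized_propagation(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric normalization P = D^{-1/2} A D^{-1/2} of a self-looped
    adjacency.  Self-loops guarantee positive degrees."""
    adjacency = np.asarray(adjacency, dtype=float)
    degrees = adjacency.sum(axis=1)
    assert (degrees >= 1).all(), "zero-degree node: adjacency lacks self-loops"
    inv_sqrt = 1.0 / np.sqrt(degrees)
    return adjacency * inv_sqrt[:, None] * inv_sqrt[None, :]

def beta_schedule(
    layer: int, lambda_decay: float, printed_form: bool = False
) -> float:
    """Identity-map weight b_l for layer l >= 1.

    Default is the depth-decaying form ln(lambda/l + 1); ``printed_form``
    selects ln(lambda*l + 1) instead (increasing in l).
    """
    if layer < 1:
        raise ValueError("layer index must be >= 1")
    if lambda_decay < 0:
        raise ValueError("lambda_decay must be >= 0")
    if printed_form:
        return float(np.log(lambda_decay * layer + 1.0))
    return float(np.log(lambda_decay / layer + 1.0))


def graph_pool(H: Tensor, adjacency: np.ndarray, pool_ratio: float, w: Tensor):
    """Learnable-score top-k pooling with sigmoid gating.

    Scores s = H w / ||w||; the top ceil(rho*n) nodes (ties to the lower
    index, at least one node kept) are selected and their embeddings gated by
    sigmoid(s) so the score vector stays trainable.  Returns
    ``(selected_idx ascending, H_pooled, induced_adjacency)``.
    """
    n = H.shape[0]
    k = max(1, int(np.ceil(pool_ratio * n)))
    norm = (w * w).sum() ** 0.5
    scores = (H @ w.reshape(-1, 1)).reshape(-1) / norm
    order = np.argsort(-scores.data, kind="stable")  # stable: ties -> lower idx
    selected = np.sort(order[:k])
    gate = scores[selected].sigmoid().reshape(-1, 1)
    H_pooled = gather_rows(H, selected) * gate
    induced = np.asarray(adjacency, dtype=bool)[np.ix_(selected, selected)]
    return selected, H_pooled, induced


def subgraph_conv_layer(
    H: Tensor, H0: Tensor, P: np.ndarray, W: Tensor, alpha: float, beta: float
) -> Tensor:
    """One subgraph-channel propagation step (initial residual + identity map)."""
    if H.shape[1] != H0.shape[1]:
        raise ValueError("H and H(0) widths differ")
    support = Tensor(P) @ H * (1.0 - alpha) + H0 * alpha
    return (support * (1.0 - beta) + (support @ W) * beta).relu()


def agat_attention_layer(
    H: Tensor,
    edge_index: np.ndarray,
    edge_features: Tensor | np.ndarray,
    params: dict,
    n_heads: int,
    leaky_slope: float = 0.2,
    return_coefficients: bool = False,
):
    """Edge-aware multi-head graph attention aggregation.

    Per node i and neighbor j (self included), the attention logit is
    ``LeakyReLU(a^T [W_h h_i || W_h h_j || W_e e_ij])``; coefficients are
    softmax-normalized over N(i) and aggregate W_h h_j.  Head outputs are
    averaged.  ``params`` holds per-head ``Wh{k}, We{k}, a_dst{k}, a_src{k},
    a_edge{k}``.
    """
    E = np.asarray(edge_index)
    src, dst = E[0], E[1]
    n = H.shape[0]
    if isinstance(edge_features, np.ndarray):
        edge_features = Tensor(edge_features)
    if edge_features.shape[0] != src.shape[0]:
        raise ValueError("one edge feature row required per adjacent pair")
    head_outputs = []
    coeff_rows = None
    for k in range(n_heads):
        Whh = H @ params[f"Wh{k}"]
        # contract a_edge^T (We e) to (We a_edge)^T e: avoids an E x d intermediate
        edge_term = edge_features @ (params[f"We{k}"] @ params[f"a_edge{k}"].reshape(-1, 1))
        logits = (
            gather_rows(Whh @ params[f"a_dst{k}"].reshape(-1, 1), dst)
            + gather_rows(Whh @ params[f"a_src{k}"].reshape(-1, 1), src)
            + edge_term
        ).leaky_relu(leaky_slope)
        # stable segment softmax over each destination's neighborhood
        seg_max = np.full(n, -np.inf)
        np.maximum.at(seg_max, dst, logits.data[:, 0])
        shifted = logits - Tensor(seg_max[dst, None])
        num = shifted.exp()
        denom = segment_sum(num, dst, n)
        coeff = num / gather_rows(denom, dst)
        head_outputs.append(segment_sum(coeff * gather_rows(Whh, src), dst, n))
        if coeff_rows is None:
            coeff_rows = coeff
    out = head_outputs[0]
    for h in head_outputs[1:]:
        out = out + h
    out = out * (1.0 / n_heads)
    if return_coefficients:
        return out, coeff_rows
    return out


def gcnii_layer(
    H_in: Tensor, H0: Tensor, W: Tensor, alpha: float, beta: float
) -> Tensor:
    """GCNII-style combine of the aggregated embedding with the initial one."""
    d = H_in.shape[1]
    if W.shape != (2 * d, d):
        raise ValueError(f"W must have shape {(2 * d, d)}, got {W.shape}")
    residual = (H_in * (1.0 - alpha) + H0 * alpha) * (1.0 - beta)
    identity = (concatenate([H_in, H0], axis=1) @ W) * beta
    return (residual + identity).relu()


def att_fusion(H_sub_full: Tensor, H_agat: Tensor, d_sub: int | None = None) -> Tensor:
    """Scaled dot-product fusion: subgraph embeddings (scattered back to all
    residues) act as query and key, the full-graph channel as value."""
    if H_sub_full.shape[0] != H_agat.shape[0]:
        raise ValueError("row-count mismatch between channel outputs")
    if d_sub is None:
        d_sub = H_sub_full.shape[1]
    scores = (H_sub_full @ H_sub_full.T) * (1.0 / np.sqrt(d_sub))
    return softmax(scores, axis=1) @ H_agat


# ---------------------------------------------------------------------------
# Parameter initialization


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class SiteModel:
    """The full dual-view network with named parameters.

    Channel/fusion switches support the ablation variants: with
    ``use_att_fusion=False`` the fused block is replaced by the scattered
    subgraph embedding itself (plain concatenation baseline).
    """

    def __init__(
        self,
        config: ModelConfig,
        d_node: int,
        d_edge: int = 2,
        use_subgraph_channel: bool = True,
        use_agat_channel: bool = True,
        use_att_fusion: bool = True,
    ):
        if not (use_subgraph_channel or use_agat_channel):
            raise ValueError("at least one channel must be enabled")
        self.config = config
        self.d_node = d_node
        self.d_edge = d_edge
        self.use_subgraph_channel = use_subgraph_channel
        self.use_agat_channel = use_agat_channel
        self.use_att_fusion = use_att_fusion and use_subgraph_channel and use_agat_channel
        self.params: dict[str, Tensor] = {}
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        self._init_params(np.random.default_rng(config.seed))

    # -- construction ------------------------------------------------------
    def _add(self, name: str, array: np.ndarray) -> None:
        self.params[name] = Tensor(array, requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        d = cfg.d_hidden
        self._add("proj_W", _glorot(rng, self.d_node, d))
        self._add("proj_b", np.zeros(d))
        if self.use_subgraph_channel:
            self._add("pool_w", rng.standard_normal(d) / np.sqrt(d))
            for layer in range(cfg.n_layers_sub):
                self._add(f"sub_W{layer}", _glorot(rng, d, d))
        if self.use_agat_channel:
            for layer in range(cfg.n_layers_agat):
                for k in range(cfg.n_heads):
                    self._add(f"agat{layer}_Wh{k}", _glorot(rng, d, d))
                    self._add(f"agat{layer}_We{k}", _glorot(rng, self.d_edge, d))
                    self._add(f"agat{layer}_a_dst{k}", rng.standard_normal(d) / np.sqrt(d))
                    self._add(f"agat{layer}_a_src{k}", rng.standard_normal(d) / np.sqrt(d))
                    self._add(f"agat{layer}_a_edge{k}", rng.standard_normal(d) / np.sqrt(d))
                self._add(f"agat{layer}_W", _glorot(rng, 2 * d, d))
        d_head_in = d * (2 if (self.use_subgraph_channel and self.use_agat_channel) else 1)
        self._add("mlp_W0", _glorot(rng, d_head_in, d))
        self._add("mlp_b0", np.zeros(d))
        self._add("mlp_W1", _glorot(rng, d, d // 2))
        self._add("mlp_b1", np.zeros(d // 2))
        self._add("mlp_W2", _glorot(rng, d // 2, cfg.n_classes))
        self._add("mlp_b2", np.zeros(cfg.n_classes))

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def reseed_dropout(self, seed: int) -> None:
        self._dropout_rng = np.random.default_rng(seed)

    def _dropout(self, t: Tensor, train: bool) -> Tensor:
        rate = self.config.dropout
        if not train or rate == 0.0:
            return t
        mask = (self._dropout_rng.random(t.shape) >= rate) / (1.0 - rate)
        return t * Tensor(mask)

    # -- forward -----------------------------------------------------------
    def _beta(self, layer: int) -> float:
        return beta_schedule(
            layer + 1, self.config.lambda_decay, self.config.printed_beta_form
        )

    def forward_tensor(self, graph: ResidueGraph, train: bool = False) -> Tensor:
        """Full pipeline; returns the [n x 2] row-stochastic probability
        Tensor (differentiable w.r.t. all parameters)."""
        cfg = self.config
        X = Tensor(graph.node_features)
        H0 = (X @ self.params["proj_W"] + self.params["proj_b"]).relu()
        adjacency = graph.adjacency

        blocks = []
        H_agat = None
        if self.use_agat_channel:
            H = H0
            edge_feats = Tensor(graph.edge_features)
            for layer in range(cfg.n_layers_agat):
                attended = agat_attention_layer(
                    H,
                    graph.edge_index,
                    edge_feats,
                    {
                        key.split("_", 1)[1]: self.params[key]
                        for key in self.params
                        if key.startswith(f"agat{layer}_")
                    },
                    n_heads=cfg.n_heads,
                    leaky_slope=cfg.leaky_slope,
                )
                H = gcnii_layer(
                    attended,
                    H0,
                    self.params[f"agat{layer}_W"],
                    cfg.alpha_prop,
                    self._beta(layer),
                )
                H = self._dropout(H, train)
            H_agat = H

        if self.use_subgraph_channel:
            selected, H_pool, induced = graph_pool(
                H0, adjacency, cfg.pool_ratio, self.params["pool_w"]
            )
            P = normalized_propagation(induced)
            H0_sub = H_pool
            H = H0_sub
            for layer in range(cfg.n_layers_sub):
                H = subgraph_conv_layer(
                    H,
                    H0_sub,
                    P,
                    self.params[f"sub_W{layer}"],
                    cfg.alpha_prop,
                    self._beta(layer),
                )
                H = self._dropout(H, train)
            H_sub_full = scatter_rows(H, selected, graph.n_residues)
            if self.use_att_fusion:
                fused = att_fusion(H_sub_full, H_agat, cfg.d_sub)
                blocks = [fused, H_agat]
            elif self.use_agat_channel:
                blocks = [H_sub_full, H_agat]
            else:
                blocks = [H_sub_full]
        else:
            blocks = [H_agat]

        H_cat = blocks[0] if len(blocks) == 1 else concatenate(blocks, axis=1)
        h = (H_cat @ self.params["mlp_W0"] + self.params["mlp_b0"]).relu()
        h = self._dropout(h, train)
        h = (h @ self.params["mlp_W1"] + self.params["mlp_b1"]).relu()
        h = self._dropout(h, train)
        logits = h @ self.params["mlp_W2"] + self.params["mlp_b2"]
        return softmax(logits, axis=1)

    def predict(self, graph: ResidueGraph, threshold: float = 0.5) -> PredictionResult:
        probs = self.forward_tensor(graph, train=False).data
        return PredictionResult.from_probs(probs, threshold)


# ---------------------------------------------------------------------------
# Checkpointing

CHECKPOINT_VERSION = 1


def save_checkpoint(model: SiteModel, path) -> None:
    header = {
        "format_version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "d_node": model.d_node,
        "d_edge": model.d_edge,
        "use_subgraph_channel": model.use_subgraph_channel,
        "use_agat_channel": model.use_agat_channel,
        "use_att_fusion": model.use_att_fusion,
    }
    arrays = {name: p.data for name, p in model.params.items()}
    arrays["header"] = np.frombuffer(
        json.dumps(header).encode("utf-8"), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path, expected_config: ModelConfig | None = None) -> SiteModel:
    with np.load(path, allow_pickle=False) as data:
        arrays = {key: data[key] for key in data.files}
    if "header" not in arrays:
        raise ValueError("not a checkpoint file (missing header)")
    header = json.loads(arrays.pop("header").tobytes().decode("utf-8"))
    if header.get("format_version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {header.get('format_version')!r}")
    config = ModelConfig(**header["config"])
    if expected_config is not None and asdict(expected_config) != asdict(config):
        raise ValueError("checkpoint config does not match the expected config")
    model = SiteModel(
        config,
        d_node=header["d_node"],
        d_edge=header["d_edge"],
        use_subgraph_channel=header["use_subgraph_channel"],
        use_agat_channel=header["use_agat_channel"],
        use_att_fusion=header["use_att_fusion"],
    )
    if set(arrays) != set(model.params):
        raise ValueError("checkpoint parameters do not match the model layout")
    for name, value in arrays.items():
        if model.params[name].data.shape != value.shape:
            raise ValueError(f"checkpoint parameter {name} has mismatched shape")
        model.params[name].data = value.astype(np.float64)
    return model
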