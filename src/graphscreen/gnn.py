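"""Multimodal graph-attention classifier (GATv2 with static-GAT ablation).

Architecture, at defaults: three graph-attention layers with eight heads
each (per-head width 256, head outputs averaged so the hidden space stays
256-dimensional), batch normalization + ELU + dropout between layers;
dual-pooling readout g = [GAP || GMP] (512); a 50->64->32 ReLU descriptor
branch; fusion z = [g || d] (544) into a 544->512->1 feedforward head with
batch norm, ReLU, dropout and a sigmoid output.

Attention modes:

* ``gatv2`` (dynamic): score(i,j) = a^T LeakyReLU(W_t h_i + W_s h_j + W_e e_ij)
* ``gat`` (static):    score(i,j) = LeakyReLU(a^T [W_t h_i || W_s h_j || W_e e_ij])

followed by a softmax over each node's in-neighborhood. Two transform
matrices (W_s for messages/sources, W_t for targets) keep the dynamic mode
non-degenerate. Self-loops (zero bond features) are added to every node so
isolated atoms have a defined neighborhood. In the static mode the score is
a monotone function of (center-constant + neighbor term), so the attention
ranking over a shared neighbor set cannot depend on the center node — the
dynamic mode removes exactly that restriction.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np

from . import nn
from .featurize import (
    ATOM_FEATURE_DIM,
    BOND_FEATURE_DIM,
    DESCRIPTOR_DIM,
    DescriptorScaler,
    MolecularGraph,
)


@dataclass(frozen=True)
class ModelConfig:
    n_layers: int = 3
    hidden_dim: int = 256  # per-head output size
    n_heads: int = 8
    head_aggregation: str = "mean"  # mean | concat
    attention_mode: str = "gatv2"  # gatv2 | gat
    leaky_slope: float = 0.2
    dropout: float = 0.2
    use_edge_features: bool = True
    use_descriptors: bool = True
    use_batch_norm: bool = True
    pooling: str = "dual"  # dual | mean_only
    descriptor_dims: tuple = (DESCRIPTOR_DIM, 64, 32)
    head_hidden: int = 512
    atom_dim: int = ATOM_FEATURE_DIM
    bond_dim: int = BOND_FEATURE_DIM

    def __post_init__(self):
        if self.head_aggregation not in ("mean", "concat"):
            raise ValueError("head_aggregation must be 'mean' or 'concat'")
        if self.attention_mode not in ("gatv2", "gat"):
            raise ValueError("attention_mode must be 'gatv2' or 'gat'")
        if self.pooling not in ("dual", "mean_only"):
            raise ValueError("pooling must be 'dual' or 'mean_only'")

    @property
    def layer_out_dim(self) -> int:
        return (
            self.hidden_dim
            if self.head_aggregation == "mean"
            else self.hidden_dim * self.n_heads
        )

    @property
    def graph_embedding_dim(self) -> int:
        return self.layer_out_dim * (2 if self.pooling == "dual" else 1)

    @property
    def fused_dim(self) -> int:
        d = self.graph_embedding_dim
        if self.use_descriptors:
            d += self.descriptor_dims[-1]
        return d


# --------------------------------------------------------------------- modules


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


class Linear:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = nn.parameter(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)))
        self.b = nn.parameter(np.zeros(out_dim))

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[nn.Tensor]:
        return [self.W, self.b]


class BatchNorm1d:
    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = nn.parameter(np.ones(dim))
        self.beta = nn.parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: nn.Tensor, train: bool) -> nn.Tensor:
        if train:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered**2).mean(axis=0, keepdims=True)
            xhat = centered / (var + self.eps) ** 0.5
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta

    def parameters(self) -> list[nn.Tensor]:
        return [self.gamma, self.beta]


def attention_coefficients(
    h_center: np.ndarray,
    h_neighbors: np.ndarray,
    w_s: np.ndarray,
    w_t: np.ndarray,
    a: np.ndarray,
    mode: str = "gatv2",
    slope: float = 0.2,
    w_e: np.ndarray | None = None,
    e_feats: np.ndarray | None = None,
) -> np.ndarray:
    """Attention weights of one center node over its neighbors (pure NumPy).

    Returns alpha_{ij} for j in N(i): positive, summing to 1.
    """
    h_center = np.atleast_1d(np.asarray(h_center, dtype=float))
    h_neighbors = np.atleast_2d(np.asarray(h_neighbors, dtype=float))
    if h_neighbors.shape[0] == 0:
        raise ValueError("empty neighborhood: add self-loops first")
    w_s = np.atleast_2d(w_s)
    w_t = np.atleast_2d(w_t)
    a = np.atleast_1d(a)
    ht = h_center @ w_t  # (out,)
    hs = h_neighbors @ w_s  # (k, out)
    edge = 0.0
    if w_e is not None and e_feats is not None:
        edge = np.atleast_2d(e_feats) @ np.atleast_2d(w_e)

    def leaky(x):
        return np.where(x > 0, x, slope * x)

    if mode == "gatv2":
        scores = leaky(ht[None, :] + hs + edge) @ a
    elif mode == "gat":
        k = hs.shape[0]
        parts = [np.tile(ht, (k, 1)), hs]
        if w_e is not None and e_feats is not None:
            parts.append(np.broadcast_to(edge, hs.shape))
        scores = leaky(np.concatenate(parts, axis=1) @ a)
    else:
        raise ValueError(f"unknown attention mode {mode!r}")
    scores = scores - scores.max()
    e = np.exp(scores)
    return e / e.sum()


class GraphAttentionLayer:
    """One multi-head attention layer over a batched disjoint-union graph."""

    def __init__(self, in_dim: int, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.in_dim = in_dim
        out = config.hidden_dim
        self.heads: list[dict] = []
        for _ in range(config.n_heads):
            head = {
                "W_s": nn.parameter(_glorot(rng, in_dim, out, (in_dim, out))),
                "W_t": nn.parameter(_glorot(rng, in_dim, out, (in_dim, out))),
            }
            if config.use_edge_features:
                head["W_e"] = nn.parameter(
                    _glorot(rng, config.bond_dim, out, (config.bond_dim, out))
                )
            if config.attention_mode == "gatv2":
                a_dim = out
            else:
                a_dim = 2 * out + (out if config.use_edge_features else 0)
            head["a"] = nn.parameter(_glorot(rng, a_dim, 1, (a_dim, 1)))
            self.heads.append(head)

    def forward(
        self,
        x: nn.Tensor,
        src: np.ndarray,
        dst: np.ndarray,
        efeat: np.ndarray,
        n_nodes: int,
        train: bool,
        rng: np.random.Generator,
        return_attention: bool = False,
    ):
        cfg = self.config
        if np.bincount(dst, minlength=n_nodes).min() == 0:
            raise ValueError("node with empty neighborhood: self-loops missing")
        efeat_t = nn.Tensor(efeat)
        outputs = []
        attentions = []
        for head in self.heads:
            hs = x @ head["W_s"]
            ht = x @ head["W_t"]
            hs_e = nn.gather_rows(hs, src)
            ht_e = nn.gather_rows(ht, dst)
            edge_term = None
            if cfg.use_edge_features:
                edge_term = efeat_t @ head["W_e"]
            if cfg.attention_mode == "gatv2":
                pre = ht_e + hs_e
                if edge_term is not None:
                    pre = pre + edge_term
                score = pre.leaky_relu(cfg.leaky_slope) @ head["a"]
            else:
                parts = [ht_e, hs_e]
                if edge_term is not None:
                    parts.append(edge_term)
                score = (nn.concat(parts, axis=1) @ head["a"]).leaky_relu(
                    cfg.leaky_slope
                )
            # softmax over each node's in-neighborhood (detached max shift)
            m = np.full(n_nodes, -np.inf)
            np.maximum.at(m, dst, score.data.ravel())
            e = (score - m[dst][:, None]).exp()
            denom = nn.segment_sum(e, dst, n_nodes)
            alpha = e / nn.gather_rows(denom, dst)
            msg = alpha * hs_e
            outputs.append(nn.segment_sum(msg, dst, n_nodes))
            if return_attention:
                attentions.append(alpha.data.ravel().copy())
        if cfg.head_aggregation == "mean":
            out = outputs[0]
            for o in outputs[1:]:
                out = out + o
            out = out * (1.0 / len(outputs))
        else:
            out = nn.concat(outputs, axis=1)
        if return_attention:
            return out, attentions
        return out

    def parameters(self) -> list[nn.Tensor]:
        params = []
        for head in self.heads:
            params.extend(head[k] for k in sorted(head))
        return params


# ----------------------------------------------------------------------- batch


@dataclass
class GraphBatch:
    x: np.ndarray  # (N_total, 78)
    src: np.ndarray
    dst: np.ndarray
    efeat: np.ndarray  # (E_total, 12) incl. zero rows for self-loops
    graph_ids: np.ndarray  # (N_total,)
    descriptors: np.ndarray  # (B, 50), scaled if a scaler was given
    labels: np.ndarray | None
    n_graphs: int

    @classmethod
    def from_graphs(
        cls, graphs: list[MolecularGraph], scaler: DescriptorScaler | None = None
    ) -> "GraphBatch":
        if not graphs:
            raise ValueError("empty batch")
        xs, srcs, dsts, efeats, gids = [], [], [], [], []
        offset = 0
        for gid, g in enumerate(graphs):
            xs.append(g.atom_features)
            if g.edges.shape[1]:
                srcs.append(g.edges[0] + offset)
                dsts.append(g.edges[1] + offset)
                efeats.append(g.bond_features)
            loop = np.arange(g.n_atoms) + offset
            srcs.append(loop)
            dsts.append(loop)
            efeats.append(np.zeros((g.n_atoms, BOND_FEATURE_DIM)))
            gids.append(np.full(g.n_atoms, gid))
            offset += g.n_atoms
        desc = np.stack([g.descriptors_raw for g in graphs])
        if scaler is not None:
            desc = scaler.transform(desc)
        labels = None
        if all(g.label is not None for g in graphs):
            labels = np.array([g.label for g in graphs], dtype=float)
        return cls(
            x=np.concatenate(xs),
            src=np.concatenate(srcs),
            dst=np.concatenate(dsts),
            efeat=np.concatenate(efeats),
            graph_ids=np.concatenate(gids),
            descriptors=desc,
            labels=labels,
            n_graphs=len(graphs),
        )


def dual_pool(h: nn.Tensor, graph_ids: np.ndarray, n_graphs: int) -> nn.Tensor:
    """g = [GAP || GMP] over each graph's atoms."""
    if h.data.shape[0] == 0:
        raise ValueError("cannot pool an empty graph")
    counts = np.bincount(graph_ids, minlength=n_graphs).astype(float)
    if counts.min() == 0:
        raise ValueError("cannot pool an empty graph")
    gap = nn.segment_sum(h, graph_ids, n_graphs) * (1.0 / counts)[:, None]
    gmp = nn.segment_max(h, graph_ids, n_graphs)
    return nn.concat([gap, gmp], axis=1)


def mean_pool(h: nn.Tensor, graph_ids: np.ndarray, n_graphs: int) -> nn.Tensor:
    counts = np.bincount(graph_ids, minlength=n_graphs).astype(float)
    if h.data.shape[0] == 0 or counts.min() == 0:
        raise ValueError("cannot pool an empty graph")
    return nn.segment_sum(h, graph_ids, n_graphs) * (1.0 / counts)[:, None]


# ----------------------------------------------------------------------- model


class GraphScreenModel:
    """GATv2 (or static-GAT) backbone + descriptor branch + fusion head."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 42):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.layers: list[GraphAttentionLayer] = []
        self.norms: list[BatchNorm1d] = []
        in_dim = config.atom_dim
        for _ in range(config.n_layers):
            self.layers.append(GraphAttentionLayer(in_dim, config, rng))
            self.norms.append(BatchNorm1d(config.layer_out_dim))
            in_dim = config.layer_out_dim

        d_in, d_hidden, d_out = config.descriptor_dims
        self.desc1 = Linear(d_in, d_hidden, rng)
        self.desc2 = Linear(d_hidden, d_out, rng)

        self.head1 = Linear(config.fused_dim, config.head_hidden, rng)
        self.head_norm = BatchNorm1d(config.head_hidden)
        self.head2 = Linear(config.head_hidden, 1, rng)

    # -- submodel forwards -------------------------------------------------
    def descriptor_branch(
        self, d: nn.Tensor, train: bool, rng: np.random.Generator
    ) -> nn.Tensor:
        p = self.config.dropout
        h = self.desc1(d).relu().dropout(p, rng, train)
        return self.desc2(h).relu().dropout(p, rng, train)

    def graph_embedding(
        self, batch: GraphBatch, train: bool, rng: np.random.Generator
    ) -> nn.Tensor:
        cfg = self.config
        h = nn.Tensor(batch.x)
        n_nodes = batch.x.shape[0]
        for layer, norm in zip(self.layers, self.norms):
            h = layer.forward(h, batch.src, batch.dst, batch.efeat, n_nodes, train, rng)
            if cfg.use_batch_norm:
                h = norm(h, train)
            h = h.elu().dropout(cfg.dropout, rng, train)
        if cfg.pooling == "dual":
            return dual_pool(h, batch.graph_ids, batch.n_graphs)
        return mean_pool(h, batch.graph_ids, batch.n_graphs)

    def forward(
        self,
        batch: GraphBatch,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> nn.Tensor:
        """Per-graph activity probability, shape (B, 1), strictly in (0, 1)."""
        cfg = self.config
        if rng is None:
            rng = np.random.default_rng(0)
        g = self.graph_embedding(batch, train, rng)
        if cfg.use_descriptors:
            if batch.descriptors.shape[1] != cfg.descriptor_dims[0]:
                raise ValueError(
                    f"descriptor length {batch.descriptors.shape[1]} != "
                    f"{cfg.descriptor_dims[0]}"
                )
            d = self.descriptor_branch(nn.Tensor(batch.descriptors), train, rng)
            z = nn.concat([g, d], axis=1)
        else:
            z = g
        h = self.head1(z)
        if cfg.use_batch_norm:
            h = self.head_norm(h, train)
        h = h.relu().dropout(cfg.dropout, rng, train)
        return self.head2(h).sigmoid()

    def predict_proba(
        self,
        graphs: list[MolecularGraph],
        scaler: DescriptorScaler | None = None,
        batch_size: int = 256,
    ) -> np.ndarray:
        """Eval-mode probabilities for a list of featurized graphs."""
        probs = []
        for i in range(0, len(graphs), batch_size):
            batch = GraphBatch.from_graphs(graphs[i : i + batch_size], scaler)
            probs.append(self.forward(batch, train=False).data.ravel())
        return np.concatenate(probs)

    # -- parameters and state ---------------------------------------------
    def parameters(self) -> list[nn.Tensor]:
        params: list[nn.Tensor] = []
        for layer, norm in zip(self.layers, self.norms):
            params.extend(layer.parameters())
            params.extend(norm.parameters())
        params.extend(self.desc1.parameters())
        params.extend(self.desc2.parameters())
        params.extend(self.head1.parameters())
        params.extend(self.head_norm.parameters())
        params.extend(self.head2.parameters())
        return params

    def buffers(self) -> list[np.ndarray]:
        bufs = []
        for norm in self.norms + [self.head_norm]:
            bufs.extend([norm.running_mean, norm.running_var])
        return bufs

    def get_state(self) -> dict:
        return {
            "params": [p.data.copy() for p in self.parameters()],
            "buffers": [b.copy() for b in self.buffers()],
        }

    def set_state(self, state: dict) -> None:
        for p, data in zip(self.parameters(), state["params"]):
            p.data = data.copy()
        norms = self.norms + [self.head_norm]
        for k, norm in enumerate(norms):
            norm.running_mean = state["buffers"][2 * k].copy()
            norm.running_var = state["buffers"][2 * k + 1].copy()

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def count_parameters(config: ModelConfig = ModelConfig()) -> int:
    """Exact trainable-scalar count for a configuration."""
    return GraphScreenModel(config, seed=0).count_parameters()


# ------------------------------------------------------------------ checkpoint


def save_checkpoint(
    path: str | os.PathLike,
    model: GraphScreenModel,
    scaler: DescriptorScaler | None = None,
) -> None:
    """Single-file container: config + parameters + batch-norm state + scaler."""
    cfg = dataclasses.asdict(model.config)
    cfg["descriptor_dims"] = list(cfg["descriptor_dims"])
    payload = {"config_json": np.array(json.dumps(cfg))}
    state = model.get_state()
    for i, p in enumerate(state["params"]):
        payload[f"param_{i}"] = p
    for i, b in enumerate(state["buffers"]):
        payload[f"buffer_{i}"] = b
    if scaler is not None:
        payload["scaler_mean"] = scaler.mean
        payload["scaler_std"] = scaler.std
    with open(path, "wb") as fh:  # keep the exact path (no forced .npz suffix)
        np.savez(fh, **payload)


def load_checkpoint(
    path: str | os.PathLike,
    expected_config: ModelConfig | None = None,
) -> tuple[GraphScreenModel, DescriptorScaler | None]:
    """Rebuild a model from a checkpoint; refuses a mismatched config."""
    with np.load(path) as data:
        cfg_dict = json.loads(str(data["config_json"]))
        cfg_dict["descriptor_dims"] = tuple(cfg_dict["descriptor_dims"])
        config = ModelConfig(**cfg_dict)
        if expected_config is not None and config != expected_config:
            raise ValueError("checkpoint config does not match expected config")
        model = GraphScreenModel(config, seed=0)
        n_params = len(model.parameters())
        n_buffers = len(model.buffers())
        state = {
            "params": [data[f"param_{i}"] for i in range(n_params)],
            "buffers": [data[f"buffer_{i}"] for i in range(n_buffers)],
        }
        model.set_state(state)
        scaler = None
        if "scaler_mean" in data:
            scaler = DescriptorScaler(mean=data["scaler_mean"], std=data["scaler_std"])
    return model, scaler
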