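"""Message-passing encoder and prompt-guided attention readout.

The encoder is an isomorphism-network-style message passer: node states are
initialized from the atom features and updated for ``n_layers`` rounds by
summing relu(neighbor state + embedded bond features) into the node and
passing the result through a two-layer update network.

The readout is a multi-head attention pool in which a learned per-channel
*prompt embedding* acts as the query and the atom states act as keys and
values: h_g^p = sum_x alpha_x * v_x with alpha_x = softmax(q . k_x / sqrt(d_k)).
Each self-supervised channel ([MCD], [SCD], [CP]) owns its prompt vector while
the three projection matrices are shared, so the same molecule is pooled into
channel-specific graph representations.

Desk-scale defaults (2 layers, 32 dims, 2 heads) keep CPU training fast; the
paper-scale configuration (5 layers, 300 dims) is reachable through the same
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .autodiff import Tensor
from .chem_graph import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, GraphFeatures

CHANNELS = ("MCD", "SCD", "CP")

DEFAULT_N_LAYERS = 2
DEFAULT_HIDDEN_DIM = 32
DEFAULT_N_HEADS = 2


def glorot(rng: np.random.Generator, d_in: int, d_out: int) -> Tensor:
    scale = np.sqrt(2.0 / (d_in + d_out))
    return Tensor(rng.normal(0.0, scale, size=(d_in, d_out)), requires_grad=True)


@dataclass
class EncoderParams:
    """Trainable message-passing parameters (deterministic given the seed)."""

    n_layers: int = DEFAULT_N_LAYERS
    hidden_dim: int = DEFAULT_HIDDEN_DIM
    seed: int = 0
    tensors: Dict[str, Tensor] = field(default_factory=dict)

    @classmethod
    def init(cls, n_layers: int = DEFAULT_N_LAYERS, hidden_dim: int = DEFAULT_HIDDEN_DIM,
             seed: int = 0) -> "EncoderParams":
        rng = np.random.default_rng(seed)
        t: Dict[str, Tensor] = {
            "embed_node": glorot(rng, ATOM_FEATURE_DIM, hidden_dim),
            "embed_edge": glorot(rng, BOND_FEATURE_DIM, hidden_dim),
        }
        for layer in range(n_layers):
            t[f"layer{layer}_w1"] = glorot(rng, hidden_dim, hidden_dim)
            t[f"layer{layer}_b1"] = Tensor(np.zeros(hidden_dim), requires_grad=True)
            t[f"layer{layer}_w2"] = glorot(rng, hidden_dim, hidden_dim)
            t[f"layer{layer}_b2"] = Tensor(np.zeros(hidden_dim), requires_grad=True)
        return cls(n_layers=n_layers, hidden_dim=hidden_dim, seed=seed, tensors=t)


@dataclass
class AggregationParams:
    """Prompt embeddings (one per channel) and shared attention projections."""

    hidden_dim: int = DEFAULT_HIDDEN_DIM
    n_heads: int = DEFAULT_N_HEADS
    tensors: Dict[str, Tensor] = field(default_factory=dict)

    @classmethod
    def init(cls, hidden_dim: int = DEFAULT_HIDDEN_DIM, n_heads: int = DEFAULT_N_HEADS,
             seed: int = 0) -> "AggregationParams":
        if hidden_dim % n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")
        rng = np.random.default_rng(seed + 1)
        t: Dict[str, Tensor] = {
            "W_q": glorot(rng, hidden_dim, hidden_dim),
            "W_k": glorot(rng, hidden_dim, hidden_dim),
            "W_v": glorot(rng, hidden_dim, hidden_dim),
            "W_o": glorot(rng, hidden_dim, hidden_dim),
        }
        for ch in CHANNELS:
            t[f"prompt_{ch}"] = Tensor(rng.normal(0.0, 0.1, size=(1, hidden_dim)),
                                       requires_grad=True)
        return cls(hidden_dim=hidden_dim, n_heads=n_heads, tensors=t)

    def set_trainable(self, flag: bool) -> None:
        """Freeze/unfreeze the whole aggregation module (fine-tune contract)."""
        for p in self.tensors.values():
            p.requires_grad = flag
            if not flag:
                p.zero_grad()


@dataclass
class ChannelOutput:
    """One channel's pooled graph representation and its attention weights."""

    graph_repr: Tensor            # (n_graphs, hidden_dim)
    attention: Tensor             # (n_nodes,), head-averaged, sums to 1 per graph
    graph_ids: np.ndarray         # graph id per node row


class BatchedGraphs:
    """Several molecular graphs concatenated into one disjoint union."""

    def __init__(self, graphs: Sequence[GraphFeatures]):
        if not graphs:
            raise ValueError("empty batch")
        xs, eidx, efeat, gids = [], [], [], []
        offset = 0
        for gid, g in enumerate(graphs):
            xs.append(g.node_features)
            if g.edge_index.shape[0]:
                eidx.append(g.edge_index + offset)
                efeat.append(g.edge_features)
            gids.append(np.full(g.n_atoms, gid, dtype=np.intp))
            offset += g.n_atoms
        self.node_features = np.concatenate(xs, axis=0)
        self.edge_index = (
            np.concatenate(eidx, axis=0) if eidx else np.zeros((0, 2), dtype=np.intp)
        )
        self.edge_features = (
            np.concatenate(efeat, axis=0) if efeat else np.zeros((0, BOND_FEATURE_DIM))
        )
        self.graph_ids = np.concatenate(gids)
        self.n_graphs = len(graphs)
        self.n_nodes = self.node_features.shape[0]


# --------------------------------------------------------------------------
# Forward passes
# --------------------------------------------------------------------------

def encode_nodes(batch: BatchedGraphs | GraphFeatures, params: EncoderParams) -> Tensor:
    """Per-atom representations after `n_layers` rounds of message passing."""
    if isinstance(batch, GraphFeatures):
        batch = BatchedGraphs([batch])
    if batch.node_features.shape[1] != ATOM_FEATURE_DIM:
        raise ValueError("node feature dimension does not match the schema")
    h = Tensor(batch.node_features) @ params.tensors["embed_node"]
    if batch.edge_index.shape[0]:
        e_emb = Tensor(batch.edge_features) @ params.tensors["embed_edge"]
        src = batch.edge_index[:, 0]
        dst = batch.edge_index[:, 1]
    else:
        e_emb = src = dst = None
    for layer in range(params.n_layers):
        if src is not None:
            msg = (h.gather(src) + e_emb).relu()
            agg = msg.segment_sum(dst, batch.n_nodes)
            z = h + agg
        else:
            z = h
        z = (z @ params.tensors[f"layer{layer}_w1"] + params.tensors[f"layer{layer}_b1"]).relu()
        h = z @ params.tensors[f"layer{layer}_w2"] + params.tensors[f"layer{layer}_b2"]
        if layer < params.n_layers - 1:
            h = h.relu()
    return h


def _segment_softmax(logits: Tensor, graph_ids: np.ndarray, n_graphs: int) -> Tensor:
    """Softmax over the nodes of each graph, per column (head)."""
    # constant max-shift per graph for numerical stability
    shift = np.full((n_graphs,) + logits.shape[1:], -np.inf)
    np.maximum.at(shift, graph_ids, logits.data)
    z = (logits - Tensor(shift[graph_ids])).exp()
    denom = z.segment_sum(graph_ids, n_graphs)
    return z / denom.gather(graph_ids)


def prompt_aggregate(
    node_reprs: Tensor,
    graph_ids: np.ndarray,
    n_graphs: int,
    channel: str,
    params: AggregationParams,
) -> ChannelOutput:
    """Pool atom representations into per-graph vectors, queried by the prompt.

    alpha_x = softmax_x(q . k_x / sqrt(d_k)) per attention head, with
    q = W_q h_p, k_x = W_k h_x, v_x = W_v h_x; heads are concatenated and
    linearly projected back to hidden_dim.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel token {channel!r}; expected one of {CHANNELS}")
    n_nodes = node_reprs.shape[0]
    if n_nodes == 0:
        raise ValueError("cannot aggregate an empty node set")
    heads, d_k = params.n_heads, params.hidden_dim // params.n_heads
    q = (params.tensors[f"prompt_{channel}"] @ params.tensors["W_q"]).reshape(heads, d_k)
    k = (node_reprs @ params.tensors["W_k"]).reshape(n_nodes, heads, d_k)
    v = (node_reprs @ params.tensors["W_v"]).reshape(n_nodes, heads, d_k)
    logits = (k * q).sum(axis=-1) * (1.0 / np.sqrt(d_k))  # (n_nodes, heads)
    alpha = _segment_softmax(logits, graph_ids, n_graphs)
    pooled = (alpha.reshape(n_nodes, heads, 1) * v).segment_sum(graph_ids, n_graphs)
    graph_repr = pooled.reshape(n_graphs, params.hidden_dim) @ params.tensors["W_o"]
    return ChannelOutput(
        graph_repr=graph_repr,
        attention=alpha.mean(axis=-1),
        graph_ids=graph_ids,
    )


def encode_graphs(
    graphs: Sequence[GraphFeatures],
    enc: EncoderParams,
    agg: AggregationParams,
    channel: str,
) -> ChannelOutput:
    """Convenience: featurized graphs -> one channel's graph representations."""
    batch = BatchedGraphs(graphs)
    h = encode_nodes(batch, enc)
    return prompt_aggregate(h, batch.graph_ids, batch.n_graphs, channel, params=agg)
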