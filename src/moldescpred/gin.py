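"""Graph isomorphism network (GIN) encoder with edge features.

Forward pass, for a molecular graph with node features v^j and edge
features e^{j,k}:

    h_v^{j,(0)} = ReLU(W_n v^j + b_n)                 initial node embedding
    h_e^{j,k}   = W_e e^{j,k} + b_e                   initial edge embedding (linear)
    h_v^{j,(l)} = psi^(l)( h_v^{j,(l-1)}
                    + sum_k ReLU(h_v^{k,(l-1)} + h_e^{j,k}) )   l = 1..L
    h_g         = mean_j h_v^{j,(L)}                  average pooling
    h           = PReLU(W_r h_g + b_r)                projection to the
                                                      molecular representation

psi^(l) is a two-layer 300→300→300 network with ReLU hidden units; the
second layer is ReLU except at the last message-passing layer, where it is
linear. Edge embeddings are computed once and shared across layers. Each
bond is stored as two directed edges, so the neighbour sum is a segment sum
over incoming edges.

The message uses the *neighbour's* previous embedding h_v^{k,(l-1)} by
default (the edge-featured GIN variant this architecture follows); a
``literal_messages`` switch substitutes the centre node's own embedding in
the message for comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._autodiff import Tensor, relu, prelu, gather, segment_sum
from .featurize import MolecularGraph


@dataclass(frozen=True)
class GINConfig:
    node_feature_dim: int
    edge_feature_dim: int
    num_layers: int = 3
    hidden_dim: int = 300
    representation_dim: int = 1024
    dropout_rate: float = 0.1
    literal_messages: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def _affine_init(rng: np.random.Generator, fan_in: int, fan_out: int):
    """Uniform fan-in initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(fan_in)
    W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = rng.uniform(-bound, bound, size=(fan_out,))
    return W, b


class GINParameters:
    """All learnable weights of the encoder, as named autodiff tensors."""

    def __init__(self, config: GINConfig, seed: int = 0, params: dict | None = None):
        self.config = config
        if params is not None:
            self.params = {k: Tensor(v, requires_grad=True) for k, v in params.items()}
            return
        rng = np.random.default_rng(seed)
        d, h, r = config.node_feature_dim, config.hidden_dim, config.representation_dim
        p: dict[str, np.ndarray] = {}
        p["phi_n.W"], p["phi_n.b"] = _affine_init(rng, d, h)
        p["phi_e.W"], p["phi_e.b"] = _affine_init(rng, config.edge_feature_dim, h)
        for l in range(1, config.num_layers + 1):
            p[f"psi{l}.W1"], p[f"psi{l}.b1"] = _affine_init(rng, h, h)
            p[f"psi{l}.W2"], p[f"psi{l}.b2"] = _affine_init(rng, h, h)
        p["r.W"], p["r.b"] = _affine_init(rng, h, r)
        p["r.a"] = np.array(0.25)  # PReLU slope, learnable
        self.params = {k: Tensor(v, requires_grad=True) for k, v in p.items()}

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: t.value.copy() for k, t in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            if state[k].shape != t.value.shape:
                raise ValueError(f"shape mismatch for {k}")
            t.value = np.asarray(state[k], dtype=np.float64).copy()

    def count_parameters(self) -> int:
        return int(sum(t.value.size for t in self.params.values()))


@dataclass
class GraphBatch:
    """Several molecular graphs packed into flat arrays for the encoder."""

    node_features: np.ndarray   # (N, node_dim)
    edge_features: np.ndarray   # (E, edge_dim)
    src: np.ndarray             # (E,) message source node (neighbour k)
    dst: np.ndarray             # (E,) message destination node (centre j)
    graph_ids: np.ndarray       # (N,)
    num_graphs: int

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph]) -> "GraphBatch":
        nodes, edges, srcs, dsts, gids = [], [], [], [], []
        offset = 0
        for gi, g in enumerate(graphs):
            nodes.append(g.node_features)
            edges.append(g.edge_features)
            if g.num_edges:
                # edge row (j, k): message flows neighbour k -> centre j
                dsts.append(g.edge_index[:, 0] + offset)
                srcs.append(g.edge_index[:, 1] + offset)
            gids.append(np.full(g.num_nodes, gi, dtype=np.intp))
            offset += g.num_nodes
        cat = lambda xs, w: (
            np.concatenate(xs) if xs else np.zeros((0, w))
        )
        edge_dim = graphs[0].edge_features.shape[1] if graphs else 0
        return cls(
            node_features=np.concatenate(nodes),
            edge_features=cat(edges, edge_dim),
            src=np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.intp),
            dst=np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.intp),
            graph_ids=np.concatenate(gids),
            num_graphs=len(graphs),
        )


def _dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rate <= 0 or rng is None:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def gin_encode(
    batch: GraphBatch,
    gin: GINParameters,
    stochastic: bool = False,
    rng: np.random.Generator | None = None,
    collect_layers: bool = False,
):
    """Encode a batch of graphs into representation vectors.

    Returns (representations, pooled, layer_embeddings) where
    ``representations`` is a (num_graphs, representation_dim) tensor on the
    autodiff tape. ``layer_embeddings`` is populated (as plain arrays) only
    when ``collect_layers`` is set. With ``stochastic=False`` the pass is
    deterministic; otherwise dropout is applied to each node-update hidden
    layer and to the representation.
    """
    cfg = gin.config
    p = gin.params
    drop_rng = rng if stochastic and cfg.dropout_rate > 0 else None
    if stochastic and cfg.dropout_rate > 0 and rng is None:
        raise ValueError("stochastic forward pass requires an rng")

    X = Tensor(batch.node_features)
    E = Tensor(batch.edge_features)
    N = batch.node_features.shape[0]

    h = relu(X @ p["phi_n.W"] + p["phi_n.b"])
    layers = [h.value.copy()] if collect_layers else None
    e = E @ p["phi_e.W"] + p["phi_e.b"]

    for l in range(1, cfg.num_layers + 1):
        if batch.src.size:
            centre = batch.dst if cfg.literal_messages else batch.src
            msg = relu(gather(h, centre) + e)
            agg = segment_sum(msg, batch.dst, N)
            u = h + agg
        else:
            u = h  # isolated nodes: neighbour sum is zero
        a1 = relu(u @ p[f"psi{l}.W1"] + p[f"psi{l}.b1"])
        a1 = _dropout(a1, cfg.dropout_rate, drop_rng)
        h = a1 @ p[f"psi{l}.W2"] + p[f"psi{l}.b2"]
        if l < cfg.num_layers:
            h = relu(h)
        if collect_layers:
            layers.append(h.value.copy())

    counts = np.bincount(batch.graph_ids, minlength=batch.num_graphs).astype(float)
    pooled = segment_sum(h, batch.graph_ids, batch.num_graphs) * Tensor(
        1.0 / counts[:, None]
    )
    rep = prelu(pooled @ p["r.W"] + p["r.b"], p["r.a"])
    rep = _dropout(rep, cfg.dropout_rate, drop_rng)
    return rep, pooled, layers


@dataclass
class GraphEmbedding:
    """Single-molecule encoder output with intermediate embeddings."""

    node_embeddings: list[np.ndarray]   # per layer, (num_nodes, hidden)
    edge_embeddings: np.ndarray         # (num_directed_edges, hidden)
    pooled: np.ndarray                  # (hidden,)
    representation: np.ndarray          # (representation_dim,)


def gin_forward(
    graph: MolecularGraph,
    gin: GINParameters,
    stochastic: bool = False,
    rng: np.random.Generator | None = None,
) -> GraphEmbedding:
    """Convenience single-graph forward pass returning plain arrays."""
    cfg = gin.config
    if graph.node_features.shape[1] != cfg.node_feature_dim:
        raise ValueError(
            f"graph node dim {graph.node_features.shape[1]} does not match "
            f"encoder ({cfg.node_feature_dim})"
        )
    batch = GraphBatch.from_graphs([graph])
    rep, pooled, layers = gin_encode(
        batch, gin, stochastic=stochastic, rng=rng, collect_layers=True
    )
    e = graph.edge_features @ gin.params["phi_e.W"].value + gin.params["phi_e.b"].value
    return GraphEmbedding(
        node_embeddings=layers,
        edge_embeddings=e,
        pooled=pooled.value[0],
        representation=rep.value[0],
    )


# -- checkpointing -------------------------------------------------------


def save_checkpoint(path, gin: GINParameters, extra_arrays: dict | None = None,
                    extra_manifest: dict | None = None) -> None:
    """Write a named-tensor archive with an embedded JSON manifest."""
    manifest = {"config": gin.config.to_dict()}
    if extra_manifest:
        manifest.update(extra_manifest)
    arrays = {f"gin/{k}": v for k, v in gin.state_dict().items()}
    if extra_arrays:
        arrays.update({f"extra/{k}": np.asarray(v) for k, v in extra_arrays.items()})
    np.savez(path, __manifest__=np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, expected_config: GINConfig | None = None):
    """Load (GINParameters, extra_arrays, manifest); refuse architectural mismatch."""
    with np.load(path) as npz:
        manifest = json.loads(bytes(npz["__manifest__"]).decode())
        arrays = {k: npz[k] for k in npz.files if k != "__manifest__"}
    config = GINConfig(**manifest["config"])
    if expected_config is not None and config != expected_config:
        diffs = {
            k: (getattr(config, k), getattr(expected_config, k))
            for k in config.to_dict()
            if getattr(config, k) != getattr(expected_config, k)
        }
        raise ValueError(f"checkpoint architecture mismatch: {diffs}")
    gin = GINParameters(
        config, params={k[4:]: v for k, v in arrays.items() if k.startswith("gin/")}
    )
    extra = {k[6:]: v for k, v in arrays.items() if k.startswith("extra/")}
    return gin, extra, manifest
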