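"""Multi-head graph attention network for edge-level quality regression.

The network stacks four graph attention layers over the interface graph.
Intermediate layers run four attention heads whose outputs are concatenated
along the feature dimension; the output layer has a single head. Per-head
hidden dimensions are 32, 16, 8, 4 (input dimension 32, scaling factor 0.5
per layer).

Each layer embeds, for every directed edge (j -> i), the source node's
current embedding concatenated with the *static* raw edge features,

    z_ij = W_l [h_j || e_ij],

computes an attention logit from the concatenated destination/source
embeddings through a leaky rectifier, normalizes the logits into attention
weights by a softmax over each node's incident (inter-chain) neighbours,
and updates the node as the nonlinearity of the attention-weighted message
sum,

    h_i = act( sum_j alpha_ij z_ij ).

Intermediate updates use a rectifier; the output layer is linear so the
final 4-dimensional embeddings are unconstrained in sign, as a regression
head requires. At inference each edge's quality is the logistic squashing
of the dot product of its endpoint embeddings, and the overall interface
quality Q is the arithmetic mean of the edge scores.

Forward pass, analytic backward pass and Xavier initialization are
implemented directly on numpy arrays; heads are evaluated batched and
neighbourhood aggregation uses sorted-segment reductions. Gradient
correctness is exercised against numerical differentiation in the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .edge_features import EDGE_FEATURE_DIM
from .node_features import NODE_FEATURE_DIM

FEATURE_VERSION = "node17-edge27-v1"

_LEAKY_SLOPE = 0.2


@dataclass
class GATConfig:
    """Architecture hyperparameters.

    ``hidden_input`` and ``hidden_scale`` define the per-head hidden sizes
    as hidden_input * hidden_scale**layer; the defaults give 32, 16, 8, 4.
    """

    n_layers: int = 4
    heads_per_layer: tuple[int, ...] = (4, 4, 4, 1)
    hidden_input: int = 32
    hidden_scale: float = 0.5
    node_dim: int = NODE_FEATURE_DIM
    edge_dim: int = EDGE_FEATURE_DIM
    raw_dot: bool = False  # skip the logistic squashing of the edge score
    random_seed: int = 0

    @property
    def hidden_dims(self) -> list[int]:
        return [int(round(self.hidden_input * self.hidden_scale ** l))
                for l in range(self.n_layers)]

    @property
    def node_dims(self) -> list[int]:
        """Input node dimension of each layer (heads concatenated)."""
        dims = [self.node_dim]
        for l in range(self.n_layers - 1):
            dims.append(self.hidden_dims[l] * self.heads_per_layer[l])
        return dims


class GATParams:
    """Learned weights, Xavier-uniform initialized from the config seed.

    Per layer l: ``W[l]`` of shape (heads, hidden, node_in + edge_dim) and
    attention vectors ``a[l]`` of shape (heads, 2 * hidden); ``W[l][k]``
    indexes head k.
    """

    def __init__(self, config: GATConfig):
        self.config = config
        rng = np.random.default_rng(config.random_seed)
        self.W: list[np.ndarray] = []
        self.a: list[np.ndarray] = []
        for l in range(config.n_layers):
            d_in = config.node_dims[l] + config.edge_dim
            d_out = config.hidden_dims[l]
            K = config.heads_per_layer[l]
            self.W.append(np.stack([_xavier(rng, d_out, d_in)
                                    for _ in range(K)]))
            self.a.append(np.stack([_xavier(rng, 1, 2 * d_out)[0]
                                    for _ in range(K)]))

    def flat(self) -> list[np.ndarray]:
        out = []
        for l in range(self.config.n_layers):
            out.append(self.W[l])
            out.append(self.a[l])
        return out

    def copy(self) -> "GATParams":
        dup = GATParams.__new__(GATParams)
        dup.config = self.config
        dup.W = [w.copy() for w in self.W]
        dup.a = [a.copy() for a in self.a]
        return dup


def _xavier(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_out, fan_in))


def _leaky_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, _LEAKY_SLOPE)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class GraphIndex:
    """Directed-edge bookkeeping for one graph, computed once and cached.

    Undirected edges are expanded into both directions; directed edges are
    stored sorted by destination so neighbourhood reductions (softmax,
    weighted sums) run as contiguous-segment ``reduceat`` calls. ``opp``
    maps each directed edge to its reverse.
    """

    def __init__(self, edges: list[tuple[int, int]], n_nodes: int):
        E = len(edges)
        pairs = np.asarray(edges, dtype=np.intp)
        src = np.concatenate([pairs[:, 1], pairs[:, 0]])
        dst = np.concatenate([pairs[:, 0], pairs[:, 1]])
        eid = np.concatenate([np.arange(E), np.arange(E)])
        twin = np.concatenate([np.arange(E) + E, np.arange(E)])
        order = np.argsort(dst, kind="stable")
        rank = np.empty(2 * E, dtype=np.intp)
        rank[order] = np.arange(2 * E)
        self.src = src[order]
        self.dst = dst[order]
        self.eid = eid[order]
        self.opp = rank[twin[order]]
        if not np.array_equal(np.unique(self.dst), np.arange(n_nodes)):
            raise ValueError("every node must appear in at least one edge")
        self.starts = np.flatnonzero(
            np.r_[True, self.dst[1:] != self.dst[:-1]])
        # a second ordering sorted by source, for backpropagating into nodes
        sorder = np.argsort(self.src, kind="stable")
        self.src_order = sorder
        self.src_sorted = self.src[sorder]
        self.src_starts = np.flatnonzero(
            np.r_[True, self.src_sorted[1:] != self.src_sorted[:-1]])
        self.n_nodes = n_nodes
        self.n_edges = E


def graph_index(graph) -> GraphIndex:
    idx = getattr(graph, "_gat_index", None)
    if idx is None or idx.n_edges != graph.n_edges:
        idx = GraphIndex(graph.edges, graph.n_nodes)
        graph._gat_index = idx
    return idx


def _segment_softmax(logits: np.ndarray, gi: GraphIndex) -> np.ndarray:
    mx = np.maximum.reduceat(logits, gi.starts, axis=0)
    ex = np.exp(logits - mx[gi.dst])
    denom = np.add.reduceat(ex, gi.starts, axis=0)
    return ex / denom[gi.dst]


@dataclass
class _LayerCache:
    xcat: np.ndarray      # (T, node_in + edge_dim) per directed edge
    z: np.ndarray         # (T, K, d) embedded messages
    pre: np.ndarray       # (T, K) attention logits before leaky rectifier
    alpha: np.ndarray     # (T, K) attention weights
    s: np.ndarray         # (V, K, d) pre-activation update
    linear: bool


def _layer_forward_all_heads(H, Ef, gi: GraphIndex, W, a, linear):
    """One layer over all heads. W: (K, d, d_in); a: (K, 2d)."""
    K, d, d_in = W.shape
    xcat = np.concatenate([H[gi.src], Ef[gi.eid]], axis=1)
    z = (xcat @ W.reshape(K * d, d_in).T).reshape(-1, K, d)
    z_opp = z[gi.opp]
    pre = (z_opp * a[None, :, :d]).sum(axis=2) \
        + (z * a[None, :, d:]).sum(axis=2)
    logit = np.where(pre > 0, pre, _LEAKY_SLOPE * pre)
    alpha = _segment_softmax(logit, gi)
    s = np.add.reduceat(alpha[:, :, None] * z, gi.starts, axis=0)
    h = s if linear else np.maximum(s, 0.0)
    return h.reshape(gi.n_nodes, -1), _LayerCache(xcat, z, pre, alpha, s,
                                                  linear)


def _layer_backward_all_heads(dh, cache: _LayerCache, gi: GraphIndex, W, a,
                              d_node: int):
    """Gradients of one layer; returns (dH_in, dW, da)."""
    K, d, d_in = W.shape
    T = cache.z.shape[0]
    dh = dh.reshape(gi.n_nodes, K, d)
    ds = dh if cache.linear else dh * (cache.s > 0)
    ds_at = ds[gi.dst]                                  # (T, K, d)
    dalpha = (cache.z * ds_at).sum(axis=2)
    dz = cache.alpha[:, :, None] * ds_at
    g = np.add.reduceat(cache.alpha * dalpha, gi.starts, axis=0)
    dlogit = cache.alpha * (dalpha - g[gi.dst])
    dpre = dlogit * _leaky_grad(cache.pre)
    z_opp = cache.z[gi.opp]
    da = np.concatenate([
        (dpre[:, :, None] * z_opp).sum(axis=0),
        (dpre[:, :, None] * cache.z).sum(axis=0),
    ], axis=1)
    dz += dpre[:, :, None] * a[None, :, d:]
    dz += (dpre[:, :, None] * a[None, :, :d])[gi.opp]
    dz2 = dz.reshape(T, K * d)
    dW = (dz2.T @ cache.xcat).reshape(K, d, d_in)
    dxnode = dz2 @ W[:, :, :d_node].reshape(K * d, d_node)
    dH = np.add.reduceat(dxnode[gi.src_order], gi.src_starts, axis=0)
    return dH, dW, da


class GATForwardCache:
    """Intermediates retained for the analytic backward pass."""

    def __init__(self):
        self.layer_caches: list[_LayerCache] = []
        self.final_embeds: np.ndarray | None = None


def network_forward(node_feats: np.ndarray, edge_feats: np.ndarray,
                    edges_or_index, params: GATParams,
                    ) -> tuple[np.ndarray, GATForwardCache]:
    """Final node embeddings (V, 4) plus cached intermediates."""
    cfg = params.config
    gi = edges_or_index if isinstance(edges_or_index, GraphIndex) \
        else GraphIndex(list(edges_or_index), node_feats.shape[0])
    H = node_feats
    cache = GATForwardCache()
    for l in range(cfg.n_layers):
        H, lc = _layer_forward_all_heads(
            H, edge_feats, gi, params.W[l], params.a[l],
            linear=l == cfg.n_layers - 1)
        if np.isnan(H).any():
            raise FloatingPointError(f"NaN embedding at layer {l}")
        cache.layer_caches.append(lc)
    cache.final_embeds = H
    return H, cache


def layer_forward(node_embeds: np.ndarray, edge_feats: np.ndarray,
                  edges: list[tuple[int, int]], params: GATParams,
                  layer_index: int) -> np.ndarray:
    """One attention layer (all heads concatenated); exposed for testing."""
    gi = GraphIndex(edges, node_embeds.shape[0])
    h, _ = _layer_forward_all_heads(
        node_embeds, edge_feats, gi, params.W[layer_index],
        params.a[layer_index],
        linear=layer_index == params.config.n_layers - 1)
    return h


def attention_weights(node_embeds: np.ndarray, edge_feats: np.ndarray,
                      edges: list[tuple[int, int]], params: GATParams,
                      layer_index: int) -> tuple[np.ndarray, np.ndarray]:
    """(per-directed-edge attention weights (T, K), destination indices)."""
    gi = GraphIndex(edges, node_embeds.shape[0])
    _, c = _layer_forward_all_heads(
        node_embeds, edge_feats, gi, params.W[layer_index],
        params.a[layer_index],
        linear=layer_index == params.config.n_layers - 1)
    return c.alpha, gi.dst


def edge_score(final_node_embeds: np.ndarray, edge: tuple[int, int],
               raw_dot: bool = False) -> float:
    """Quality of one edge: logistic of the endpoint-embedding dot product."""
    i, j = edge
    dot = float(final_node_embeds[i] @ final_node_embeds[j])
    return dot if raw_dot else float(_sigmoid(np.float64(dot)))


def edge_scores(final_node_embeds: np.ndarray,
                edges: list[tuple[int, int]],
                raw_dot: bool = False) -> np.ndarray:
    idx = np.asarray(edges)
    dots = (final_node_embeds[idx[:, 0]]
            * final_node_embeds[idx[:, 1]]).sum(axis=1)
    return dots if raw_dot else _sigmoid(dots)


def aggregate_quality(scores: np.ndarray) -> float:
    """Overall interface quality Q: the mean of the per-edge scores."""
    scores = np.asarray(scores, float)
    if scores.size == 0:
        raise ValueError("cannot aggregate an empty edge-score set")
    return float(scores.mean())


def model_forward(graph, params: GATParams) -> tuple[np.ndarray, float]:
    """(per-edge quality scores, overall Q) for a featurized graph."""
    if graph.node_features is None or graph.edge_features is None:
        raise ValueError("graph must be featurized before scoring")
    embeds, _ = network_forward(graph.node_features, graph.edge_features,
                                graph_index(graph), params)
    scores = edge_scores(embeds, graph.edges, raw_dot=params.config.raw_dot)
    return scores, aggregate_quality(scores)


# ---------------------------------------------------------------------------
# loss and analytic gradients
# ---------------------------------------------------------------------------

class GATGradients:
    """Zero-initialized gradient holder shaped like :class:`GATParams`."""

    def __init__(self, config: GATConfig):
        self.config = config
        self.W = [np.zeros((config.heads_per_layer[l], config.hidden_dims[l],
                            config.node_dims[l] + config.edge_dim))
                  for l in range(config.n_layers)]
        self.a = [np.zeros((config.heads_per_layer[l],
                            2 * config.hidden_dims[l]))
                  for l in range(config.n_layers)]

    def flat(self) -> list[np.ndarray]:
        out = []
        for l in range(self.config.n_layers):
            out.append(self.W[l])
            out.append(self.a[l])
        return out


def loss_and_gradients(graph, params: GATParams,
                       ) -> tuple[float, GATGradients]:
    """Sum-reduced squared error of edge scores vs labels, with gradients."""
    if graph.edge_label is None:
        raise ValueError("graph has no edge labels")
    cfg = params.config
    gi = graph_index(graph)
    embeds, cache = network_forward(graph.node_features, graph.edge_features,
                                    gi, params)
    idx = np.asarray(graph.edges)
    dots = (embeds[idx[:, 0]] * embeds[idx[:, 1]]).sum(axis=1)
    scores = _sigmoid(dots)
    resid = scores - graph.edge_label
    loss = float((resid ** 2).sum())

    ddots = 2.0 * resid * scores * (1.0 - scores)
    dH = np.zeros_like(embeds)
    np.add.at(dH, idx[:, 0], ddots[:, None] * embeds[idx[:, 1]])
    np.add.at(dH, idx[:, 1], ddots[:, None] * embeds[idx[:, 0]])

    grads = GATGradients(cfg)
    for l in reversed(range(cfg.n_layers)):
        dH, dW, da = _layer_backward_all_heads(
            dH, cache.layer_caches[l], gi, params.W[l], params.a[l],
            d_node=cfg.node_dims[l])
        grads.W[l] += dW
        grads.a[l] += da
    return loss, grads


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(params: GATParams, path: str) -> None:
    """Portable single-file checkpoint: config, weights, feature version."""
    cfg = params.config
    meta = {
        "version": FEATURE_VERSION,
        "n_layers": cfg.n_layers,
        "heads_per_layer": list(cfg.heads_per_layer),
        "hidden_input": cfg.hidden_input,
        "hidden_scale": cfg.hidden_scale,
        "node_dim": cfg.node_dim,
        "edge_dim": cfg.edge_dim,
        "raw_dot": cfg.raw_dot,
        "random_seed": cfg.random_seed,
    }
    arrays = {"_meta": np.frombuffer(json.dumps(meta).encode(),
                                     dtype=np.uint8)}
    for l in range(cfg.n_layers):
        arrays[f"W_{l}"] = params.W[l]
        arrays[f"a_{l}"] = params.a[l]
    # write through a handle so numpy cannot append ".npz" to the path
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path: str) -> GATParams:
    data = np.load(path)
    meta = json.loads(bytes(data["_meta"]).decode())
    if meta.pop("version") != FEATURE_VERSION:
        raise ValueError(
            f"checkpoint {path} was written with an incompatible feature "
            f"version (expected {FEATURE_VERSION})"
        )
    meta["heads_per_layer"] = tuple(meta["heads_per_layer"])
    cfg = GATConfig(**meta)
    params = GATParams(cfg)
    for l in range(cfg.n_layers):
        params.W[l] = data[f"W_{l}"]
        params.a[l] = data[f"a_{l}"]
    return params
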