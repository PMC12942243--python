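"""Edge-attributed spine graph and dual-stream graph transformer.

Each radiograph becomes a chain graph alternating vertebra and disc nodes.
Node embeddings fuse a *local* stream (a small encoder over per-node ROI
crops) with a *global* stream (an encoder over the downsampled whole image);
attention scores between neighbors are modulated by a learnable transform of
the geometric edge attributes (distance, orientation, curvature):

    score(i, j) = (q_i + phi(a_ij))^T k_j / sqrt(d_k),   j in N(i),

followed by a softmax over N(i), multi-head aggregation of values, and
residual + layer-norm feedforward updates.  Mean-pooled node embeddings feed
a 6-class diagnosis head and a 4-vector geometry-index regression head.

The published-scale backbones are replaced by small pluggable encoders: any
object with an ``out_dim`` attribute and a ``__call__`` mapping a feature
tensor to embeddings can serve as either stream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from . import _autograd as ag
from ._autograd import Tensor
from .geometry import LandmarkSet, edge_attributes
from .nn import MLP, LayerNorm, Linear, Module
from .phantom import CLASSES

__all__ = [
    "SpineGraph",
    "TransformerConfig",
    "PatchEncoder",
    "ImageEncoder",
    "build_graph",
    "extract_rois",
    "encode_nodes",
    "edge_aware_attention",
    "transformer_forward",
    "predict",
    "SpineGraphModel",
    "INDEX_SCALE",
]

#: per-index normalization scales (slip, disc asymmetry, SI px, Cobb deg)
INDEX_SCALE = np.array([0.5, 0.6, 6.0, 40.0])

#: gain applied to normalized index features fed to the classifier head,
#: bringing their scale in line with the layer-normalized embedding dims
INDEX_FEATURE_GAIN = 4.0


@dataclass
class SpineGraph:
    """Chain graph of anatomical sites: vertebra and disc nodes alternating."""

    positions: np.ndarray   # (M, 2) node centers
    kinds: np.ndarray       # (M,) 0 = vertebra, 1 = disc
    roi_boxes: np.ndarray   # (M, 4) x, y, w, h
    edges: np.ndarray       # (E, 2) undirected consecutive pairs
    edge_attrs: np.ndarray  # (E, 3) distance, orientation (i->j), curvature

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def adjacency(self) -> np.ndarray:
        m = self.n_nodes
        adj = np.zeros((m, m), dtype=bool)
        for i, j in self.edges:
            adj[i, j] = adj[j, i] = True
        return adj

    def edge_attr_dense(self) -> np.ndarray:
        """Directed dense (M, M, 3) attribute tensor; orientation flips with
        direction, distance and curvature are symmetric."""
        m = self.n_nodes
        dense = np.zeros((m, m, 3))
        for (i, j), (d, o, k) in zip(self.edges, self.edge_attrs):
            dense[i, j] = (d, o, k)
            o_rev = o - math.pi if o > 0 else o + math.pi
            dense[j, i] = (d, o_rev, k)
        return dense

    def to_edge_csv(self, path):
        import pandas as pd

        pd.DataFrame({
            "i": self.edges[:, 0], "j": self.edges[:, 1],
            "distance": self.edge_attrs[:, 0],
            "orientation": self.edge_attrs[:, 1],
            "curvature": self.edge_attrs[:, 2],
        }).to_csv(path, index=False)


@dataclass
class TransformerConfig:
    """Graph-transformer hyperparameters (published-scale defaults)."""

    node_dim: int = 256
    n_heads: int = 4
    n_layers: int = 3
    edge_mlp_hidden: tuple = (32,)

    def __post_init__(self):
        if self.node_dim % self.n_heads != 0:
            raise ValueError("node_dim must be divisible by n_heads")


def build_graph(landmarks: LandmarkSet, roi_size: int = 16) -> SpineGraph:
    """Chain graph with vertebra-disc-vertebra alternating nodes.

    N vertebrae give 2N-1 nodes and 2N-2 edges; disc nodes sit at the midpoint
    of adjacent centroids.  Each edge carries geometric attributes computed on
    the node chain.
    """
    n = landmarks.n_vertebrae
    if n < 1:
        raise ValueError("need at least one vertebra to build a graph")
    c = landmarks.centroids
    positions, kinds = [], []
    for i in range(n):
        positions.append(c[i])
        kinds.append(0)
        if i < n - 1:
            positions.append((c[i] + c[i + 1]) / 2.0)
            kinds.append(1)
    positions = np.asarray(positions)
    kinds = np.asarray(kinds)
    m = len(positions)
    edges = np.array([(i, i + 1) for i in range(m - 1)], dtype=int).reshape(-1, 2)
    attrs = np.array([
        edge_attributes(positions[i], positions[j], chain=positions, edge=(i, j)).as_array()
        for i, j in edges
    ]).reshape(-1, 3)
    half = roi_size / 2.0
    boxes = np.stack([
        positions[:, 0] - half, positions[:, 1] - half,
        np.full(m, float(roi_size)), np.full(m, float(roi_size)),
    ], axis=1)
    return SpineGraph(positions, kinds, boxes, edges, attrs)


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

class PatchEncoder(Module):
    """Local stream: flattened ROI crop -> MLP -> d_l embedding."""

    def __init__(self, patch_size: int = 16, out_dim: int = 16, hidden: int = 32,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.patch_size = patch_size
        self.out_dim = out_dim
        self.net = MLP([patch_size * patch_size, hidden, out_dim], rng)

    def __call__(self, crops) -> Tensor:
        return self.net(ag.as_tensor(crops))


class ImageEncoder(Module):
    """Global stream: whole image downsampled to a fixed grid -> MLP -> d_g."""

    def __init__(self, grid: int = 24, out_dim: int = 16, hidden: int = 48,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(1)
        self.grid = grid
        self.out_dim = out_dim
        self.net = MLP([grid * grid, hidden, out_dim], rng)

    def downsample(self, image: np.ndarray) -> np.ndarray:
        return _sk_resize(image, (self.grid, self.grid), anti_aliasing=True).reshape(-1)

    def __call__(self, flat_images) -> Tensor:
        return self.net(ag.as_tensor(flat_images))


def extract_rois(image: np.ndarray, graph: SpineGraph, roi_size: int = 16) -> np.ndarray:
    """(M, roi*roi) crops centered on nodes, zero-padded past image borders."""
    h, w = image.shape
    crops = np.zeros((graph.n_nodes, roi_size, roi_size))
    half = roi_size // 2
    for k, (cx, cy) in enumerate(graph.positions):
        r0, c0 = int(round(cy)) - half, int(round(cx)) - half
        r1, c1 = r0 + roi_size, c0 + roi_size
        rs, cs = max(r0, 0), max(c0, 0)
        re, ce = min(r1, h), min(c1, w)
        if re > rs and ce > cs:
            crops[k, rs - r0:re - r0, cs - c0:ce - c0] = image[rs:re, cs:ce]
    return crops.reshape(graph.n_nodes, -1)


def encode_nodes(image: np.ndarray, graph: SpineGraph, local_encoder, global_encoder) -> Tensor:
    """Fused per-node embeddings: [local(ROI crop) || global(image)].

    The global stream runs once per image; its vector is shared by all nodes.
    """
    crops = extract_rois(image, graph, local_encoder.patch_size)
    local = local_encoder(crops)                    # (M, d_l)
    g = global_encoder(global_encoder.downsample(image).reshape(1, -1))  # (1, d_g)
    gtile = g * Tensor(np.ones((graph.n_nodes, 1)))
    fused = ag.concatenate([local, gtile], axis=-1)
    if fused.shape[-1] != local_encoder.out_dim + global_encoder.out_dim:
        raise ValueError("encoder output dimension mismatch with declared out_dim")
    return fused


# ---------------------------------------------------------------------------
# edge-aware attention
# ---------------------------------------------------------------------------

def _mha(h: Tensor, Wq: Linear, Wk: Linear, Wv: Linear, edge_mlp: MLP,
         attr_dense: np.ndarray, adj: np.ndarray, n_heads: int,
         return_weights: bool = False):
    """Batched multi-head edge-aware attention.

    h           : (B, M, D) node embeddings
    attr_dense  : (B, M, M, 3) directed edge attributes (constant)
    adj         : (B, M, M) boolean neighbor mask (no self-loops; rows without
                  neighbors fall back to self-attention)
    """
    B, M, D = h.shape
    dk = D // n_heads
    scale = 1.0 / math.sqrt(dk)

    adj = adj.copy()
    lonely = ~adj.any(axis=-1)
    if lonely.any():
        bi, ni = np.nonzero(lonely)
        adj[bi, ni, ni] = True

    def heads(t):
        return t.reshape(B, M, n_heads, dk).transpose(0, 2, 1, 3)  # (B,H,M,dk)

    Q, K, V = heads(Wq(h)), heads(Wk(h)), heads(Wv(h))
    E = edge_mlp(Tensor(attr_dense.reshape(B * M * M, 3)))
    E = E.reshape(B, M, M, n_heads, dk).transpose(0, 3, 1, 2, 4)   # (B,H,M,M,dk)
    QE = Q.reshape(B, n_heads, M, 1, dk) + E
    scores = (QE * K.reshape(B, n_heads, 1, M, dk)).sum(axis=-1) * scale  # (B,H,M,M)
    mask = np.broadcast_to(adj[:, None, :, :], scores.shape)
    scores = ag.where_mask(mask, scores, Tensor(np.full(scores.shape, -1e30)))
    weights = ag.softmax(scores, axis=-1)
    out = ag.matmul(weights, V)                                     # (B,H,M,dk)
    out = out.transpose(0, 2, 1, 3).reshape(B, M, D)
    if return_weights:
        return out, weights
    return out


def edge_aware_attention(embeddings: Tensor, graph: SpineGraph, params: dict,
                         n_heads: int = 4) -> np.ndarray:
    """Attention weights (H, M, M) for one graph; each row over N(i) sums to 1.

    ``params`` holds the layer's Wq/Wk/Wv Linear modules and the shared edge
    MLP phi (output dimension H*d_k).  With phi == 0 this reduces exactly to
    standard scaled dot-product attention restricted to the neighborhood.
    """
    h = ag.as_tensor(embeddings)
    M = h.shape[0]
    _, w = _mha(h.reshape(1, M, h.shape[1]), params["Wq"], params["Wk"], params["Wv"],
                params["edge_mlp"], graph.edge_attr_dense()[None],
                graph.adjacency()[None], n_heads, return_weights=True)
    return w.data[0]


class TransformerLayer(Module):
    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        D = cfg.node_dim
        dk = D // cfg.n_heads
        self.Wq = Linear(D, D, rng)
        self.Wk = Linear(D, D, rng)
        self.Wv = Linear(D, D, rng)
        self.Wo = Linear(D, D, rng)
        self.edge_mlp = MLP([3, *cfg.edge_mlp_hidden, cfg.n_heads * dk], rng)
        self.ffn = MLP([D, 2 * D, D], rng)
        self.ln1 = LayerNorm(D)
        self.ln2 = LayerNorm(D)
        self._heads = cfg.n_heads

    def __call__(self, h: Tensor, attr_dense: np.ndarray, adj: np.ndarray) -> Tensor:
        a = _mha(h, self.Wq, self.Wk, self.Wv, self.edge_mlp, attr_dense, adj, self._heads)
        h = self.ln1(h + self.Wo(a))
        h = self.ln2(h + self.ffn(h))
        return h


class SpineTransformer(Module):
    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.layers = [TransformerLayer(cfg, rng) for _ in range(cfg.n_layers)]

    def __call__(self, h: Tensor, attr_dense: np.ndarray, adj: np.ndarray) -> Tensor:
        for li, layer in enumerate(self.layers):
            h = layer(h, attr_dense, adj)
            if not np.all(np.isfinite(h.data)):
                raise FloatingPointError(f"non-finite embedding after transformer layer {li}")
        return h


def transformer_forward(embeddings: Tensor, graph: SpineGraph,
                        model: SpineTransformer) -> Tensor:
    """Run the stacked edge-aware transformer on a single graph."""
    h = ag.as_tensor(embeddings)
    M, D = h.shape
    out = model(h.reshape(1, M, D), graph.edge_attr_dense()[None],
                graph.adjacency()[None])
    return out.reshape(M, D)


def predict(updated_embeddings: Tensor, heads: "PredictionHeads") -> tuple:
    """Mean-pool node embeddings and apply the linear class/index heads."""
    h = ag.as_tensor(updated_embeddings)
    if h.shape[0] == 0:
        raise ValueError("empty graph: no nodes to pool")
    pooled = h.mean(axis=0).reshape(1, -1)
    return heads(pooled)


class PredictionHeads(Module):
    def __init__(self, in_dim: int, rng: np.random.Generator, n_classes: int = len(CLASSES)):
        self.cls = Linear(in_dim, n_classes, rng)
        self.reg = Linear(in_dim, 4, rng)

    def __call__(self, pooled: Tensor):
        return self.cls(pooled), self.reg(pooled)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class SpineGraphModel(Module):
    """Dual-stream encoders + edge-aware graph transformer + prediction heads.

    ``use_index_features``: append the (normalized) geometry-index summary of
    each image to the pooled embedding before the heads — the desk-scale
    realization of geometry-aware classification.  Disabled by the
    "without geometry indices" ablation.
    """

    def __init__(self, cfg: TransformerConfig | None = None, d_local: int = 16,
                 d_global: int = 16, patch_size: int = 16, seed: int = 0,
                 use_index_features: bool = True):
        rng = np.random.default_rng(seed)
        cfg = cfg or TransformerConfig(node_dim=d_local + d_global, n_heads=4, n_layers=2)
        if cfg.node_dim != d_local + d_global:
            raise ValueError("node_dim must equal d_local + d_global (fused embedding)")
        self.cfg = cfg
        self.patch_size = patch_size
        self.local_encoder = PatchEncoder(patch_size, d_local, rng=rng)
        self.global_encoder = ImageEncoder(out_dim=d_global, rng=rng)
        self.transformer = SpineTransformer(cfg, rng)
        self.use_index_features = use_index_features
        head_dim = cfg.node_dim + (4 if use_index_features else 0)
        self.heads = PredictionHeads(head_dim, rng)

    # -- batched forward over padded graphs ---------------------------------
    def forward_batch(self, batch: dict, return_pooled: bool = False):
        """batch: dict of padded arrays built by :meth:`prepare_batch`."""
        crops = Tensor(batch["crops"])              # (B, M, P*P)
        local = self.local_encoder(crops)           # (B, M, d_l)
        g = self.global_encoder(batch["global_feats"])  # (B, d_g)
        B, M = batch["node_mask"].shape
        gtile = g.reshape(B, 1, -1) * Tensor(np.ones((1, M, 1)))
        h = ag.concatenate([local, gtile], axis=-1)
        h = self.transformer(h, batch["attr_dense"], batch["adjacency"])
        mask = Tensor(batch["node_mask"][:, :, None].astype(float))
        counts = batch["node_mask"].sum(axis=1, keepdims=True).astype(float)
        pooled = (h * mask).sum(axis=1) / Tensor(counts)
        if self.use_index_features:
            pooled = ag.concatenate([pooled, Tensor(batch["index_feats"])], axis=-1)
        logits, reg = self.heads(pooled)
        if return_pooled:
            return logits, reg, pooled
        return logits, reg

    def prepare_batch(self, images, graphs, index_summaries) -> dict:
        """Pad a list of (image, graph, index summary) into dense batch arrays."""
        B = len(images)
        M = max(g.n_nodes for g in graphs)
        P = self.patch_size
        crops = np.zeros((B, M, P * P))
        node_mask = np.zeros((B, M), dtype=bool)
        adjacency = np.zeros((B, M, M), dtype=bool)
        attr_dense = np.zeros((B, M, M, 3))
        global_feats = np.zeros((B, self.global_encoder.grid ** 2))
        index_feats = np.zeros((B, 4))
        for b, (img, graph) in enumerate(zip(images, graphs)):
            m = graph.n_nodes
            crops[b, :m] = extract_rois(img, graph, P)
            node_mask[b, :m] = True
            adjacency[b, :m, :m] = graph.adjacency()
            attr_dense[b, :m, :m] = graph.edge_attr_dense()
            global_feats[b] = self.global_encoder.downsample(img)
            if index_summaries is not None:
                index_feats[b] = (np.asarray(index_summaries[b]) / INDEX_SCALE
                                  * INDEX_FEATURE_GAIN)
        return {
            "crops": crops, "node_mask": node_mask, "adjacency": adjacency,
            "attr_dense": attr_dense, "global_feats": global_feats,
            "index_feats": index_feats,
        }

    def predict_proba(self, images, graphs, index_summaries) -> np.ndarray:
        logits, _ = self.forward_batch(self.prepare_batch(images, graphs, index_summaries))
        return ag.softmax(logits, axis=-1).data

    # -- persistence ---------------------------------------------------------
    def save(self, path):
        meta = {
            "node_dim": self.cfg.node_dim, "n_heads": self.cfg.n_heads,
            "n_layers": self.cfg.n_layers, "edge_mlp_hidden": list(self.cfg.edge_mlp_hidden),
            "d_local": self.local_encoder.out_dim, "d_global": self.global_encoder.out_dim,
            "patch_size": self.patch_size, "use_index_features": self.use_index_features,
        }
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, __config__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "SpineGraphModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__config__"]))
            cfg = TransformerConfig(meta["node_dim"], meta["n_heads"], meta["n_layers"],
                                    tuple(meta["edge_mlp_hidden"]))
            model = cls(cfg, meta["d_local"], meta["d_global"], meta["patch_size"],
                        use_index_features=meta["use_index_features"])
            state = [z[f"p{i}"] for i in range(len(model.parameters()))]
        model.load_state(state)
        return model
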