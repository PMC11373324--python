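"""The three modality encoders and their prior-knowledge attention biases.

1D — a standard Transformer over the ESPF token sequence; the input is the sum
of a substructure embedding and a learned positional embedding.

2D — a graph Transformer: a Graph Isomorphism Network (GIN) produces per-atom
representations, degree embeddings are added as a centrality positional
encoding, and every self-attention head receives an additive shortest-path
distance (SPD) bias, one learned scalar per (head, SPD bucket).

3D — a graph Transformer: SchNet continuous-filter convolutions over
radial-basis-expanded interatomic distances produce per-atom representations,
a learned map of the Gaussian-basis-expanded distance row sum is added as the
spatial positional encoding, and each attention head receives a learned
projection of the Gaussian-basis-expanded pairwise distances as its bias.

Every encoder reports a *local* representation (middle Transformer layer for
1D; the graph-encoder output for 2D/3D) and a *global* one (final layer),
both mean-pooled — these feed the hierarchical contrastive objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor
from .chemio import (
    ESPFSequence,
    GeometryGraph,
    TopologyGraph,
    NUM_ATOM_TYPES,
    NUM_BOND_TYPES,
    NUM_CHARGE_BUCKETS,
    UNREACHABLE,
    default_kernel_params,
    gaussian_basis_expand,
)

__all__ = [
    "EncoderConfig",
    "EncoderOutput",
    "AtomRepresentations",
    "Encoder1D",
    "GIN",
    "SchNet",
    "GraphTransformer2D",
    "GraphTransformer3D",
    "ProjectionHead",
    "pool",
    "encode_1d",
    "gin_forward",
    "schnet_forward",
    "graph_transformer_2d",
    "graph_transformer_3d",
    "project",
    "spd_buckets",
]


@dataclass
class EncoderConfig:
    """Hyperparameters shared by the encoders.

    ``hidden_dim`` must be divisible by ``n_heads``; ``local_layer`` (1-based)
    selects which Transformer layer provides the 1D local representation and
    defaults to the middle layer ⌈L/2⌉.
    """

    hidden_dim: int = 128
    n_layers: int = 4
    n_heads: int = 8
    dropout: float = 0.0
    view: str = "1d"
    local_layer: Optional[int] = None
    gin_layers: int = 3
    schnet_interactions: int = 3
    spd_max: int = 20
    n_kernel: int = 32
    cutoff: float = 10.0
    sum_dist_max: float = 256.0
    max_len: int = 256
    max_degree: int = 12
    ff_mult: int = 2
    proj_dim: int = 64
    normalize: bool = True
    vocab_size: int = 0  # set from the vocabulary for the 1D encoder

    def __post_init__(self):
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if self.local_layer is None:
            self.local_layer = math.ceil(self.n_layers / 2)
        if not (1 <= self.local_layer <= self.n_layers):
            raise ValueError("local_layer must lie in [1, n_layers]")

    @property
    def head_dim(self) -> int:
        return self.hidden_dim // self.n_heads


@dataclass
class EncoderOutput:
    """Hidden states, attention maps, and pooled local/global vectors."""

    layer_states: np.ndarray  # (L+1, n_items, h), detached
    attention: np.ndarray  # (L, n_heads, n_items, n_items), post-softmax
    local: Tensor  # h-vector
    global_: Tensor  # h-vector


@dataclass
class AtomRepresentations:
    values: Tensor  # d × h

    @property
    def d(self) -> int:
        return self.values.shape[0]


def pool(items: Tensor) -> Tensor:
    """Arithmetic mean over rows — the readout for every local/global vector."""
    if items.shape[0] == 0:
        raise ValueError("cannot pool an empty set of items")
    return items.mean(axis=0)


# ---------------------------------------------------------------------------
# Transformer backbone
# ---------------------------------------------------------------------------


class MultiHeadSelfAttention(nn.Module):
    def __init__(self, cfg: EncoderConfig, rng):
        h = cfg.hidden_dim
        self.n_heads = cfg.n_heads
        self.head_dim = cfg.head_dim
        self.wq = nn.Linear(h, h, rng)
        self.wk = nn.Linear(h, h, rng)
        self.wv = nn.Linear(h, h, rng)
        self.wo = nn.Linear(h, h, rng)

    def __call__(self, x: Tensor, bias: Optional[Tensor] = None):
        n, h = x.shape
        def split(t):  # (n, h) → (heads, n, head_dim)
            return t.reshape((n, self.n_heads, self.head_dim)).swapaxes(0, 1)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.T) * (1.0 / math.sqrt(self.head_dim))
        if bias is not None:
            scores = scores + bias
        attn = scores.softmax(axis=-1)
        out = (attn @ v).swapaxes(0, 1).reshape((n, h))
        return self.wo(out), attn.detach()


class TransformerBlock(nn.Module):
    """Pre-norm block: x + MHA(LN(x)), then x + FF(LN(x))."""

    def __init__(self, cfg: EncoderConfig, rng):
        h = cfg.hidden_dim
        self.ln1 = nn.LayerNorm(h)
        self.attn = MultiHeadSelfAttention(cfg, rng)
        self.ln2 = nn.LayerNorm(h)
        self.ff = nn.MLP([h, cfg.ff_mult * h, h], rng, activation="relu")

    def __call__(self, x: Tensor, bias: Optional[Tensor] = None):
        a, attn = self.attn(self.ln1(x), bias)
        x = x + a
        x = x + self.ff(self.ln2(x))
        return x, attn


class TransformerStack(nn.Module):
    def __init__(self, cfg: EncoderConfig, rng):
        self.blocks = nn.ModuleList([TransformerBlock(cfg, rng) for _ in range(cfg.n_layers)])

    def __call__(self, x: Tensor, biases=None):
        states = [x]
        attns = []
        for i, block in enumerate(self.blocks):
            bias = None if biases is None else biases[i]
            x, attn = block(x, bias)
            states.append(x)
            attns.append(attn)
        return states, attns


# ---------------------------------------------------------------------------
# 1D encoder
# ---------------------------------------------------------------------------


class Encoder1D(nn.Module):
    """Transformer over the ESPF token sequence (token + positional embedding)."""

    def __init__(self, cfg: EncoderConfig, rng):
        if cfg.vocab_size <= 0:
            raise ValueError("EncoderConfig.vocab_size must be set for the 1D encoder")
        self.cfg = cfg
        self.token_emb = nn.Embedding(cfg.vocab_size, cfg.hidden_dim, rng)
        self.pos_emb = nn.Embedding(cfg.max_len, cfg.hidden_dim, rng)
        self.stack = TransformerStack(cfg, rng)

    def __call__(self, seq: ESPFSequence) -> EncoderOutput:
        if seq.e < 1:
            raise ValueError("empty ESPF sequence")
        x = self.token_emb(seq.tokens) + self.pos_emb(seq.positions)
        states, attns = self.stack(x)
        return EncoderOutput(
            layer_states=np.stack([s.detach() for s in states]),
            attention=np.stack(attns),
            local=pool(states[self.cfg.local_layer]),
            global_=pool(states[-1]),
        )


# ---------------------------------------------------------------------------
# Graph encoders
# ---------------------------------------------------------------------------


class GIN(nn.Module):
    """Graph Isomorphism Network with learnable ε and bond-type embeddings.

    Update: h_v ← MLP((1+ε)·h_v + Σ_{u∈N(v)} (h_u + emb(e_uv))).  No batch
    normalization — forward passes here are per-molecule, so there is no batch
    dimension to normalize over.
    """

    def __init__(self, cfg: EncoderConfig, rng):
        h = cfg.hidden_dim
        self.atom_emb = nn.Embedding(NUM_ATOM_TYPES, h, rng)
        self.charge_emb = nn.Embedding(NUM_CHARGE_BUCKETS, h, rng)
        self.bond_embs = nn.ModuleList(
            [nn.Embedding(NUM_BOND_TYPES, h, rng) for _ in range(cfg.gin_layers)]
        )
        self.mlps = nn.ModuleList(
            [nn.MLP([h, h, h], rng, activation="relu") for _ in range(cfg.gin_layers)]
        )
        self.eps = [nn.Parameter(np.zeros(())) for _ in range(cfg.gin_layers)]

    def __call__(self, graph: TopologyGraph) -> AtomRepresentations:
        d = graph.d
        x = self.atom_emb(graph.atom_features[:, 0]) + self.charge_emb(graph.atom_features[:, 1])
        adj = Tensor(graph.adjacency().astype(np.float64))
        # incidence counts: row v, column t = number of type-t bonds at atom v
        counts = np.zeros((d, NUM_BOND_TYPES))
        for i, j, t in graph.bonds:
            counts[i, t] += 1
            counts[j, t] += 1
        counts_t = Tensor(counts)
        for layer in range(len(self.mlps)):
            neighbor = adj @ x + counts_t @ self.bond_embs[layer].weight
            x = self.mlps[layer]((1.0 + self.eps[layer]) * x + neighbor)
        return AtomRepresentations(values=x)


class SchNet(nn.Module):
    """Continuous-filter convolutions over radial-basis-expanded distances.

    Each interaction block computes, for atom i,
    ``m_i = Σ_{j≠i, d_ij<cutoff} (x_j W) ⊙ F(rbf(d_ij))`` followed by an
    atom-wise (linear, shifted-softplus, linear) refinement added residually.
    """

    def __init__(self, cfg: EncoderConfig, rng):
        h = cfg.hidden_dim
        self.cfg = cfg
        self.atom_emb = nn.Embedding(NUM_ATOM_TYPES, h, rng)
        self.in2f = nn.ModuleList(
            [nn.Linear(h, h, rng, bias=False) for _ in range(cfg.schnet_interactions)]
        )
        self.filters = nn.ModuleList(
            [nn.MLP([cfg.n_kernel, h, h], rng, activation="ssp")
             for _ in range(cfg.schnet_interactions)]
        )
        self.out1 = nn.ModuleList([nn.Linear(h, h, rng) for _ in range(cfg.schnet_interactions)])
        self.out2 = nn.ModuleList([nn.Linear(h, h, rng) for _ in range(cfg.schnet_interactions)])

    def __call__(self, geom: GeometryGraph, atom_types: Optional[np.ndarray] = None
                 ) -> AtomRepresentations:
        d = geom.d
        types = geom.atom_types if atom_types is None else atom_types
        x = self.atom_emb(types)
        rbf = gaussian_basis_expand(geom.dist, _pairwise_kernels(self.cfg, geom))
        mask = ((geom.dist < self.cfg.cutoff) & ~np.eye(d, dtype=bool)).astype(np.float64)
        mask_t = Tensor(mask[:, :, None])
        rbf_t = Tensor(rbf.reshape(d * d, -1))
        for layer in range(len(self.filters)):
            filt = self.filters[layer](rbf_t).reshape((d, d, -1))
            xj = self.in2f[layer](x).reshape((1, d, -1))
            msg = (filt * xj * mask_t).sum(axis=1)
            y = self.out2[layer](nn.shifted_softplus(self.out1[layer](msg)))
            x = x + y
        return AtomRepresentations(values=x)


def _pairwise_kernels(cfg: EncoderConfig, geom: GeometryGraph):
    """Kernels for pairwise distances: the geometry's own when they match the
    encoder's kernel count (the filter weights are sized to n_kernel)."""
    if geom.kernel_params and len(geom.kernel_params) == cfg.n_kernel:
        return geom.kernel_params
    return default_kernel_params(cfg.n_kernel, 0.0, cfg.cutoff)


# ---------------------------------------------------------------------------
# Graph Transformers (2D and 3D)
# ---------------------------------------------------------------------------


def spd_buckets(spd: np.ndarray, spd_max: int) -> np.ndarray:
    """Clip raw SPD values into embedding buckets 0..spd_max, with the
    UNREACHABLE sentinel mapped to its own bucket spd_max+1."""
    b = np.clip(spd, 0, spd_max)
    b[spd == UNREACHABLE] = spd_max + 1
    return b.astype(np.intp)


class GraphTransformer2D(nn.Module):
    """GIN atom encoder + Transformer with degree encoding and SPD attention bias."""

    def __init__(self, cfg: EncoderConfig, rng):
        self.cfg = cfg
        self.gin = GIN(cfg, rng)
        self.degree_emb = nn.Embedding(cfg.max_degree + 1, cfg.hidden_dim, rng)
        # per-layer SPD bias tables: one scalar per (bucket, head)
        self.spd_bias = nn.ModuleList(
            [nn.Embedding(cfg.spd_max + 2, cfg.n_heads, rng) for _ in range(cfg.n_layers)]
        )
        self.stack = TransformerStack(cfg, rng)

    def __call__(self, graph: TopologyGraph) -> EncoderOutput:
        atoms = self.gin(graph)
        local = pool(atoms.values)
        deg = np.clip(graph.degrees, 0, self.cfg.max_degree)
        x = atoms.values + self.degree_emb(deg)
        buckets = spd_buckets(graph.spd, self.cfg.spd_max)
        biases = [
            self.spd_bias[i](buckets.ravel())
            .reshape((graph.d, graph.d, self.cfg.n_heads))
            .swapaxes(0, 2)
            .swapaxes(1, 2)
            for i in range(self.cfg.n_layers)
        ]
        states, attns = self.stack(x, biases)
        return EncoderOutput(
            layer_states=np.stack([s.detach() for s in states]),
            attention=np.stack(attns),
            local=local,
            global_=pool(states[-1]),
        )


class GraphTransformer3D(nn.Module):
    """SchNet atom encoder + Transformer with distance-sum encoding and a
    Gaussian-basis 3D-distance attention bias."""

    def __init__(self, cfg: EncoderConfig, rng):
        self.cfg = cfg
        self.schnet = SchNet(cfg, rng)
        self.sum_proj = nn.Linear(cfg.n_kernel, cfg.hidden_dim, rng)
        self.bias_proj = nn.ModuleList(
            [nn.Linear(cfg.n_kernel, cfg.n_heads, rng, bias=False)
             for _ in range(cfg.n_layers)]
        )
        self.stack = TransformerStack(cfg, rng)
        self.sum_kernels = default_kernel_params(cfg.n_kernel, 0.0, cfg.sum_dist_max)

    def __call__(self, geom: GeometryGraph, atom_types: Optional[np.ndarray] = None
                 ) -> EncoderOutput:
        atoms = self.schnet(geom, atom_types=atom_types)
        local = pool(atoms.values)
        d = geom.d
        sum_feat = gaussian_basis_expand(geom.dist_sum, self.sum_kernels)
        x = atoms.values + self.sum_proj(Tensor(sum_feat))
        rbf = Tensor(
            gaussian_basis_expand(geom.dist, _pairwise_kernels(self.cfg, geom)).reshape(d * d, -1)
        )
        biases = [
            self.bias_proj[i](rbf)
            .reshape((d, d, self.cfg.n_heads))
            .swapaxes(0, 2)
            .swapaxes(1, 2)
            for i in range(self.cfg.n_layers)
        ]
        states, attns = self.stack(x, biases)
        return EncoderOutput(
            layer_states=np.stack([s.detach() for s in states]),
            attention=np.stack(attns),
            local=local,
            global_=pool(states[-1]),
        )


# ---------------------------------------------------------------------------
# Projection head
# ---------------------------------------------------------------------------


class ProjectionHead(nn.Module):
    """Two-layer nonlinear map to the contrastive space, L2-normalized by default."""

    def __init__(self, in_dim: int, out_dim: int, rng, normalize: bool = True):
        self.lin1 = nn.Linear(in_dim, in_dim, rng)
        self.lin2 = nn.Linear(in_dim, out_dim, rng)
        self.normalize = normalize

    def __call__(self, rep: Tensor) -> Tensor:
        z = self.lin2(self.lin1(rep).relu())
        if self.normalize:
            norm = ((z**2).sum() + 1e-12) ** 0.5
            z = z / norm
        return z


# ---------------------------------------------------------------------------
# Thin functional interfaces
# ---------------------------------------------------------------------------


def encode_1d(seq: ESPFSequence, encoder: Encoder1D) -> EncoderOutput:
    return encoder(seq)


def gin_forward(graph: TopologyGraph, gin: GIN) -> AtomRepresentations:
    return gin(graph)


def schnet_forward(geom: GeometryGraph, schnet: SchNet,
                   atom_types: Optional[np.ndarray] = None) -> AtomRepresentations:
    return schnet(geom, atom_types=atom_types)


def graph_transformer_2d(graph: TopologyGraph, enc: GraphTransformer2D) -> EncoderOutput:
    return enc(graph)


def graph_transformer_3d(geom: GeometryGraph, enc: GraphTransformer3D,
                         atom_types: Optional[np.ndarray] = None) -> EncoderOutput:
    return enc(geom, atom_types=atom_types)


def project(rep: Tensor, head: ProjectionHead) -> Tensor:
    return head(rep)
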