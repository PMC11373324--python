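"""Attention-guided masking augmentation.

For each view, the positive (augmented) sample is built by masking the items
(ESPF segments for 1D; atoms for 2D/3D) that receive the *most* attention in
the current model state: attention received is averaged over the final
layer's heads and query positions, items are ranked by descending score (ties
broken by ascending index), and the top ``max(1, ⌊r·d/100⌋)`` items are
masked.  Masking replaces item attributes only — bonds, SPD, coordinates and
distances are untouched, so the structural attention biases stay valid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chemio import (
    ESPFSequence,
    GeometryGraph,
    TopologyGraph,
    Vocabulary,
    MASK_ATOM_TYPE,
    NEUTRAL_CHARGE_BUCKET,
)

__all__ = [
    "MaskVector",
    "aggregate_attention",
    "select_mask",
    "random_mask",
    "apply_mask_1d",
    "apply_mask_graph",
]


@dataclass
class MaskVector:
    m: np.ndarray  # binary, 1 = masked
    r: float  # masking percentage (0, 100]
    ranks: np.ndarray  # 1 = highest attention score
    n_masked: int


def aggregate_attention(attn: np.ndarray) -> np.ndarray:
    """Score item i by the final layer's mean attention it *receives*.

    ``attn`` has shape (L, n_heads, n, n) with post-softmax rows; the score is
    the mean over heads and query positions of column i in the last layer, so
    scores sum to 1 over items.
    """
    attn = np.asarray(attn)
    if attn.ndim != 4:
        raise ValueError(f"expected (L, heads, n, n) attention, got shape {attn.shape}")
    return attn[-1].mean(axis=(0, 1))


def select_mask(scores: np.ndarray, r: float) -> MaskVector:
    """Mask the top-ranked items per the declared ranking and tie rule."""
    scores = np.asarray(scores, dtype=np.float64)
    d = scores.shape[0]
    if d < 1:
        raise ValueError("empty score vector")
    if not (0 < r <= 100):
        raise ValueError(f"masking percentage must be in (0, 100], got {r}")
    n_masked = max(1, int(np.floor(r * d / 100.0)))
    order = np.argsort(-scores, kind="stable")  # descending score, ties by index
    ranks = np.empty(d, dtype=np.int64)
    ranks[order] = np.arange(1, d + 1)
    m = (ranks <= n_masked).astype(np.int64)
    return MaskVector(m=m, r=float(r), ranks=ranks, n_masked=n_masked)


def random_mask(d: int, r: float, rng: np.random.Generator) -> MaskVector:
    """Uniform-random mask of the same size — the RandomMask ablation."""
    scores = rng.random(d)
    return select_mask(scores, r)


def apply_mask_1d(seq: ESPFSequence, mask: MaskVector, vocab: Vocabulary) -> ESPFSequence:
    if len(mask.m) != seq.e:
        raise ValueError(f"mask length {len(mask.m)} != sequence length {seq.e}")
    tokens = [vocab.mask_id if mask.m[t] else tok for t, tok in enumerate(seq.tokens)]
    strings = ["[MASK]" if mask.m[t] else s for t, s in enumerate(seq.token_strings)]
    return ESPFSequence(
        tokens=tokens,
        positions=list(seq.positions),
        source_spans=list(seq.source_spans),
        token_strings=strings,
    )


def apply_mask_graph(graph, mask: MaskVector):
    """Attribute masking for 2D/3D graphs; structure is preserved exactly.

    For a :class:`TopologyGraph`, masked atoms get the reserved MASK atom type
    and a neutral charge bucket.  For a :class:`GeometryGraph`, the maskable
    ``atom_types`` are replaced; coords/dist/dist_sum are shared unchanged.
    """
    masked = np.asarray(mask.m).astype(bool)
    if isinstance(graph, TopologyGraph):
        if masked.shape[0] != graph.d:
            raise ValueError(f"mask length {masked.shape[0]} != atom count {graph.d}")
        feats = graph.atom_features.copy()
        feats[masked, 0] = MASK_ATOM_TYPE
        feats[masked, 1] = NEUTRAL_CHARGE_BUCKET
        return TopologyGraph(
            atom_features=feats,
            bonds=list(graph.bonds),
            degrees=graph.degrees,
            spd=graph.spd,
        )
    if isinstance(graph, GeometryGraph):
        if masked.shape[0] != graph.d:
            raise ValueError(f"mask length {masked.shape[0]} != atom count {graph.d}")
        types = graph.atom_types.copy()
        types[masked] = MASK_ATOM_TYPE
        return replace(graph, atom_types=types)
    raise TypeError(f"unsupported graph type {type(graph).__name__}")
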