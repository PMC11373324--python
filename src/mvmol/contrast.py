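"""Adaptive multi-view contrastive loss (AMCLoss) with dynamic weight
averaging (DWA) and the two-level hierarchical combination.

For a batch of molecules, each molecule contributes up to six embeddings
(views 1d/2d/3d and their attention-masked augmentations).  For molecule a
with view-index set M_a, every ordered anchor/positive pair (i, j), i ∈ M_a,
j ∈ M_a \\ {i}, contributes

    −log( w_t(i,j) · exp(z_i·z_j) / Σ_{o ∉ M_a} exp(z_i·z_o) ),

i.e. an InfoNCE-style term whose denominator ranges over *all* embeddings of
the other molecules in the batch, and whose per-pair-type weight w enters
inside the logarithm (an additive −log w per term; a SupCon-style
multiplicative ``weight_mode="outside"`` is available).  The batch loss is
the mean over molecules of the per-molecule double sum.

Pair types are the C(6,2) = 15 unordered view pairs; DWA sets each type's
weight from the ratio of its mean losses in the two preceding periods via a
softmax scaled to sum to K.  Local and global levels each keep their own DWA
state, and the hierarchical loss is a weighted sum of the two level losses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .nn import Tensor

__all__ = [
    "VIEW_LABELS",
    "ContrastBatch",
    "PairTypeState",
    "AMCLossResult",
    "pair_type",
    "all_pair_types",
    "amc_loss",
    "dwa_update",
    "hierarchical_loss",
]

#: The six per-molecule views.
VIEW_LABELS = ("1d", "2d", "3d", "1d_aug", "2d_aug", "3d_aug")

PairType = tuple[str, str]


def pair_type(view_a: str, view_b: str) -> PairType:
    """The unordered pair-type id of two view labels of one molecule."""
    if view_a == view_b:
        raise ValueError(f"a molecule has one sample per view; got ({view_a}, {view_b})")
    return tuple(sorted((view_a, view_b)))  # type: ignore[return-value]


def all_pair_types(views: Sequence[str] = VIEW_LABELS) -> list[PairType]:
    return [tuple(sorted(p)) for p in itertools.combinations(sorted(views), 2)]


@dataclass
class ContrastBatch:
    """Embeddings with molecule and view bookkeeping for one level."""

    z: Union[Tensor, np.ndarray]  # (n_embeddings, dim)
    mol_of: list  # embedding index → molecule id
    view_of: list[str]  # embedding index → view label
    level: str = "global"

    def __post_init__(self):
        n = len(self.mol_of)
        if len(self.view_of) != n:
            raise ValueError("mol_of and view_of must have equal length")
        zshape = self.z.shape
        if zshape[0] != n:
            raise ValueError(f"z has {zshape[0]} rows for {n} labels")
        by_mol: dict = {}
        for m, v in zip(self.mol_of, self.view_of):
            by_mol.setdefault(m, []).append(v)
        view_sets = {frozenset(vs) for vs in by_mol.values()}
        if len(view_sets) != 1:
            raise ValueError("every molecule in the batch must carry the same view set")
        for vs in by_mol.values():
            if len(set(vs)) != len(vs):
                raise ValueError("duplicate view for one molecule in the batch")
        self.views = sorted(next(iter(view_sets)))
        self.molecules = list(dict.fromkeys(self.mol_of))


@dataclass
class PairTypeState:
    """Per-pair-type DWA bookkeeping carried across update periods."""

    types: list[PairType]
    weights: dict = field(default=None)  # type: ignore[assignment]
    loss_prev: Optional[dict] = None  # mean losses two periods ago
    loss_last: Optional[dict] = None  # mean losses one period ago
    p: int = 0  # completed update periods

    def __post_init__(self):
        self.types = [tuple(t) for t in self.types]
        if self.weights is None:
            self.weights = {t: 1.0 for t in self.types}

    @property
    def K(self) -> int:
        return len(self.types)

    @classmethod
    def for_views(cls, views: Sequence[str] = VIEW_LABELS) -> "PairTypeState":
        return cls(types=all_pair_types(views))


@dataclass
class AMCLossResult:
    total: Tensor  # scalar (mean over molecules)
    per_type: dict  # pair type → mean of its terms (float)
    terms: dict  # (anchor index, positive index) → float


def _as_tensor(z) -> Tensor:
    return z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=np.float64))


def amc_loss(
    batch: ContrastBatch,
    state: Optional[PairTypeState] = None,
    weight_mode: str = "as_written",
    temperature: float = 1.0,
) -> AMCLossResult:
    """The adaptive multi-view contrastive loss over one batch.

    ``state`` supplies the per-pair-type weights (all 1 when omitted).  With
    ``weight_mode="as_written"`` the weight sits inside the logarithm; with
    ``"outside"`` it multiplies the unweighted term.  ``temperature`` divides
    the dot products (1.0 reproduces the plain exp(z_i·z_j) form).
    """
    if weight_mode not in ("as_written", "outside"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    z = _as_tensor(batch.z)
    n = z.shape[0]
    mol_of = np.asarray(batch.mol_of, dtype=object)
    n_mols = len(batch.molecules)
    if n_mols < 2:
        raise ValueError("AMCLoss needs at least two molecules for negatives")

    same_mol = mol_of[:, None] == mol_of[None, :]
    other = (~same_mol).astype(np.float64)  # negatives: all views of other molecules
    pos = same_mol & ~np.eye(n, dtype=bool)  # anchor/positive pairs

    dots = (z @ z.T) * (1.0 / temperature)
    denom = ((dots.exp()) * Tensor(other)).sum(axis=1)  # per-anchor Σ_o exp(z_i·z_o)
    log_denom = denom.log()

    weights = state.weights if state is not None else {}
    logw = np.zeros((n, n))
    wmat = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if pos[i, j]:
                t = pair_type(batch.view_of[i], batch.view_of[j])
                w = float(weights.get(t, 1.0))
                logw[i, j] = np.log(w)
                wmat[i, j] = w

    # raw per-pair matrix: log_denom[i] − z_i·z_j
    raw = log_denom.reshape((n, 1)) - dots
    pos_t = Tensor(pos.astype(np.float64))
    if weight_mode == "as_written":
        total = ((raw - Tensor(logw)) * pos_t).sum() * (1.0 / n_mols)
        term_values = (raw.detach() - logw)
    else:
        total = (raw * Tensor(wmat) * pos_t).sum() * (1.0 / n_mols)
        term_values = raw.detach() * wmat

    terms = {}
    type_sums: dict = {}
    type_counts: dict = {}
    for i in range(n):
        for j in range(n):
            if pos[i, j]:
                t = pair_type(batch.view_of[i], batch.view_of[j])
                v = float(term_values[i, j])
                terms[(i, j)] = v
                type_sums[t] = type_sums.get(t, 0.0) + v
                type_counts[t] = type_counts.get(t, 0) + 1
    per_type = {t: type_sums[t] / type_counts[t] for t in type_sums}
    return AMCLossResult(total=total, per_type=per_type, terms=terms)


def dwa_update(state: PairTypeState, current: dict) -> PairTypeState:
    """Advance the DWA state with one period's per-type mean losses.

    For the first two periods all weights stay 1; from the third period on,
    each type's ratio is last/previous mean loss (1 when the previous loss is
    0 or the type was unobserved), and weights are K·softmax(ratios).
    """
    current = {tuple(t): float(v) for t, v in current.items()}
    new_prev = state.loss_last
    new_last = current
    p = state.p + 1
    K = state.K
    if new_prev is not None and p >= 2:
        ratios = np.empty(K)
        for k, t in enumerate(state.types):
            last = new_last.get(t)
            prev = new_prev.get(t)
            if last is None or prev is None or prev == 0.0:
                ratios[k] = 1.0
            else:
                ratios[k] = last / prev
        e = np.exp(ratios - ratios.max())
        w = K * e / e.sum()
        weights = {t: float(w[k]) for k, t in enumerate(state.types)}
    else:
        weights = {t: 1.0 for t in state.types}
    return PairTypeState(
        types=list(state.types),
        weights=weights,
        loss_prev=new_prev,
        loss_last=new_last,
        p=p,
    )


def hierarchical_loss(
    local_batch: ContrastBatch,
    global_batch: ContrastBatch,
    local_state: Optional[PairTypeState] = None,
    global_state: Optional[PairTypeState] = None,
    lambda_local: float = 1.0,
    lambda_global: float = 1.0,
    weight_mode: str = "as_written",
    temperature: float = 1.0,
):
    """λ_local·AMCLoss(local) + λ_global·AMCLoss(global), each level with its
    own DWA state.  Returns (total Tensor, local result, global result)."""
    if sorted(zip(local_batch.mol_of, local_batch.view_of)) != sorted(
        zip(global_batch.mol_of, global_batch.view_of)
    ):
        raise ValueError("local and global batches must cover identical molecules and views")
    res_l = amc_loss(local_batch, local_state, weight_mode, temperature)
    res_g = amc_loss(global_batch, global_state, weight_mode, temperature)
    total = res_l.total * lambda_local + res_g.total * lambda_global
    return total, res_l, res_g
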