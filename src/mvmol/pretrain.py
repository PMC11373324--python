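"""Multi-view contrastive pre-training.

Each step: (1) forward the originals through the three encoders, collecting
attention maps; (2) build one attention-guided mask per view and forward the
masked (augmented) views; (3) project every view at the local and global
levels through its own projection head; (4) evaluate the hierarchical
adaptive multi-view contrastive loss; (5) take one Adam step.  Per-pair-type
losses are accumulated across the epoch and fed to the dynamic-weight-average
update at the period boundary, separately for the local and global levels.

Molecules are processed one at a time inside a batch (no padding needed at
these sizes); the loss itself is joint over the batch.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .augment import aggregate_attention, apply_mask_1d, apply_mask_graph, random_mask, select_mask
from .chemio import (
    ESPFSequence,
    GeometryGraph,
    Molecule,
    TopologyGraph,
    Vocabulary,
    build_geometry_graph,
    build_topology_graph,
    tokenize_espf,
)
from .contrast import ContrastBatch, PairTypeState, hierarchical_loss
from .encoders import Encoder1D, EncoderConfig, GraphTransformer2D, GraphTransformer3D, ProjectionHead
from . import nn
from .nn import Adam, Tensor

__all__ = [
    "PretrainConfig",
    "TrainState",
    "MultiViewEncoderModel",
    "MolFeatures",
    "featurize",
    "init_train_state",
    "pretrain_step",
    "run_pretraining",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_VERSION",
]

CHECKPOINT_VERSION = "mvmol-ckpt-1"


@dataclass
class PretrainConfig:
    """Everything a pre-training run needs; every field has a toy-scale default."""

    hidden_dim: int = 128
    n_layers: int = 4
    n_heads: int = 8
    proj_dim: int = 64
    gin_layers: int = 3
    schnet_interactions: int = 3
    spd_max: int = 20
    n_kernel: int = 32
    cutoff: float = 10.0
    normalize: bool = True
    mask_ratio: float = 25.0
    mask_ratio_per_view: dict = field(default_factory=dict)
    batch_size: int = 8
    epochs: int = 10
    lr: float = 1e-4
    seed: int = 0
    weight_mode: str = "as_written"
    temperature: float = 1.0
    dwa_period: str = "epoch"  # "epoch" | "step"
    lambda_local: float = 1.0
    lambda_global: float = 1.0
    views: tuple = ("1d", "2d", "3d")
    # ablation switches
    no_local: bool = False
    no_3d: bool = False
    random_mask: bool = False
    fixed_weight: bool = False

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be ≥ 2 (the loss needs negatives)")
        if self.epochs < 1:
            raise ValueError("epochs must be ≥ 1")
        if self.no_3d:
            self.views = tuple(v for v in self.views if v != "3d")
        if self.no_local:
            self.lambda_local = 0.0
        if len(self.views) < 2:
            raise ValueError("need at least two views for multi-view contrast")

    @property
    def view_labels(self) -> list[str]:
        return list(self.views) + [v + "_aug" for v in self.views]

    def encoder_config(self, view: str, vocab_size: int = 0) -> EncoderConfig:
        return EncoderConfig(
            hidden_dim=self.hidden_dim,
            n_layers=self.n_layers,
            n_heads=self.n_heads,
            view=view,
            gin_layers=self.gin_layers,
            schnet_interactions=self.schnet_interactions,
            spd_max=self.spd_max,
            n_kernel=self.n_kernel,
            cutoff=self.cutoff,
            proj_dim=self.proj_dim,
            normalize=self.normalize,
            vocab_size=vocab_size,
        )


@dataclass
class MolFeatures:
    """Pre-computed views of one molecule."""

    mol: Molecule
    seq: Optional[ESPFSequence]
    topo: Optional[TopologyGraph]
    geom: Optional[GeometryGraph]


def featurize(mols: Sequence[Molecule], vocab: Vocabulary, views=("1d", "2d", "3d")
              ) -> list[MolFeatures]:
    """Build the requested views for every molecule; raises listing offenders."""
    out = []
    bad = []
    for m in mols:
        try:
            seq = tokenize_espf(m.smiles, vocab) if "1d" in views else None
            topo = build_topology_graph(m) if "2d" in views else None
            geom = build_geometry_graph(m) if "3d" in views else None
            out.append(MolFeatures(mol=m, seq=seq, topo=topo, geom=geom))
        except Exception as exc:  # noqa: BLE001 — collect and report all offenders
            bad.append((m.id, str(exc)))
    if bad:
        raise ValueError(f"unfeaturizable molecules: {bad}")
    return out


class MultiViewEncoderModel(nn.Module):
    """The three encoders plus twelve projection heads (6 views × 2 levels)."""

    def __init__(self, config: PretrainConfig, vocab: Vocabulary, rng: np.random.Generator):
        self.config = config
        self.vocab = vocab
        h = config.hidden_dim
        if "1d" in config.views:
            self.enc1d = Encoder1D(config.encoder_config("1d", vocab.size_with_reserved), rng)
        if "2d" in config.views:
            self.gt2d = GraphTransformer2D(config.encoder_config("2d"), rng)
        if "3d" in config.views:
            self.gt3d = GraphTransformer3D(config.encoder_config("3d"), rng)
        self.heads = {
            f"{label}:{level}": ProjectionHead(h, config.proj_dim, rng, config.normalize)
            for label in config.view_labels
            for level in ("local", "global")
        }

    # -- forward passes -------------------------------------------------------
    def encode_view(self, view: str, feats: MolFeatures, masked=None):
        if view == "1d":
            seq = feats.seq if masked is None else masked
            return self.enc1d(seq)
        if view == "2d":
            topo = feats.topo if masked is None else masked
            return self.gt2d(topo)
        if view == "3d":
            if masked is None:
                return self.gt3d(feats.geom)
            return self.gt3d(masked, atom_types=masked.atom_types)
        raise ValueError(f"unknown view {view!r}")

    def project(self, label: str, level: str, rep: Tensor) -> Tensor:
        return self.heads[f"{label}:{level}"](rep)

    def mask_view(self, view: str, feats: MolFeatures, scores, rng: np.random.Generator):
        cfg = self.config
        r = cfg.mask_ratio_per_view.get(view, cfg.mask_ratio)
        if cfg.random_mask:
            mask = random_mask(len(scores), r, rng)
        else:
            mask = select_mask(scores, r)
        if view == "1d":
            return apply_mask_1d(feats.seq, mask, self.vocab), mask
        if view == "2d":
            return apply_mask_graph(feats.topo, mask), mask
        return apply_mask_graph(feats.geom, mask), mask


@dataclass
class TrainState:
    model: MultiViewEncoderModel
    optimizer: Adam
    states: dict  # level → PairTypeState
    epoch: int = 0
    trace: list = field(default_factory=list)
    rng: np.random.Generator = None


def init_train_state(config: PretrainConfig, vocab: Vocabulary) -> TrainState:
    master = np.random.default_rng(config.seed)
    model = MultiViewEncoderModel(config, vocab, master)
    optimizer = Adam(model.parameters(), lr=config.lr)
    states = {
        "local": PairTypeState.for_views(config.view_labels),
        "global": PairTypeState.for_views(config.view_labels),
    }
    return TrainState(model=model, optimizer=optimizer, states=states, rng=master)


def _forward_batch(model: MultiViewEncoderModel, batch: Sequence[MolFeatures],
                   rng: np.random.Generator):
    """Originals + attention-guided augmentations, projected at both levels."""
    config = model.config
    z_local, z_global, mol_of, view_of = [], [], [], []
    for feats in batch:
        originals = {}
        for view in config.views:
            out = model.encode_view(view, feats)
            originals[view] = out
        for view in config.views:
            out = originals[view]
            scores = aggregate_attention(out.attention)
            masked, _ = model.mask_view(view, feats, scores, rng)
            aug_out = model.encode_view(view, feats, masked=masked)
            for label, o in ((view, out), (view + "_aug", aug_out)):
                z_local.append(model.project(label, "local", o.local))
                z_global.append(model.project(label, "global", o.global_))
                mol_of.append(feats.mol.id)
                view_of.append(label)
    local = ContrastBatch(z=nn.stack(z_local), mol_of=mol_of, view_of=view_of, level="local")
    global_ = ContrastBatch(z=nn.stack(z_global), mol_of=mol_of, view_of=view_of, level="global")
    return local, global_


def pretrain_step(batch: Sequence[MolFeatures], state: TrainState,
                  config: PretrainConfig) -> dict:
    """One optimization step on one batch; returns the loss record."""
    if len(batch) < 2:
        raise ValueError("a pre-training batch needs at least two molecules")
    model = state.model
    local, global_ = _forward_batch(model, batch, state.rng)
    weights = None if config.fixed_weight else state.states
    total, res_l, res_g = hierarchical_loss(
        local,
        global_,
        local_state=None if weights is None else weights["local"],
        global_state=None if weights is None else weights["global"],
        lambda_local=config.lambda_local,
        lambda_global=config.lambda_global,
        weight_mode=config.weight_mode,
        temperature=config.temperature,
    )
    state.optimizer.zero_grad()
    total.backward()
    state.optimizer.step()
    return {
        "total": total.item(),
        "local": res_l.per_type,
        "global": res_g.per_type,
        "local_total": res_l.total.item(),
        "global_total": res_g.total.item(),
    }


def _dwa_advance(state: TrainState, accum: dict, config: PretrainConfig):
    from .contrast import dwa_update

    for level in ("local", "global"):
        sums, counts = accum[level]
        means = {t: sums[t] / counts[t] for t in sums}
        if not config.fixed_weight:
            state.states[level] = dwa_update(state.states[level], means)


def run_pretraining(
    corpus: Sequence[Molecule],
    config: PretrainConfig,
    vocab: Vocabulary,
    out_dir=None,
) -> TrainState:
    """Run the full pre-training loop; writes a checkpoint and a diagnostics
    CSV when ``out_dir`` is given, and returns the final state either way."""
    if len(corpus) < 2 * config.batch_size:
        raise ValueError("corpus must hold at least two batches of molecules")
    feats = featurize(corpus, vocab, views=config.views)
    state = init_train_state(config, vocab)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    n = len(feats)
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        accum = {lvl: ({}, {}) for lvl in ("local", "global")}
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:
                continue
            record = pretrain_step([feats[i] for i in idx], state, config)
            epoch_losses.append(record["total"])
            for level in ("local", "global"):
                sums, counts = accum[level]
                for t, v in record[level].items():
                    sums[t] = sums.get(t, 0.0) + v
                    counts[t] = counts.get(t, 0) + 1
            if config.dwa_period == "step":
                _dwa_advance(state, accum, config)
                accum = {lvl: ({}, {}) for lvl in ("local", "global")}
        if config.dwa_period == "epoch":
            _dwa_advance(state, accum, config)
        state.epoch = epoch + 1
        state.trace.append(
            {
                "epoch": epoch + 1,
                "mean_loss": float(np.mean(epoch_losses)),
                "weights_local": dict(state.states["local"].weights),
                "weights_global": dict(state.states["global"].weights),
            }
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(state, out_dir / "checkpoint.npz")
        _write_diagnostics(state, out_dir / "diagnostics.csv")
    return state


def _write_diagnostics(state: TrainState, path):
    import csv as _csv

    types = state.states["global"].types
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["epoch", "mean_loss"]
                   + [f"w_local[{a}|{b}]" for a, b in types]
                   + [f"w_global[{a}|{b}]" for a, b in types])
        for row in state.trace:
            w.writerow(
                [row["epoch"], f"{row['mean_loss']:.6f}"]
                + [f"{row['weights_local'][t]:.6f}" for t in types]
                + [f"{row['weights_global'][t]:.6f}" for t in types]
            )


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def _state_meta(state: TrainState) -> dict:
    def ser_pts(pts: PairTypeState) -> dict:
        return {
            "types": [list(t) for t in pts.types],
            "weights": {"|".join(t): v for t, v in pts.weights.items()},
            "loss_prev": None if pts.loss_prev is None
            else {"|".join(t): v for t, v in pts.loss_prev.items()},
            "loss_last": None if pts.loss_last is None
            else {"|".join(t): v for t, v in pts.loss_last.items()},
            "p": pts.p,
        }

    return {
        "version": CHECKPOINT_VERSION,
        "config": dataclasses.asdict(state.model.config),
        "vocab": state.model.vocab.substructures,
        "epoch": state.epoch,
        "seed": state.model.config.seed,
        "states": {lvl: ser_pts(pts) for lvl, pts in state.states.items()},
    }


def save_checkpoint(state: TrainState, path) -> Path:
    path = Path(path)
    arrays = {f"param/{k}": v for k, v in state.model.state_dict().items()}
    arrays["meta"] = np.frombuffer(
        json.dumps(_state_meta(state)).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)
    return path if path.suffix == ".npz" else Path(str(path) + ".npz")


def load_checkpoint(path, vocab: Optional[Vocabulary] = None) -> TrainState:
    """Restore a checkpoint; raises on version mismatch without partial state."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta"]).decode("utf-8"))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"incompatible checkpoint version {meta.get('version')!r}; "
                f"expected {CHECKPOINT_VERSION!r}"
            )
        params = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    cfg_dict = dict(meta["config"])
    cfg_dict["views"] = tuple(cfg_dict["views"])
    # __post_init__ re-applies ablation switches; feed it the pre-switch fields
    config = PretrainConfig(**{k: v for k, v in cfg_dict.items()
                               if k in {f.name for f in dataclasses.fields(PretrainConfig)}})
    if vocab is None:
        vocab = Vocabulary(substructures=list(meta["vocab"]))
    state = init_train_state(config, vocab)
    state.model.load_state_dict(params)
    state.epoch = int(meta["epoch"])

    def de_pts(d: dict) -> PairTypeState:
        def keys(x):
            return None if x is None else {tuple(k.split("|")): v for k, v in x.items()}

        return PairTypeState(
            types=[tuple(t) for t in d["types"]],
            weights=keys(d["weights"]),
            loss_prev=keys(d["loss_prev"]),
            loss_last=keys(d["loss_last"]),
            p=int(d["p"]),
        )

    state.states = {lvl: de_pts(d) for lvl, d in meta["states"].items()}
    return state
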