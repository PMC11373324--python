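"""Transfer stage: representations from the pre-trained 1D and 2D encoders,
fine-tuning on molecular property prediction, and representation export.

The transfer representation of a molecule is the concatenation of
``mean(local, global)`` from the 1D encoder and ``mean(local, global)`` from
the 2D encoder — dimension 2h — so no 3D coordinates are needed at transfer
time even though the encoders were shaped by 3D geometry during
pre-training.  The property-prediction head is a 2-layer feed-forward
network; fine-tuning can update the encoders too (``mode="full"``) or freeze
them (``mode="probe"``, the fast path).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .nn import Adam, Tensor
from .chemio import Molecule, SplitResult, scaffold_split
from .pretrain import MolFeatures, MultiViewEncoderModel, TrainState, featurize

__all__ = [
    "MolecularRepresentation",
    "FinetuneResult",
    "representation_tensor",
    "extract_representation",
    "extract_many",
    "finetune_mpp",
    "evaluate_auc",
    "export_representations",
]


@dataclass
class MolecularRepresentation:
    vector: np.ndarray  # length 2h
    molecule_id: str
    checkpoint_id: str


@dataclass
class FinetuneResult:
    valid_auc: float
    test_auc: float
    split: SplitResult
    head_state: dict
    history: list


def _checkpoint_id(state: TrainState) -> str:
    return f"seed{state.model.config.seed}-epoch{state.epoch}"


def representation_tensor(model: MultiViewEncoderModel, feats: MolFeatures) -> Tensor:
    """Differentiable 2h-vector: [mean(local₁d, global₁d); mean(local₂d, global₂d)]."""
    out1 = model.enc1d(feats.seq)
    out2 = model.gt2d(feats.topo)
    r1 = (out1.local + out1.global_) * 0.5
    r2 = (out2.local + out2.global_) * 0.5
    return nn.concatenate([r1, r2], axis=0)


def extract_representation(mol: Molecule, state: TrainState) -> MolecularRepresentation:
    """Deterministic transfer representation of one molecule (1D + 2D only)."""
    feats = featurize([mol], state.model.vocab, views=("1d", "2d"))[0]
    vec = representation_tensor(state.model, feats).detach()
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"non-finite representation for {mol.id!r}")
    return MolecularRepresentation(
        vector=vec, molecule_id=mol.id, checkpoint_id=_checkpoint_id(state)
    )


def extract_many(mols: Sequence[Molecule], state: TrainState) -> np.ndarray:
    feats = featurize(mols, state.model.vocab, views=("1d", "2d"))
    return np.stack([representation_tensor(state.model, f).detach() for f in feats])


def evaluate_auc(scores, labels) -> float:
    """Rank-based ROC AUC (ties count 1/2); both classes must be present."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


class _Head(nn.Module):
    """2-layer feed-forward predictor on the 2h representation."""

    def __init__(self, in_dim: int, width: int, n_tasks: int, rng):
        self.lin1 = nn.Linear(in_dim, width, rng)
        self.lin2 = nn.Linear(width, n_tasks, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


def _bce_masked(logits: Tensor, y: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over observed labels (NaN labels masked out)."""
    m = Tensor(mask.astype(np.float64))
    y_t = Tensor(np.nan_to_num(y))
    per = logits.softplus() - logits * y_t
    return (per * m).sum() * (1.0 / max(mask.sum(), 1))


def _labels_matrix(mols: Sequence[Molecule], n_tasks: Optional[int] = None) -> np.ndarray:
    rows = []
    for m in mols:
        if m.label is None:
            raise ValueError(f"molecule {m.id!r} has no label")
        rows.append(np.atleast_1d(np.asarray(m.label, dtype=float)))
    if not rows:
        return np.zeros((0, n_tasks or 1))
    return np.stack(rows)


def _mean_auc(scores: np.ndarray, y: np.ndarray) -> float:
    aucs = []
    for t in range(y.shape[1]):
        obs = ~np.isnan(y[:, t])
        if obs.sum() and np.unique(y[obs, t]).size == 2:
            aucs.append(evaluate_auc(scores[obs, t], y[obs, t]))
    if not aucs:
        raise ValueError("no task with both classes present")
    return float(np.mean(aucs))


def finetune_mpp(
    dataset: Sequence[Molecule],
    state: TrainState,
    mode: str = "full",
    head_width: int = 32,
    epochs: int = 60,
    lr: float = 1e-3,
    seed: int = 0,
    fractions=(0.8, 0.1, 0.1),
) -> FinetuneResult:
    """Scaffold-split fine-tuning with validation-AUC model selection.

    ``mode="full"`` updates the encoders and the head; ``mode="probe"``
    freezes the encoders and trains the head on precomputed representations.
    """
    if mode not in ("full", "probe"):
        raise ValueError(f"unknown mode {mode!r}")
    split = scaffold_split(dataset, fractions, seed=seed)
    by_id = {m.id: m for m in dataset}
    parts = {
        name: [by_id[i] for i in ids]
        for name, ids in (
            ("train", split.train_ids),
            ("valid", split.valid_ids),
            ("test", split.test_ids),
        )
    }
    y_train = _labels_matrix(parts["train"])
    n_tasks = y_train.shape[1]
    y = {
        "train": y_train,
        "valid": _labels_matrix(parts["valid"], n_tasks),
        "test": _labels_matrix(parts["test"], n_tasks),
    }
    for t in range(n_tasks):
        obs = ~np.isnan(y["train"][:, t])
        if np.unique(y["train"][obs, t]).size < 2:
            raise ValueError(f"training partition has a single class for task {t}")

    model = state.model
    feats = {k: featurize(v, model.vocab, views=("1d", "2d")) for k, v in parts.items()}
    rng = np.random.default_rng(seed)
    head = _Head(2 * model.config.hidden_dim, head_width, n_tasks, rng)
    params = list(head.parameters())
    if mode == "full":
        params = params + model.parameters()
    opt = Adam(params, lr=lr)

    cached = None
    if mode == "probe":
        cached = {k: np.stack([representation_tensor(model, f).detach() for f in fs])
                  for k, fs in feats.items()}

    def predict(part: str) -> np.ndarray:
        if mode == "probe":
            return head(Tensor(cached[part])).detach()
        return np.stack(
            [head(representation_tensor(model, f)).detach() for f in feats[part]]
        )

    best = (-np.inf, None, None)
    history = []
    for epoch in range(epochs):
        if mode == "probe":
            logits = head(Tensor(cached["train"]))
        else:
            logits = nn.stack([head(representation_tensor(model, f)) for f in feats["train"]])
        mask = ~np.isnan(y["train"])
        loss = _bce_masked(logits, y["train"], mask)
        opt.zero_grad()
        loss.backward()
        opt.step()
        try:
            valid_auc = _mean_auc(predict("valid"), y["valid"])
        except ValueError:
            # degenerate validation partition: no class contrast to select on
            valid_auc = 0.5
        history.append({"epoch": epoch + 1, "loss": loss.item(), "valid_auc": valid_auc})
        if valid_auc > best[0]:
            best = (
                valid_auc,
                head.state_dict(),
                model.state_dict() if mode == "full" else None,
            )
    head.load_state_dict(best[1])
    if mode == "full" and best[2] is not None:
        model.load_state_dict(best[2])
    test_auc = _mean_auc(predict("test"), y["test"])
    return FinetuneResult(
        valid_auc=float(best[0]),
        test_auc=float(test_auc),
        split=split,
        head_state=best[1],
        history=history,
    )


def export_representations(
    mols: Sequence[Molecule], state: TrainState, path, manifest_path=None
) -> Path:
    """Write a CSV of representations (id + 2h columns) plus a JSON manifest."""
    path = Path(path)
    reps = extract_many(mols, state)
    header = "id," + ",".join(f"z{i}" for i in range(reps.shape[1]))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for m, r in zip(mols, reps):
            fh.write(m.id + "," + ",".join(f"{v:.12g}" for v in r) + "\n")
    manifest = {
        "checkpoint_id": _checkpoint_id(state),
        "n_molecules": len(mols),
        "dim": int(reps.shape[1]),
        "normalize": state.model.config.normalize,
    }
    manifest_path = Path(manifest_path) if manifest_path else path.with_suffix(".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return path
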