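"""Model/Results facade over the pre-training and transfer machinery.

``MultiViewModel`` is built from data (a list of molecules, or a DataFrame
with a ``smiles`` column) plus a :class:`~mvmol.pretrain.PretrainConfig`;
``fit()`` runs the contrastive pre-training and returns a
:class:`PretrainResults` carrying the trained encoders, the loss trace, the
dynamic pair-type weights, and convenience methods for representation
extraction, fine-tuning, export and checkpointing.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chemio import Molecule, Vocabulary
from .downstream import (
    FinetuneResult,
    export_representations,
    extract_many,
    finetune_mpp,
)
from .fixtures import toy_vocab
from .pretrain import (
    PretrainConfig,
    TrainState,
    init_train_state,
    load_checkpoint,
    run_pretraining,
    save_checkpoint,
)

__all__ = ["MultiViewModel", "PretrainResults"]


class MultiViewModel:
    """Multi-view contrastive representation model for molecules."""

    def __init__(
        self,
        molecules: Sequence[Molecule],
        config: Optional[PretrainConfig] = None,
        vocab: Optional[Vocabulary] = None,
    ):
        self.molecules = list(molecules)
        self.config = config or PretrainConfig()
        self.vocab = vocab or toy_vocab()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, smiles_column: str = "smiles",
                       label_column: Optional[str] = None, **kwargs) -> "MultiViewModel":
        mols = []
        for i, row in frame.iterrows():
            label = float(row[label_column]) if label_column else None
            mols.append(Molecule(id=str(row.get("id", f"mol{i}")),
                                 smiles=row[smiles_column], label=label))
        return cls(mols, **kwargs)

    def fit(self, out_dir=None) -> "PretrainResults":
        state = run_pretraining(self.molecules, self.config, self.vocab, out_dir=out_dir)
        return PretrainResults(self, state)

    def init_only(self) -> "PretrainResults":
        """Randomly initialized encoders without pre-training (the NoPretrain
        reference point)."""
        return PretrainResults(self, init_train_state(self.config, self.vocab))

    @classmethod
    def from_checkpoint(cls, path) -> "PretrainResults":
        state = load_checkpoint(path)
        model = cls([], config=state.model.config, vocab=state.model.vocab)
        return PretrainResults(model, state)


class PretrainResults:
    """Fitted encoders plus training diagnostics."""

    def __init__(self, model: MultiViewModel, state: TrainState):
        self.model = model
        self.state = state

    # -- diagnostics ----------------------------------------------------------
    @property
    def loss_trace(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"epoch": r["epoch"], "mean_loss": r["mean_loss"]} for r in self.state.trace]
        )

    @property
    def pair_weights(self) -> pd.DataFrame:
        rows = []
        for r in self.state.trace:
            for level in ("local", "global"):
                for t, w in r[f"weights_{level}"].items():
                    rows.append({"epoch": r["epoch"], "level": level,
                                 "pair": "|".join(t), "weight": w})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cfg = self.state.model.config
        lines = [
            "Multi-view contrastive pre-training results",
            "=" * 44,
            f"views:           {', '.join(cfg.views)}",
            f"hidden dim:      {cfg.hidden_dim}   layers: {cfg.n_layers}   heads: {cfg.n_heads}",
            f"projection dim:  {cfg.proj_dim} (normalize={cfg.normalize})",
            f"mask ratio:      {cfg.mask_ratio}%  weight mode: {cfg.weight_mode}",
            f"epochs run:      {self.state.epoch}",
        ]
        if self.state.trace:
            first = self.state.trace[0]["mean_loss"]
            last = self.state.trace[-1]["mean_loss"]
            lines.append(f"mean loss:       {first:.4f} (first epoch) → {last:.4f} (final epoch)")
        for level in ("local", "global"):
            w = self.state.states[level].weights
            if w:
                hi = max(w, key=w.get)
                lo = min(w, key=w.get)
                lines.append(
                    f"{level:6s} weights: max {w[hi]:.3f} ({'|'.join(hi)}), "
                    f"min {w[lo]:.3f} ({'|'.join(lo)})"
                )
        return "\n".join(lines)

    # -- transfer -------------------------------------------------------------
    def extract(self, molecules: Sequence[Molecule]) -> pd.DataFrame:
        reps = extract_many(molecules, self.state)
        frame = pd.DataFrame(reps, columns=[f"z{i}" for i in range(reps.shape[1])])
        frame.insert(0, "id", [m.id for m in molecules])
        return frame

    def finetune(self, dataset: Sequence[Molecule], **kwargs) -> FinetuneResult:
        return finetune_mpp(dataset, self.state, **kwargs)

    def export(self, molecules: Sequence[Molecule], path, **kwargs):
        return export_representations(molecules, self.state, path, **kwargs)

    def save(self, path):
        return save_checkpoint(self.state, path)

    def similarity(self, molecules: Sequence[Molecule]) -> np.ndarray:
        """Cosine-similarity matrix of transfer representations — the plain
        retrieval utility."""
        reps = extract_many(molecules, self.state)
        norms = np.linalg.norm(reps, axis=1, keepdims=True)
        unit = reps / np.maximum(norms, 1e-12)
        return unit @ unit.T
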