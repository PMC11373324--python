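import numpy as np
import pytest

from mvmol.fixtures import FixtureSpec, builtin_molecules, toy_vocab
from mvmol.pretrain import (
    PretrainConfig,
    featurize,
    init_train_state,
    run_pretraining,
)


@pytest.fixture(scope="session")
def vocab():
    return toy_vocab()


@pytest.fixture(scope="session")
def toy8():
    return builtin_molecules(FixtureSpec(n_molecules=8, seed=7))


@pytest.fixture(scope="session")
def corpus64():
    return builtin_molecules(FixtureSpec(n_molecules=64, seed=7))


def small_config(**overrides) -> PretrainConfig:
    """A reduced-width configuration for fast unit tests."""
    base = dict(
        hidden_dim=32,
        n_layers=2,
        n_heads=4,
        proj_dim=16,
        gin_layers=2,
        schnet_interactions=2,
        n_kernel=8,
        batch_size=4,
        epochs=2,
        seed=11,
    )
    base.update(overrides)
    return PretrainConfig(**base)


def mean_pair_cosine(state, feats, view_a="2d", view_b="3d", level="global"):
    """Mean cosine similarity between two views' projections per molecule."""
    vals = []
    for f in feats:
        oa = state.model.encode_view(view_a, f)
        ob = state.model.encode_view(view_b, f)
        rep_a = oa.global_ if level == "global" else oa.local
        rep_b = ob.global_ if level == "global" else ob.local
        za = state.model.project(view_a, level, rep_a).detach()
        zb = state.model.project(view_b, level, rep_b).detach()
        vals.append(float(za @ zb / (np.linalg.norm(za) * np.linalg.norm(zb))))
    return float(np.mean(vals))


@pytest.fixture(scope="session")
def pretrained(corpus64, vocab):
    """The toy pre-training run (default configuration, fixed seed), with the
    positive-pair cosine measured at initialization and after training."""
    config = PretrainConfig(seed=1)
    feats = featurize(corpus64[:16], vocab)
    init_state = init_train_state(config, vocab)
    cos_init = mean_pair_cosine(init_state, feats)
    state = run_pretraining(corpus64, config, vocab)
    cos_final = mean_pair_cosine(state, feats)
    return {"state": state, "cos_init": cos_init, "cos_final": cos_final, "config": config}
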