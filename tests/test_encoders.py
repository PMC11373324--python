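"""Shape contracts, attention normalization, and the symmetry properties of
the three encoders (permutation equivariance/invariance, rigid-motion
invariance, bias-to-zero reduction)."""

import numpy as np
import pytest

from mvmol.chemio import (
    GeometryGraph,
    Molecule,
    TopologyGraph,
    Vocabulary,
    build_geometry_graph,
    build_topology_graph,
    tokenize_espf,
)
from mvmol.encoders import (
    Encoder1D,
    EncoderConfig,
    GIN,
    GraphTransformer2D,
    GraphTransformer3D,
    ProjectionHead,
    SchNet,
    pool,
)
from mvmol.nn import Tensor


def cfg1d(vocab, **kw):
    base = dict(hidden_dim=32, n_layers=2, n_heads=4, n_kernel=8,
                vocab_size=vocab.size_with_reserved, view="1d")
    base.update(kw)
    return EncoderConfig(**base)


def cfg_graph(**kw):
    base = dict(hidden_dim=32, n_layers=2, n_heads=4, n_kernel=8, view="2d")
    base.update(kw)
    return EncoderConfig(**base)


@pytest.fixture(scope="module")
def small_vocab():
    return Vocabulary(substructures=["CC", "C", "O", "N", "c1ccccc1", "c", "1", "(", ")", "="])


def _mol(smiles, coords=None):
    return Molecule(id="x", smiles=smiles, coords=coords)


def permute_topology(g: TopologyGraph, perm: np.ndarray) -> TopologyGraph:
    inv = np.argsort(perm)
    return TopologyGraph(
        atom_features=g.atom_features[perm],
        bonds=[(int(inv[i]), int(inv[j]), t) for i, j, t in g.bonds],
        degrees=g.degrees[perm],
        spd=g.spd[np.ix_(perm, perm)],
    )


def permute_geometry(g: GeometryGraph, perm: np.ndarray) -> GeometryGraph:
    return GeometryGraph(
        coords=g.coords[perm],
        dist=g.dist[np.ix_(perm, perm)],
        dist_sum=g.dist_sum[perm],
        kernel_params=g.kernel_params,
        atom_types=g.atom_types[perm],
    )


# ---------------------------------------------------------------------------
# configuration and pooling
# ---------------------------------------------------------------------------


def test_config_validation():
    with pytest.raises(ValueError):
        EncoderConfig(hidden_dim=30, n_heads=4)
    with pytest.raises(ValueError):
        EncoderConfig(n_layers=4, local_layer=5)
    assert EncoderConfig(n_layers=4).local_layer == 2  # middle layer


def test_pool_examples():
    assert np.allclose(pool(Tensor([[1.0, 2.0], [3.0, 4.0]])).data, [2.0, 3.0])
    assert np.allclose(pool(Tensor([[5.0, 6.0]])).data, [5.0, 6.0])
    with pytest.raises(ValueError):
        pool(Tensor(np.zeros((0, 4))))


def test_projection_head_unit_norm_and_instantiation():
    rng = np.random.default_rng(0)
    head = ProjectionHead(8, 4, rng, normalize=True)
    z = head(Tensor(rng.normal(size=8)))
    assert abs(np.linalg.norm(z.data) - 1.0) < 1e-6
    raw = ProjectionHead(8, 4, rng, normalize=False)
    raw.lin1.weight.data[:] = 0
    raw.lin1.bias.data[:] = 0
    raw.lin2.weight.data[:] = 0
    raw.lin2.bias.data[:] = 0
    assert np.allclose(raw(Tensor(np.ones(8))).data, 0.0)


# ---------------------------------------------------------------------------
# 1D encoder
# ---------------------------------------------------------------------------


def test_encode_1d_shapes_and_row_sums(small_vocab):
    rng = np.random.default_rng(1)
    enc = Encoder1D(cfg1d(small_vocab), rng)
    seq = tokenize_espf("CCOC(=O)C", small_vocab)
    out = enc(seq)
    e, h = seq.e, 32
    assert out.layer_states.shape == (3, e, h)
    assert out.attention.shape == (2, 4, e, e)
    assert np.abs(out.attention.sum(axis=-1) - 1.0).max() < 1e-6
    assert out.local.shape == (h,) and out.global_.shape == (h,)


def test_encode_1d_position_sensitivity(small_vocab):
    """Swapping token order changes the output (positional embedding)."""
    from mvmol.chemio import ESPFSequence

    rng = np.random.default_rng(2)
    enc = Encoder1D(cfg1d(small_vocab), rng)
    a = ESPFSequence(tokens=[0, 2], positions=[0, 1], source_spans=[(0, 2), (2, 3)],
                     token_strings=["CC", "O"])
    b = ESPFSequence(tokens=[2, 0], positions=[0, 1], source_spans=[(0, 1), (1, 3)],
                     token_strings=["O", "CC"])
    assert not np.allclose(enc(a).global_.data, enc(b).global_.data)


# ---------------------------------------------------------------------------
# GIN
# ---------------------------------------------------------------------------


def test_gin_single_atom_is_mlp_of_scaled_embedding():
    rng = np.random.default_rng(3)
    gin = GIN(cfg_graph(gin_layers=2), rng)
    g = build_topology_graph(_mol("C"))
    out = gin(g).values.data
    x = (gin.atom_emb(g.atom_features[:, 0]) + gin.charge_emb(g.atom_features[:, 1]))
    for layer in range(2):
        x = gin.mlps[layer]((1.0 + gin.eps[layer]) * x)
    assert np.allclose(out, x.data)


def test_gin_permutation_equivariance():
    rng = np.random.default_rng(4)
    gin = GIN(cfg_graph(), rng)
    g = build_topology_graph(_mol("CC(=O)Oc1ccccc1C(=O)O"))
    base = gin(g).values.data
    prng = np.random.default_rng(7)
    for _ in range(3):
        perm = prng.permutation(g.d)
        assert np.allclose(gin(permute_topology(g, perm)).values.data, base[perm], atol=1e-10)


def test_gin_isomorphic_graphs_same_multiset():
    """A 4-node path relabeled by a permutation yields the same multiset of
    atom vectors."""
    rng = np.random.default_rng(5)
    gin = GIN(cfg_graph(), rng)
    g = build_topology_graph(_mol("CCCO"))
    perm = np.array([3, 1, 0, 2])
    a = gin(g).values.data
    b = gin(permute_topology(g, perm)).values.data
    assert np.allclose(np.sort(a, axis=0), np.sort(b, axis=0), atol=1e-10)


# ---------------------------------------------------------------------------
# SchNet
# ---------------------------------------------------------------------------


def _geom(smiles, seed=0):
    rng = np.random.default_rng(seed)
    m = _mol(smiles)
    m.coords = rng.normal(scale=2.0, size=(m.d, 3))
    return build_geometry_graph(m)


def test_schnet_rigid_motion_invariance():
    rng = np.random.default_rng(6)
    net = SchNet(cfg_graph(view="3d"), rng)
    g = _geom("CCOCC")
    base = net(g).values.data
    q, _ = np.linalg.qr(np.random.default_rng(8).normal(size=(3, 3)))
    m2 = _mol("CCOCC")
    m2.coords = g.coords @ q.T + 5.0
    g2 = build_geometry_graph(m2)
    assert np.abs(net(g2).values.data - base).max() < 1e-5


def test_schnet_single_atom_skips_interactions():
    rng = np.random.default_rng(7)
    net = SchNet(cfg_graph(view="3d"), rng)
    m = _mol("C")
    m.coords = np.zeros((1, 3))
    g = build_geometry_graph(m)
    out = net(g).values.data
    # empty neighbor sum: each interaction adds out2(ssp(out1(0)))
    from mvmol.nn import Tensor as T, shifted_softplus

    x = net.atom_emb(g.atom_types)
    for layer in range(len(net.filters)):
        msg = T(np.zeros_like(x.data))
        x = x + net.out2[layer](shifted_softplus(net.out1[layer](msg)))
    assert np.allclose(out, x.data)


def test_schnet_permutation_equivariance():
    rng = np.random.default_rng(8)
    net = SchNet(cfg_graph(view="3d"), rng)
    g = _geom("CCOCN")
    base = net(g).values.data
    perm = np.random.default_rng(9).permutation(g.d)
    assert np.allclose(net(permute_geometry(g, perm)).values.data, base[perm], atol=1e-10)


# ---------------------------------------------------------------------------
# graph transformers
# ---------------------------------------------------------------------------


def _zero_2d_extras(enc: GraphTransformer2D):
    enc.degree_emb.weight.data[:] = 0
    for emb in enc.spd_bias:
        emb.weight.data[:] = 0


def _zero_3d_extras(enc: GraphTransformer3D):
    enc.sum_proj.weight.data[:] = 0
    enc.sum_proj.bias.data[:] = 0
    for lin in enc.bias_proj:
        lin.weight.data[:] = 0


def test_gt2d_zero_bias_reduces_to_plain_transformer():
    rng = np.random.default_rng(10)
    enc = GraphTransformer2D(cfg_graph(), rng)
    _zero_2d_extras(enc)
    g = build_topology_graph(_mol("CC(=O)Oc1ccccc1"))
    out = enc(g)
    atoms = enc.gin(g)
    states, attns = enc.stack(atoms.values)  # no biases at all
    assert np.abs(out.layer_states[-1] - states[-1].data).max() < 1e-6
    assert np.abs(out.attention - np.stack(attns)).max() < 1e-6


def test_gt2d_attention_rows_sum_to_one_despite_bias():
    rng = np.random.default_rng(11)
    enc = GraphTransformer2D(cfg_graph(), rng)
    out = enc(build_topology_graph(_mol("c1ccncc1")))
    assert np.abs(out.attention.sum(axis=-1) - 1.0).max() < 1e-6


def test_gt2d_permutation_invariance_of_pooled_vectors():
    rng = np.random.default_rng(12)
    enc = GraphTransformer2D(cfg_graph(), rng)
    g = build_topology_graph(_mol("CC(=O)Nc1ccc(O)cc1"))
    base_local = enc(g).local.data
    base_global = enc(g).global_.data
    prng = np.random.default_rng(13)
    for _ in range(10):
        perm = prng.permutation(g.d)
        out = enc(permute_topology(g, perm))
        assert np.abs(out.local.data - base_local).max() < 1e-5
        assert np.abs(out.global_.data - base_global).max() < 1e-5


def test_gt3d_rigid_motion_invariance_end_to_end():
    rng = np.random.default_rng(14)
    enc = GraphTransformer3D(cfg_graph(view="3d"), rng)
    g = _geom("CC(=O)OC", seed=20)
    base = enc(g)
    mrng = np.random.default_rng(21)
    for _ in range(10):
        q, _ = np.linalg.qr(mrng.normal(size=(3, 3)))
        m2 = _mol("CC(=O)OC")
        m2.coords = g.coords @ q.T + mrng.normal(size=3) * 10
        out = enc(build_geometry_graph(m2))
        assert np.abs(out.local.data - base.local.data).max() < 1e-5
        assert np.abs(out.global_.data - base.global_.data).max() < 1e-5


def test_gt3d_zero_bias_reduces_to_plain_transformer():
    rng = np.random.default_rng(15)
    enc = GraphTransformer3D(cfg_graph(view="3d"), rng)
    _zero_3d_extras(enc)
    g = _geom("CCNCC", seed=22)
    out = enc(g)
    atoms = enc.schnet(g)
    states, attns = enc.stack(atoms.values)
    assert np.abs(out.layer_states[-1] - states[-1].data).max() < 1e-6
    assert np.abs(out.attention - np.stack(attns)).max() < 1e-6
    assert out.attention.shape == (2, 4, g.d, g.d)


def test_gt3d_permutation_invariance():
    rng = np.random.default_rng(16)
    enc = GraphTransformer3D(cfg_graph(view="3d"), rng)
    g = _geom("CCOC(N)C", seed=23)
    base = enc(g)
    prng = np.random.default_rng(24)
    for _ in range(5):
        perm = prng.permutation(g.d)
        out = enc(permute_geometry(g, perm))
        assert np.abs(out.local.data - base.local.data).max() < 1e-5
        assert np.abs(out.global_.data - base.global_.data).max() < 1e-5
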