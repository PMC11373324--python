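"""The contrastive objective: pair-type taxonomy, closed forms, the literal
triple-loop oracle, DWA weight updates, and the hierarchical combination."""

import itertools
import math

import numpy as np
import pytest

from mvmol.contrast import (
    VIEW_LABELS,
    ContrastBatch,
    PairTypeState,
    all_pair_types,
    amc_loss,
    dwa_update,
    hierarchical_loss,
    pair_type,
)


# ---------------------------------------------------------------------------
# pair types
# ---------------------------------------------------------------------------


def test_pair_type_unordered_and_distinct():
    assert pair_type("1d", "2d") == pair_type("2d", "1d")
    assert pair_type("2d", "2d_aug") != pair_type("2d", "3d")
    with pytest.raises(ValueError):
        pair_type("2d", "2d")


def test_fifteen_types_for_six_views():
    types = all_pair_types(VIEW_LABELS)
    assert len(types) == 15 == len(set(types))
    enumerated = {tuple(sorted(p)) for p in itertools.combinations(VIEW_LABELS, 2)}
    assert set(types) == enumerated


# ---------------------------------------------------------------------------
# AMCLoss
# ---------------------------------------------------------------------------


def _random_batch(rng, n_mols, views, dim=6):
    zs, mol_of, view_of = [], [], []
    for a in range(n_mols):
        for v in views:
            z = rng.normal(size=dim)
            zs.append(z / np.linalg.norm(z))
            mol_of.append(f"m{a}")
            view_of.append(v)
    return ContrastBatch(z=np.array(zs), mol_of=mol_of, view_of=view_of)


def _oracle_amc(batch, weights, weight_mode="as_written"):
    """Literal triple loop over anchors, positives and negatives."""
    z = np.asarray(batch.z if not hasattr(batch.z, "data") else batch.z.data)
    mol_of = list(batch.mol_of)
    mols = list(dict.fromkeys(mol_of))
    terms = {}
    total = 0.0
    for a in mols:
        Ma = [i for i, m in enumerate(mol_of) if m == a]
        other = [o for o, m in enumerate(mol_of) if m != a]
        mol_sum = 0.0
        for i in Ma:
            denom = sum(math.exp(float(z[i] @ z[o])) for o in other)
            for j in Ma:
                if j == i:
                    continue
                w = weights.get(pair_type(batch.view_of[i], batch.view_of[j]), 1.0)
                if weight_mode == "as_written":
                    t = -math.log(w * math.exp(float(z[i] @ z[j])) / denom)
                else:
                    t = w * (-math.log(math.exp(float(z[i] @ z[j])) / denom))
                terms[(i, j)] = t
                mol_sum += t
        total += mol_sum
    return total / len(mols), terms


def test_closed_form_two_molecules_two_views():
    """All embeddings equal and w=1: every term is log 2, per-molecule loss
    2·log 2, for any common dot product (factors cancel)."""
    u = np.ones(4) / 2.0
    batch = ContrastBatch(
        z=np.stack([u, u, u, u]),
        mol_of=["a", "a", "b", "b"],
        view_of=["2d", "2d_aug", "2d", "2d_aug"],
    )
    res = amc_loss(batch)
    assert abs(res.total.item() - 2 * math.log(2)) < 1e-9
    assert all(abs(t - math.log(2)) < 1e-9 for t in res.terms.values())


def test_matches_triple_loop_oracle_on_random_batches():
    rng = np.random.default_rng(17)
    for trial in range(100):
        n_mols = int(rng.integers(2, 5))
        n_views = int(rng.integers(2, 7))
        views = list(VIEW_LABELS[:n_views])
        batch = _random_batch(rng, n_mols, views)
        state = PairTypeState.for_views(views)
        K = state.K
        raw = rng.uniform(0.3, 2.0, size=K)
        w = K * raw / raw.sum()
        state.weights = {t: float(w[k]) for k, t in enumerate(state.types)}
        mode = "as_written" if trial % 2 == 0 else "outside"
        res = amc_loss(batch, state, weight_mode=mode)
        o_total, o_terms = _oracle_amc(batch, state.weights, mode)
        assert abs(res.total.item() - o_total) < 1e-6
        for key, val in o_terms.items():
            assert abs(res.terms[key] - val) < 1e-6


def test_doubling_one_weight_shifts_only_that_type():
    rng = np.random.default_rng(18)
    batch = _random_batch(rng, 3, ["1d", "2d", "3d"])
    state = PairTypeState.for_views(["1d", "2d", "3d"])
    base = amc_loss(batch, state)
    t0 = pair_type("1d", "2d")
    state.weights[t0] = 2.0
    bumped = amc_loss(batch, state)
    for key in base.terms:
        i, j = key
        delta = bumped.terms[key] - base.terms[key]
        if pair_type(batch.view_of[i], batch.view_of[j]) == t0:
            assert abs(delta + math.log(2)) < 1e-12
        else:
            assert abs(delta) < 1e-12


def test_single_molecule_batch_rejected():
    batch = _random_batch(np.random.default_rng(0), 2, ["1d", "2d"])
    solo = ContrastBatch(z=np.asarray(batch.z)[:2], mol_of=["a", "a"], view_of=["1d", "2d"])
    with pytest.raises(ValueError):
        amc_loss(solo)


def test_loss_decreases_when_positive_dot_increases():
    """Monotonicity in z_i·z_j, everything else held fixed — checked on the
    oracle's explicit formula by perturbing one positive dot product."""
    rng = np.random.default_rng(19)
    batch = _random_batch(rng, 2, ["2d", "3d"])
    z = np.asarray(batch.z)
    dots = z @ z.T
    mol_of = list(batch.mol_of)

    def loss_from_dots(dmat):
        total = 0.0
        mols = list(dict.fromkeys(mol_of))
        for a in mols:
            Ma = [i for i, m in enumerate(mol_of) if m == a]
            other = [o for o, m in enumerate(mol_of) if m != a]
            for i in Ma:
                denom = sum(math.exp(dmat[i, o]) for o in other)
                for j in Ma:
                    if j != i:
                        total += -math.log(math.exp(dmat[i, j]) / denom)
        return total / len(mols)

    base = loss_from_dots(dots)
    bumped = dots.copy()
    bumped[0, 1] += 0.05  # one anchor-positive dot, nothing else
    assert loss_from_dots(bumped) < base


def test_molecule_order_permutation_invariance():
    rng = np.random.default_rng(20)
    batch = _random_batch(rng, 4, ["1d", "2d", "2d_aug"])
    base = amc_loss(batch).total.item()
    z = np.asarray(batch.z)
    idx = np.arange(len(batch.mol_of)).reshape(4, 3)[::-1].ravel()  # reverse molecules
    shuffled = ContrastBatch(
        z=z[idx],
        mol_of=[batch.mol_of[i] for i in idx],
        view_of=[batch.view_of[i] for i in idx],
    )
    assert abs(amc_loss(shuffled).total.item() - base) < 1e-9


# ---------------------------------------------------------------------------
# DWA
# ---------------------------------------------------------------------------


def _state_with_history(types, prev, last, p=2):
    return PairTypeState(
        types=types,
        loss_prev={t: prev[k] for k, t in enumerate(types)},
        loss_last={t: last[k] for k, t in enumerate(types)},
        p=p,
    )


def test_dwa_equal_ratios_give_unit_weights():
    types = all_pair_types(["1d", "2d", "3d"])
    st = _state_with_history(types, [1.0] * 3, [0.7] * 3)
    new = dwa_update(st, {t: 0.5 for t in types})
    assert all(abs(w - 1.0) < 1e-12 for w in new.weights.values())


def test_dwa_two_type_worked_example():
    """Ratios (1.0, 0.5) for K=2 give weights 2e^r/Σe^r ≈ (1.244919, 0.755081)."""
    types = [("1d", "2d"), ("1d", "3d")]
    st = _state_with_history(types, [2.0, 2.0], [1.0, 2.0])
    # the update uses ratio = current / most-recent: (1.0/1.0, 1.0/2.0)
    new = dwa_update(st, {types[0]: 1.0, types[1]: 1.0})
    assert abs(new.weights[types[0]] - 1.244919) < 1e-5
    assert abs(new.weights[types[1]] - 0.755081) < 1e-5
    assert abs(sum(new.weights.values()) - 2.0) < 1e-9


def test_dwa_first_two_periods_unit_weights_and_sum_invariant():
    types = all_pair_types(VIEW_LABELS)
    st = PairTypeState.for_views(VIEW_LABELS)
    rng = np.random.default_rng(21)
    for period in range(6):
        losses = {t: float(rng.uniform(0.5, 3.0)) for t in types}
        st = dwa_update(st, losses)
        assert abs(sum(st.weights.values()) - st.K) < 1e-9
        assert all(w > 0 for w in st.weights.values())
        if period < 1:  # weights for periods 1–2 stay at 1
            assert all(abs(w - 1.0) < 1e-12 for w in st.weights.values())


def test_dwa_weight_monotone_in_own_ratio():
    types = [("1d", "2d"), ("1d", "3d"), ("2d", "3d")]
    weights = []
    for own in (0.6, 0.9, 1.3):
        st = _state_with_history(types, [1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        current = {types[0]: own, types[1]: 1.0, types[2]: 1.0}
        new = dwa_update(st, current)
        weights.append(new.weights[types[0]])
    assert weights[0] < weights[1] < weights[2]


def test_dwa_zero_previous_loss_ratio_convention():
    types = [("1d", "2d"), ("1d", "3d")]
    st = _state_with_history(types, [1.0, 1.0], [0.0, 1.0])
    new = dwa_update(st, {t: 1.0 for t in types})
    # zero-prev type gets ratio 1, same as the other → both weights 1
    assert all(abs(w - 1.0) < 1e-12 for w in new.weights.values())


# ---------------------------------------------------------------------------
# hierarchical combination
# ---------------------------------------------------------------------------


def test_hierarchical_lambda_and_additivity():
    rng = np.random.default_rng(22)
    local = _random_batch(rng, 3, ["1d", "2d"])
    global_ = _random_batch(rng, 3, ["1d", "2d"])
    total, res_l, res_g = hierarchical_loss(local, global_)
    assert abs(total.item() - (res_l.total.item() + res_g.total.item())) < 1e-9
    only_global, _, rg = hierarchical_loss(local, global_, lambda_local=0.0)
    assert abs(only_global.item() - rg.total.item()) < 1e-12
    doubled, _, _ = hierarchical_loss(local, local)
    assert abs(doubled.item() - 2 * amc_loss(local).total.item()) < 1e-9


def test_hierarchical_rejects_mismatched_levels():
    rng = np.random.default_rng(23)
    a = _random_batch(rng, 2, ["1d", "2d"])
    b = _random_batch(rng, 2, ["1d", "3d"])
    with pytest.raises(ValueError):
        hierarchical_loss(a, b)
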