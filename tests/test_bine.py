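"""Bipartite embedding: shared-partner matrices, walks, gradient steps."""

import numpy as np
import pytest

from hetdti import (
    BineHyperparams,
    BipartiteDTINetwork,
    EntityRegistry,
    cohits_homogeneous,
    explicit_update,
    generate_walks,
    implicit_update,
    train_bine,
)
from hetdti.bine import CoHitsMatrix, EmbeddingTable

from conftest import SMALL_BINE


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _random_network(rng, m, n):
    adj = (rng.random((m, n)) < 0.5).astype(float)
    adj[:, 0] = 1.0
    adj[0, :] = 1.0
    reg = EntityRegistry(
        tuple(f"d{i}" for i in range(m)), tuple(f"t{j}" for j in range(n))
    )
    return BipartiteDTINetwork(reg, adj)


class TestCoHits:
    def test_worked_example(self, toy_network):
        homo = cohits_homogeneous(toy_network, "drug")
        assert homo.values[0, 1] == 1.0  # Drug1, Drug2 share Target2
        assert homo.values[0, 2] == 0.0  # Drug1, Drug3 share nothing

    def test_all_zero(self):
        reg = EntityRegistry(("d1",), ("t1",))
        with pytest.warns(UserWarning):
            net = BipartiteDTINetwork(reg, np.zeros((1, 1)))
        assert cohits_homogeneous(net, "drug").values[0, 0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("side", ["drug", "target"])
    def test_equals_shared_partner_count_oracle(self, seed, side):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(2, 21), rng.integers(2, 21)
        net = _random_network(rng, m, n)
        homo = cohits_homogeneous(net, side).values
        mat = net.adjacency if side == "drug" else net.adjacency.T
        k = mat.shape[0]
        expect = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                expect[i, j] = sum(mat[i, p] * mat[j, p] for p in range(mat.shape[1]))
        np.testing.assert_allclose(homo, expect)


class TestWalks:
    def _chain(self):
        vals = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        return CoHitsMatrix("drug", vals)

    def test_restart_one_keeps_start_vertex_only(self):
        params = BineHyperparams(restart_prob=1.0, stop_prob=0.15, max_walks=4)
        corpus = generate_walks(self._chain(), params, np.random.default_rng(0))
        for seq in corpus.sequences:
            assert set(seq) == {seq[0]}

    def test_stop_one_gives_length_one(self):
        params = BineHyperparams(stop_prob=1.0, max_walks=4)
        corpus = generate_walks(self._chain(), params, np.random.default_rng(0))
        assert all(len(seq) == 1 for seq in corpus.sequences)

    def test_seed_reproducible(self):
        params = BineHyperparams(max_walks=6, seed=42)
        a = generate_walks(self._chain(), params)
        b = generate_walks(self._chain(), params)
        assert a.sequences == b.sequences

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError, match="no walkable"):
            generate_walks(CoHitsMatrix("drug", np.zeros((3, 3))), BineHyperparams())

    def test_transition_frequencies_match_weights(self):
        # uneven weights from the middle of a 3-vertex chain: 1 vs 3
        vals = np.array([[0, 1, 0], [1, 0, 3], [0, 3, 0]], dtype=float)
        params = BineHyperparams(
            stop_prob=0.15, restart_prob=0.0, max_walks=4000, min_walks=1
        )
        corpus = generate_walks(CoHitsMatrix("drug", vals), params, np.random.default_rng(7))
        taken = {0: 0, 2: 0}
        for seq in corpus.sequences:
            for a, b in zip(seq, seq[1:]):
                if a == 1:
                    taken[b] += 1
        total = taken[0] + taken[2]
        p_hat = taken[2] / total
        p_true = 0.75
        se = np.sqrt(p_true * (1 - p_true) / total)
        assert total > 10_000
        assert abs(p_hat - p_true) < 3 * se


class TestExplicitUpdate:
    def test_zero_weight_is_identity(self):
        u, v = np.ones(3), np.full(3, 2.0)
        u2, v2 = explicit_update(u, v, 0.0, gamma=1.0, lr=0.5)
        np.testing.assert_array_equal(u2, u)
        np.testing.assert_array_equal(v2, v)

    def test_origin_is_fixed_point(self):
        u, v = np.zeros(2), np.zeros(2)
        u2, v2 = explicit_update(u, v, 1.0, gamma=1.0, lr=1.0)
        np.testing.assert_array_equal(u2, 0)
        np.testing.assert_array_equal(v2, 0)

    def test_inputs_not_mutated(self):
        u, v = np.ones(2), np.ones(2)
        explicit_update(u, v, 1.0, gamma=1.0, lr=0.1)
        np.testing.assert_array_equal(u, 1)

    def test_matches_finite_difference_gradient(self):
        rng = np.random.default_rng(1)
        gamma, w = 0.7, 1.0
        for _ in range(5):
            u, v = rng.normal(size=4), rng.normal(size=4)
            u2, _ = explicit_update(u, v, w, gamma, lr=1.0)
            step_u = u2 - u
            h = 1e-6
            num = np.zeros(4)
            for d in range(4):
                up, um = u.copy(), u.copy()
                up[d] += h
                um[d] -= h
                f = lambda uu: gamma * w * np.log(_sigmoid(uu @ v))
                num[d] = (f(up) - f(um)) / (2 * h)
            np.testing.assert_allclose(step_u, num, rtol=1e-4, atol=1e-8)

    def test_repeated_ascent_drives_sigma_to_one(self):
        # single-edge closed-form behaviour: sigma(u.v) rises monotonically
        u, v = np.full(4, 0.1), np.full(4, 0.1)
        last = _sigmoid(u @ v)
        for _ in range(300):
            u, v = explicit_update(u, v, 1.0, gamma=1.0, lr=0.1)
            cur = _sigmoid(u @ v)
            assert cur >= last
            last = cur
        assert last > 0.99


class TestImplicitUpdate:
    def _tables(self, rng, n=6, dim=4):
        return EmbeddingTable(
            "drug", rng.normal(size=(n, dim)), rng.normal(size=(n, dim))
        )

    def test_zero_weight_is_identity(self):
        tables = self._tables(np.random.default_rng(0))
        out = implicit_update(tables, 0, 1, [2, 3], weight=0.0, lr=0.5)
        np.testing.assert_array_equal(out.vectors, tables.vectors)
        np.testing.assert_array_equal(out.context_vectors, tables.context_vectors)

    def test_unknown_vertex_errors(self):
        tables = self._tables(np.random.default_rng(0))
        with pytest.raises(ValueError, match="unknown vertex"):
            implicit_update(tables, 0, 99, [], weight=1.0, lr=0.1)

    def test_matches_finite_difference_gradient(self):
        rng = np.random.default_rng(2)
        weight = 0.4
        tables = self._tables(rng)
        center, context, negs = 0, 1, [2, 3]
        out = implicit_update(tables, center, context, negs, weight, lr=1.0)
        step = out.vectors[center] - tables.vectors[center]

        def objective(u):
            th = tables.context_vectors
            val = np.log(_sigmoid(u @ th[context]))
            for z in negs:
                val += np.log(_sigmoid(-(u @ th[z])))
            return weight * val

        h = 1e-6
        num = np.zeros(4)
        u0 = tables.vectors[center]
        for d in range(4):
            up, um = u0.copy(), u0.copy()
            up[d] += h
            um[d] -= h
            num[d] = (objective(up) - objective(um)) / (2 * h)
        np.testing.assert_allclose(step, num, rtol=1e-4, atol=1e-8)

    def test_small_step_increases_objective(self):
        rng = np.random.default_rng(3)
        tables = self._tables(rng)
        weight, lr = 0.4, 1e-4

        def objective(tab):
            u = tab.vectors[0]
            th = tab.context_vectors
            return weight * (
                np.log(_sigmoid(u @ th[1]))
                + np.log(_sigmoid(-(u @ th[2])))
                + np.log(_sigmoid(-(u @ th[3])))
            )

        out = implicit_update(tables, 0, 1, [2, 3], weight, lr)
        # evaluate with the updated context vectors as well
        assert objective(out) > objective(tables)


class TestTrainBine:
    def test_zero_epochs_returns_initialization(self, default_dataset):
        params = SMALL_BINE
        p0 = BineHyperparams(**{**params.__dict__, "max_iter": 0})
        drugs, targets = train_bine(default_dataset.network, p0)
        dim = p0.dim
        assert np.abs(drugs.vectors).max() <= 0.5 / dim
        np.testing.assert_array_equal(drugs.context_vectors, 0.0)
        np.testing.assert_array_equal(targets.context_vectors, 0.0)

    def test_reproducible_under_seed(self, default_dataset):
        p = BineHyperparams(**{**SMALL_BINE.__dict__, "max_iter": 2})
        a = train_bine(default_dataset.network, p)
        b = train_bine(default_dataset.network, p)
        np.testing.assert_array_equal(a[0].vectors, b[0].vectors)
        np.testing.assert_array_equal(a[1].vectors, b[1].vectors)

    def test_norms_stay_finite(self, default_dataset):
        drugs, targets = train_bine(default_dataset.network, SMALL_BINE)
        assert np.isfinite(drugs.vectors).all() and np.isfinite(targets.vectors).all()
        assert np.linalg.norm(drugs.vectors, axis=1).max() < 1e3

    def test_planted_blocks_separate_in_embedding_space(self, default_dataset):
        ds = default_dataset
        drugs, _ = train_bine(ds.network, SMALL_BINE)
        U = drugs.vectors
        U = U / np.linalg.norm(U, axis=1, keepdims=True)
        cos = U @ U.T
        same = ds.drug_blocks[:, None] == ds.drug_blocks[None, :]
        np.fill_diagonal(same, False)
        other = ~same
        np.fill_diagonal(other, False)
        margin = cos[same].mean() - cos[other].mean()
        assert margin > 0.0
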