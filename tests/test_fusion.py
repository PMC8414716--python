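"""Entropy/redundancy screening and similarity network fusion."""

import numpy as np
import pytest

from hetdti import (
    SimilarityMatrix,
    SimilarityCollection,
    build_composite,
    entropy_screen,
    matrix_entropy,
    redundancy_screen,
    snf_fuse,
)

from conftest import random_similarity


def reference_snf(mats, K, t, alpha=1.0):
    """Independent straight-from-the-equations cross-diffusion, loop-coded."""
    mats = [np.array(m, dtype=float) for m in mats]
    nv = len(mats)
    k = mats[0].shape[0]

    def norm_full(w):
        out = np.zeros_like(w)
        for i in range(k):
            s = w[i].sum()
            out[i] = w[i] / s if s else w[i]
        return (out + out.T) / 2

    def norm_local(w):
        out = np.zeros_like(w)
        for i in range(k):
            order = sorted(range(k), key=lambda j: -w[i, j])[:K]
            s = sum(w[i, j] for j in order)
            for j in order:
                out[i, j] = w[i, j] / s if s else 0.0
        return out

    P = [norm_full(m) for m in mats]
    S = [norm_local(p) for p in P]
    for _ in range(t):
        newP = []
        for v in range(nv):
            others = P[v] if nv == 1 else sum(P[u] for u in range(nv) if u != v) / (nv - 1)
            w = S[v] @ others @ S[v].T + alpha * np.eye(k)
            newP.append((w + w.T) / 2)
        P = newP
    fused = sum(P) / nv
    for i in range(k):
        fused[i] = fused[i] / fused[i].sum()
    return (fused + fused.T + np.eye(k)) / 2


class TestEntropy:
    def test_uniform_matrix_attains_ln_k(self):
        mat = SimilarityMatrix("drug", "u", np.full((2, 2), 0.3))
        assert matrix_entropy(mat) == pytest.approx(np.log(4))

    def test_single_entry_zero_entropy(self):
        vals = np.zeros((3, 3))
        vals[1, 1] = 5.0
        assert matrix_entropy(SimilarityMatrix("drug", "x", vals)) == 0.0

    def test_hand_computed_example(self):
        mat = SimilarityMatrix("drug", "x", np.array([[2.0, 1.0], [1.0, 0.0]]))
        # distribution (0.5, 0.25, 0.25, 0)
        expect = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert matrix_entropy(mat) == pytest.approx(expect)
        assert matrix_entropy(mat) == pytest.approx(1.0397, abs=1e-4)

    @pytest.mark.parametrize("seed", range(4))
    def test_bounded_by_ln_k(self, seed):
        rng = np.random.default_rng(seed)
        mat = random_similarity(rng, "drug", "x", 6)
        h = matrix_entropy(mat)
        assert 0.0 <= h <= np.log(36) + 1e-12

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            matrix_entropy(SimilarityMatrix("drug", "x", np.zeros((2, 2))))


def _structured(k, name="structured", side="drug"):
    vals = np.eye(k)
    return SimilarityMatrix(side, name, vals)


def _near_uniform(rng, k, name="uniform", side="drug"):
    noise = rng.normal(0, 1e-3, (k, k))
    return SimilarityMatrix(side, name, 0.5 + (noise + noise.T) / 2)


class TestEntropyScreen:
    def test_threshold_straddle(self):
        rng = np.random.default_rng(0)
        coll = SimilarityCollection(
            "drug", [_near_uniform(rng, 8), _structured(8)]
        )
        kept, report = entropy_screen(coll, c1=0.7)
        assert kept.names == ["structured"]
        assert report.removed_by_entropy == ["uniform"]
        assert report.entropy_threshold == pytest.approx(0.7 * np.log(64))

    def test_c1_one_removes_nothing(self):
        rng = np.random.default_rng(1)
        coll = SimilarityCollection(
            "drug", [_near_uniform(rng, 8), _structured(8)]
        )
        kept, _ = entropy_screen(coll, c1=1.0)
        assert kept.names == coll.names

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(2)
        mats = [random_similarity(rng, "drug", f"m{i}", 7) for i in range(5)]
        coll = SimilarityCollection("drug", mats)
        try:
            kept, _ = entropy_screen(coll, c1=0.95)
            kept_names = kept.names
        except ValueError:
            kept_names = []
        expect = [
            m.name for m in mats if matrix_entropy(m) <= 0.95 * np.log(49)
        ]
        assert kept_names == expect

    def test_all_removed_errors(self):
        rng = np.random.default_rng(3)
        coll = SimilarityCollection("drug", [_near_uniform(rng, 8)])
        with pytest.raises(ValueError, match="raise c1"):
            entropy_screen(coll, c1=0.5)

    def test_max_observed_reference(self):
        rng = np.random.default_rng(4)
        coll = SimilarityCollection(
            "drug", [_near_uniform(rng, 8), _structured(8)]
        )
        _, report = entropy_screen(coll, c1=0.7, entropy_reference="max_observed")
        assert report.entropy_threshold == pytest.approx(
            0.7 * max(report.entropies.values())
        )


class TestRedundancyScreen:
    def test_exact_duplicate_removed(self):
        a = _structured(5, "a")
        b = SimilarityMatrix("drug", "b", a.values.copy())
        kept, report = redundancy_screen(SimilarityCollection("drug", [a, b]))
        assert kept.names == ["a"]
        assert report.es_pairs[("a", "b")] == pytest.approx(1.0)

    def test_distance_one_keeps_both(self):
        a = _structured(5, "a")
        vals = a.values.copy()
        vals[0, 0] += 1.0  # flattened Euclidean distance exactly 1
        b = SimilarityMatrix("drug", "b", vals)
        kept, report = redundancy_screen(SimilarityCollection("drug", [a, b]))
        assert set(kept.names) == {"a", "b"}
        assert report.es_pairs[min(report.es_pairs)] == pytest.approx(0.5)

    def test_matches_sequential_oracle(self):
        rng = np.random.default_rng(5)
        mats = [random_similarity(rng, "drug", f"m{i}", 6) for i in range(4)]
        mats.append(SimilarityMatrix("drug", "m4", mats[0].values + 1e-4))
        coll = SimilarityCollection("drug", mats)
        kept, _ = redundancy_screen(coll, c2=0.6)

        # independent step-by-step simulation of the procedure
        ent = {m.name: matrix_entropy(m) for m in mats}
        order = sorted([m.name for m in mats], key=lambda nm: (ent[nm], nm))
        by = {m.name: m.values.ravel() for m in mats}
        removed = set()
        for i, cur in enumerate(order):
            if cur in removed:
                continue
            for other in order[i + 1:]:
                if other in removed:
                    continue
                es = 1.0 / (1.0 + np.linalg.norm(by[cur] - by[other]))
                if es > 0.6:
                    removed.add(other)
        expect = [m.name for m in mats if m.name not in removed]
        assert kept.names == expect


class TestSNF:
    def test_single_view_is_normalization_fixed_point(self):
        rng = np.random.default_rng(6)
        a = random_similarity(rng, "drug", "a", 12)
        single = snf_fuse(SimilarityCollection("drug", [a]), K=5, t=10)
        b = SimilarityMatrix("drug", "b", a.values.copy())
        double = snf_fuse(SimilarityCollection("drug", [a, b]), K=5, t=10)
        np.testing.assert_allclose(double.values, single.values, atol=1e-8)

    @pytest.mark.parametrize("n_views", [1, 2, 3])
    def test_matches_independent_reference(self, n_views):
        rng = np.random.default_rng(7)
        mats = [random_similarity(rng, "drug", f"m{i}", 20) for i in range(n_views)]
        fused = snf_fuse(SimilarityCollection("drug", mats), K=6, t=8)
        expect = reference_snf([m.values for m in mats], K=6, t=8)
        np.testing.assert_allclose(fused.values, expect, atol=1e-6)

    def test_output_symmetric_nonnegative(self):
        rng = np.random.default_rng(8)
        mats = [random_similarity(rng, "drug", f"m{i}", 15) for i in range(2)]
        fused = snf_fuse(SimilarityCollection("drug", mats), K=5, t=5)
        assert (fused.values >= 0).all()
        np.testing.assert_allclose(fused.values, fused.values.T)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        mats = [random_similarity(rng, "drug", f"m{i}", 10) for i in range(2)]
        fused = snf_fuse(SimilarityCollection("drug", mats), K=4, t=5)
        perm = rng.permutation(10)
        permuted = [
            SimilarityMatrix("drug", m.name, m.values[np.ix_(perm, perm)])
            for m in mats
        ]
        fused_p = snf_fuse(SimilarityCollection("drug", permuted), K=4, t=5)
        np.testing.assert_allclose(
            fused_p.values, fused.values[np.ix_(perm, perm)], atol=1e-10
        )

    def test_k_clipped_for_tiny_matrices(self):
        rng = np.random.default_rng(10)
        a = random_similarity(rng, "drug", "a", 4)
        fused = snf_fuse(SimilarityCollection("drug", [a]), K=20, t=3)
        assert fused.dim == 4


class TestBuildComposite:
    def test_single_matrix_no_removals(self):
        a = _structured(8, "a")
        composite, report = build_composite(SimilarityCollection("drug", [a]))
        assert report.retained == ["a"]
        assert not report.removed_by_entropy and not report.removed_by_redundancy
        expect = snf_fuse(SimilarityCollection("drug", [a]))
        np.testing.assert_allclose(composite.values, expect.values)

    def test_pipeline_trace(self):
        rng = np.random.default_rng(11)
        a = _structured(8, "a")
        copy_a = SimilarityMatrix("drug", "copy", a.values + 1e-6)
        uniform = _near_uniform(rng, 8, "noise")
        coll = SimilarityCollection("drug", [a, copy_a, uniform])
        composite, report = build_composite(coll)
        assert report.removed_by_entropy == ["noise"]
        assert report.removed_by_redundancy == ["copy"]
        assert report.retained == ["a"]
        expect = snf_fuse(SimilarityCollection("drug", [a]))
        np.testing.assert_allclose(composite.values, expect.values)

    def test_synthetic_injections_screened(self, screen_dataset):
        _, report = build_composite(screen_dataset.drug_sims)
        assert set(report.removed_by_entropy) == {"drug_uniform_1", "drug_uniform_2"}
        assert set(report.removed_by_redundancy) == {
            "drug_sim_1_dup1", "drug_sim_1_dup2",
        }
        assert report.retained == ["drug_sim_1"]
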