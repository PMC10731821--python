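"""Neighbor selection and pair-embedding fusion."""

import numpy as np
import pytest

from dtilink import (
    EmbeddingTable,
    InteractionMatrix,
    fuse_all_pairs,
    fuse_pair,
    read_interactions,
    top_n_neighbors,
    write_interactions,
)
from dtilink.similarity import SimilarityMatrix, similarity_matrix


def _sim(ids, values):
    return SimilarityMatrix(ids, np.asarray(values, float), "cosine")


class TestInteractionIO:
    def test_round_trip(self, tmp_path):
        mat = InteractionMatrix(["d1", "d2"], ["t1", "t2", "t3"], np.array([[0, 1, 0], [1, 0, 1]]))
        path = tmp_path / "mat.tsv"
        write_interactions(mat, path)
        loaded = read_interactions(path)
        assert loaded.drug_ids == mat.drug_ids
        assert loaded.target_ids == mat.target_ids
        assert np.array_equal(loaded.values, mat.values)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            InteractionMatrix(["d"], ["t"], np.array([[2]]))


class TestTopNeighbors:
    def test_forced_single_neighbor(self):
        sim = _sim(["a", "b"], [[1.0, 0.3], [0.3, 1.0]])
        ns = top_n_neighbors(sim, "a", 1)
        assert ns.neighbors == [("b", 0.3)]

    def test_tie_broken_by_ascending_id(self):
        sim = _sim(
            ["a", "c", "b", "d"],
            [
                [1.0, 0.9, 0.9, 0.1],
                [0.9, 1.0, 0.0, 0.0],
                [0.9, 0.0, 1.0, 0.0],
                [0.1, 0.0, 0.0, 1.0],
            ],
        )
        ns = top_n_neighbors(sim, "a", 1)
        assert ns.neighbors == [("b", 0.9)]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((6, 6))
        values = (x + x.T) / 2
        np.fill_diagonal(values, 1.0)
        ids = [f"e{i}" for i in range(6)]
        sim = _sim(ids, values)
        ns = top_n_neighbors(sim, "e2", 3)
        oracle = sorted(
            ((ids[k], values[2, k]) for k in range(6) if k != 2),
            key=lambda it: (-it[1], it[0]),
        )[:3]
        assert ns.neighbors == oracle
        assert all(w1 >= w2 for (_, w1), (_, w2) in zip(ns.neighbors, ns.neighbors[1:]))

    def test_n_out_of_range(self):
        sim = _sim(["a", "b"], [[1.0, 0.2], [0.2, 1.0]])
        with pytest.raises(ValueError):
            top_n_neighbors(sim, "a", 2)


def _hand_fixture():
    """3 drugs x 3 targets with 1-D embeddings, scripted for hand evaluation."""
    drug_table = EmbeddingTable(["d0", "d1", "d2"], np.array([[2.0], [4.0], [6.0]]))
    target_table = EmbeddingTable(["t0", "t1", "t2"], np.array([[5.0], [7.0], [9.0]]))
    sim_dd = _sim(
        ["d0", "d1", "d2"],
        [[1.0, 0.9, 0.6], [0.9, 1.0, 0.2], [0.6, 0.2, 1.0]],
    )
    sim_tt = _sim(
        ["t0", "t1", "t2"],
        [[1.0, 0.8, 0.3], [0.8, 1.0, 0.1], [0.3, 0.1, 1.0]],
    )
    mat_int = InteractionMatrix(
        ["d0", "d1", "d2"], ["t0", "t1", "t2"], np.array([[0, 0, 0], [1, 0, 0], [0, 0, 0]])
    )
    return drug_table, target_table, sim_dd, sim_tt, mat_int


class TestFusePair:
    def test_hand_computed_as_printed(self):
        drug_table, target_table, sim_dd, sim_tt, mat_int = _hand_fixture()
        pair = fuse_pair("d0", "t0", drug_table, target_table, sim_dd, sim_tt, mat_int, n=2)
        # drug side: neighbors d1 (0.9), d2 (0.6); d1 interacts with t0
        #   Vd_fusion = (0.9 + 0.6) * 2 + 1 * 5 = 8.0
        # target side: neighbors t1 (0.8), t2 (0.3); d0 interacts with neither
        #   Vt_fusion = (0.8 + 0.3) * 5 + 0 * 2 = 5.5
        assert pair.vector == pytest.approx([8.0, 5.5], abs=1e-12)

    def test_zero_weights_and_interactions_give_zero_vector(self):
        drug_table = EmbeddingTable(["d0", "d1"], np.array([[2.0], [3.0]]))
        target_table = EmbeddingTable(["t0", "t1"], np.array([[5.0], [4.0]]))
        sim0 = _sim(["d0", "d1"], [[1.0, 0.0], [0.0, 1.0]])
        simt = _sim(["t0", "t1"], [[1.0, 0.0], [0.0, 1.0]])
        mat = InteractionMatrix(["d0", "d1"], ["t0", "t1"], np.zeros((2, 2), dtype=int))
        pair = fuse_pair("d0", "t0", drug_table, target_table, sim0, simt, mat, n=1)
        assert np.array_equal(pair.vector, np.zeros(2))

    def test_neighbor_vectors_mode_uses_neighbor_embeddings(self):
        drug_table, target_table, sim_dd, sim_tt, mat_int = _hand_fixture()
        pair = fuse_pair(
            "d0", "t0", drug_table, target_table, sim_dd, sim_tt, mat_int, n=2,
            mode="neighbor-vectors",
        )
        # Vd_intg = 0.9 * vec(d1) + 0.6 * vec(d2) = 3.6 + 3.6 = 7.2; + 1 * 5
        # Vt_intg = 0.8 * vec(t1) + 0.3 * vec(t2) = 5.6 + 2.7 = 8.3; + 0
        assert pair.vector == pytest.approx([12.2, 8.3], abs=1e-12)

    def test_anchor_scaling_linearity(self):
        drug_table, target_table, sim_dd, sim_tt, mat_int = _hand_fixture()
        scaled = EmbeddingTable(drug_table.ids, drug_table.vectors * 3.0)
        base = fuse_pair("d0", "t1", drug_table, target_table, sim_dd, sim_tt, mat_int, n=2)
        big = fuse_pair("d0", "t1", scaled, target_table, sim_dd, sim_tt, mat_int, n=2)
        k = drug_table.dimension
        # Vd_intg and Vt_test carry vec(d): those contributions scale by 3
        vd_intg = sum(w for _, w in [("d1", 0.9), ("d2", 0.6)]) * drug_table.vector("d0")
        assert big.vector[:k] - (base.vector[:k] - vd_intg) == pytest.approx(3 * vd_intg)

    def test_dimension_mismatch_errors(self):
        drug_table = EmbeddingTable(["d0", "d1"], np.ones((2, 3)))
        target_table = EmbeddingTable(["t0", "t1"], np.ones((2, 2)))
        sim = _sim(["d0", "d1"], np.eye(2))
        simt = _sim(["t0", "t1"], np.eye(2))
        mat = InteractionMatrix(["d0", "d1"], ["t0", "t1"], np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError, match="dimension"):
            fuse_pair("d0", "t0", drug_table, target_table, sim, simt, mat, n=1)


class TestFuseAllPairs:
    def test_count_and_order(self):
        drug_table = EmbeddingTable(["d0", "d1"], np.ones((2, 2)))
        target_table = EmbeddingTable(["t0", "t1", "t2"], np.ones((3, 2)))
        sim_dd = similarity_matrix(drug_table, "cosine")
        sim_tt = similarity_matrix(target_table, "cosine")
        mat = InteractionMatrix(["d0", "d1"], ["t0", "t1", "t2"], np.zeros((2, 3), dtype=int))
        pairs = fuse_all_pairs(drug_table, target_table, sim_dd, sim_tt, mat, n=1)
        assert len(pairs) == 6
        assert [(p.drug, p.target) for p in pairs[:3]] == [("d0", "t0"), ("d0", "t1"), ("d0", "t2")]
        assert all(len(p.vector) == 2 * 2 for p in pairs)

    @pytest.mark.parametrize("mode", ["as-printed", "neighbor-vectors"])
    def test_consistency_with_fuse_pair(self, mode):
        rng = np.random.default_rng(8)
        drugs = [f"d{i}" for i in range(4)]
        targets = [f"t{i}" for i in range(4)]
        drug_table = EmbeddingTable(drugs, rng.standard_normal((4, 3)))
        target_table = EmbeddingTable(targets, rng.standard_normal((4, 3)))
        sim_dd = similarity_matrix(drug_table, "cosine")
        sim_tt = similarity_matrix(target_table, "cosine")
        mat = InteractionMatrix(drugs, targets, rng.integers(0, 2, size=(4, 4)))
        pairs = fuse_all_pairs(drug_table, target_table, sim_dd, sim_tt, mat, n=2, mode=mode)
        for p in pairs:
            single = fuse_pair(
                p.drug, p.target, drug_table, target_table, sim_dd, sim_tt, mat, n=2, mode=mode
            )
            assert np.allclose(p.vector, single.vector, atol=1e-12)

    def test_exhaustive_neighbors_with_max_n(self):
        rng = np.random.default_rng(3)
        drugs = [f"d{i}" for i in range(5)]
        drug_table = EmbeddingTable(drugs, rng.standard_normal((5, 3)))
        sim = similarity_matrix(drug_table, "cosine")
        ns = top_n_neighbors(sim, "d2", n=4)
        assert sorted(z for z, _ in ns.neighbors) == ["d0", "d1", "d3", "d4"]

    def test_empty_interactions_zero_test_terms(self):
        drug_table, target_table, sim_dd, sim_tt, _ = _hand_fixture()
        mat = InteractionMatrix(
            ["d0", "d1", "d2"], ["t0", "t1", "t2"], np.zeros((3, 3), dtype=int)
        )
        pairs = fuse_all_pairs(drug_table, target_table, sim_dd, sim_tt, mat, n=2)
        for p in pairs:
            wsum_d = sum(w for _, w in top_n_neighbors(sim_dd, p.drug, 2).neighbors)
            wsum_t = sum(w for _, w in top_n_neighbors(sim_tt, p.target, 2).neighbors)
            expected = np.concatenate(
                [wsum_d * drug_table.vector(p.drug), wsum_t * target_table.vector(p.target)]
            )
            assert np.allclose(p.vector, expected, atol=1e-12)
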