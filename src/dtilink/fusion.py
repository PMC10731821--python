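"""Neighbor-weighted pair-embedding fusion.

For a pair ``(d, t)`` the fused representation combines four ingredients:
the ``n`` most similar drugs of ``d`` (weights from the drug-drug similarity
matrix), the ``n`` most similar targets of ``t``, and the rows/columns of the
binary interaction matrix belonging to those neighbors.

The default ``as-printed`` mode implements the fusion equations literally:

    Vd_intg = (sum of the n neighbor weights of d)              * vec(d)
    Vt_intg = (sum of the n neighbor weights of t)              * vec(t)
    Vd_test = (number of d's neighbor drugs interacting with t) * vec(t)
    Vt_test = (number of t's neighbor targets interacting with d) * vec(d)
    pair    = [Vd_intg + Vd_test  ||  Vt_intg + Vt_test]

so the similarity weights scale the anchor's own vector.  The alternate
``neighbor-vectors`` mode instead applies the similarity weights to the
neighbor embeddings (``Vd_intg = sum_z w_z * vec(d_z)``), the reading used by
related bipartite-fusion methods; the interaction-count terms keep the cross
anchor vectors in both modes.  The entry ``MatInt[d, t]`` itself is never
consulted when fusing ``(d, t)`` - only neighbors' rows and columns are.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .embeddings import EmbeddingTable
from .similarity import SimilarityMatrix

__all__ = [
    "InteractionMatrix",
    "NeighborSet",
    "PairEmbedding",
    "read_interactions",
    "write_interactions",
    "top_n_neighbors",
    "fuse_pair",
    "fuse_all_pairs",
]

FUSION_MODES = ("as-printed", "neighbor-vectors")


@dataclass
class InteractionMatrix:
    """Binary drugs x targets interaction matrix."""

    drug_ids: list[str]
    target_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.drug_ids), len(self.target_ids)):
            raise ValueError("matrix shape must match id lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("interaction matrix must be binary")
        self.values = self.values.astype(int)
        self._drug_index = {d: i for i, d in enumerate(self.drug_ids)}
        self._target_index = {t: j for j, t in enumerate(self.target_ids)}

    def entry(self, drug: str, target: str) -> int:
        return int(self.values[self._drug_index[drug], self._target_index[target]])

    def drug_index(self, drug: str) -> int:
        return self._drug_index[drug]

    def target_index(self, target: str) -> int:
        return self._target_index[target]


@dataclass
class NeighborSet:
    """The n most similar entities to an anchor, weights non-increasing."""

    anchor: str
    neighbors: list[tuple[str, float]]


@dataclass
class PairEmbedding:
    drug: str
    target: str
    vector: np.ndarray


def write_interactions(mat: InteractionMatrix, path: str | Path) -> None:
    """TSV: first row target ids, first column drug ids, 0/1 cells."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\t" + "\t".join(mat.target_ids) + "\n")
        for d, row in zip(mat.drug_ids, mat.values):
            fh.write(d + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_interactions(path: str | Path) -> InteractionMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        target_ids = header[1:]
        drug_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(target_ids) + 1:
                raise ValueError(f"{path}: row {lineno} has wrong cell count")
            drug_ids.append(fields[0])
            rows.append([int(v) for v in fields[1:]])
    return InteractionMatrix(drug_ids, target_ids, np.array(rows))


def top_n_neighbors(sim: SimilarityMatrix, anchor: str, n: int) -> NeighborSet:
    """The n largest off-diagonal entries of the anchor's similarity row.

    Ties are broken by ascending id order, so the selection is deterministic.
    """
    if not (1 <= n <= len(sim.ids) - 1):
        raise ValueError(f"n must be in [1, {len(sim.ids) - 1}]")
    row = sim.row(anchor)
    candidates = [(id_, float(row[k])) for k, id_ in enumerate(sim.ids) if id_ != anchor]
    candidates.sort(key=lambda item: (-item[1], item[0]))
    return NeighborSet(anchor, candidates[:n])


def _check_tables(drug_table: EmbeddingTable, target_table: EmbeddingTable) -> None:
    if drug_table.dimension != target_table.dimension:
        raise ValueError(
            f"drug and target embedding dimensions differ "
            f"({drug_table.dimension} vs {target_table.dimension}); align them first"
        )


def fuse_pair(
    d: str,
    t: str,
    drug_table: EmbeddingTable,
    target_table: EmbeddingTable,
    sim_dd: SimilarityMatrix,
    sim_tt: SimilarityMatrix,
    mat_int: InteractionMatrix,
    n: int = 5,
    mode: str = "as-printed",
) -> PairEmbedding:
    """Fused embedding of one (drug, target) pair; see the module docstring."""
    if mode not in FUSION_MODES:
        raise ValueError(f"mode must be one of {FUSION_MODES}")
    _check_tables(drug_table, target_table)
    vec_d = drug_table.vector(d)
    vec_t = target_table.vector(t)
    d_near = top_n_neighbors(sim_dd, d, n)
    t_near = top_n_neighbors(sim_tt, t, n)

    if mode == "as-printed":
        vd_intg = sum(w for _, w in d_near.neighbors) * vec_d
        vt_intg = sum(w for _, w in t_near.neighbors) * vec_t
    else:
        vd_intg = np.sum(
            [w * drug_table.vector(z) for z, w in d_near.neighbors], axis=0
        )
        vt_intg = np.sum(
            [w * target_table.vector(z) for z, w in t_near.neighbors], axis=0
        )
    vd_test = sum(mat_int.entry(z, t) for z, _ in d_near.neighbors) * vec_t
    vt_test = sum(mat_int.entry(d, z) for z, _ in t_near.neighbors) * vec_d

    vd_fusion = vd_intg + vd_test
    vt_fusion = vt_intg + vt_test
    return PairEmbedding(d, t, np.concatenate([vd_fusion, vt_fusion]))


def fuse_all_pairs(
    drug_table: EmbeddingTable,
    target_table: EmbeddingTable,
    sim_dd: SimilarityMatrix,
    sim_tt: SimilarityMatrix,
    mat_int: InteractionMatrix,
    n: int = 5,
    mode: str = "as-printed",
) -> list[PairEmbedding]:
    """Fused embeddings for all drug x target pairs, row-major (drugs outer).

    Vectorized equivalent of calling :func:`fuse_pair` on every pair.
    """
    if mode not in FUSION_MODES:
        raise ValueError(f"mode must be one of {FUSION_MODES}")
    _check_tables(drug_table, target_table)
    drugs, targets = mat_int.drug_ids, mat_int.target_ids
    D = drug_table.subset(drugs).vectors
    T = target_table.subset(targets).vectors
    M = mat_int.values

    d_neigh = [top_n_neighbors(sim_dd, d, n) for d in drugs]
    t_neigh = [top_n_neighbors(sim_tt, t, n) for t in targets]
    d_wsum = np.array([sum(w for _, w in ns.neighbors) for ns in d_neigh])
    t_wsum = np.array([sum(w for _, w in ns.neighbors) for ns in t_neigh])
    # neighbor-indicator matrices over the interaction matrix's own id order
    Nd = np.zeros((len(drugs), len(drugs)))
    for i, ns in enumerate(d_neigh):
        for z, _ in ns.neighbors:
            if z in mat_int._drug_index:
                Nd[i, mat_int.drug_index(z)] = 1.0
    Nt = np.zeros((len(targets), len(targets)))
    for j, ns in enumerate(t_neigh):
        for z, _ in ns.neighbors:
            if z in mat_int._target_index:
                Nt[j, mat_int.target_index(z)] = 1.0
    drug_nbr_count = Nd @ M        # (i, j): how many of drug i's neighbors hit target j
    target_nbr_count = M @ Nt.T    # (i, j): how many of target j's neighbors hit drug i

    if mode == "as-printed":
        vd_intg = d_wsum[:, None, None] * D[:, None, :]
    else:
        Wd = np.zeros((len(drugs), len(drugs)))
        for i, ns in enumerate(d_neigh):
            for z, w in ns.neighbors:
                Wd[i, mat_int.drug_index(z)] = w
        Wt = np.zeros((len(targets), len(targets)))
        for j, ns in enumerate(t_neigh):
            for z, w in ns.neighbors:
                Wt[j, mat_int.target_index(z)] = w
        vd_intg = np.broadcast_to((Wd @ D)[:, None, :], (len(drugs), len(targets), D.shape[1])).copy()
        vt_intg_nv = Wt @ T
    vd_test = drug_nbr_count[:, :, None] * T[None, :, :]
    vt_test = target_nbr_count[:, :, None] * D[:, None, :]
    if mode == "as-printed":
        vt_intg = t_wsum[None, :, None] * T[None, :, :]
    else:
        vt_intg = np.broadcast_to(vt_intg_nv[None, :, :], vd_test.shape)
    vd_fusion = vd_intg + vd_test
    vt_fusion = vt_intg + vt_test

    out: list[PairEmbedding] = []
    for i, d in enumerate(drugs):
        for j, t in enumerate(targets):
            out.append(PairEmbedding(d, t, np.concatenate([vd_fusion[i, j], vt_fusion[i, j]])))
    return out
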