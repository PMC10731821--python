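"""Pairwise drug-drug / target-target similarity matrices from embeddings.

Five metrics are supported: cosine, Pearson correlation (across vector
coordinates), Euclidean and Manhattan distances converted to similarities by
``s = 1 / (1 + d)``, and Jaccard.  Jaccard on non-negative real vectors is
the Ruzicka generalization ``sum(min) / sum(max)``, which reduces to the
exact set Jaccard on binary fingerprints; it is undefined for negative
entries, and callers are told to binarize or shift in that case.

Zero-vector policy: cosine (and Pearson, for constant vectors) against a
degenerate vector is defined as 0 off-diagonal, and the diagonal is forced
to exactly 1 for every metric so neighbor selection can never prefer a
numerical-noise off-diagonal value to self (self is excluded anyway).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .embeddings import EmbeddingTable

__all__ = ["METRICS", "SimilarityMatrix", "similarity_matrix", "read_similarity", "write_similarity"]

METRICS = ("cosine", "euclidean", "manhattan", "jaccard", "pearson")


@dataclass
class SimilarityMatrix:
    """Labeled square symmetric matrix of pairwise similarities."""

    ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity values must be finite")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def row(self, id_: str) -> np.ndarray:
        return self.values[self._index[id_]]

    def index(self, id_: str) -> int:
        return self._index[id_]


def _cosine_like(X: np.ndarray, center: bool) -> np.ndarray:
    if center:
        X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    ok = norms > 0
    Xn = np.zeros_like(X)
    Xn[ok] = X[ok] / norms[ok, None]
    sim = Xn @ Xn.T
    # degenerate (zero / constant) vectors: 0 against everything off-diagonal
    sim[~ok, :] = 0.0
    sim[:, ~ok] = 0.0
    return np.clip(sim, -1.0, 1.0)


def _ruzicka(X: np.ndarray) -> np.ndarray:
    if (X < 0).any():
        raise ValueError(
            "jaccard similarity needs non-negative vectors; binarize the "
            "features or shift them to be non-negative first"
        )
    mins = np.minimum(X[:, None, :], X[None, :, :]).sum(axis=2)
    maxs = np.maximum(X[:, None, :], X[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(maxs > 0, mins / np.where(maxs > 0, maxs, 1.0), 0.0)
    return sim


def similarity_matrix(table: EmbeddingTable, metric: str = "cosine") -> SimilarityMatrix:
    """All-pairs similarity of the table's vectors under one metric."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if len(table) == 0:
        raise ValueError("embedding table is empty")
    X = table.vectors
    if metric == "cosine":
        sim = _cosine_like(X, center=False)
    elif metric == "pearson":
        sim = _cosine_like(X, center=True)
    elif metric in ("euclidean", "manhattan"):
        d = cdist(X, X, metric="euclidean" if metric == "euclidean" else "cityblock")
        sim = 1.0 / (1.0 + d)
    else:
        sim = _ruzicka(X)
    sim = (sim + sim.T) / 2.0  # kill numerical asymmetry
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(list(table.ids), sim, metric)


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    """TSV with an id header row and id-labeled rows; metric on a comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# metric: {sim.metric}\n")
        fh.write("id\t" + "\t".join(sim.ids) + "\n")
        for id_, row in zip(sim.ids, sim.values):
            fh.write(id_ + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_similarity(path: str | Path) -> SimilarityMatrix:
    metric = "cosine"
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# metric:"):
                metric = line.split(":", 1)[1].strip()
            elif line.startswith("id\t"):
                header = line.split("\t")[1:]
            elif line.strip():
                fields = line.split("\t")
                ids.append(fields[0])
                rows.append([float(v) for v in fields[1:]])
    if ids != header:
        raise ValueError(f"{path}: row ids do not match the header ids")
    return SimilarityMatrix(ids, np.array(rows), metric)
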