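"""Embedding tables and interchangeable embedding providers.

An :class:`EmbeddingTable` maps string identifiers to fixed-length real
vectors; it is the common currency between the knowledge-graph embedder, the
local featurizers, the similarity builder and the fusion step.  Providers
(trained KGE, precomputed file, protein language model, seeded mock) all
return this one container, and :func:`pca_align` brings tables of different
widths to a shared dimension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "EmbeddingTable",
    "load_embedding_table",
    "write_embedding_table",
    "mock_provider",
    "protbert_provider",
    "pca_align",
]

logger = logging.getLogger(__name__)

_HEADER_PREFIX = "# dimension:"


@dataclass
class EmbeddingTable:
    """Ordered ids with one real vector of identical length per id."""

    ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D array (one row per id)")
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError("one vector required per id")
        if self.vectors.shape[1] < 1:
            raise ValueError("embedding dimension must be positive")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def vector(self, id_: str) -> np.ndarray:
        try:
            return self.vectors[self._index[id_]]
        except KeyError:
            raise KeyError(f"no embedding for id {id_!r}") from None

    def subset(self, ids: Sequence[str]) -> "EmbeddingTable":
        """Restrict the table to ``ids``, in the given order."""
        rows = np.stack([self.vector(i) for i in ids])
        return EmbeddingTable(list(ids), rows)

    def __contains__(self, id_: str) -> bool:
        return id_ in self._index

    def __len__(self) -> int:
        return len(self.ids)


def write_embedding_table(table: EmbeddingTable, path: str | Path) -> None:
    """Serialize as text: a dimension header then ``id<TAB>v1<TAB>...<TAB>vk``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{_HEADER_PREFIX} {table.dimension}\n")
        for id_, row in zip(table.ids, table.vectors):
            fh.write(id_ + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def load_embedding_table(path: str | Path) -> EmbeddingTable:
    """Read the text format written by :func:`write_embedding_table`."""
    ids: list[str] = []
    rows: list[list[float]] = []
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(_HEADER_PREFIX):
                dim = int(line[len(_HEADER_PREFIX) :].strip())
                continue
            fields = line.split("\t")
            if dim is None:
                raise ValueError(f"{path}: missing dimension header before row {lineno}")
            if len(fields) != dim + 1:
                raise ValueError(
                    f"{path}: row {lineno} has {len(fields) - 1} values, expected {dim}"
                )
            if fields[0] in ids:
                raise ValueError(f"{path}: duplicate id {fields[0]!r} at row {lineno}")
            ids.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    if dim is None or not ids:
        raise ValueError(f"{path}: no embedding rows found")
    return EmbeddingTable(ids, np.array(rows))


def mock_provider(ids: Sequence[str], dimension: int, seed: int = 0) -> EmbeddingTable:
    """Seeded standard-normal embeddings, a stand-in provider for tests."""
    if len(ids) == 0:
        raise ValueError("mock_provider needs at least one id")
    if dimension <= 0:
        raise ValueError("dimension must be positive")
    rng = np.random.default_rng(seed)
    return EmbeddingTable(list(ids), rng.standard_normal((len(ids), dimension)))


def protbert_provider(
    sequences: Mapping[str, str],
    model_dir: str | Path | None = None,
    pooling: str = "mean",
) -> EmbeddingTable:
    """Protein-language-model embeddings (optional provider).

    Runs a locally stored BERT-style protein model over each sequence and
    pools the per-residue vectors of the final layer (``mean`` by default,
    ``cls`` for the classification token).  Requires the optional ``torch``
    and ``transformers`` dependencies plus a local model directory; library
    code never downloads anything.
    """
    if pooling not in ("mean", "cls"):
        raise ValueError("pooling must be 'mean' or 'cls'")
    try:
        import torch  # noqa: F401
        from transformers import AutoModel, AutoTokenizer
    except ImportError as exc:
        raise RuntimeError(
            "protbert_provider needs the optional 'torch' and 'transformers' "
            "packages and a locally downloaded protein BERT model; install "
            "them and pass model_dir=<path to the local model>, or use "
            "mock_provider / the KGE provider instead"
        ) from exc
    if model_dir is None or not Path(model_dir).exists():
        raise RuntimeError(
            f"model assets not found at {model_dir!r}; download a protein BERT "
            "model offline and pass its directory as model_dir"
        )
    tokenizer = AutoTokenizer.from_pretrained(str(model_dir), do_lower_case=False)
    model = AutoModel.from_pretrained(str(model_dir))
    model.eval()
    ids, rows = [], []
    with torch.no_grad():
        for pid, seq in sequences.items():
            spaced = " ".join(seq.upper())
            inputs = tokenizer(spaced, return_tensors="pt")
            hidden = model(**inputs).last_hidden_state[0]
            vec = hidden[0] if pooling == "cls" else hidden[1:-1].mean(dim=0)
            ids.append(pid)
            rows.append(vec.numpy())
    return EmbeddingTable(ids, np.stack(rows))


def pca_align(table: EmbeddingTable, target_dim: int) -> EmbeddingTable:
    """Project a table onto its top principal axes to reach ``target_dim``.

    Used to bring drug and target tables from different providers to one
    shared width before fusion.  Rows are mean-centered and projected onto
    the leading right-singular vectors; each axis is oriented so that its
    largest-magnitude loading is positive, which removes the sign
    indeterminacy of the decomposition.
    """
    n, k = table.vectors.shape
    if not (1 <= target_dim <= min(k, n - 1)):
        raise ValueError(
            f"target_dim must be in [1, min(dimension={k}, n_ids-1={n - 1})]"
        )
    centered = table.vectors - table.vectors.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    components = vt[:target_dim]
    signs = np.sign(components[np.arange(target_dim), np.argmax(np.abs(components), axis=1)])
    signs[signs == 0] = 1.0
    components = components * signs[:, None]
    return EmbeddingTable(list(table.ids), centered @ components.T)


def explained_variance_ratios(table: EmbeddingTable) -> np.ndarray:
    """Non-increasing PCA explained-variance ratios of a table's rows."""
    centered = table.vectors - table.vectors.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    var = s**2
    total = var.sum()
    return var / total if total > 0 else var
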