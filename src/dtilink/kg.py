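"""Knowledge-graph triple store: reading, writing, splitting and negative sampling.

A knowledge graph is a set of ``(head, relation, tail)`` facts over opaque,
case-sensitive string identifiers.  Entity and relation vocabularies preserve
first-appearance order so that downstream embedding tables are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Triple",
    "KnowledgeGraph",
    "TripleParseError",
    "read_triples",
    "write_triples",
    "split_triples",
    "corrupt_triple",
]


class TripleParseError(ValueError):
    """Raised when a triple file line cannot be parsed."""


@dataclass(frozen=True, order=True)
class Triple:
    """One ``head -relation-> tail`` fact."""

    head: str
    relation: str
    tail: str

    def __post_init__(self) -> None:
        if self.head == "" or self.tail == "":
            raise ValueError("triple head and tail must be non-empty")


@dataclass
class KnowledgeGraph:
    """Ordered entity/relation vocabularies plus a duplicate-free triple list."""

    entities: list[str] = field(default_factory=list)
    relations: list[str] = field(default_factory=list)
    triples: list[Triple] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._triple_set = set(self.triples)
        if len(self._triple_set) != len(self.triples):
            raise ValueError("duplicate triples in knowledge graph")
        ent = set(self.entities)
        rel = set(self.relations)
        for t in self.triples:
            if t.head not in ent or t.tail not in ent or t.relation not in rel:
                raise ValueError(f"triple {t} references unknown entity/relation")

    @classmethod
    def from_triples(cls, triples: Iterable[Triple]) -> "KnowledgeGraph":
        """Build a graph from triples, vocabularies in first-appearance order."""
        entities: dict[str, None] = {}
        relations: dict[str, None] = {}
        seen: set[Triple] = set()
        unique: list[Triple] = []
        for t in triples:
            if t in seen:
                continue
            seen.add(t)
            unique.append(t)
            entities.setdefault(t.head)
            entities.setdefault(t.tail)
            relations.setdefault(t.relation)
        return cls(list(entities), list(relations), unique)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self._triple_set

    def __len__(self) -> int:
        return len(self.triples)


def read_triples(path: str | Path) -> KnowledgeGraph:
    """Read a tab-separated triple file into a :class:`KnowledgeGraph`.

    Each non-empty, non-``#`` line must hold at least three tab-separated
    fields ``head<TAB>relation<TAB>tail``; extra fields are ignored and
    duplicate lines collapse to a single triple.
    """
    triples: list[Triple] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3 or any(f == "" for f in fields[:3]):
                raise TripleParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields, "
                    f"got {line!r}"
                )
            triples.append(Triple(fields[0], fields[1], fields[2]))
    return KnowledgeGraph.from_triples(triples)


def write_triples(kg: KnowledgeGraph, path: str | Path) -> None:
    """Write triples one per line, tab-separated, UTF-8."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in kg.triples:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def split_triples(
    kg: KnowledgeGraph,
    fractions: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[KnowledgeGraph, KnowledgeGraph, KnowledgeGraph]:
    """Partition triples into train/valid/test graphs.

    Sizes are ``floor(fraction * N)`` per split with the remainder assigned to
    train, so the partition is deterministic given ``seed``.  Vocabularies of
    each split are rebuilt in first-appearance order of its own triples.
    """
    if len(fractions) != 3:
        raise ValueError("fractions must be a (train, valid, test) triple")
    if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    n = len(kg.triples)
    n_valid = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_valid - n_test
    if n >= 3:
        for size, frac, name in (
            (n_train, fractions[0], "train"),
            (n_valid, fractions[1], "valid"),
            (n_test, fractions[2], "test"),
        ):
            if frac > 0 and size == 0:
                raise ValueError(f"{name} split is empty for fraction {frac}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    idx_train = sorted(order[:n_train])
    idx_valid = sorted(order[n_train : n_train + n_valid])
    idx_test = sorted(order[n_train + n_valid :])
    pick = lambda idx: KnowledgeGraph.from_triples(kg.triples[i] for i in idx)
    return pick(idx_train), pick(idx_valid), pick(idx_test)


def corrupt_triple(
    t: Triple,
    kg: KnowledgeGraph,
    rng: np.random.Generator,
    filtered: bool = True,
) -> Triple:
    """Produce a negative triple by replacing the head or the tail of ``t``.

    The corrupted side is chosen by a fair coin from ``rng`` and the
    replacement entity uniformly among eligible entities.  In ``filtered``
    mode (the default) a replacement that would re-create a known triple of
    ``kg`` is ineligible, so the sample is a guaranteed negative; the raw mode
    skips that membership check for speed.  If the coin-chosen side has no
    eligible entity the other side is tried; if neither side has one, a
    ``ValueError`` is raised.
    """
    if len(kg.entities) < 2:
        raise ValueError("need at least 2 entities to corrupt a triple")
    corrupt_head_first = bool(rng.integers(2))
    for corrupt_head in (corrupt_head_first, not corrupt_head_first):
        original = t.head if corrupt_head else t.tail
        eligible = []
        for e in kg.entities:
            if e == original:
                continue
            cand = Triple(e, t.relation, t.tail) if corrupt_head else Triple(t.head, t.relation, e)
            if filtered and cand in kg:
                continue
            eligible.append(cand)
        if eligible:
            return eligible[int(rng.integers(len(eligible)))]
    raise ValueError(f"no eligible corruption exists for {t}")
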