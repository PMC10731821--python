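"""DistMult knowledge-graph embedding: training and link-prediction ranking.

DistMult is the bilinear-diagonal model: a triple ``(h, r, t)`` scores
``sum_i h_i * r_i * t_i``, which is symmetric in head and tail.  Training
minimizes binary cross-entropy of the sigmoid score over observed triples
against uniformly sampled filtered negatives, with plain full-precision SGD
so that a seed fully determines the result.  Ranking evaluation reports mean
reciprocal rank and Hits@k over both head and tail prediction, with mean-rank
tie handling and an optional filtered candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embeddings import EmbeddingTable
from .kg import KnowledgeGraph, Triple

__all__ = [
    "KGETrainConfig",
    "RankingReport",
    "TrainedKGE",
    "distmult_score",
    "train_distmult",
    "evaluate_ranking",
]


@dataclass
class KGETrainConfig:
    """Hyperparameters of the DistMult trainer.

    ``dimension`` defaults to the 400-wide embedding space used for
    full-scale prediction; toy runs typically use 8-16.
    """

    dimension: int = 400
    epochs: int = 50
    learning_rate: float = 0.05
    negatives: int = 2
    batch_size: int = 256
    seed: int = 0
    weight_decay: float = 1e-4  # L2 on touched rows; keeps dense graphs stable
    grad_clip: float = 5.0  # elementwise clip, guards against SGD blow-up

    def __post_init__(self) -> None:
        if min(self.dimension, self.learning_rate, self.negatives, self.batch_size) <= 0:
            raise ValueError("dimension, learning_rate, negatives, batch_size must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")


@dataclass
class RankingReport:
    """MRR and Hits@k of a link-prediction evaluation."""

    mrr: float
    hits_at: dict[int, float]
    n_test: int


@dataclass
class TrainedKGE:
    """Entity and relation tables plus the per-epoch mean training loss."""

    entities: EmbeddingTable
    relations: EmbeddingTable
    epoch_losses: list[float] = field(default_factory=list)


def distmult_score(h_vec: np.ndarray, r_vec: np.ndarray, t_vec: np.ndarray) -> float:
    """Bilinear-diagonal triple score ``sum_i h_i * r_i * t_i``."""
    h_vec, r_vec, t_vec = (np.asarray(v, dtype=float) for v in (h_vec, r_vec, t_vec))
    if not (h_vec.shape == r_vec.shape == t_vec.shape) or h_vec.ndim != 1:
        raise ValueError("h, r and t vectors must be 1-D with equal length")
    return float(np.sum(h_vec * r_vec * t_vec))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_distmult(kg_train: KnowledgeGraph, config: KGETrainConfig) -> TrainedKGE:
    """Learn entity/relation embeddings on ``kg_train``.

    Initialization is uniform in ``[-0.5/sqrt(k), +0.5/sqrt(k)]`` from the
    config seed; ``epochs=0`` returns the raw initialization.  Each positive
    triple is paired with ``config.negatives`` corruptions (head or tail by a
    fair coin, resampled a few times if the corruption is itself a known
    triple), and a full SGD step is taken per minibatch.
    """
    if len(kg_train) == 0:
        raise ValueError("cannot train on an empty knowledge graph")
    k = config.dimension
    rng = np.random.default_rng(config.seed)
    n_ent, n_rel = len(kg_train.entities), len(kg_train.relations)
    ent_idx = {e: i for i, e in enumerate(kg_train.entities)}
    rel_idx = {r: i for i, r in enumerate(kg_train.relations)}
    scale = 0.5 / np.sqrt(k)
    E = rng.uniform(-scale, scale, size=(n_ent, k))
    R = rng.uniform(-scale, scale, size=(n_rel, k))

    heads = np.array([ent_idx[t.head] for t in kg_train.triples])
    rels = np.array([rel_idx[t.relation] for t in kg_train.triples])
    tails = np.array([ent_idx[t.tail] for t in kg_train.triples])
    known = {(h, r, t) for h, r, t in zip(heads, rels, tails)}
    n_pos = len(heads)
    losses: list[float] = []

    for _ in range(config.epochs):
        order = rng.permutation(n_pos)
        epoch_loss = 0.0
        n_examples = 0
        for start in range(0, n_pos, config.batch_size):
            batch = order[start : start + config.batch_size]
            bh, br, bt = heads[batch], rels[batch], tails[batch]
            # negatives: corrupt head or tail uniformly, filtered with retries
            neg_h = np.repeat(bh, config.negatives)
            neg_r = np.repeat(br, config.negatives)
            neg_t = np.repeat(bt, config.negatives)
            corrupt_head = rng.integers(2, size=neg_h.shape[0]).astype(bool)
            repl = rng.integers(n_ent, size=neg_h.shape[0])
            for attempt in range(10):
                cand_h = np.where(corrupt_head, repl, neg_h)
                cand_t = np.where(corrupt_head, neg_t, repl)
                bad = np.array(
                    [(h, r, t) in known for h, r, t in zip(cand_h, neg_r, cand_t)]
                )
                if not bad.any():
                    break
                repl = np.where(bad, rng.integers(n_ent, size=repl.shape[0]), repl)
            neg_h, neg_t = cand_h, cand_t

            all_h = np.concatenate([bh, neg_h])
            all_r = np.concatenate([br, neg_r])
            all_t = np.concatenate([bt, neg_t])
            y = np.concatenate([np.ones(len(bh)), np.zeros(len(neg_h))])

            eh, er, et = E[all_h], R[all_r], E[all_t]
            scores = np.sum(eh * er * et, axis=1)
            p = _sigmoid(scores)
            eps = 1e-12
            epoch_loss += float(-np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
            n_examples += len(y)

            g = (p - y)[:, None]  # d(loss)/d(score)
            c = config.grad_clip
            wd = config.weight_decay
            grad_h = np.clip(g * er * et + wd * eh, -c, c)
            grad_r = np.clip(g * eh * et + wd * er, -c, c)
            grad_t = np.clip(g * eh * er + wd * et, -c, c)
            lr = config.learning_rate
            np.add.at(E, all_h, -lr * grad_h)
            np.add.at(R, all_r, -lr * grad_r)
            np.add.at(E, all_t, -lr * grad_t)
        losses.append(epoch_loss / max(n_examples, 1))

    return TrainedKGE(
        EmbeddingTable(list(kg_train.entities), E),
        EmbeddingTable(list(kg_train.relations), R),
        losses,
    )


def _rank_of(scores: np.ndarray, true_idx: int, pool: np.ndarray) -> float:
    """Mean-rank (1-based) of ``true_idx`` among candidate indices ``pool``."""
    s = scores[pool]
    s_true = scores[true_idx]
    higher = int(np.sum(s > s_true))
    tied = int(np.sum(s == s_true))  # includes the true candidate itself
    return higher + (tied + 1) / 2.0


def evaluate_ranking(
    entity_table: EmbeddingTable,
    relation_table: EmbeddingTable,
    test: KnowledgeGraph,
    filter_against: KnowledgeGraph | None = None,
    mode: str = "filtered",
    hits_ks: tuple[int, ...] = (1, 3, 10),
) -> RankingReport:
    """Rank each test triple's true head and true tail among all entities.

    For every test triple the true tail is ranked among all candidate tails
    by DistMult score (and symmetrically for the head); ties receive the mean
    rank of the tied block.  In ``filtered`` mode candidates that would form
    a known triple of ``filter_against`` (other than the test triple itself)
    are removed from the pool.
    """
    if mode not in ("raw", "filtered"):
        raise ValueError("mode must be 'raw' or 'filtered'")
    if mode == "filtered" and filter_against is None:
        raise ValueError("filtered mode needs a filter_against graph")
    ents = entity_table.ids
    ent_idx = {e: i for i, e in enumerate(ents)}
    E = entity_table.vectors
    for t in test.triples:
        for id_ in (t.head, t.tail):
            if id_ not in entity_table:
                raise KeyError(f"no embedding for entity {id_!r}")
        if t.relation not in relation_table:
            raise KeyError(f"no embedding for relation {t.relation!r}")

    rr: list[float] = []
    hits = {k: 0 for k in hits_ks}
    for triple in test.triples:
        h = ent_idx[triple.head]
        t = ent_idx[triple.tail]
        r_vec = relation_table.vector(triple.relation)
        for side in ("tail", "head"):
            if side == "tail":
                scores = E @ (E[h] * r_vec)
                true_idx = t
                known = lambda e: Triple(triple.head, triple.relation, e) in filter_against
            else:
                scores = E @ (E[t] * r_vec)
                true_idx = h
                known = lambda e: Triple(e, triple.relation, triple.tail) in filter_against
            if mode == "filtered":
                pool = np.array(
                    [i for i, e in enumerate(ents) if i == true_idx or not known(e)]
                )
            else:
                pool = np.arange(len(ents))
            rank = _rank_of(scores, true_idx, pool)
            rr.append(1.0 / rank)
            for k in hits_ks:
                if rank <= k:
                    hits[k] += 1
    n = len(rr)
    return RankingReport(
        mrr=float(np.mean(rr)),
        hits_at={k: hits[k] / n for k in hits_ks},
        n_test=len(test.triples),
    )


def mean_filtered_rank(
    entity_table: EmbeddingTable,
    relation_table: EmbeddingTable,
    test: KnowledgeGraph,
    filter_against: KnowledgeGraph,
) -> float:
    """Mean filtered rank (head and tail sides) of the true entities."""
    ents = entity_table.ids
    ent_idx = {e: i for i, e in enumerate(ents)}
    E = entity_table.vectors
    ranks: list[float] = []
    for triple in test.triples:
        h, t = ent_idx[triple.head], ent_idx[triple.tail]
        r_vec = relation_table.vector(triple.relation)
        tail_pool = np.array(
            [
                i
                for i, e in enumerate(ents)
                if i == t or Triple(triple.head, triple.relation, e) not in filter_against
            ]
        )
        head_pool = np.array(
            [
                i
                for i, e in enumerate(ents)
                if i == h or Triple(e, triple.relation, triple.tail) not in filter_against
            ]
        )
        ranks.append(_rank_of(E @ (E[h] * r_vec), t, tail_pool))
        ranks.append(_rank_of(E @ (E[t] * r_vec), h, head_pool))
    return float(np.mean(ranks))
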