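"""Modified multi-label k-nearest-neighbour classifier.

Similarity between protein vectors is the cosine coefficient. The k=10
nearest training proteins each vote for *all* of their function classes, and
every class collecting at least ``min_votes`` (=3) votes is assigned — a
protein can have multiple functions, so the classifier may emit several
labels per query. The confidence of an assigned class f is the mean cosine
between the query and the neighbours that voted for f.

Ranking ties at the k-th position are broken by protein id ascending so runs
are reproducible regardless of training-set iteration order. A query whose
vector is all-zero (no characteristic term in its abstracts) still gets
predictions by the vote, flagged ``zero_vector`` so evaluation can report
those separately.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .represent import FeatureVector


@dataclass(frozen=True)
class Prediction:
    protein_id: str
    class_id: str
    votes: int
    confidence: float
    zero_vector: bool = False


def cosine(p: FeatureVector | np.ndarray, q: FeatureVector | np.ndarray) -> float:
    """Cosine of the angle between two vectors; 0 if either is all-zero."""
    a = p.weights if isinstance(p, FeatureVector) else np.asarray(p, dtype=float)
    b = q.weights if isinstance(q, FeatureVector) else np.asarray(q, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


class KnnIndex:
    """Training vectors stacked for batch cosine queries."""

    def __init__(self, train: Mapping[str, tuple[FeatureVector, Iterable[str]]]):
        self.ids = sorted(train)
        self.labels = {p: frozenset(train[p][1]) for p in self.ids}
        self.matrix = np.vstack([train[p][0].weights for p in self.ids])
        norms = np.linalg.norm(self.matrix, axis=1)
        self._unit = np.divide(
            self.matrix,
            norms[:, None],
            out=np.zeros_like(self.matrix),
            where=norms[:, None] > 0,
        )

    def __len__(self) -> int:
        return len(self.ids)

    def similarities(self, query: FeatureVector) -> np.ndarray:
        qn = np.linalg.norm(query.weights)
        if qn == 0.0:
            return np.zeros(len(self.ids))
        return self._unit @ (query.weights / qn)

    def nearest(self, query: FeatureVector, k: int) -> list[tuple[str, float]]:
        """Top-k (protein id, cosine) by similarity descending, id ascending."""
        sims = self.similarities(query)
        order = np.argsort(-sims, kind="stable")[:k]
        return [(self.ids[i], float(sims[i])) for i in order]


def knn_predict(
    query_id: str,
    query: FeatureVector,
    train: Mapping[str, tuple[FeatureVector, Iterable[str]]] | KnnIndex,
    k: int = 10,
    min_votes: int = 3,
) -> list[Prediction]:
    """Predict function classes for one query protein.

    ``train`` maps training protein id -> (vector, label set); the query
    protein must not be in it. Returns one :class:`Prediction` per class with
    at least ``min_votes`` votes among the k nearest neighbours, ordered by
    descending vote count then class id.
    """
    index = train if isinstance(train, KnnIndex) else KnnIndex(train)
    if len(index) < k:
        raise ValueError(f"need at least k={k} training proteins, have {len(index)}")
    neighbours = index.nearest(query, k)
    zero = bool(np.linalg.norm(query.weights) == 0.0)

    votes: Counter = Counter()
    voters: dict[str, list[float]] = {}
    for pid, sim in neighbours:
        for label in index.labels[pid]:
            votes[label] += 1
            voters.setdefault(label, []).append(sim)
    predictions = [
        Prediction(
            protein_id=query_id,
            class_id=class_id,
            votes=n,
            confidence=confidence_from_cosines(voters[class_id]),
            zero_vector=zero,
        )
        for class_id, n in votes.items()
        if n >= min_votes
    ]
    predictions.sort(key=lambda p: (-p.votes, p.class_id))
    return predictions


def confidence_from_cosines(cosines: Sequence[float]) -> float:
    """Confidence C_f(p): the mean cosine between p and its class-f voters."""
    if not cosines:
        raise ValueError("confidence requires at least one voting neighbour")
    return float(sum(cosines) / len(cosines))


def write_predictions_tsv(predictions: Iterable[Prediction], stream: IO[str]) -> None:
    stream.write("protein_id\tclass_id\tvotes\tconfidence\tzero_vector\n")
    for p in predictions:
        stream.write(
            f"{p.protein_id}\t{p.class_id}\t{p.votes}\t{p.confidence:.12g}"
            f"\t{int(p.zero_vector)}\n"
        )


def write_cafa_submission(predictions: Iterable[Prediction], stream: IO[str]) -> None:
    """``protein_id<TAB>go_id<TAB>score`` with scores clamped into (0, 1]."""
    for p in predictions:
        score = min(max(p.confidence, 1e-6), 1.0)
        stream.write(f"{p.protein_id}\t{p.class_id}\t{score:.3f}\n")
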