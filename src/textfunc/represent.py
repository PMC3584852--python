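"""Protein feature vectors over the characteristic-term axes.

A protein with linked abstracts D_p is a bag of words over the union term set
T_N: the weight of term t_i is the number of occurrences of t_i across D_p
divided by the total occurrences of all T_N terms in D_p (raw multiplicity,
not per-abstract presence). Non-zero vectors therefore sum to 1; a protein
whose abstracts contain no characteristic term gets the all-zero vector.

A *textless* protein (no linked abstracts) borrows text features from its
homologs: take the three hits with the lowest e-values among proteins that do
have text vectors, scale each vector by the hit's percent identity, and
average over three. The result is deliberately not renormalised — cosine
similarity is scale-invariant, so classification is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .corpus import AbstractDoc
from .features import CharacteristicTerms


@dataclass(frozen=True)
class HomologHit:
    subject_protein_id: str
    e_value: float | None
    percent_identity: float  # fraction in [0, 1]
    score: float = 0.0  # alignment score, used for ranking when e-values are absent


@dataclass
class FeatureVector:
    """Weights over a fixed term order; non-zero weights sum to 1."""

    weights: np.ndarray
    feature_order: tuple[str, ...]

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.feature_order),):
            raise ValueError("weight vector does not match feature order")

    @property
    def is_zero(self) -> bool:
        return not self.weights.any()


def vectorize(
    protein_docs: Iterable[AbstractDoc], terms: CharacteristicTerms
) -> FeatureVector:
    """Normalised term-count vector of a protein's abstract set D_p."""
    index = terms.term_index
    weights = np.zeros(len(terms.union_terms))
    for doc in protein_docs:
        for term, count in doc.terms.items():
            i = index.get(term)
            if i is not None:
                weights[i] += count
    total = weights.sum()
    if total > 0:
        weights /= total
    return FeatureVector(weights, terms.union_terms)


def rank_hits(hits: Sequence[HomologHit]) -> list[HomologHit]:
    """Sort by e-value ascending (score descending when e-values are absent);
    ties broken by subject id for determinism."""
    if any(h.e_value is None for h in hits):
        return sorted(hits, key=lambda h: (-h.score, h.subject_protein_id))
    return sorted(hits, key=lambda h: (h.e_value, h.subject_protein_id))


class NoHomologsError(ValueError):
    """A textless protein has no homolog with a text-derived vector."""


def textless_vector(
    query_id: str,
    hits: Sequence[HomologHit],
    reference_vectors: Mapping[str, FeatureVector],
    n_homologs: int = 3,
) -> FeatureVector:
    """Identity-weighted combination of the top homologs' text vectors.

    The best ``n_homologs`` hits (by e-value) that have reference vectors are
    combined as sum_j identity_j * v_j / count, where count is the number of
    homologs actually used (the divisor shrinks with the hit list rather than
    staying at 3, so a single strong homolog is not systematically damped).
    """
    usable = [h for h in rank_hits(hits) if h.subject_protein_id in reference_vectors]
    if not usable:
        raise NoHomologsError(f"no homologs with text for {query_id}")
    top = usable[:n_homologs]
    order = reference_vectors[top[0].subject_protein_id].feature_order
    weights = np.zeros(len(order))
    for hit in top:
        weights += hit.percent_identity * reference_vectors[hit.subject_protein_id].weights
    weights /= len(top)
    return FeatureVector(weights, order)


def read_blast_tabular(stream: IO[str]) -> dict[str, list[HomologHit]]:
    """Read BLAST ``-outfmt 6`` rows into query -> ranked hits.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore. ``pident`` (0-100) is converted to a fraction.
    """
    hits: dict[str, list[HomologHit]] = {}
    for line_no, line in enumerate(stream, 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 12:
            raise ValueError(f"BLAST tabular line {line_no}: expected 12 columns")
        hits.setdefault(fields[0], []).append(
            HomologHit(
                subject_protein_id=fields[1],
                e_value=float(fields[10]),
                percent_identity=float(fields[2]) / 100.0,
                score=float(fields[11]),
            )
        )
    return {q: rank_hits(h) for q, h in hits.items()}


def write_sparse_vectors(
    vectors: Mapping[str, FeatureVector], stream: IO[str]
) -> None:
    """Write ``protein_id<TAB>term<TAB>weight`` rows (non-zero weights only)."""
    for protein_id in sorted(vectors):
        vec = vectors[protein_id]
        for i in np.flatnonzero(vec.weights):
            stream.write(
                f"{protein_id}\t{vec.feature_order[i]}\t{vec.weights[i]:.12g}\n"
            )


def read_sparse_vectors(
    stream: IO[str], feature_order: Sequence[str]
) -> dict[str, FeatureVector]:
    """Read vectors written by :func:`write_sparse_vectors`."""
    order = tuple(feature_order)
    index = {t: i for i, t in enumerate(order)}
    out: dict[str, FeatureVector] = {}
    for line in stream:
        if not line.strip():
            continue
        protein_id, term, weight = line.rstrip("\n").split("\t")
        vec = out.setdefault(protein_id, FeatureVector(np.zeros(len(order)), order))
        vec.weights[index[term]] = float(weight)
    return out
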