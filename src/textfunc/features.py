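"""Characteristic-term selection by the pooled two-proportion Z-score.

For a term *t* and function classes *f*, *f'*, let Pr(t|f) be the fraction of
class-*f* abstracts containing *t* (presence, not multiplicity). The
significance of the difference in occurrence probability is

    Z_{f,f'}(t) = (Pr(t|f) - Pr(t|f'))
                  / sqrt( P.(1-P.) (1/|D_f| + 1/|D_f'|) )

with the pooled estimate P. = (|D_f| Pr(t|f) + |D_f'| Pr(t|f')) / (|D_f|+|D_f'|).
A term is *characteristic* for class f iff |Z_{f,f'}(t)| exceeds the threshold
against every other class f' of the same namespace. When P. is 0 or 1 both
probabilities sit on the boundary, there is no discriminative evidence, and Z
is defined as 0. The union of all per-class characteristic terms, in fixed
lexicographic order, forms the feature axes for protein vectors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus import AbstractDoc, Vocabulary

logger = logging.getLogger(__name__)


class NoCharacteristicTermsError(ValueError):
    """No term passes the Z-score threshold for any class."""


@dataclass
class TermClassStats:
    """Per-class document counts and term-presence counts.

    ``class_ids`` fixes the column order; ``n_docs[c]`` is |D_c| and
    ``presence[t]`` a vector of per-class counts of abstracts containing t.
    """

    class_ids: tuple[str, ...]
    n_docs: dict[str, int]
    presence: dict[str, np.ndarray]

    def prob(self, term: str, class_id: str) -> float:
        col = self.class_ids.index(class_id)
        counts = self.presence.get(term)
        if counts is None:
            return 0.0
        return counts[col] / self.n_docs[class_id]


def compute_stats(
    class_docs: Mapping[str, Sequence[AbstractDoc]],
    vocabulary: Vocabulary | None = None,
) -> TermClassStats:
    """Tally per-class term presence, optionally restricted to a vocabulary."""
    class_ids = tuple(sorted(class_docs))
    for c in class_ids:
        if not class_docs[c]:
            raise ValueError(f"class {c} has no abstracts")
    presence: dict[str, np.ndarray] = {}
    for col, c in enumerate(class_ids):
        for doc in class_docs[c]:
            for term in set(doc.terms):
                if vocabulary is not None and term not in vocabulary:
                    continue
                row = presence.get(term)
                if row is None:
                    row = presence[term] = np.zeros(len(class_ids))
                row[col] += 1
    return TermClassStats(
        class_ids=class_ids,
        n_docs={c: len(class_docs[c]) for c in class_ids},
        presence=presence,
    )


def class_term_probability(
    term: str, class_id: str, class_docs: Mapping[str, Sequence[AbstractDoc]]
) -> float:
    """Maximum-likelihood Pr(term | class): fraction of class abstracts containing it."""
    docs = class_docs[class_id]
    if not docs:
        raise ValueError(f"class {class_id} has no abstracts")
    return sum(1 for d in docs if term in d.terms) / len(docs)


def pooled_z(p1: float, n1: int, p2: float, n2: int) -> float:
    """Pooled two-proportion z-statistic; 0 when the pooled estimate is degenerate."""
    pooled = (n1 * p1 + n2 * p2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if var <= 0.0:
        return 0.0
    return (p1 - p2) / math.sqrt(var)


def z_score(term: str, f: str, f_prime: str, stats: TermClassStats) -> float:
    """Z_{f,f'}(term) from tallied statistics."""
    if stats.n_docs[f] < 1 or stats.n_docs[f_prime] < 1:
        raise ValueError("both classes need at least one abstract")
    return pooled_z(
        stats.prob(term, f), stats.n_docs[f],
        stats.prob(term, f_prime), stats.n_docs[f_prime],
    )


@dataclass
class CharacteristicTerms:
    """Per-class selected terms and their union (the fixed feature axes)."""

    per_class: dict[str, set[str]]
    union_terms: tuple[str, ...]
    z_threshold: float

    @property
    def term_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.union_terms)}


def select_characteristic_terms(
    vocabulary: Vocabulary,
    class_docs: Mapping[str, Sequence[AbstractDoc]],
    z_threshold: float = 1.96,
    signed: bool = False,
) -> CharacteristicTerms:
    """Select, per class, the vocabulary terms significant against all other classes.

    With ``signed=True`` the over-representation direction is required
    (Z > threshold rather than |Z| > threshold), i.e. a term must be *more*
    frequent in the class than in every other class.
    """
    if len(class_docs) < 2:
        raise ValueError("need at least two classes to contrast")
    stats = compute_stats(class_docs, vocabulary)
    class_ids = stats.class_ids
    n = np.array([stats.n_docs[c] for c in class_ids], dtype=float)

    terms = sorted(vocabulary.terms)
    counts = np.zeros((len(terms), len(class_ids)))
    for i, t in enumerate(terms):
        row = stats.presence.get(t)
        if row is not None:
            counts[i] = row
    probs = counts / n  # (T, C)

    per_class: dict[str, set[str]] = {c: set() for c in class_ids}
    for a in range(len(class_ids)):
        ok = np.ones(len(terms), dtype=bool)
        for b in range(len(class_ids)):
            if a == b:
                continue
            pooled = (n[a] * probs[:, a] + n[b] * probs[:, b]) / (n[a] + n[b])
            var = pooled * (1.0 - pooled) * (1.0 / n[a] + 1.0 / n[b])
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(var > 0.0, (probs[:, a] - probs[:, b]) / np.sqrt(var), 0.0)
            ok &= (z if signed else np.abs(z)) > z_threshold
        per_class[class_ids[a]] = {terms[i] for i in np.flatnonzero(ok)}
        logger.info(
            "class %s: %d characteristic terms", class_ids[a], int(ok.sum())
        )

    union = sorted(set().union(*per_class.values()))
    if not union:
        raise NoCharacteristicTermsError(
            f"no characteristic terms at |Z| > {z_threshold}"
        )
    return CharacteristicTerms(per_class, tuple(union), z_threshold)


def write_terms_report(terms: CharacteristicTerms, stats: TermClassStats, path) -> None:
    """TSV report ``class_id<TAB>term<TAB>min_abs_z`` plus a feature-order file."""
    with open(path, "w") as fh:
        fh.write("class_id\tterm\tmin_abs_z\n")
        for class_id in sorted(terms.per_class):
            for term in sorted(terms.per_class[class_id]):
                min_z = min(
                    abs(z_score(term, class_id, other, stats))
                    for other in stats.class_ids
                    if other != class_id
                )
                fh.write(f"{class_id}\t{term}\t{min_z:.6g}\n")
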