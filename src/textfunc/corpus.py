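"""Abstract ingestion and text preprocessing.

Abstracts are reduced to a bag of stemmed unigrams and bigrams:

    lowercase -> split on non-alphanumeric runs -> drop tokens shorter than
    two characters and pure numbers -> Porter-stem -> form unigrams and
    bigrams of consecutive stemmed tokens -> drop stop-word unigrams and any
    bigram with a stop-word component.

Bigrams are rendered as ``"tokA tokB"``. The candidate vocabulary is then
pruned by document frequency: terms in more than ``max_df_frac`` of the
abstracts are too common to discriminate, terms in fewer than
``min_df_count`` abstracts are too rare to test. An abstract linked to many
proteins of differing function cannot characterise any one class and is
excluded (:func:`filter_promiscuous_abstracts`).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

from ._porter import stem

logger = logging.getLogger(__name__)

#: Fixed English stop-word list shipped with the package (versioned here so
#: preprocessing is reproducible; matching is done on stemmed forms).
STOPWORDS: frozenset[str] = frozenset("""
a about above after again against all am an and any are as at be because been
before being below between both but by can cannot could did do does doing down
during each few for from further had has have having he her here hers herself
him himself his how i if in into is it its itself just me more most my myself
no nor not now of off on once only or other our ours ourselves out over own
same she should so some such than that the their theirs them themselves then
there these they this those through to too under until up very was we were
what when where which while who whom why will with you your yours yourself
yourselves
""".split())

_TOKEN_SPLIT = re.compile(r"[^a-z0-9]+")
_PURE_NUMBER = re.compile(r"^[0-9]+$")


@dataclass
class AbstractDoc:
    """One abstract: raw text, its processed term multiset and linked proteins."""

    pmid: str
    raw_text: str
    terms: Counter = field(default_factory=Counter)
    linked_proteins: set[str] = field(default_factory=set)


def preprocess_abstract(
    raw_text: str, stopword_set: frozenset[str] | set[str] = STOPWORDS
) -> Counter:
    """Turn raw abstract text into a multiset of stemmed unigrams and bigrams."""
    stopstems = {stem(w) for w in stopword_set}
    tokens = [
        stem(t)
        for t in _TOKEN_SPLIT.split(raw_text.lower())
        if len(t) >= 2 and not _PURE_NUMBER.match(t)
    ]
    terms: Counter = Counter(t for t in tokens if t not in stopstems)
    for a, b in zip(tokens, tokens[1:]):
        if a not in stopstems and b not in stopstems:
            terms[f"{a} {b}"] += 1
    return terms


def read_abstracts_tsv(stream: IO[str]) -> dict[str, str]:
    """Read ``pmid<TAB>text`` rows into a pmid -> text mapping."""
    abstracts: dict[str, str] = {}
    for line_no, line in enumerate(stream, 1):
        if not line.strip():
            continue
        try:
            pmid, text = line.rstrip("\n").split("\t", 1)
        except ValueError:
            raise ValueError(f"abstracts TSV line {line_no}: expected 2 columns")
        abstracts[pmid] = text
    return abstracts


def read_links_tsv(stream: IO[str]) -> list[tuple[str, str]]:
    """Read ``protein_id<TAB>pmid`` link rows."""
    links = []
    for line_no, line in enumerate(stream, 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ValueError(f"links TSV line {line_no}: expected 2 columns")
        links.append((fields[0], fields[1]))
    return links


def build_docs(
    abstracts: Mapping[str, str],
    links: Iterable[tuple[str, str]],
    stopword_set: frozenset[str] | set[str] = STOPWORDS,
) -> list[AbstractDoc]:
    """Assemble :class:`AbstractDoc` objects from abstract text and links."""
    docs = {
        pmid: AbstractDoc(pmid, text, preprocess_abstract(text, stopword_set))
        for pmid, text in abstracts.items()
    }
    for protein_id, pmid in links:
        if pmid in docs:
            docs[pmid].linked_proteins.add(protein_id)
        else:
            logger.warning("link to unknown pmid %s ignored", pmid)
    return [docs[pmid] for pmid in sorted(docs)]


class EmptyVocabularyError(ValueError):
    """No term survives the document-frequency window."""


@dataclass
class Vocabulary:
    """Document frequencies of the retained candidate terms."""

    doc_freq: dict[str, int]
    n_docs: int
    max_df_frac: float = 0.7
    min_df_count: int = 3

    @property
    def terms(self) -> set[str]:
        return set(self.doc_freq)

    def __contains__(self, term: str) -> bool:
        return term in self.doc_freq

    def __len__(self) -> int:
        return len(self.doc_freq)


def build_vocabulary(
    docs: Sequence[AbstractDoc],
    max_df_frac: float = 0.7,
    min_df_count: int = 3,
) -> Vocabulary:
    """Candidate vocabulary from training abstracts, df-window pruned.

    Document frequency counts presence, not multiplicity. Terms in more than
    ``max_df_frac`` of the documents or fewer than ``min_df_count`` documents
    are removed.
    """
    if not docs:
        raise ValueError("cannot build a vocabulary from zero documents")
    df: Counter = Counter()
    for doc in docs:
        df.update(set(doc.terms))
    max_df = int(max_df_frac * len(docs))
    kept = {
        t: c for t, c in df.items() if min_df_count <= c <= max_df
    }
    if not kept:
        raise EmptyVocabularyError(
            f"no term has document frequency in [{min_df_count}, {max_df}] "
            f"over {len(docs)} documents"
        )
    return Vocabulary(kept, len(docs), max_df_frac, min_df_count)


def filter_promiscuous_abstracts(
    abstracts: Sequence[AbstractDoc],
    protein_labels: Mapping[str, frozenset[str]],
    max_distinct: int = 3,
) -> list[AbstractDoc]:
    """Drop abstracts linked to many proteins of differing function.

    An abstract is removed iff it is linked to more than ``max_distinct``
    labelled proteins and those proteins' label sets are not all equal —
    such an abstract cannot discriminate any single class.
    """
    kept = []
    n_removed = 0
    for doc in abstracts:
        labelled = [p for p in doc.linked_proteins if p in protein_labels]
        if len(labelled) > max_distinct:
            label_sets = {protein_labels[p] for p in labelled}
            if len(label_sets) > 1:
                n_removed += 1
                continue
        kept.append(doc)
    if n_removed:
        logger.info(
            "filter_promiscuous_abstracts: removed %d of %d abstracts",
            n_removed, len(abstracts),
        )
    return kept
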