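"""Baseline classifiers: prior-distribution sampling and sequence-similarity voting.

*Base-Prior* fits the label frequencies of the training proteins and assigns
each test protein a single label by Monte-Carlo sampling from that
distribution, with the class prior as confidence. Its ``assign_all`` mode
(the CAFA-style prior) instead emits *every* class for every protein, again
with the prior as confidence.

*Base-Seq* ranks training proteins by sequence similarity to the query, takes
the top k=10 hits, and votes exactly like the text kNN: every class shared by
at least ``min_votes`` hits is assigned. Similarity comes from a pluggable
backend: a built-in Smith-Waterman local aligner (BLOSUM62, gap open 11,
extend 1), precomputed BLAST tabular files, or an external blastp executable.
Base-Seq confidence is the mean percent identity of the voting hits.
"""

from __future__ import annotations

import io
import logging
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .classify import Prediction
from .represent import HomologHit, rank_hits, read_blast_tabular

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Base-Prior
# ---------------------------------------------------------------------------

@dataclass
class PriorModel:
    """Label-occurrence frequencies over training proteins."""

    class_probs: dict[str, float]
    mode: str = "sample"  # or "assign_all"


def prior_fit(
    training_labels: Mapping[str, Iterable[str]], mode: str = "sample"
) -> PriorModel:
    """Fit class priors; multi-label proteins contribute one count per label."""
    if not training_labels:
        raise ValueError("cannot fit a prior on zero proteins")
    if mode not in ("sample", "assign_all"):
        raise ValueError(f"unknown prior mode: {mode}")
    counts: Counter = Counter()
    for labels in training_labels.values():
        counts.update(labels)
    total = sum(counts.values())
    return PriorModel(
        class_probs={c: counts[c] / total for c in sorted(counts)}, mode=mode
    )


def prior_predict(
    model: PriorModel,
    protein_ids: Sequence[str],
    rng_seed: int | np.random.Generator = 0,
) -> list[Prediction]:
    """Assign labels from the prior: one sampled label per protein in ``sample``
    mode, or every class per protein in ``assign_all`` mode. Confidence is the
    class prior either way."""
    classes = sorted(model.class_probs)
    probs = np.array([model.class_probs[c] for c in classes])
    if model.mode == "assign_all":
        return [
            Prediction(p, c, votes=0, confidence=model.class_probs[c])
            for p in protein_ids
            for c in classes
        ]
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    draws = rng.choice(len(classes), size=len(protein_ids), p=probs)
    return [
        Prediction(p, classes[i], votes=0, confidence=float(probs[i]))
        for p, i in zip(protein_ids, draws)
    ]


# ---------------------------------------------------------------------------
# Sequence similarity backends
# ---------------------------------------------------------------------------

def builtin_align(query_seq: str, ref_seq: str) -> tuple[float, float]:
    """Smith-Waterman local alignment score and percent identity.

    BLOSUM62 scoring with gap open 11 / extend 1; percent identity is the
    number of identical aligned positions divided by the alignment length
    (columns, including gaps).
    """
    if not query_seq or not ref_seq:
        raise ValueError("cannot align an empty sequence")
    for seq in (query_seq, ref_seq):
        bad = set(seq.upper()) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard residues: {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    alignments = aligner.align(query_seq.upper(), ref_seq.upper())
    try:
        best = alignments[0]
    except IndexError:  # no positive-scoring local alignment
        return 0.0, 0.0
    counts = best.counts()
    identity = counts.identities / best.length if best.length else 0.0
    return float(best.score), float(identity)


class BuiltinAligner:
    """SimilarityBackend over the built-in Smith-Waterman aligner.

    Hits are ranked by alignment score descending (no e-value statistics are
    computed), ties by subject id.
    """

    def rank(self, query_seq: str, refs: Mapping[str, str]) -> list[HomologHit]:
        hits = []
        for subject_id in sorted(refs):
            score, identity = builtin_align(query_seq, refs[subject_id])
            if score > 0.0:
                hits.append(
                    HomologHit(subject_id, e_value=None,
                               percent_identity=identity, score=score)
                )
        return rank_hits(hits)


class BlastTabularBackend:
    """SimilarityBackend over precomputed BLAST ``-outfmt 6`` hits."""

    def __init__(self, stream_or_path: IO[str] | str | Path):
        if isinstance(stream_or_path, (str, Path)):
            with open(stream_or_path) as fh:
                self.hits = read_blast_tabular(fh)
        else:
            self.hits = read_blast_tabular(stream_or_path)
        self.query_id: str | None = None  # set before rank() is called

    def rank(self, query_seq: str, refs: Mapping[str, str]) -> list[HomologHit]:
        if self.query_id is None:
            raise ValueError("BlastTabularBackend.query_id must be set before rank()")
        return [
            h for h in self.hits.get(self.query_id, []) if h.subject_protein_id in refs
        ]


class BlastExecutableBackend:
    """SimilarityBackend calling an external ``blastp`` (never required by tests)."""

    def __init__(self, blastp: str = "blastp", makeblastdb: str = "makeblastdb"):
        self.blastp = blastp
        self.makeblastdb = makeblastdb

    def rank(self, query_seq: str, refs: Mapping[str, str]) -> list[HomologHit]:
        with tempfile.TemporaryDirectory() as tmp:
            db = Path(tmp) / "refs.fasta"
            db.write_text(
                "".join(f">{pid}\n{seq}\n" for pid, seq in sorted(refs.items()))
            )
            query = Path(tmp) / "query.fasta"
            query.write_text(f">query\n{query_seq}\n")
            subprocess.run(
                [self.makeblastdb, "-in", str(db), "-dbtype", "prot"],
                check=True, capture_output=True,
            )
            result = subprocess.run(
                [self.blastp, "-query", str(query), "-db", str(db), "-outfmt", "6"],
                check=True, capture_output=True, text=True,
            )
        hits = read_blast_tabular(io.StringIO(result.stdout))
        return hits.get("query", [])


def read_fasta(stream_or_path: IO[str] | str | Path) -> dict[str, str]:
    """Read protein sequences keyed by record id."""
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(stream_or_path, "fasta")
    }


# ---------------------------------------------------------------------------
# Base-Seq
# ---------------------------------------------------------------------------

def base_seq_predict(
    query_id: str,
    query_seq: str,
    backend,
    train: Mapping[str, tuple[str, Iterable[str]]],
    k: int = 10,
    min_votes: int = 3,
) -> list[Prediction]:
    """Vote over the top-k sequence-similarity hits, as the text kNN does.

    ``train`` maps protein id -> (sequence, label set). If the backend
    returns fewer than k hits, voting runs over however many exist; no hits
    at all yields no predictions (logged).
    """
    if len(train) < k:
        raise ValueError(f"need at least k={k} training proteins, have {len(train)}")
    if hasattr(backend, "query_id"):
        backend.query_id = query_id
    refs = {pid: seq for pid, (seq, _) in train.items()}
    hits = backend.rank(query_seq, refs)[:k]
    if not hits:
        logger.warning("base_seq: no similarity hits for %s", query_id)
        return []
    votes: Counter = Counter()
    identities: dict[str, list[float]] = {}
    for hit in hits:
        for label in train[hit.subject_protein_id][1]:
            votes[label] += 1
            identities.setdefault(label, []).append(hit.percent_identity)
    predictions = [
        Prediction(
            protein_id=query_id,
            class_id=class_id,
            votes=n,
            confidence=float(np.mean(identities[class_id])),
        )
        for class_id, n in votes.items()
        if n >= min_votes
    ]
    predictions.sort(key=lambda p: (-p.votes, p.class_id))
    return predictions
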