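"""Self-contained synthetic fixtures: GO-like DAG, labelled proteins,
abstracts with planted class-characteristic terms, and sequence families.

The generator emulates the statistical structure the term-selection step
assumes: each function class has ``planted_terms_per_class`` marker tokens
that occur in an abstract of a class member with probability ``p_in`` and in
other abstracts with probability ``p_out``, on top of a Zipf-distributed
background vocabulary (so that frequent, uninformative words exist — the
ingredient behind the small-class failure mode). Sequences form one family
per class: point-mutated copies of a class ancestor, with expected pairwise
identity governed by ``within_class_identity``.

Default sizes (5 classes x 100 proteins, 1-3 abstracts per protein — about
two per protein, the ratio seen in curated protein databases) keep every
downstream module testable in seconds without any external corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import corpus, features
from .baselines import AMINO_ACIDS
from .ontology import Annotation

GO_ROOT = "GO:0000001"


@dataclass
class SynthConfig:
    n_classes: int = 5
    proteins_per_class: int | Sequence[int] = 100
    abstracts_per_protein: tuple[int, int] = (1, 3)
    vocab_size: int = 2000
    planted_terms_per_class: int = 10
    p_in: float = 0.6
    p_out: float = 0.05
    zipf_exponent: float = 1.1
    abstract_length: tuple[int, int] = (80, 200)
    multi_label_fraction: float = 0.1
    textless_fraction: float = 0.0
    seq_length: int = 120
    within_class_identity: float = 0.9
    namespace: str = "molecular_function"
    seed: int = 0

    def class_sizes(self) -> list[int]:
        if isinstance(self.proteins_per_class, int):
            return [self.proteins_per_class] * self.n_classes
        sizes = list(self.proteins_per_class)
        if len(sizes) != self.n_classes:
            raise ValueError("proteins_per_class list must have n_classes entries")
        return sizes

    def validate(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if any(s < 1 for s in self.class_sizes()):
            raise ValueError("class sizes must be positive")
        for name in ("abstracts_per_protein", "abstract_length"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if not 0.0 <= self.multi_label_fraction <= 1.0:
            raise ValueError("multi_label_fraction must be in [0, 1]")
        if not 0.0 <= self.textless_fraction < 1.0:
            raise ValueError("textless_fraction must be in [0, 1)")
        if not 0.0 < self.within_class_identity <= 1.0:
            raise ValueError("within_class_identity must be in (0, 1]")
        if self.vocab_size < 10 or self.planted_terms_per_class < 1:
            raise ValueError("vocab_size/planted_terms_per_class too small")


@dataclass
class SyntheticDataset:
    config: SynthConfig
    obo_text: str
    class_ids: list[str]
    annotations: list[Annotation]
    abstracts: dict[str, str]  # pmid -> text
    links: list[tuple[str, str]]  # (protein_id, pmid)
    labels: dict[str, frozenset[str]]  # ground-truth level-2 labels
    primary_class: dict[str, str]
    planted: dict[str, tuple[str, ...]]  # class_id -> planted marker tokens
    textless: set[str] = field(default_factory=set)
    sequences: dict[str, str] = field(default_factory=dict)

    def docs(self) -> list[corpus.AbstractDoc]:
        return corpus.build_docs(self.abstracts, self.links)


def _class_id(i: int) -> str:
    return f"GO:{10 + i:07d}"


def _leaf_id(class_index: int, leaf_index: int) -> str:
    return f"GO:{1000 + 10 * class_index + leaf_index:07d}"


def _make_obo(config: SynthConfig, class_ids: Sequence[str]) -> str:
    ns = config.namespace
    lines = ["format-version: 1.2", f"ontology: synthetic-{ns}", ""]
    lines += ["[Term]", f"id: {GO_ROOT}", f"name: {ns} root", f"namespace: {ns}", ""]
    for i, cid in enumerate(class_ids):
        lines += [
            "[Term]", f"id: {cid}", f"name: function class {i}",
            f"namespace: {ns}", f"is_a: {GO_ROOT} ! {ns} root", "",
        ]
        for leaf in range(2):
            lines += [
                "[Term]", f"id: {_leaf_id(i, leaf)}",
                f"name: leaf {leaf} of class {i}", f"namespace: {ns}",
                f"is_a: {cid} ! function class {i}", "",
            ]
    return "\n".join(lines)


def _zipf_probs(config: SynthConfig) -> np.ndarray:
    ranks = np.arange(1, config.vocab_size + 1, dtype=float)
    probs = ranks ** -config.zipf_exponent
    return probs / probs.sum()


def generate_corpus(config: SynthConfig) -> SyntheticDataset:
    """Build the ontology fixture, annotations, abstracts and links.

    Every protein carries one or two second-level labels (annotated at leaf
    terms so the collapse is exercised); each of its abstracts contains each
    planted term of a label class with probability ``p_in`` and every other
    class's planted terms with probability ``p_out``, plus Zipf background
    words. A ``textless_fraction`` of proteins receive no abstracts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    class_ids = [_class_id(i) for i in range(config.n_classes)]
    planted = {
        cid: tuple(f"mark{i}x{j}" for j in range(config.planted_terms_per_class))
        for i, cid in enumerate(class_ids)
    }
    background = np.array([f"bg{i:04d}" for i in range(config.vocab_size)])
    zipf = _zipf_probs(config)

    labels: dict[str, frozenset[str]] = {}
    primary: dict[str, str] = {}
    annotations: list[Annotation] = []
    abstracts: dict[str, str] = {}
    links: list[tuple[str, str]] = []
    textless: set[str] = set()
    pmid_counter = 0

    for ci, (cid, size) in enumerate(zip(class_ids, config.class_sizes())):
        for pi in range(size):
            pid = f"P{ci}_{pi:04d}"
            label_set = {cid}
            if (
                config.n_classes > 1
                and rng.random() < config.multi_label_fraction
            ):
                other = int(rng.integers(config.n_classes - 1))
                other = other + 1 if other >= ci else other
                label_set.add(class_ids[other])
            labels[pid] = frozenset(label_set)
            primary[pid] = cid
            for lab in sorted(label_set):
                leaf = _leaf_id(class_ids.index(lab), int(rng.integers(2)))
                annotations.append(Annotation(pid, leaf, "IDA"))

            if rng.random() < config.textless_fraction:
                textless.add(pid)
                continue
            lo, hi = config.abstracts_per_protein
            for _ in range(int(rng.integers(lo, hi + 1))):
                pmid_counter += 1
                pmid = f"PM{pmid_counter:06d}"
                length = int(
                    rng.integers(config.abstract_length[0], config.abstract_length[1] + 1)
                )
                tokens = list(background[rng.choice(config.vocab_size, size=length, p=zipf)])
                for other_cid in class_ids:
                    p = config.p_in if other_cid in label_set else config.p_out
                    for term in planted[other_cid]:
                        if rng.random() < p:
                            tokens.append(term)
                rng.shuffle(tokens)
                abstracts[pmid] = " ".join(tokens)
                links.append((pid, pmid))

    return SyntheticDataset(
        config=config,
        obo_text=_make_obo(config, class_ids),
        class_ids=class_ids,
        annotations=annotations,
        abstracts=abstracts,
        links=links,
        labels=labels,
        primary_class=primary,
        planted=planted,
        textless=textless,
    )


def generate_sequences(config: SynthConfig, dataset: SyntheticDataset) -> dict[str, str]:
    """One random ancestor per class; members are point-mutated copies.

    Each site mutates to a different residue with probability
    ``1 - within_class_identity``. Textless proteins get sequences from their
    class family, so homology-based vector transfer is recoverable. The
    mutation stream is seeded independently of the corpus stream
    (seed + 1) so corpora with and without sequences are otherwise identical.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    aa = np.array(list(AMINO_ACIDS))
    ancestors = {
        cid: rng.choice(len(aa), size=config.seq_length)
        for cid in dataset.class_ids
    }
    mutation_rate = 1.0 - config.within_class_identity
    sequences: dict[str, str] = {}
    for pid in sorted(dataset.labels):
        seq = ancestors[dataset.primary_class[pid]].copy()
        mutate = rng.random(config.seq_length) < mutation_rate
        if mutate.any():
            # substitute with a uniformly chosen *different* residue
            shift = rng.integers(1, len(aa), size=int(mutate.sum()))
            seq[mutate] = (seq[mutate] + shift) % len(aa)
        sequences[pid] = "".join(aa[seq])
    dataset.sequences = sequences
    return sequences


def generate(config: SynthConfig | None = None) -> SyntheticDataset:
    """Full fixture: corpus plus sequences."""
    config = config or SynthConfig()
    dataset = generate_corpus(config)
    generate_sequences(config, dataset)
    return dataset


def write_files(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture in the exact dialects the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ontology": out / "ontology.obo",
        "annotations": out / "annotations.tsv",
        "abstracts": out / "abstracts.tsv",
        "links": out / "links.tsv",
        "fasta": out / "sequences.fasta",
    }
    paths["ontology"].write_text(dataset.obo_text + "\n")
    paths["annotations"].write_text(
        "".join(f"{a.protein_id}\t{a.term_id}\t{a.evidence}\n" for a in dataset.annotations)
    )
    paths["abstracts"].write_text(
        "".join(f"{pmid}\t{text}\n" for pmid, text in sorted(dataset.abstracts.items()))
    )
    paths["links"].write_text(
        "".join(f"{pid}\t{pmid}\n" for pid, pmid in dataset.links)
    )
    if dataset.sequences:
        paths["fasta"].write_text(
            "".join(f">{pid}\n{seq}\n" for pid, seq in sorted(dataset.sequences.items()))
        )
    else:
        del paths["fasta"]
    return paths


def recover_planted_terms(
    dataset: SyntheticDataset,
    z_threshold: float = 1.96,
    max_df_frac: float = 0.7,
    min_df_count: int = 3,
) -> dict[str, float]:
    """Fraction of each class's planted terms selected as characteristic for it.

    Runs the full selection pipeline (preprocessing, df pruning, Z-score) over
    the whole corpus with ground-truth labels.
    """
    docs = dataset.docs()
    vocab = corpus.build_vocabulary(docs, max_df_frac, min_df_count)
    class_docs: dict[str, list[corpus.AbstractDoc]] = {c: [] for c in dataset.class_ids}
    for doc in docs:
        for cid in {c for p in doc.linked_proteins for c in dataset.labels[p]}:
            class_docs[cid].append(doc)
    terms = features.select_characteristic_terms(vocab, class_docs, z_threshold)
    return {
        cid: sum(1 for t in dataset.planted[cid] if t in terms.per_class[cid])
        / len(dataset.planted[cid])
        for cid in dataset.class_ids
    }
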