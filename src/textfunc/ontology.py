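"""Gene Ontology handling: OBO parsing, GAF/TSV annotation reading, evidence
filtering, second-level collapse and construction of the function-class label
space.

The classifier does not predict individual GO terms: annotations are collapsed
upward to *second-level* categories — terms one ``is_a`` step below a
namespace root (e.g. ``binding`` or ``catalytic activity`` under
``molecular_function``). Only ``is_a`` edges define the hierarchy. Proteins
annotated with three or more distinct second-level categories within a
namespace are excluded as functionally ambiguous, and categories with fewer
than ``min_class_size`` member proteins are dropped (together with proteins
that thereby lose all labels).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, NamedTuple

import obonet

logger = logging.getLogger(__name__)

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")

#: GO evidence codes accepted by default: experimental / curator-reviewed
#: assignments only. Annotations inferred by computational methods are
#: excluded so the training labels are of high certainty.
INCLUDED_EVIDENCE = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "IC", "TAS"}
)
EXCLUDED_EVIDENCE = frozenset(
    {"ISS", "ISO", "ISA", "ISM", "IGC", "RCA", "IEA", "NAS"}
)
KNOWN_EVIDENCE = INCLUDED_EVIDENCE | EXCLUDED_EVIDENCE


class OboParseError(ValueError):
    """Raised when an OBO stream cannot be parsed."""


class Annotation(NamedTuple):
    protein_id: str
    term_id: str
    evidence: str
    qualifier: str = ""


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    namespace: str
    parents: frozenset[str]  # is_a parents, same namespace


@dataclass
class OntologyGraph:
    """An is_a DAG over GO terms, one root per namespace."""

    terms: dict[str, Term]
    alt_ids: dict[str, str]
    roots: dict[str, str]

    def resolve(self, term_id: str) -> str:
        """Map an alternate id to its primary id (primary ids pass through)."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_ids:
            return self.alt_ids[term_id]
        raise KeyError(f"unknown GO term: {term_id}")

    def level2_terms(self, namespace: str) -> set[str]:
        """Terms exactly one is_a step below the namespace root."""
        root = self.roots.get(namespace)
        if root is None:
            return set()
        return {
            t.term_id
            for t in self.terms.values()
            if t.namespace == namespace and root in t.parents
        }


def parse_obo(source: IO[str] | str) -> OntologyGraph:
    """Parse OBO 1.2/1.4 text into an :class:`OntologyGraph`.

    Obsolete terms are skipped, ``alt_id`` mappings are collected and only
    ``is_a`` edges are retained. A root is a term with no is_a parent in its
    namespace; each namespace present must have exactly one root.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph = obonet.read_obo(source)
    except Exception as exc:  # obonet raises ValueError on malformed stanzas
        raise OboParseError(f"malformed OBO stanza: {exc}") from exc

    terms: dict[str, Term] = {}
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        namespace = data.get("namespace", "")
        parents = frozenset(
            parent
            for _, parent, key in graph.out_edges(node, keys=True)
            if key == "is_a"
        )
        terms[node] = Term(node, data.get("name", node), namespace, parents)
        for alt in data.get("alt_id", []):
            if alt in alt_ids and alt_ids[alt] != node:
                raise OboParseError(
                    f"alt_id {alt} maps to both {alt_ids[alt]} and {node}"
                )
            alt_ids[alt] = node

    roots: dict[str, str] = {}
    for term in terms.values():
        same_ns_parents = {
            p for p in term.parents if terms.get(p, term).namespace == term.namespace
        }
        if not same_ns_parents and term.namespace:
            if term.namespace in roots:
                raise OboParseError(
                    f"multiple roots in namespace {term.namespace}: "
                    f"{roots[term.namespace]}, {term.term_id}"
                )
            roots[term.namespace] = term.term_id
    return OntologyGraph(terms=terms, alt_ids=alt_ids, roots=roots)


def _check_evidence(code: str, line_no: int, source: str) -> bool:
    if code not in KNOWN_EVIDENCE:
        logger.warning(
            "%s line %d: unknown evidence code %r, row skipped",
            source, line_no, code,
        )
        return False
    return True


def read_gaf(stream: IO[str]) -> list[Annotation]:
    """Read GO annotations from GAF 2.0/2.1/2.2 (tab-separated, ``!`` comments).

    Rows with unknown evidence codes are skipped with a warning.
    """
    annotations = []
    for line_no, line in enumerate(stream, 1):
        if not line.strip() or line.startswith("!"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 15:
            raise ValueError(f"GAF line {line_no}: expected >=15 columns, got {len(fields)}")
        protein_id, qualifier, term_id, evidence = (
            fields[1], fields[3], fields[4], fields[6],
        )
        if not _check_evidence(evidence, line_no, "GAF"):
            continue
        annotations.append(Annotation(protein_id, term_id, evidence, qualifier))
    return annotations


def read_annotations_tsv(stream: IO[str]) -> list[Annotation]:
    """Read the simple dialect ``protein_id<TAB>go_id<TAB>evidence[<TAB>qualifier]``."""
    annotations = []
    for line_no, line in enumerate(stream, 1):
        if not line.strip() or line.startswith(("#", "!")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"annotations TSV line {line_no}: expected >=3 columns"
            )
        qualifier = fields[3] if len(fields) > 3 else ""
        if not _check_evidence(fields[2], line_no, "annotations TSV"):
            continue
        annotations.append(Annotation(fields[0], fields[1], fields[2], qualifier))
    return annotations


def filter_evidence(
    annotations: Iterable[Annotation],
    policy: frozenset[str] | set[str] = INCLUDED_EVIDENCE,
) -> list[Annotation]:
    """Keep annotations whose evidence code is in ``policy``.

    NOT-qualified rows are dropped as well: a NOT annotation is evidence
    *against* class membership, not for it.
    """
    return [
        a
        for a in annotations
        if a.evidence in policy and "NOT" not in a.qualifier.split("|")
    ]


def level2_ancestors(term_id: str, graph: OntologyGraph) -> set[str]:
    """All second-level terms reachable upward from ``term_id`` via is_a.

    A term that is itself second-level returns ``{itself}``; a namespace root
    returns the empty set (with a warning).
    """
    primary = graph.resolve(term_id)
    term = graph.terms[primary]
    if primary in graph.roots.values():
        logger.warning("level2_ancestors called on namespace root %s", primary)
        return set()
    level2 = graph.level2_terms(term.namespace)
    found: set[str] = set()
    seen = {primary}
    frontier = [primary]
    while frontier:
        nxt = []
        for tid in frontier:
            if tid in level2:
                found.add(tid)
            for parent in graph.terms[tid].parents:
                if parent not in seen and parent in graph.terms:
                    seen.add(parent)
                    nxt.append(parent)
        frontier = nxt
    return found


@dataclass
class FunctionClass:
    """A second-level GO category used as a classification label."""

    class_id: str
    namespace: str
    members: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.members)


class NoTrainableClassesError(ValueError):
    """Raised when filtering leaves no usable function classes."""


def build_classes(
    proteins: Mapping[str, Iterable[Annotation]],
    graph: OntologyGraph,
    namespace: str,
    min_class_size: int = 15,
    max_level2_per_protein: int = 2,
) -> tuple[list[FunctionClass], dict[str, frozenset[str]]]:
    """Collapse evidence-filtered annotations to the second-level label space.

    Returns the retained classes (sorted by id) and a mapping of retained
    protein id -> its label set. Proteins with more than
    ``max_level2_per_protein`` distinct second-level labels in the namespace
    are excluded; classes with fewer than ``min_class_size`` members are
    dropped together with proteins that thereby lose all labels. The
    filtering is a single pass, not iterated to a fixed point.
    """
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace: {namespace}")
    root = graph.roots.get(namespace)

    labels: dict[str, frozenset[str]] = {}
    n_ambiguous = 0
    for protein_id, annotations in proteins.items():
        level2: set[str] = set()
        for ann in annotations:
            primary = graph.resolve(ann.term_id)
            if graph.terms[primary].namespace != namespace or primary == root:
                continue
            level2 |= level2_ancestors(primary, graph)
        if not level2:
            continue
        if len(level2) > max_level2_per_protein:
            n_ambiguous += 1
            continue
        labels[protein_id] = frozenset(level2)
    logger.info(
        "build_classes[%s]: %d proteins labelled, %d excluded with >%d level-2 labels",
        namespace, len(labels), n_ambiguous, max_level2_per_protein,
    )

    members: dict[str, set[str]] = {}
    for protein_id, label_set in labels.items():
        for class_id in label_set:
            members.setdefault(class_id, set()).add(protein_id)

    kept_classes = {c for c, m in members.items() if len(m) >= min_class_size}
    dropped = sorted(set(members) - kept_classes)
    if dropped:
        logger.info(
            "build_classes[%s]: dropped %d classes with <%d members: %s",
            namespace, len(dropped), min_class_size, ", ".join(dropped),
        )
    retained: dict[str, frozenset[str]] = {}
    for protein_id, label_set in labels.items():
        kept = label_set & kept_classes
        if kept:
            retained[protein_id] = frozenset(kept)

    if not kept_classes:
        raise NoTrainableClassesError(
            f"no trainable classes in namespace {namespace} "
            f"(min_class_size={min_class_size})"
        )
    classes = [
        FunctionClass(
            class_id=c,
            namespace=namespace,
            members={p for p, ls in retained.items() if c in ls},
        )
        for c in sorted(kept_classes)
    ]
    return classes, retained
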