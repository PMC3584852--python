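"""Stratified repeated cross-validation and metrics.

Proteins are partitioned into k=5 folds preserving the label distribution
(per label-set, fold counts differ by at most one); the whole 5-fold cycle is
repeated (5 times by default) under derived seeds. Within every fold the
pipeline is: build the vocabulary from training abstracts, select
characteristic terms on the training set only, vectorise train and test
proteins, classify, tally metrics — feature selection never sees test
abstracts.

Per class f, over the test proteins: TP if f was predicted and is a true
label, FP if predicted and not true, FN if true and not predicted, TN
otherwise. Precision = TP/(TP+FP), Recall = TP/(TP+FN),
F = 2PR/(P+R), Specificity = TN/(TN+FP); zero denominators yield 0. The
overall accuracy O_acc = C/n counts a test protein as correct when its
predicted label set intersects its true label set (an ``all`` mode requiring
every true label is available). Confidence thresholds are strict: a
prediction is kept when its confidence exceeds the threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from . import baselines, classify, corpus, features, represent

logger = logging.getLogger(__name__)


def stratified_folds(
    proteins_with_labels: Mapping[str, frozenset[str]],
    k: int = 5,
    seed: int = 0,
) -> list[set[str]]:
    """Partition proteins into k folds, stratified by label set.

    Within every label-set group the fold counts differ by at most one, so in
    single-label data every class keeps the same distribution across folds.
    Reproducible under ``seed``.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, ...], list[str]] = {}
    for pid, labels in proteins_with_labels.items():
        groups.setdefault(tuple(sorted(labels)), []).append(pid)

    folds: list[set[str]] = [set() for _ in range(k)]
    for key in sorted(groups):
        members = sorted(groups[key])
        if len(members) < k:
            logger.warning(
                "label group %s has %d < k=%d proteins", key, len(members), k
            )
        rng.shuffle(members)
        perm = rng.permutation(k)
        for chunk, fold_idx in zip(np.array_split(members, k), perm):
            folds[fold_idx].update(chunk.tolist())
    return folds


@dataclass
class ClassMetrics:
    class_id: str
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def recall(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)


@dataclass
class EvalReport:
    per_class: list[ClassMetrics]
    overall_accuracy: float
    n_test: int
    n_correct: int
    fold_id: int = 0
    repeat_id: int = 0
    confidence_threshold: float = 0.0


def _predicted_sets(
    predictions: Iterable[classify.Prediction],
) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for p in predictions:
        out.setdefault(p.protein_id, set()).add(p.class_id)
    return out


def per_class_metrics(
    predictions: Iterable[classify.Prediction],
    truth: Mapping[str, frozenset[str]],
    evaluated_classes: Sequence[str],
) -> list[ClassMetrics]:
    """Decision-level confusion tally for every evaluated class."""
    predicted = _predicted_sets(predictions)
    unknown = set(predicted) - set(truth)
    if unknown:
        raise ValueError(f"predictions for unknown proteins: {sorted(unknown)}")
    metrics = []
    for class_id in evaluated_classes:
        m = ClassMetrics(class_id)
        for pid, true_labels in truth.items():
            hit = class_id in predicted.get(pid, ())
            present = class_id in true_labels
            if hit and present:
                m.tp += 1
            elif hit:
                m.fp += 1
            elif present:
                m.fn += 1
            else:
                m.tn += 1
        metrics.append(m)
    return metrics


def overall_accuracy(
    predictions: Iterable[classify.Prediction],
    truth: Mapping[str, frozenset[str]],
    mode: str = "any",
) -> float:
    """O_acc = C/n: fraction of test proteins classified correctly.

    ``any``: correct when predicted and true label sets intersect;
    ``all``: correct when every true label is predicted.
    """
    if not truth:
        raise ValueError("empty test set")
    predicted = _predicted_sets(predictions)
    if mode == "any":
        correct = sum(
            1 for pid, labels in truth.items() if predicted.get(pid, set()) & labels
        )
    elif mode == "all":
        correct = sum(
            1 for pid, labels in truth.items() if labels <= predicted.get(pid, set())
        )
    else:
        raise ValueError(f"unknown accuracy mode: {mode}")
    return correct / len(truth)


def threshold_sweep(
    raw_predictions: Sequence[classify.Prediction],
    thresholds: Sequence[float],
    truth: Mapping[str, frozenset[str]],
    evaluated_classes: Sequence[str],
    accuracy_mode: str = "any",
) -> list[EvalReport]:
    """Re-evaluate at each confidence threshold (strict ``confidence > t``)."""
    reports = []
    for t in sorted(thresholds):
        kept = [p for p in raw_predictions if p.confidence > t]
        acc = overall_accuracy(kept, truth, accuracy_mode) if truth else 0.0
        reports.append(
            EvalReport(
                per_class=per_class_metrics(kept, truth, evaluated_classes),
                overall_accuracy=acc,
                n_test=len(truth),
                n_correct=round(acc * len(truth)),
                confidence_threshold=t,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    reports: list[EvalReport]
    classes: list[str]
    mean_overall_accuracy: float = field(init=False)

    def __post_init__(self):
        self.mean_overall_accuracy = float(
            np.mean([r.overall_accuracy for r in self.reports])
        )


def _docs_by_protein(docs: Sequence[corpus.AbstractDoc]) -> dict[str, list[corpus.AbstractDoc]]:
    by_protein: dict[str, list[corpus.AbstractDoc]] = {}
    for doc in docs:
        for pid in doc.linked_proteins:
            by_protein.setdefault(pid, []).append(doc)
    return by_protein


def _fold_text_predictions(
    train_ids: set[str],
    test_ids: set[str],
    labels: Mapping[str, frozenset[str]],
    docs: Sequence[corpus.AbstractDoc],
    sequences: Mapping[str, str] | None,
    z_threshold: float,
    k: int,
    min_votes: int,
    max_df_frac: float,
    min_df_count: int,
) -> list[classify.Prediction]:
    by_protein = _docs_by_protein(docs)
    train_docs = [d for d in docs if d.linked_proteins & train_ids]
    vocab = corpus.build_vocabulary(train_docs, max_df_frac, min_df_count)

    class_docs: dict[str, list[corpus.AbstractDoc]] = {}
    for doc in train_docs:
        for class_id in sorted(
            {c for p in doc.linked_proteins & train_ids for c in labels[p]}
        ):
            class_docs.setdefault(class_id, []).append(doc)
    terms = features.select_characteristic_terms(vocab, class_docs, z_threshold)

    train_with_text = {
        pid: (represent.vectorize(by_protein[pid], terms), labels[pid])
        for pid in sorted(train_ids)
        if pid in by_protein
    }
    index = classify.KnnIndex(train_with_text)

    aligner = baselines.BuiltinAligner() if sequences else None
    predictions: list[classify.Prediction] = []
    for pid in sorted(test_ids):
        if pid in by_protein:
            query = represent.vectorize(by_protein[pid], terms)
        elif aligner is not None and pid in sequences:
            refs = {
                t: sequences[t]
                for t in train_with_text
                if sequences and t in sequences
            }
            hits = aligner.rank(sequences[pid], refs)
            vectors = {t: v for t, (v, _) in train_with_text.items()}
            try:
                query = represent.textless_vector(pid, hits, vectors)
            except represent.NoHomologsError:
                query = represent.FeatureVector(
                    np.zeros(len(terms.union_terms)), terms.union_terms
                )
        else:
            query = represent.FeatureVector(
                np.zeros(len(terms.union_terms)), terms.union_terms
            )
        predictions.extend(classify.knn_predict(pid, query, index, k, min_votes))
    return predictions


def cross_validate(
    labels: Mapping[str, frozenset[str]],
    docs: Sequence[corpus.AbstractDoc],
    classifier: str = "text_knn",
    sequences: Mapping[str, str] | None = None,
    k_folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
    z_threshold: float = 1.96,
    k: int = 10,
    min_votes: int = 3,
    max_df_frac: float = 0.7,
    min_df_count: int = 3,
    confidence_threshold: float = 0.0,
    accuracy_mode: str = "any",
) -> CVResult:
    """Repeated stratified k-fold cross-validation of one classifier.

    ``classifier`` is one of ``text_knn``, ``base_prior``, ``base_seq`` (the
    latter needs ``sequences``). Fold assignment for repeat r uses seed+r.
    Promiscuous abstracts (linked to >3 proteins of differing function) are
    removed once before folding.
    """
    if classifier not in ("text_knn", "base_prior", "base_seq"):
        raise ValueError(f"unknown classifier: {classifier}")
    if classifier == "base_seq" and not sequences:
        raise ValueError("base_seq requires protein sequences")
    labels = dict(labels)
    docs = corpus.filter_promiscuous_abstracts(list(docs), labels)
    classes = sorted({c for ls in labels.values() for c in ls})

    reports: list[EvalReport] = []
    for repeat in range(repeats):
        folds = stratified_folds(labels, k_folds, seed + repeat)
        for fold_id, test_ids in enumerate(folds):
            train_ids = set(labels) - test_ids
            truth = {pid: labels[pid] for pid in test_ids}
            if classifier == "text_knn":
                predictions = _fold_text_predictions(
                    train_ids, test_ids, labels, docs, sequences,
                    z_threshold, k, min_votes, max_df_frac, min_df_count,
                )
            elif classifier == "base_prior":
                model = baselines.prior_fit({p: labels[p] for p in train_ids})
                predictions = baselines.prior_predict(
                    model, sorted(test_ids),
                    rng_seed=np.random.default_rng((seed + repeat) * 1000 + fold_id),
                )
            else:
                backend = baselines.BuiltinAligner()
                train = {p: (sequences[p], labels[p]) for p in sorted(train_ids)}
                predictions = []
                for pid in sorted(test_ids):
                    predictions.extend(
                        baselines.base_seq_predict(
                            pid, sequences[pid], backend, train, k, min_votes
                        )
                    )
            kept = [p for p in predictions if p.confidence > confidence_threshold]
            acc = overall_accuracy(kept, truth, accuracy_mode)
            reports.append(
                EvalReport(
                    per_class=per_class_metrics(kept, truth, classes),
                    overall_accuracy=acc,
                    n_test=len(truth),
                    n_correct=round(acc * len(truth)),
                    fold_id=fold_id,
                    repeat_id=repeat,
                    confidence_threshold=confidence_threshold,
                )
            )
            logger.info(
                "repeat %d fold %d: O_acc=%.3f over %d proteins",
                repeat, fold_id, acc, len(truth),
            )
    return CVResult(reports=reports, classes=classes)


def write_report_tsv(report: EvalReport, stream: IO[str]) -> None:
    stream.write("class_id\tTP\tFP\tFN\tTN\tprecision\trecall\tf_measure\tspecificity\n")
    for m in report.per_class:
        stream.write(
            f"{m.class_id}\t{m.tp}\t{m.fp}\t{m.fn}\t{m.tn}"
            f"\t{m.precision:.6g}\t{m.recall:.6g}\t{m.f_measure:.6g}"
            f"\t{m.specificity:.6g}\n"
        )


def write_run_json(result: CVResult, config: Mapping, stream: IO[str]) -> None:
    payload = {
        "mean_overall_accuracy": result.mean_overall_accuracy,
        "classes": result.classes,
        "folds": [
            {
                "repeat_id": r.repeat_id,
                "fold_id": r.fold_id,
                "overall_accuracy": r.overall_accuracy,
                "n_test": r.n_test,
                "n_correct": r.n_correct,
                "confidence_threshold": r.confidence_threshold,
            }
            for r in result.reports
        ],
        "config": dict(config),
    }
    json.dump(payload, stream, indent=2, sort_keys=True)
    stream.write("\n")
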