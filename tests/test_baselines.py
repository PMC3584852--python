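import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats as sps

import textfunc as tf
from textfunc.baselines import BuiltinAligner


class TestPriorFit:
    def test_label_frequencies(self):
        labels = {f"P{i}": {"binding"} for i in range(6)}
        labels |= {f"Q{i}": {"catalytic"} for i in range(4)}
        model = tf.prior_fit(labels)
        assert model.class_probs == {"binding": 0.6, "catalytic": 0.4}

    def test_single_class_degenerate(self):
        model = tf.prior_fit({"P1": {"f"}, "P2": {"f"}})
        assert model.class_probs == {"f": 1.0}

    def test_multilabel_counts_once_per_label(self):
        model = tf.prior_fit({"P1": {"a", "b"}, "P2": {"a"}})
        assert model.class_probs == {"a": 2 / 3, "b": 1 / 3}
        assert sum(model.class_probs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            tf.prior_fit({})


class TestPriorPredict:
    def test_degenerate_prior_assigns_single_class(self):
        model = tf.PriorModel({"f": 1.0})
        preds = tf.prior_predict(model, ["P1", "P2"], 0)
        assert [(p.protein_id, p.class_id) for p in preds] == [("P1", "f"), ("P2", "f")]

    def test_seed_reproducibility(self):
        model = tf.PriorModel({"a": 0.5, "b": 0.3, "c": 0.2})
        ids = [f"P{i}" for i in range(200)]
        assert tf.prior_predict(model, ids, 7) == tf.prior_predict(model, ids, 7)
        assert tf.prior_predict(model, ids, 7) != tf.prior_predict(model, ids, 8)

    def test_assign_all_mode_emits_every_class(self):
        model = tf.PriorModel({"a": 0.6, "b": 0.4}, mode="assign_all")
        preds = tf.prior_predict(model, ["P1", "P2", "P3"])
        assert len(preds) == 6
        assert {p.confidence for p in preds} == {0.6, 0.4}

    def test_empirical_frequencies_match_prior(self):
        # chi-squared goodness of fit, non-rejection at alpha = 0.01
        probs = {"a": 0.35, "b": 0.25, "c": 0.2, "d": 0.12, "e": 0.08}
        model = tf.PriorModel(probs)
        n = 100_000
        preds = tf.prior_predict(model, [f"P{i}" for i in range(n)], 123)
        observed = Counter(p.class_id for p in preds)
        chi2, pvalue = sps.chisquare(
            [observed[c] for c in sorted(probs)],
            [probs[c] * n for c in sorted(probs)],
        )
        assert pvalue > 0.01


class TestBuiltinAlign:
    def test_identical_sequences(self):
        score, identity = tf.builtin_align("ACDEFGHIK", "ACDEFGHIK")
        assert identity == 1.0 and score > 0

    def test_single_substitution_identity(self):
        _, identity = tf.builtin_align("ACDEFGHIK", "ACDEFGHIR")
        assert identity == pytest.approx(8 / 9)

    def test_identity_symmetric(self):
        a, b = "ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWA"
        assert tf.builtin_align(a, b)[1] == tf.builtin_align(b, a)[1]

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            tf.builtin_align("", "ACD")

    def test_matches_hand_coded_dp_oracle(self):
        # independent Smith-Waterman with affine gaps on tiny pairs
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")

        def sw_score(s, t, open_=-11, ext=-1):
            n, m = len(s), len(t)
            neg = -1e9
            M = [[0.0] * (m + 1) for _ in range(n + 1)]
            X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in t
            Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in s
            best = 0.0
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + ext)
                    Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + ext)
                    sub = blosum[s[i - 1], t[j - 1]]
                    M[i][j] = max(0.0, M[i - 1][j - 1] + sub,
                                  X[i - 1][j - 1] + sub, Y[i - 1][j - 1] + sub)
                    best = max(best, M[i][j])
            return best

        rng = np.random.default_rng(2)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(15):
            s = "".join(rng.choice(aa, size=rng.integers(5, 15)))
            t = "".join(rng.choice(aa, size=rng.integers(5, 15)))
            score, _ = tf.builtin_align(s, t)
            assert score == pytest.approx(sw_score(s, t))

    def test_dissimilar_pair_low_identity(self):
        # disjoint residue composition: oracle says little can align
        _, identity = tf.builtin_align("AAAAGGGG", "WWWWYYYY")
        assert identity <= 0.5


def _family_train(dataset):
    return {
        pid: (dataset.sequences[pid], dataset.labels[pid])
        for pid in sorted(dataset.labels)
    }


class TestBaseSeqPredict:
    def test_unanimous_family_vote(self, small_dataset):
        train = _family_train(small_dataset)
        qid = sorted(small_dataset.labels)[0]
        query_seq, true_labels = train.pop(qid)
        preds = tf.base_seq_predict(qid, query_seq, BuiltinAligner(), train)
        assert preds
        assert preds[0].class_id in true_labels
        assert preds[0].votes >= 3

    def test_below_min_votes_no_prediction(self):
        # 10 hits, 2 votes per class -> nothing emitted
        seqs = {f"P{i}": "ACDEFGHIKLMNPQRSTVWY" for i in range(10)}
        train = {pid: (seq, {f"C{i % 5}"}) for i, (pid, seq) in enumerate(seqs.items())}
        preds = tf.base_seq_predict("Q", "ACDEFGHIKLMNPQRSTVWY", BuiltinAligner(),
                                    train, k=10, min_votes=3)
        assert preds == []

    def test_matches_all_pairs_alignment_oracle(self, small_dataset):
        train = _family_train(small_dataset)
        queries = sorted(small_dataset.labels)[::25][:4]
        for qid in queries:
            query_seq, _ = train[qid]
            rest = {p: sl for p, sl in train.items() if p != qid}
            preds = tf.base_seq_predict(qid, query_seq, BuiltinAligner(), rest)

            scored = sorted(
                (
                    (-tf.builtin_align(query_seq, seq)[0], pid,
                     tf.builtin_align(query_seq, seq)[1])
                    for pid, (seq, _) in rest.items()
                ),
            )[:10]
            votes, idents = Counter(), {}
            for negscore, pid, ident in scored:
                for label in rest[pid][1]:
                    votes[label] += 1
                    idents.setdefault(label, []).append(ident)
            expected = {
                c: (n, math.fsum(idents[c]) / n) for c, n in votes.items() if n >= 3
            }
            assert {p.class_id for p in preds} == set(expected)
            for p in preds:
                assert p.votes == expected[p.class_id][0]
                assert p.confidence == pytest.approx(expected[p.class_id][1], abs=1e-12)

    def test_confidence_is_mean_identity_of_voters(self, small_dataset):
        train = _family_train(small_dataset)
        qid = sorted(small_dataset.labels)[3]
        query_seq, _ = train.pop(qid)
        for p in tf.base_seq_predict(qid, query_seq, BuiltinAligner(), train):
            assert 0.0 <= p.confidence <= 1.0


def test_blast_tabular_backend_filters_to_references():
    import io

    rows = "Q1\tS1\t90\t50\t5\t0\t1\t50\t1\t50\t1e-20\t100\n" \
           "Q1\tS9\t95\t50\t2\t0\t1\t50\t1\t50\t1e-30\t120\n"
    backend = tf.BlastTabularBackend(io.StringIO(rows))
    backend.query_id = "Q1"
    hits = backend.rank("IGNORED", {"S1": "ACD"})
    assert [h.subject_protein_id for h in hits] == ["S1"]
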