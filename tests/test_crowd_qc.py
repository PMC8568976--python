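from collections import Counter

import numpy as np
import pytest

from foodsignal.crowd_qc import (
    SpanAnnotation,
    WorkerAnnotation,
    annotation_similarity,
    detect_spammers,
    enforce_worker_cap,
    filter_annotations,
    krippendorff_alpha,
    make_batches,
    read_annotations,
    run_qc,
    write_annotations,
)
from foodsignal.synthetic import GeneratorConfig, WorkerProfile, generate_corpus, simulate_workers
from foodsignal.tokens import word_tokenize


def alpha_oracle(units):
    """Independent pairwise-enumeration form of nominal alpha."""
    kept = [[v for v in u if v is not None] for u in units]
    kept = [u for u in kept if len(u) >= 2]
    n = sum(len(u) for u in kept)
    d_o = sum(
        sum(a != b for a in u for b in u) / (len(u) - 1) for u in kept
    ) / n
    if d_o == 0:
        return 1.0
    marg = Counter(v for u in kept for v in u)
    d_e = sum(marg[c] * marg[k] for c in marg for k in marg if c != k) / (n * (n - 1))
    return 1.0 - d_o / d_e


class TestBatching:
    def test_3000_by_500_gives_6(self):
        batches = make_batches(list(range(3000)), 500)
        assert len(batches) == 6 and all(len(b) == 500 for b in batches)

    def test_empty(self):
        assert make_batches([], 5) == []

    def test_remainder(self):
        assert [len(b) for b in make_batches(list(range(7)), 3)] == [3, 3, 1]

    def test_union_preserves_order(self):
        items = list("abcdefghij")
        assert [x for b in make_batches(items, 4) for x in b] == items


class TestWorkerCap:
    def _anns(self, worker, k):
        return [WorkerAnnotation(worker, f"t{i}", 3) for i in range(k)]

    def test_excess_reported(self):
        acc, vio = enforce_worker_cap(self._anns("w", 12), cap=10)
        assert len(acc) == 10 and len(vio) == 2
        assert [a.tweet_id for a in acc] == [f"t{i}" for i in range(10)]

    def test_single_accepted(self):
        acc, vio = enforce_worker_cap(self._anns("w", 1), cap=10)
        assert len(acc) == 1 and not vio

    def test_two_workers_at_cap(self):
        anns = self._anns("a", 10) + self._anns("b", 10)
        acc, vio = enforce_worker_cap(anns, cap=10)
        assert len(acc) == 20 and not vio


class TestSimilarity:
    TEXT = "I got food poisoning from a grilled cheese"
    TOKENS = word_tokenize(TEXT)
    SPANS = (SpanAnnotation("KEY", 6, 20), SpanAnnotation("FOOD", 28, 42))

    def test_identical_is_one(self):
        a = WorkerAnnotation("a", "t", 4, self.SPANS)
        b = WorkerAnnotation("b", "t", 4, self.SPANS)
        assert annotation_similarity(a, [b], self.TOKENS) == pytest.approx(1.0)

    def test_score_extremes_half(self):
        a = WorkerAnnotation("a", "t", 0, self.SPANS)
        b = WorkerAnnotation("b", "t", 5, self.SPANS)
        assert annotation_similarity(a, [b], self.TOKENS) == pytest.approx(0.5)

    def test_no_spans_equal_scores(self):
        a = WorkerAnnotation("a", "t", 2)
        b = WorkerAnnotation("b", "t", 2)
        assert annotation_similarity(a, [b], self.TOKENS) == pytest.approx(1.0)

    def test_symmetry_with_single_peer(self):
        a = WorkerAnnotation("a", "t", 1, self.SPANS[:1])
        b = WorkerAnnotation("b", "t", 4, self.SPANS)
        ab = annotation_similarity(a, [b], self.TOKENS)
        ba = annotation_similarity(b, [a], self.TOKENS)
        assert ab == pytest.approx(ba)
        assert 0.0 <= ab <= 1.0

    def test_empty_peers_error(self):
        a = WorkerAnnotation("a", "t", 1)
        with pytest.raises(ValueError):
            annotation_similarity(a, [], self.TOKENS)


class TestFilterAnnotations:
    TEXT = {"t": "I got food poisoning from a grilled cheese"}
    GOOD = (SpanAnnotation("KEY", 6, 20),)

    def _identical(self, k, score=4):
        return [WorkerAnnotation(f"w{i}", "t", score, self.GOOD) for i in range(k)]

    def test_identical_all_accepted(self):
        acc, rej, relabel, unver = filter_annotations(self._identical(5), self.TEXT)
        assert len(acc) == 5 and not rej and not relabel

    def test_outlier_rejected(self):
        outlier = WorkerAnnotation("w9", "t", 0, ())  # no spans, opposite score
        acc, rej, relabel, _ = filter_annotations(self._identical(4) + [outlier], self.TEXT)
        assert [a.worker_id for a in rej] == ["w9"]
        assert relabel == ["t"]

    def test_threshold_zero_accepts_all(self):
        outlier = WorkerAnnotation("w9", "t", 0, ())
        acc, rej, _, _ = filter_annotations(self._identical(4) + [outlier], self.TEXT, threshold=0.0)
        assert len(acc) == 5 and not rej

    def test_threshold_above_one_rejects_all(self):
        acc, rej, _, _ = filter_annotations(self._identical(3), self.TEXT, threshold=1.01)
        assert not acc and len(rej) == 3

    def test_single_annotation_unverifiable(self):
        acc, rej, _, unver = filter_annotations(self._identical(1), self.TEXT)
        assert len(acc) == 1 and not rej and unver == ["t"]


class TestSpammers:
    def test_high_rejection_blocked(self):
        assert detect_spammers({"w": (5, 4)}) == ["w"]

    def test_below_min_labeled_not_blocked(self):
        assert detect_spammers({"w": (2, 2)}) == []

    def test_clean_worker_not_blocked(self):
        assert detect_spammers({"w": (10, 0)}) == []


class TestKrippendorffAlpha:
    def test_perfect_agreement(self):
        units = [["FOOD", "FOOD", "FOOD"]] * 5 + [["O", "O", "O"]] * 5
        assert krippendorff_alpha(units) == 1.0

    def test_hand_computed_coincidence_matrix(self):
        # 2 workers, 4 tokens: (O,O,FOOD,FOOD) vs (O,O,FOOD,O).
        # Coincidence matrix: o_OO=4, o_FF=2, o_OF=o_FO=1; n=8.
        # D_o = 2/8; D_e = 2*5*3/(8*7); alpha = 1 - 0.25/(30/56) = 8/15.
        units = [["O", "O"], ["O", "O"], ["FOOD", "FOOD"], ["FOOD", "O"]]
        assert krippendorff_alpha(units) == pytest.approx(8 / 15, abs=1e-12)

    def test_single_pairable_unit(self):
        units = [["SYM", "SYM"], ["O", None], [None, None]]
        assert krippendorff_alpha(units) == 1.0

    def test_no_pairable_values_error(self):
        with pytest.raises(ValueError):
            krippendorff_alpha([["O", None], [None, "FOOD"]])

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        labels = ["FOOD", "LOC", "SYM", "KEY", "O", None]
        for _ in range(100):
            units = [
                [labels[rng.integers(len(labels))] for _ in range(3)]
                for _ in range(10)
            ]
            if not any(sum(v is not None for v in u) >= 2 for u in units):
                continue
            mine = krippendorff_alpha(units)
            assert mine == pytest.approx(alpha_oracle(units), abs=1e-12)

    def test_removing_uniform_spammer_rarely_lowers_alpha(self):
        # Dropping annotations from a worker who labels uniformly at random
        # should not decrease agreement (allow 1 failure in 20 seeds).
        failures = 0
        for seed in range(20):
            _, golds = generate_corpus(GeneratorConfig(n_tweets=40, seed=300 + seed))
            profiles = [WorkerProfile(token_flip=0.1)] * 3 + [WorkerProfile(spammer=True)]
            anns = simulate_workers(golds, profiles, seed=seed)
            texts = {g.tweet_id: g.text for g in golds}
            from foodsignal.crowd_qc import alpha_from_annotations

            with_spammer = alpha_from_annotations(anns, texts)
            without = alpha_from_annotations(
                [a for a in anns if a.worker_id != "w3"], texts
            )
            if without < with_spammer:
                failures += 1
        assert failures <= 1


class TestRunQc:
    def test_spammer_blocked_and_alpha_rises(self, small_corpus, noisy_crowd):
        tweets, _ = small_corpus
        accepted, report = run_qc(tweets, noisy_crowd, batch_size=20, cap=20)
        assert "w4" in report.blocked_workers
        assert report.alpha_after > report.alpha_before
        assert not (set(report.accepted) & set(report.rejected))

    def test_blocked_worker_absent_from_later_batches(self, small_corpus, noisy_crowd):
        tweets, _ = small_corpus
        accepted, report = run_qc(tweets, noisy_crowd, batch_size=20, cap=20)
        later_tweets = {t.id for t in tweets[20:]}
        touched = {k for k in report.accepted + report.rejected if k[1] in later_tweets}
        assert all(w != "w4" for w, _ in touched)


class TestAnnotationIO:
    def test_csv_and_jsonl_roundtrip(self, tmp_path, noisy_crowd):
        sample = noisy_crowd[:25]
        for fmt in ("csv", "jsonl"):
            p = tmp_path / f"anns.{fmt}"
            write_annotations(sample, p, fmt)
            assert read_annotations(p, fmt) == sample
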