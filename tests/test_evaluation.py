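import math

import numpy as np
import pytest

from dialogforge.evaluation import (
    PairConfusion,
    aggregate_ratings,
    bleu,
    corpus_stats,
    evaluate_clustering,
    mean_best_bleu,
    pair_confusion,
    pair_prf,
    silhouette,
    truncate3,
)


def brute_force_pairs(pred, gold):
    """All-pairs double loop oracle."""
    items = sorted(pred)
    tp = fp = tn = fn = 0
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            i, j = items[a], items[b]
            same_c = pred[i] == pred[j]
            same_g = gold[i] == gold[j]
            tp += same_c and same_g
            fp += same_c and not same_g
            tn += not same_c and not same_g
            fn += not same_c and same_g
    return tp, fp, tn, fn


def brute_force_silhouette(X, labels):
    """Pure-Python per-point silhouette oracle (Euclidean)."""
    n = len(X)
    out = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            out.append(0.0)
            continue
        a = sum(math.dist(X[i], X[j]) for j in same) / len(same)
        b = math.inf
        for lbl in set(labels) - {labels[i]}:
            others = [j for j in range(n) if labels[j] == lbl]
            b = min(b, sum(math.dist(X[i], X[j]) for j in others) / len(others))
        out.append((b - a) / max(a, b))
    return out


class TestPairConfusion:
    def test_perfect_partition_hand_count(self):
        pred = {"a": 0, "b": 0, "c": 1}
        gold = {"a": "x", "b": "x", "c": "y"}
        c = pair_confusion(pred, gold)
        assert (c.TP, c.FP, c.TN, c.FN) == (1, 0, 2, 0)

    def test_single_cluster_all_distinct_classes(self):
        pred = {i: 0 for i in "abcd"}
        gold = {i: i for i in "abcd"}
        c = pair_confusion(pred, gold)
        assert (c.TP, c.FP, c.TN, c.FN) == (0, 6, 0, 0)

    def test_total_is_n_choose_2(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            pred = {f"i{k}": int(rng.integers(3)) for k in range(n)}
            gold = {f"i{k}": str(rng.integers(3)) for k in range(n)}
            assert pair_confusion(pred, gold).total == n * (n - 1) // 2

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            pred = {f"i{k}": int(rng.integers(4)) for k in range(n)}
            gold = {f"i{k}": str(rng.integers(4)) for k in range(n)}
            c = pair_confusion(pred, gold)
            assert (c.TP, c.FP, c.TN, c.FN) == brute_force_pairs(pred, gold)

    def test_invariant_under_index_and_label_permutation(self):
        pred = {"a": 0, "b": 0, "c": 1, "d": 2}
        gold = {"a": "x", "b": "y", "c": "y", "d": "x"}
        c1 = pair_confusion(pred, gold)
        pred2 = {k: {0: 5, 1: 0, 2: 7}[v] for k, v in pred.items()}
        gold2 = {k: {"x": "q", "y": "r"}[v] for k, v in gold.items()}
        c2 = pair_confusion(pred2, gold2)
        assert c1 == c2

    def test_item_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            pair_confusion({"a": 0}, {"b": "x"})


class TestPairPRF:
    @pytest.mark.parametrize(
        "conf, expected",
        [
            (PairConfusion(1, 0, 2, 0), (1.0, 1.0, 1.0)),
            (PairConfusion(2, 2, 0, 2), (0.5, 0.5, 0.5)),
            (PairConfusion(0, 0, 3, 0), (0.0, 0.0, 0.0)),
        ],
    )
    def test_hand_arithmetic(self, conf, expected):
        assert pair_prf(conf) == pytest.approx(expected)

    def test_f1_consistency(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 10, size=4))
            p, r, f1 = pair_prf(PairConfusion(tp, fp, tn, fn))
            if p + r > 0:
                assert f1 == pytest.approx(2 * p * r / (p + r))
            else:
                assert f1 == 0.0


class TestSilhouette:
    def test_well_separated_pairs_high(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        mean, vals = silhouette(X, np.array([0, 0, 1, 1]))
        # hand: a = 0.1, b = (9.9 + 10.0)/2 or (10.0+10.1)/2 -> S ~ 0.99
        assert mean > 0.98
        assert np.all(vals > 0.98)

    def test_crossed_split_negative(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        mean, _ = silhouette(X, np.array([0, 1, 0, 1]))
        assert mean < 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 11))
            X = rng.normal(size=(n, 2))
            labels = rng.integers(0, 3, size=n)
            if len(set(labels.tolist())) < 2:
                continue
            mean, vals = silhouette(X, labels)
            oracle = brute_force_silhouette(X.tolist(), labels.tolist())
            assert np.allclose(vals, oracle, atol=1e-9)
            assert mean == pytest.approx(np.mean(oracle), abs=1e-9)

    def test_fewer_than_two_clusters_rejected(self):
        with pytest.raises(ValueError, match="2 clusters"):
            silhouette(np.zeros((4, 2)), np.zeros(4, dtype=int))


class TestBleu:
    def test_perfect_match_is_one(self):
        s = "help to use urinals at restroom"
        assert bleu(s, [s]) == pytest.approx(1.0)

    def test_zero_overlap_is_zero(self):
        assert bleu("alpha beta gamma", ["delta epsilon"]) == 0.0

    def test_hand_computed_example(self):
        cand = "the cat sat on mat"
        ref = "the cat is on the mat"
        # modified precisions by hand: p1=4/5, p2=1/4, p3 -> 1/4 (add-one on
        # 0/3), p4 -> 1/3 (add-one on 0/2); BP = exp(1 - 6/5)
        expected = math.exp(
            (math.log(4 / 5) + math.log(1 / 4) + math.log(1 / 4) + math.log(1 / 3)) / 4
            + (1 - 6 / 5)
        )
        assert bleu(cand, [ref]) == pytest.approx(expected, abs=1e-12)

    def test_short_candidate_drops_unattainable_orders(self):
        # 2-token candidate: only 1- and 2-gram precisions participate
        assert bleu("add pressure", ["add pressure"]) == pytest.approx(1.0)

    def test_empty_candidate_zero(self):
        assert bleu("", ["add pressure"]) == 0.0

    def test_mean_best_bleu_groups_by_label(self):
        generated = [("add pressure", "add-vital"), ("clean mouth", "clean-oral")]
        refs = {
            "add-vital": ["add pressure", "set temperature"],
            "clean-oral": ["wash dentures"],
        }
        score = mean_best_bleu(generated, refs)
        assert score == pytest.approx((1.0 + bleu("clean mouth", ["wash dentures"])) / 2)


class TestCorpusStats:
    def test_printed_per_class_row(self):
        rows, total = corpus_stats({"add-vital": (876, 6016)})
        assert rows[0].avg_length_display == 6.867
        assert total.utterances == 876 and total.words == 6016

    def test_truncation_not_rounding(self):
        assert truncate3(6.8696) == 6.869
        assert truncate3(6.3888) == 6.388

    def test_single_utterance(self, small_corpus):
        from dialogforge.augmentation import Corpus

        sub = Corpus(utterances=[small_corpus.utterances[0]], ontology_version="1", seed=0)
        rows, total = corpus_stats(sub)
        assert rows[0].utterances == 1
        assert rows[0].words == len(small_corpus.utterances[0].text.split())
        assert rows[0].avg_length == rows[0].words

    def test_csv_export(self, small_corpus, tmp_path):
        from dialogforge.evaluation import write_stats_csv

        rows, total = corpus_stats(small_corpus)
        p = tmp_path / "stats.csv"
        write_stats_csv(rows, total, p)
        lines = p.read_text().strip().splitlines()
        assert lines[0] == "class,utterances,words,avg_utterance_length"
        assert len(lines) == len(rows) + 2
        assert lines[-1].startswith("total,")

    def test_totals_equal_row_sums(self, small_corpus):
        rows, total = corpus_stats(small_corpus)
        assert total.utterances == sum(r.utterances for r in rows)
        assert total.words == sum(r.words for r in rows)


class TestAggregateRatings:
    def test_identity(self):
        assert aggregate_ratings([3.5, 3.5]) == 3.5

    def test_two_group_means(self):
        assert aggregate_ratings([4.83, 4.59]) == 4.71
        assert aggregate_ratings([4.79, 4.53]) == 4.66

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_ratings([])


class TestEvaluateClustering:
    def test_perfect_partition_reaches_f1_one(self):
        X = np.array([[0.0], [0.2], [5.0], [5.2]])
        from dialogforge.labeling import ClusterAssignment

        a = ClusterAssignment(items=["a", "b", "c", "d"], clusters=np.array([0, 0, 1, 1]))
        gold = {"a": "x", "b": "x", "c": "y", "d": "y"}
        report = evaluate_clustering(X, a, gold)
        assert report.f1 == 1.0
        assert report.silhouette_mean is not None and report.silhouette_mean > 0.9
        assert report.cluster_sizes == {0: 2, 1: 2}
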