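"""Evaluation metrics for generated corpora and cluster labelings.

Pair-counting precision/recall/F1 treats every unordered item pair as a
binary decision (same cluster vs same class); counts are computed from the
cluster-by-class contingency table.  The silhouette coefficient
S(i) = (b(i) - a(i)) / max(a(i), b(i)) uses Euclidean distances to match
the clustering metric.  BLEU is standard 4-gram modified precision with a
brevity penalty and add-one smoothing on zero higher-order counts for
short utterances.  Corpus statistics report per-class utterance counts,
whitespace word counts, and the average utterance length, truncated (not
rounded) to three decimals for table parity while retaining full precision
internally.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.metrics import silhouette_samples

from .augmentation import Corpus
from .labeling import ClusterAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "PairConfusion",
    "EvalReport",
    "ClassStats",
    "pair_confusion",
    "pair_prf",
    "silhouette",
    "bleu",
    "mean_best_bleu",
    "corpus_stats",
    "aggregate_ratings",
    "evaluate_clustering",
    "truncate3",
]


@dataclass(frozen=True)
class PairConfusion:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    silhouette_mean: Optional[float]
    cluster_sizes: Dict[int, int]
    config: Dict[str, object] = field(default_factory=dict)


def _as_cluster_dict(pred) -> Dict[str, int]:
    if isinstance(pred, ClusterAssignment):
        return pred.as_dict()
    return {k: int(v) for k, v in dict(pred).items()}


def pair_confusion(pred, gold: Mapping[str, str]) -> PairConfusion:
    """Pair counts over all unordered item pairs i < j.

    Computed from the contingency table: TP = sum_ij C(n_ij, 2);
    FP and FN follow from cluster/class marginals; TN is the remainder of
    n(n-1)/2.
    """
    pred_d = _as_cluster_dict(pred)
    if set(pred_d) != set(gold):
        raise ValueError("prediction and gold label item sets differ")
    n = len(pred_d)
    cont: Counter = Counter((pred_d[i], gold[i]) for i in pred_d)
    tp = sum(math.comb(c, 2) for c in cont.values())
    cluster_sizes = Counter(pred_d.values())
    class_sizes = Counter(gold.values())
    same_cluster = sum(math.comb(c, 2) for c in cluster_sizes.values())
    same_class = sum(math.comb(c, 2) for c in class_sizes.values())
    fp = same_cluster - tp
    fn = same_class - tp
    tn = math.comb(n, 2) - tp - fp - fn
    return PairConfusion(TP=tp, FP=fp, TN=tn, FN=fn)


def pair_prf(c: PairConfusion) -> Tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); degenerate
    denominators yield 0 by convention."""
    p = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else 0.0
    r = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f1


def silhouette(X, assignment) -> Tuple[float, np.ndarray]:
    """Mean and per-point silhouette values (Euclidean distances).

    Requires k >= 2 non-empty clusters; a singleton cluster's point scores
    0 by convention.
    """
    if hasattr(X, "matrix"):
        X = X.matrix
    X = np.asarray(X, dtype=float)
    labels = assignment.clusters if isinstance(assignment, ClusterAssignment) else np.asarray(assignment)
    if len(set(labels.tolist())) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    values = silhouette_samples(X, labels, metric="euclidean")
    return float(values.mean()), values


# ---------------------------------------------------------------------------
# BLEU

def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i:i + n]) for i in range(len(tokens) - n + 1))


def bleu(candidate: str, references: Sequence[str], max_n: int = 4, smoothing: bool = True) -> float:
    """Sentence BLEU: geometric mean of modified n-gram precisions (n up to
    ``max_n``) times a brevity penalty.

    A perfect match scores 1.0; zero unigram overlap scores 0.0.  For short
    sentences, higher-order precisions with zero matches receive add-one
    smoothing; orders with no attainable n-grams are dropped from the mean.
    """
    cand = candidate.split()
    refs = [r.split() for r in references]
    if not cand:
        logger.warning("empty candidate scored as 0.0")
        return 0.0
    if not refs:
        raise ValueError("at least one reference is required")
    log_precisions: List[float] = []
    for n in range(1, max_n + 1):
        possible = len(cand) - n + 1
        if possible <= 0:
            continue
        counts = _ngrams(cand, n)
        max_ref: Counter = Counter()
        for ref in refs:
            for g, c in _ngrams(ref, n).items():
                max_ref[g] = max(max_ref[g], c)
        matches = sum(min(c, max_ref[g]) for g, c in counts.items())
        if matches == 0:
            if n == 1:
                return 0.0  # no token overlap at all
            if not smoothing:
                return 0.0
            log_precisions.append(math.log((matches + 1) / (possible + 1)))
        else:
            log_precisions.append(math.log(matches / possible))
    # brevity penalty against the closest reference length (shorter wins ties)
    c_len = len(cand)
    r_len = min((len(r) for r in refs), key=lambda rl: (abs(rl - c_len), rl))
    bp = 1.0 if c_len >= r_len else math.exp(1 - r_len / c_len)
    return bp * math.exp(sum(log_precisions) / len(log_precisions))


def mean_best_bleu(generated: Sequence[Tuple[str, str]],
                   references_by_label: Mapping[str, Sequence[str]],
                   max_n: int = 4) -> float:
    """Corpus score for generated utterances: each candidate is scored
    against all reference utterances of its (inferred) label and the best
    sentence BLEU is kept; the corpus score is the mean of the maxima."""
    scores = []
    for text, label in generated:
        refs = references_by_label.get(label)
        if not refs:
            raise ValueError(f"no references for label {label!r}")
        scores.append(max(bleu(text, [r], max_n=max_n) for r in refs))
    if not scores:
        raise ValueError("no generated utterances to score")
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# corpus statistics and rating aggregation

def truncate3(x: float) -> float:
    """Truncate (never round) to 3 decimals — the reporting convention for
    average utterance length."""
    return math.floor(x * 1000) / 1000


@dataclass(frozen=True)
class ClassStats:
    label: str
    utterances: int
    words: int

    @property
    def avg_length(self) -> float:
        return self.words / self.utterances if self.utterances else 0.0

    @property
    def avg_length_display(self) -> float:
        return truncate3(self.avg_length)


def corpus_stats(c: Union[Corpus, Mapping[str, Tuple[int, int]]]) -> Tuple[List[ClassStats], ClassStats]:
    """Per-class and total (utterances, words, average length).

    Accepts a labeled corpus (words counted by whitespace tokenisation) or
    a per-class count table mapping label -> (utterances, words).  Totals
    equal the sums of the per-class rows.
    """
    if isinstance(c, Corpus):
        counts: Dict[str, List[int]] = {}
        for u in c.utterances:
            row = counts.setdefault(u.intent, [0, 0])
            row[0] += 1
            row[1] += len(u.text.split())
        table = {k: (v[0], v[1]) for k, v in counts.items()}
    else:
        table = {k: (int(u), int(w)) for k, (u, w) in dict(c).items()}
    rows = [ClassStats(label, u, w) for label, (u, w) in table.items()]
    total = ClassStats("total", sum(r.utterances for r in rows), sum(r.words for r in rows))
    return rows, total


def write_stats_csv(rows: Sequence[ClassStats], total: ClassStats, path) -> None:
    """CSV export of per-class statistics plus the totals row."""
    import csv
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "utterances", "words", "avg_utterance_length"])
        for r in [*sorted(rows, key=lambda r: r.label), total]:
            w.writerow([r.label, r.utterances, r.words, f"{r.avg_length_display:.3f}"])


def aggregate_ratings(group_means: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-group rating means, reported to
    two decimals."""
    if not group_means:
        raise ValueError("group_means must be non-empty")
    return round(sum(group_means) / len(group_means), 2)


def evaluate_clustering(X, assignment, gold: Mapping[str, str],
                        config: Optional[dict] = None) -> EvalReport:
    """Bundle pair P/R/F1, silhouette and cluster sizes into one report."""
    conf = pair_confusion(assignment, gold)
    p, r, f1 = pair_prf(conf)
    sil: Optional[float] = None
    labels = assignment.clusters if isinstance(assignment, ClusterAssignment) else np.asarray(assignment)
    if X is not None and len(set(np.asarray(labels).tolist())) >= 2:
        sil, _ = silhouette(X, assignment)
    sizes = dict(sorted(Counter(int(l) for l in labels).items()))
    return EvalReport(precision=p, recall=r, f1=f1, silhouette_mean=sil,
                      cluster_sizes=sizes, config=dict(config or {}))
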