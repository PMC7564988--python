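"""Clustering-based intent and entity labeling.

Utterance (or entity-surface) features are clustered with k-means at the
gold k — the number of distinct gold classes — and each cluster is named by
the most frequent gold label among its members, yielding a labeling
accuracy.  The objective minimised is the within-cluster sum of squared
Euclidean distances J = sum_j sum_{i in j} ||x_i - c_j||^2, with k-means++
initial centroids, a configurable number of restarts (best J kept), and a
documented farthest-point reseed for clusters that empty out during Lloyd
iterations.  All tie-breaks (equidistant points, tied majority labels) are
deterministic: lowest centroid index, lexicographically smallest label.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .augmentation import Corpus
from .features import (
    FeatureMatrix,
    MeanPoolingEncoder,
    preprocess_word_level,
    word_feature,
    word_features,
    sentence_features,
)

__all__ = [
    "ClusterModel",
    "ClusterAssignment",
    "LabeledClusters",
    "LabelingResult",
    "kmeans_fit",
    "majority_labels",
    "label_corpus",
]


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    seed: int
    objective: float
    iterations_run: int
    objective_trace: List[float] = field(default_factory=list)


@dataclass
class ClusterAssignment:
    items: List[str]
    clusters: np.ndarray  # int index per item, in [0, k)

    def as_dict(self) -> Dict[str, int]:
        return {item: int(c) for item, c in zip(self.items, self.clusters)}


@dataclass
class LabeledClusters:
    labels: Dict[int, str]  # cluster index -> majority gold label
    histograms: Dict[int, Dict[str, int]]
    accuracy: float


def _as_matrix(X: Union[FeatureMatrix, np.ndarray]) -> Tuple[np.ndarray, List[str]]:
    if isinstance(X, FeatureMatrix):
        return np.asarray(X.matrix, dtype=float), list(X.items)
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{i}" for i in range(arr.shape[0])]


def _sq_dists(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    # (n, k) squared Euclidean distances
    return ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centroids = [X[int(rng.integers(n))]]
    for _ in range(1, k):
        d2 = _sq_dists(X, np.array(centroids)).min(axis=1)
        total = d2.sum()
        if total <= 0:
            idx = int(rng.integers(n))  # all points coincide with a centroid
        else:
            idx = int(np.searchsorted(np.cumsum(d2 / total), rng.random()))
            idx = min(idx, n - 1)
        centroids.append(X[idx])
    return np.array(centroids, dtype=float)


def _lloyd(X: np.ndarray, C: np.ndarray, max_iter: int, tol: float):
    trace: List[float] = []
    assign = np.zeros(X.shape[0], dtype=int)
    it = 0
    for it in range(1, max_iter + 1):
        d2 = _sq_dists(X, C)
        assign = d2.argmin(axis=1)  # argmin breaks ties at the lowest index
        # empty-cluster policy: reseed at the point farthest from its centroid
        for j in range(C.shape[0]):
            if not np.any(assign == j):
                far = int(d2[np.arange(len(assign)), assign].argmax())
                C[j] = X[far]
                assign[far] = j
                d2 = _sq_dists(X, C)  # distances under the reseeded centroid
        trace.append(float(d2[np.arange(len(assign)), assign].sum()))
        new_C = np.vstack([X[assign == j].mean(axis=0) for j in range(C.shape[0])])
        shift = float(np.sqrt(((new_C - C) ** 2).sum(axis=1)).max())
        C = new_C
        if shift < tol:
            break
    d2 = _sq_dists(X, C)
    assign = d2.argmin(axis=1)
    obj = float(d2[np.arange(len(assign)), assign].sum())
    trace.append(obj)
    return C, assign, obj, it, trace


def kmeans_fit(
    X: Union[FeatureMatrix, np.ndarray],
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-8,
    restarts: int = 10,
    l2_normalize: bool = False,
) -> Tuple[ClusterModel, ClusterAssignment]:
    """Lloyd's algorithm from k-means++ seeds; deterministic per seed.

    The within-cluster squared-distance objective is recorded after every
    iteration and is non-increasing.  ``restarts`` independent
    initialisations are run and the best final objective kept.
    """
    M, items = _as_matrix(X)
    n = M.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must satisfy 1 <= k <= n ({k=} vs n={n})")
    if not np.all(np.isfinite(M)):
        raise ValueError("feature matrix must be finite")
    if l2_normalize:
        norms = np.linalg.norm(M, axis=1, keepdims=True)
        M = M / np.where(norms == 0, 1.0, norms)
    best = None
    for r in range(max(1, restarts)):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, r])
        C0 = _kmeanspp_init(M, k, rng)
        C, assign, obj, iters, trace = _lloyd(M, C0.copy(), max_iter, tol)
        if best is None or obj < best[2] - 1e-12:
            best = (C, assign, obj, iters, trace)
    C, assign, obj, iters, trace = best
    model = ClusterModel(
        k=k, centroids=C, seed=seed, objective=obj,
        iterations_run=iters, objective_trace=trace,
    )
    return model, ClusterAssignment(items=items, clusters=assign)


def majority_labels(a: ClusterAssignment, gold: Dict[str, str]) -> LabeledClusters:
    """Name each cluster by its most frequent gold label (ties break to the
    lexicographically smallest label) and report the labeling accuracy."""
    missing = [i for i in a.items if i not in gold]
    if missing:
        raise ValueError(f"gold labels missing for items: {missing[:5]}")
    histograms: Dict[int, Dict[str, int]] = {}
    for item, c in zip(a.items, a.clusters):
        histograms.setdefault(int(c), Counter())[gold[item]] += 1
    labels: Dict[int, str] = {}
    for c, hist in histograms.items():
        top = max(hist.values())
        labels[c] = min(lbl for lbl, cnt in hist.items() if cnt == top)
    correct = sum(1 for item, c in zip(a.items, a.clusters) if labels[int(c)] == gold[item])
    histograms = {c: dict(h) for c, h in histograms.items()}
    return LabeledClusters(labels=labels, histograms=histograms,
                           accuracy=correct / len(a.items))


@dataclass
class LabelingResult:
    features: FeatureMatrix
    model: ClusterModel
    assignment: ClusterAssignment
    labeled: LabeledClusters
    gold: Dict[str, str]

    def predictions(self) -> List[dict]:
        return [
            {
                "id": item,
                "cluster": int(c),
                "predicted_label": self.labeled.labels[int(c)],
                "gold_label": self.gold[item],
            }
            for item, c in zip(self.assignment.items, self.assignment.clusters)
        ]


def _entity_items(c: Corpus, table) -> Tuple[List[str], List[np.ndarray], Dict[str, str]]:
    ids: List[str] = []
    rows: List[np.ndarray] = []
    gold: Dict[str, str] = {}
    for ui, u in enumerate(c.utterances):
        for ei, e in enumerate(u.entities):
            t = preprocess_word_level(e.surface)
            if not t.tokens:
                continue
            try:
                v = word_feature(t, table)
            except Exception:
                continue  # unrepresentable surface: excluded, not imputed
            item = f"u{ui}.e{ei}"
            ids.append(item)
            rows.append(v)
            gold[item] = e.slot
    return ids, rows, gold


def label_corpus(
    c: Corpus,
    embedding,
    level: str = "word",
    target: str = "intent",
    k: Union[int, str] = "gold",
    seed: int = 0,
    restarts: int = 10,
) -> LabelingResult:
    """End-to-end labeling: featurize -> cluster -> majority-label.

    ``target`` selects intent clustering (one item per utterance) or entity
    clustering (one item per gold entity span; always word-level features).
    ``embedding`` is a VectorTable (word level) or a sentence encoder;
    ``k="gold"`` uses the number of distinct gold classes.
    """
    if target not in ("intent", "entity"):
        raise ValueError("target must be 'intent' or 'entity'")
    if target == "entity" or level == "word":
        table = embedding
        if not hasattr(table, "compose"):
            raise TypeError("word-level labeling requires a VectorTable [stage: featurize]")
    if target == "intent":
        ids = [f"u{i}" for i in range(len(c.utterances))]
        gold = {i: u.intent for i, u in zip(ids, c.utterances)}
        texts = c.texts()
        try:
            if level == "word":
                fm = word_features(texts, embedding, ids=ids)
            elif level == "sentence":
                encoder = embedding if hasattr(embedding, "encode") else MeanPoolingEncoder(embedding)
                fm = sentence_features(texts, encoder, ids=ids)
            else:
                raise ValueError(f"unknown feature level {level!r}")
        except ValueError as e:
            raise type(e)(f"[stage: featurize] {e}") from e
    else:
        ids, rows, gold = _entity_items(c, embedding)
        if not ids:
            raise ValueError("[stage: featurize] no representable entity surfaces")
        fm = FeatureMatrix(items=ids, matrix=np.vstack(rows), level="word")

    k_val = len(set(gold.values())) if k == "gold" else int(k)
    model, assignment = kmeans_fit(fm, k=k_val, seed=seed, restarts=restarts)
    labeled = majority_labels(assignment, gold)
    return LabelingResult(features=fm, model=model, assignment=assignment,
                          labeled=labeled, gold=gold)
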