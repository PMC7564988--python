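"""Trainable word-vector backends: skip-gram and subword n-gram models.

Both trainers implement skip-gram with negative sampling (SGNS) in NumPy.
The word-level model learns one input vector per vocabulary token; the
subword model learns vectors for boundary-marked character n-grams and
represents a word as the **sum** of its n-gram vectors, which lets it
compose vectors for out-of-vocabulary words.  Defaults follow the tuned
configuration used to embed the generated corpus: 32 features, minimum
count 3, context window 6, downsampling 1e-3, 50 epochs.

Negative-sampling count (5) and the linearly decayed learning rate (0.025)
follow standard word2vec practice and are configurable.  Training is
single-threaded and bit-reproducible per seed; the ``threads`` field is
advisory metadata only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SubwordConfig",
    "TrainConfig",
    "VectorTable",
    "VectorFormatError",
    "EmbeddingTrainError",
    "char_ngrams",
    "train_skipgram",
    "train_subword",
    "cosine_similarity",
    "nearest_neighbors",
    "read_vectors",
    "write_vectors",
]


class VectorFormatError(ValueError):
    pass


class EmbeddingTrainError(ValueError):
    pass


@dataclass(frozen=True)
class SubwordConfig:
    """Character n-gram extraction parameters for the subword model."""

    n_min: int = 3
    n_max: int = 6
    boundary_start: str = "<"
    boundary_end: str = ">"

    def __post_init__(self):
        if not (1 <= self.n_min <= self.n_max):
            raise ValueError("require 1 <= n_min <= n_max")


@dataclass(frozen=True)
class TrainConfig:
    dimension: int = 32
    min_count: int = 3
    window: int = 6
    downsample: float = 1e-3
    epochs: int = 50
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    threads: int = 4  # advisory; the NumPy trainer runs single-threaded
    seed: int = 0

    def __post_init__(self):
        for name in ("dimension", "min_count", "window", "epochs", "negative"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def char_ngrams(word: str, cfg: SubwordConfig = SubwordConfig()) -> List[str]:
    """Boundary-marked character n-grams of ``word`` in left-to-right order.

    A word shorter than ``n_min`` (after marking) collapses to the single
    marked whole word.  Duplicates are preserved.
    """
    if not word:
        raise ValueError("word must be non-empty")
    marked = cfg.boundary_start + word + cfg.boundary_end
    grams: List[str] = []
    for n in range(cfg.n_min, cfg.n_max + 1):
        for i in range(len(marked) - n + 1):
            grams.append(marked[i:i + n])
    return grams or [marked]


@dataclass
class VectorTable:
    """Token -> dense-vector map with optional subword composition support."""

    dimension: int
    vectors: Dict[str, np.ndarray]
    subword: Optional[SubwordConfig] = None
    ngram_vectors: Optional[Dict[str, np.ndarray]] = None
    norm_cached: Optional[Dict[str, float]] = field(default=None, repr=False)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def tokens(self) -> List[str]:
        return list(self.vectors)

    def compose(self, token: str) -> Optional[np.ndarray]:
        """Vector for ``token``: direct lookup, else subword composition,
        else None."""
        v = self.vectors.get(token)
        if v is not None:
            return v
        if self.subword is None or not self.ngram_vectors:
            return None
        rows = [self.ngram_vectors[g] for g in char_ngrams(token, self.subword)
                if g in self.ngram_vectors]
        if not rows:
            return None
        return np.sum(rows, axis=0)

    def norms(self) -> Dict[str, float]:
        if self.norm_cached is None:
            self.norm_cached = {t: float(np.linalg.norm(v)) for t, v in self.vectors.items()}
        return self.norm_cached


# ---------------------------------------------------------------------------
# similarity

def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def nearest_neighbors(word: str, table: VectorTable, k: int = 10,
                      threshold: float = 0.5) -> Tuple[List[Tuple[str, float]], bool]:
    """Top-``k`` vocabulary tokens by cosine similarity to ``word``.

    Returns ``(ranked, oov)``.  The query token itself is excluded; only
    neighbours with similarity >= ``threshold`` are kept; exact similarity
    ties break by lexicographic token order.  An out-of-vocabulary query on
    a subword table is composed from its n-grams; on a word-level table it
    yields ``([], True)``.
    """
    if k <= 0:
        return [], word not in table
    q = table.compose(word)
    oov = word not in table
    if q is None:
        return [], True
    qn = np.linalg.norm(q)
    if qn == 0.0:
        return [], True
    scored: List[Tuple[str, float]] = []
    norms = table.norms()
    for token, vec in table.vectors.items():
        if token == word:
            continue
        n = norms[token]
        if n == 0.0:
            continue
        sim = float(np.dot(q, vec) / (qn * n))
        if sim >= threshold:
            scored.append((token, sim))
    scored.sort(key=lambda ts: (-ts[1], ts[0]))
    return scored[:k], oov


# ---------------------------------------------------------------------------
# SGNS training

def _build_vocab(sentences: Sequence[Sequence[str]], min_count: int) -> Tuple[List[str], np.ndarray]:
    counts: Dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted((t for t, c in counts.items() if c >= min_count),
                   key=lambda t: (-counts[t], t))
    if not vocab:
        raise EmbeddingTrainError(
            f"vocabulary empty after min_count={min_count} filtering"
        )
    freqs = np.array([counts[t] for t in vocab], dtype=float)
    return vocab, freqs


def _sgns_train(sentences, cfg: TrainConfig, ngram_index=None, ngram_count: int = 0):
    """Shared SGNS loop.  ``ngram_index`` maps word id -> n-gram id array;
    when given, the input representation of a word is the sum of its n-gram
    rows (subword mode), otherwise one row per word (word mode)."""
    vocab, freqs = _build_vocab(sentences, cfg.min_count)
    index = {t: i for i, t in enumerate(vocab)}
    corpus = [np.array([index[t] for t in sent if t in index], dtype=np.int64)
              for sent in sentences]
    corpus = [ids for ids in corpus if len(ids)]
    if not corpus:
        raise EmbeddingTrainError("no trainable sentences after vocabulary filtering")

    rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)
    d = cfg.dimension
    n_in = ngram_count if ngram_index is not None else len(vocab)
    W_in = (rng.random((n_in, d)) - 0.5) / d
    W_out = np.zeros((len(vocab), d))

    # unigram^{3/4} negative-sampling distribution
    neg_cdf = np.cumsum(freqs ** 0.75)
    neg_cdf /= neg_cdf[-1]

    # word2vec-style frequency downsampling keep probability
    total = freqs.sum()
    f_rel = freqs / total
    t = cfg.downsample
    keep = np.minimum(1.0, np.sqrt(t / f_rel) + t / f_rel) if t > 0 else np.ones_like(f_rel)

    total_positions = max(1, sum(len(s) for s in corpus) * cfg.epochs)
    processed = 0
    for _epoch in range(cfg.epochs):
        for ids in corpus:
            mask = rng.random(len(ids)) < keep[ids]
            ids_kept = ids[mask]
            n = len(ids_kept)
            for pos in range(n):
                processed += 1
                center = int(ids_kept[pos])
                b = int(rng.integers(1, cfg.window + 1))
                lo, hi = max(0, pos - b), min(n, pos + b + 1)
                ctx = np.concatenate([ids_kept[lo:pos], ids_kept[pos + 1:hi]])
                if len(ctx) == 0:
                    continue
                lr = cfg.alpha + (cfg.min_alpha - cfg.alpha) * (processed / total_positions)
                neg = np.searchsorted(neg_cdf, rng.random((len(ctx), cfg.negative)))
                if ngram_index is not None:
                    rows = ngram_index[center]
                    h = W_in[rows].sum(axis=0)
                else:
                    h = W_in[center]
                # positives: label 1; negatives: label 0
                out_ids = np.concatenate([ctx, neg.ravel()])
                labels = np.concatenate([np.ones(len(ctx)), np.zeros(neg.size)])
                U = W_out[out_ids]
                g = 1.0 / (1.0 + np.exp(-U @ h)) - labels  # sigmoid - label
                h_grad = g @ U
                np.add.at(W_out, out_ids, np.outer(-lr * g, h))
                if ngram_index is not None:
                    W_in[rows] -= lr * h_grad
                else:
                    W_in[center] -= lr * h_grad
    return vocab, W_in, W_out


def train_skipgram(sentences: Sequence[Sequence[str]], cfg: TrainConfig = TrainConfig()) -> VectorTable:
    """Train word-level skip-gram vectors on tokenised sentences."""
    vocab, W_in, _ = _sgns_train(sentences, cfg)
    return VectorTable(
        dimension=cfg.dimension,
        vectors={t: W_in[i].copy() for i, t in enumerate(vocab)},
    )


def train_subword(sentences: Sequence[Sequence[str]], cfg: TrainConfig = TrainConfig(),
                  subword: SubwordConfig = SubwordConfig()) -> VectorTable:
    """Train subword n-gram vectors; each word vector is the sum of its
    n-gram vectors, and unseen words compose from shared n-grams."""
    vocab, _ = _build_vocab(sentences, cfg.min_count)
    gram_index: Dict[str, int] = {}
    word_grams: List[np.ndarray] = []
    for w in vocab:
        rows = []
        for g in char_ngrams(w, subword):
            if g not in gram_index:
                gram_index[g] = len(gram_index)
            rows.append(gram_index[g])
        word_grams.append(np.array(rows, dtype=np.int64))
    vocab2, G, _ = _sgns_train(sentences, cfg, ngram_index=word_grams,
                               ngram_count=len(gram_index))
    assert vocab2 == vocab
    ngram_vectors = {g: G[i].copy() for g, i in gram_index.items()}
    vectors = {w: G[rows].sum(axis=0) for w, rows in zip(vocab, word_grams)}
    return VectorTable(
        dimension=cfg.dimension,
        vectors=vectors,
        subword=subword,
        ngram_vectors=ngram_vectors,
    )


# ---------------------------------------------------------------------------
# word2vec text-format I/O

def write_vectors(table: VectorTable, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dimension}\n")
        for token, vec in table.vectors.items():
            fh.write(token + " " + " ".join(f"{x:.6g}" for x in vec) + "\n")


def read_vectors(path) -> VectorTable:
    p = Path(path)
    with p.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise VectorFormatError(f"{p}: line 1: expected 'vocab_size dimension' header")
        try:
            n_rows, dim = int(header[0]), int(header[1])
        except ValueError as e:
            raise VectorFormatError(f"{p}: line 1: non-integer header") from e
        vectors: Dict[str, np.ndarray] = {}
        count = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(" ")
            token, values = parts[0], parts[1:]
            if len(values) != dim:
                raise VectorFormatError(
                    f"{p}: line {lineno}: expected {dim} values for {token!r}, got {len(values)}"
                )
            if token in vectors:
                logger.warning("%s: line %d: duplicate token %r, last occurrence wins", p, lineno, token)
            count += 1
            vectors[token] = np.array([float(v) for v in values], dtype=float)
        if count != n_rows:
            raise VectorFormatError(
                f"{p}: header declares {n_rows} rows but file contains {count}"
            )
    return VectorTable(dimension=dim, vectors=vectors)
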