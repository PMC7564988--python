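"""Text normalisation and feature construction for clustering.

Word-level features: a fixed normalisation pipeline (contraction expansion
-> lower-casing -> tokenisation -> stopword removal -> lemmatisation ->
non-ASCII/punctuation stripping) followed by mean pooling of token vectors,
F_w = (1/N) * sum_n v_wn.  Sentence-level features keep inflection and
stopwords (only non-ASCII characters are removed) and go through a
sentence-encoder interface; the packaged desk-scale encoder mean-pools
trained word vectors over the sentence-level text.

Entity candidates are noun phrases located by a dependency-parser
interface.  The packaged default is a deterministic rule-based chunker
covering the corpus's verb-object / preposition-object / number+unit
sentence shapes; a statistical parser can be plugged in through the same
callable interface and the chunker serves as its fallback.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources as _ilres
from pathlib import Path
from typing import Callable, Dict, List, Optional, Protocol, Sequence, Tuple

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "TokenizedUtterance",
    "FeatureMatrix",
    "EntityCandidate",
    "MissingFeatureError",
    "EncoderUnavailableError",
    "preprocess_word_level",
    "preprocess_sentence_level",
    "lemmatize",
    "word_feature",
    "sentence_feature",
    "word_features",
    "sentence_features",
    "MeanPoolingEncoder",
    "RuleBasedChunker",
    "extract_entity_candidates",
    "write_feature_matrix",
]


class MissingFeatureError(ValueError):
    def __init__(self, item: str, message: str):
        super().__init__(message)
        self.item = item


class EncoderUnavailableError(RuntimeError):
    pass


@dataclass(frozen=True)
class TokenizedUtterance:
    original: str
    tokens: Tuple[str, ...]
    dropped: Tuple[Tuple[str, str], ...] = ()  # (token, reason)


@dataclass
class FeatureMatrix:
    items: List[str]
    matrix: np.ndarray
    level: str  # "word" | "sentence"

    def __post_init__(self):
        if len(self.items) != self.matrix.shape[0]:
            raise ValueError("row count must equal item count")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")


@dataclass(frozen=True)
class EntityCandidate:
    utterance_id: str
    phrase: str
    start: int
    end: int
    tag: str  # head dependency tag, e.g. dobj / pobj / nummod


# ---------------------------------------------------------------------------
# packaged lexical resources

def _resource_text(name: str) -> str:
    return _ilres.files("dialogforge.resources").joinpath(name).read_text(encoding="utf-8")


@lru_cache(maxsize=1)
def stopwords() -> frozenset:
    words = set()
    for line in _resource_text("stopwords.txt").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


@lru_cache(maxsize=1)
def contractions() -> Dict[str, str]:
    return dict(yaml.safe_load(_resource_text("contractions.yaml")))


@lru_cache(maxsize=1)
def _lemma_exceptions() -> Dict[str, str]:
    table: Dict[str, str] = {}
    for line in _resource_text("lemma_exceptions.txt").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            surface, lemma = line.split()
            table[surface] = lemma
    return table


def lemmatize(word: str) -> str:
    """Lexicon-backed lemmatiser: exception table first, then conservative
    suffix rules (regular plurals, long superlatives); unknown shapes pass
    through unchanged."""
    exc = _lemma_exceptions()
    if word in exc:
        return exc[word]
    if len(word) > 4 and word.endswith("ies"):
        return word[:-3] + "y"
    if len(word) > 3 and word.endswith("s") and not word.endswith(("ss", "us", "is")):
        return word[:-1]
    if len(word) >= 6 and word.endswith("est"):
        return word[:-2]
    return word


# ---------------------------------------------------------------------------
# preprocessing

_CONTRACTION_RE = None
_NON_ASCII = re.compile(r"[^\x00-\x7f]")
_EDGE_PUNCT = ".,!?;:\"'()[]"


def _expand_contractions(text: str) -> str:
    global _CONTRACTION_RE
    table = contractions()
    if _CONTRACTION_RE is None:
        _CONTRACTION_RE = re.compile(
            r"\b(" + "|".join(re.escape(k) for k in sorted(table, key=len, reverse=True)) + r")\b",
            re.IGNORECASE,
        )
    return _CONTRACTION_RE.sub(lambda m: table[m.group(0).lower()], text)


def _simple_tokens(text: str) -> List[str]:
    return [t for t in (tok.strip(_EDGE_PUNCT) for tok in text.split()) if t]


def preprocess_word_level(text: str) -> TokenizedUtterance:
    """Full word-level normalisation pipeline; deterministic.

    A text reducing to zero tokens is flagged via an empty token tuple, not
    raised.
    """
    expanded = _expand_contractions(text).lower()
    raw_tokens = _simple_tokens(expanded)
    tokens: List[str] = []
    dropped: List[Tuple[str, str]] = []
    sw = stopwords()
    for tok in raw_tokens:
        if tok in sw:
            dropped.append((tok, "stopword"))
            continue
        lemma = lemmatize(tok)
        cleaned = _NON_ASCII.sub("", lemma)
        cleaned = re.sub(r"[^\w]", "", cleaned)
        if not cleaned:
            dropped.append((tok, "non-ascii/punctuation"))
            continue
        tokens.append(cleaned)
    if not tokens:
        logger.debug("text %r reduced to zero tokens", text)
    return TokenizedUtterance(original=text, tokens=tuple(tokens), dropped=tuple(dropped))


def preprocess_sentence_level(text: str) -> str:
    """Sentence-level normalisation removes non-ASCII characters only;
    case, inflection and stopwords are preserved (lemmatising would merge
    forms such as close/closer/closest whose meanings differ)."""
    return _NON_ASCII.sub("", text)


# ---------------------------------------------------------------------------
# features

def word_feature(t: TokenizedUtterance, table) -> np.ndarray:
    """Arithmetic mean of the token vectors of ``t`` (F_w).

    Tokens absent from a word-level table are skipped rather than
    zero-imputed (zero rows bias the mean toward the origin); subword
    tables compose vectors for unseen tokens.
    """
    rows = []
    for tok in t.tokens:
        v = table.compose(tok)
        if v is not None:
            rows.append(v)
    if not rows:
        raise MissingFeatureError(
            t.original, f"no representable tokens in {t.original!r}"
        )
    return np.mean(rows, axis=0)


class SentenceEncoder(Protocol):
    dimension: int

    def encode(self, text: str) -> np.ndarray: ...


class MeanPoolingEncoder:
    """Desk-scale sentence encoder: mean-pooled trained word vectors over
    sentence-level-preprocessed text (no stopword removal, no lemmas).

    Tokens are matched exactly, falling back to their lower-cased form when
    the table was trained on lower-cased text.
    """

    def __init__(self, table):
        self.table = table
        self.dimension = table.dimension

    def encode(self, text: str) -> np.ndarray:
        if not text:
            raise ValueError("cannot encode an empty string")
        cleaned = preprocess_sentence_level(text)
        rows = []
        for tok in _simple_tokens(cleaned):
            v = self.table.compose(tok)
            if v is None:
                v = self.table.compose(tok.lower())
            if v is not None:
                rows.append(v)
        if not rows:
            raise MissingFeatureError(text, f"no representable tokens in {text!r}")
        return np.mean(rows, axis=0)


def sentence_feature(text: str, encoder: Optional[SentenceEncoder]) -> np.ndarray:
    """Fixed-length sentence representation (F_s) through the encoder
    interface; deterministic per encoder version."""
    if encoder is None:
        raise EncoderUnavailableError(
            "no sentence encoder available; use the word-level route "
            "(preprocess_word_level + word_feature) instead"
        )
    if not text:
        raise ValueError("cannot encode an empty string")
    return np.asarray(encoder.encode(text), dtype=float)


def word_features(texts: Sequence[str], table, ids: Optional[Sequence[str]] = None) -> FeatureMatrix:
    ids = list(ids) if ids is not None else [f"u{i}" for i in range(len(texts))]
    rows = [word_feature(preprocess_word_level(t), table) for t in texts]
    return FeatureMatrix(items=ids, matrix=np.vstack(rows), level="word")


def sentence_features(texts: Sequence[str], encoder: SentenceEncoder,
                      ids: Optional[Sequence[str]] = None) -> FeatureMatrix:
    ids = list(ids) if ids is not None else [f"u{i}" for i in range(len(texts))]
    rows = [sentence_feature(t, encoder) for t in texts]
    return FeatureMatrix(items=ids, matrix=np.vstack(rows), level="sentence")


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    """Delimited numeric export with a leading item-id column."""
    with Path(path).open("w", encoding="utf-8") as fh:
        dim = fm.matrix.shape[1]
        fh.write("item\t" + "\t".join(f"f{i}" for i in range(dim)) + "\n")
        for item, row in zip(fm.items, fm.matrix):
            fh.write(item + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# entity candidates

_PREPOSITIONS = {"with", "at", "for", "to", "on", "in", "from", "until", "since", "by", "of"}
_DETERMINERS = {"a", "an", "the", "this", "that", "his", "her", "my", "your", "their", "its"}
_AUX_HEAD = {
    "please", "i", "you", "can", "could", "did", "do", "have", "has", "had",
    "when", "where", "what", "who", "why", "how", "is", "are", "was", "were",
    "been", "helped", "help", "assist", "use", "used",
}
_NUMBER = re.compile(r"^\d[\d.:]*$")


@lru_cache(maxsize=1)
def _verb_inventory() -> frozenset:
    words = set()
    forms = yaml.safe_load(_resource_text("verb_forms.yaml"))
    for k, v in forms.items():
        words.add(k)
        words.add(v)
    syn = yaml.safe_load(_resource_text("synonyms.yaml"))
    for k, vals in syn.items():
        words.update(k.split())
        for s in vals:
            words.update(s.split())
    return frozenset(words)


class RuleBasedChunker:
    """Deterministic noun-phrase chunker over the corpus's sentence shapes.

    Rules: (1) the tokens between the verb head and the first preposition
    form the direct object (dobj); (2) each preposition's trailing tokens up
    to the next preposition form its object (pobj); (3) a phrase led by a
    number token is tagged nummod (number + unit).  Leading determiners are
    excluded; output spans are contiguous, non-overlapping token spans.
    """

    def __call__(self, text: str, utterance_id: str = "") -> List[EntityCandidate]:
        spans = [(m.group(0), m.start(), m.end()) for m in re.finditer(r"\S+", text)]
        norm = [tok.strip(_EDGE_PUNCT).lower() for tok, _, _ in spans]
        verbs = _verb_inventory()
        n = len(spans)
        i = 0
        # skip the verb head and auxiliary/question prefixes
        while i < n and (norm[i] in verbs or norm[i] in _AUX_HEAD or norm[i] == "to"):
            i += 1
        out: List[EntityCandidate] = []

        def emit(lo: int, hi: int, tag: str):
            while lo < hi and norm[lo] in _DETERMINERS:
                lo += 1
            if lo >= hi:
                return
            if _NUMBER.match(norm[lo]):
                tag = "nummod"
            start, end = spans[lo][1], spans[hi - 1][2]
            phrase = text[start:end].strip(_EDGE_PUNCT)
            end = start + len(phrase)
            if phrase:
                out.append(EntityCandidate(utterance_id, phrase, start, end, tag))

        j = i
        while j < n and norm[j] not in _PREPOSITIONS:
            j += 1
        if j > i:
            emit(i, j, "dobj")
        while j < n:
            # norm[j] is a preposition
            k = j + 1
            while k < n and norm[k] not in _PREPOSITIONS:
                k += 1
            emit(j + 1, k, "pobj")
            j = k
        return out


def extract_entity_candidates(
    text: str,
    parser: Optional[Callable[..., List[EntityCandidate]]] = None,
    utterance_id: str = "",
) -> List[EntityCandidate]:
    """Noun-phrase entity candidates with head dependency tags.

    ``parser`` is any callable matching the chunker interface (a wrapped
    statistical dependency parser qualifies); on parser failure the
    rule-based chunker takes over with a logged notice.
    """
    fallback = RuleBasedChunker()
    if parser is None:
        return fallback(text, utterance_id)
    try:
        return parser(text, utterance_id)
    except Exception as e:  # noqa: BLE001 - any parser failure falls back
        logger.warning("dependency parser failed on %r (%s); using rule-based chunker", text, e)
        return fallback(text, utterance_id)
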