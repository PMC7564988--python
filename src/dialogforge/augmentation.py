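"""Rule-based utterance augmentation: shuffle, fill, paraphrase.

The generator composes three stages.  (A) *Word shuffling* enumerates every
ordering of an intent's prepositional record phrases behind the fixed
``verb + activity`` head, respecting subject-verb-object order.  (B) *Word
replacing* fills slot placeholders with every surface value (and synonym)
from the ontology, tracking character-exact entity spans.  (C) *Utterance
paraphrasing* applies four syntactic transformation rules — question form,
politeness insertion, active-to-passive, keyword synonym replacement —
re-computing spans so gold labels survive every transformation.

All randomness is driven by explicit integer seeds; a corpus is a pure
function of (ontology, config, seed).
"""

from __future__ import annotations

import json
import logging
import math
import re
import zlib
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .ontology import EntitySlot, IntentSpec, Ontology, PhraseTemplate

logger = logging.getLogger(__name__)

__all__ = [
    "EntitySpan",
    "UtteranceTemplate",
    "LabeledUtterance",
    "Corpus",
    "GenerationConfig",
    "ConfigurationError",
    "DEFAULT_BUDGETS",
    "PARAPHRASE_RULES",
    "enumerate_orderings",
    "fill_slots",
    "expand_synonyms",
    "paraphrase",
    "generate_corpus",
    "default_lexicon",
    "write_corpus_jsonl",
    "read_corpus_jsonl",
    "write_corpus_text",
    "corpus_text",
]


class ConfigurationError(ValueError):
    pass


#: Per-intent utterance budgets of the reference six-intent corpus
#: (3546 utterances in total).
DEFAULT_BUDGETS: Dict[str, int] = {
    "add-vital": 876,
    "clean-oral": 606,
    "assist-toilet": 408,
    "prepare-meal": 756,
    "assist-bath": 560,
    "change-diaper": 340,
}

PARAPHRASE_RULES = ("question", "politeness", "passive", "synonym")


@dataclass(frozen=True)
class EntitySpan:
    """A gold entity: slot name plus a 0-based half-open character span."""

    slot: str
    start: int
    end: int
    surface: str


@dataclass(frozen=True)
class UtteranceTemplate:
    """One rendering order: verb + activity head followed by record phrases."""

    intent: str
    verb: str
    activity_slot: str
    ordered_phrases: Tuple[PhraseTemplate, ...]

    def __post_init__(self):
        slots = [p.slot for p in self.ordered_phrases]
        if len(slots) != len(set(slots)):
            raise ConfigurationError(
                f"template for intent {self.intent!r} references a slot twice: {slots}"
            )


@dataclass(frozen=True)
class LabeledUtterance:
    text: str
    intent: str
    entities: Tuple[EntitySpan, ...]
    provenance: Tuple[dict, ...] = ()

    def check_spans(self) -> None:
        """Raise if any entity span is inconsistent with the text."""
        prev_end = -1
        for e in sorted(self.entities, key=lambda e: e.start):
            if not (0 <= e.start < e.end <= len(self.text)):
                raise ValueError(f"span ({e.start},{e.end}) outside text {self.text!r}")
            if e.start < prev_end:
                raise ValueError(f"overlapping spans in {self.text!r}")
            if self.text[e.start:e.end] != e.surface:
                raise ValueError(
                    f"span mismatch: {self.text[e.start:e.end]!r} != {e.surface!r}"
                )
            prev_end = e.end


@dataclass
class Corpus:
    utterances: List[LabeledUtterance]
    ontology_version: str
    seed: int
    shortfalls: Dict[str, int] = field(default_factory=dict)

    def texts(self) -> List[str]:
        return [u.text for u in self.utterances]

    def by_intent(self) -> Dict[str, List[LabeledUtterance]]:
        out: Dict[str, List[LabeledUtterance]] = {}
        for u in self.utterances:
            out.setdefault(u.intent, []).append(u)
        return out


# ---------------------------------------------------------------------------
# (A) word shuffling

def enumerate_orderings(spec: IntentSpec) -> List[UtteranceTemplate]:
    """All distinct record-phrase orderings behind the verb+activity head.

    The head never moves (subject-verb-object constraint); for *m* distinct
    record phrases exactly ``m!`` templates are produced, in a deterministic
    order, with previously generated orderings skipped.
    """
    from itertools import permutations

    out: List[UtteranceTemplate] = []
    seen = set()
    for perm in permutations(spec.record_templates):
        key = tuple(p.slot for p in perm)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            UtteranceTemplate(
                intent=spec.name,
                verb=spec.verbs[0],
                activity_slot=spec.activity_slot,
                ordered_phrases=perm,
            )
        )
    return out


# ---------------------------------------------------------------------------
# (B) word replacing / slot filling

def _render(t: UtteranceTemplate, activity_surface: str, phrase_surfaces: Sequence[str]) -> LabeledUtterance:
    parts: List[str] = [t.verb]
    pos = len(t.verb) + 1
    entities: List[EntitySpan] = [
        EntitySpan(t.activity_slot, pos, pos + len(activity_surface), activity_surface)
    ]
    parts.append(activity_surface)
    pos += len(activity_surface) + 1
    for phrase, surf in zip(t.ordered_phrases, phrase_surfaces):
        lead = " ".join([phrase.preposition, *phrase.modifiers]).strip()
        if lead:
            parts.append(lead)
            pos += len(lead) + 1
        parts.append(surf)
        entities.append(EntitySpan(phrase.slot, pos, pos + len(surf), surf))
        pos += len(surf) + 1
    text = " ".join(parts)
    prov = (
        {
            "op": "fill",
            "verb": t.verb,
            "activity_slot": t.activity_slot,
            "ordering": [p.slot for p in t.ordered_phrases],
        },
    )
    u = LabeledUtterance(text=text, intent=t.intent, entities=tuple(entities), provenance=prov)
    u.check_spans()
    return u


def fill_slots(t: UtteranceTemplate, o: Ontology, budget: int, seed: int = 0) -> List[LabeledUtterance]:
    """Fill every placeholder of one template with ontology surfaces.

    If the Cartesian product of slot surfaces fits within ``budget`` it is
    emitted exhaustively (deterministic order); otherwise a uniform sample
    without replacement is drawn under ``seed``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    axes: List[List[str]] = []
    for slot_name in [t.activity_slot, *(p.slot for p in t.ordered_phrases)]:
        surfaces = o.slot(slot_name).surfaces()
        if not surfaces:
            raise ConfigurationError(f"slot {slot_name!r} has no fillable values")
        axes.append(surfaces)
    sizes = [len(a) for a in axes]
    total = math.prod(sizes)
    if total <= budget:
        indices: Iterable[int] = range(total)
    else:
        rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(t.intent.encode())])
        indices = sorted(int(i) for i in rng.choice(total, size=budget, replace=False))
    out: List[LabeledUtterance] = []
    for flat in indices:
        combo = []
        rem = flat
        for size in reversed(sizes):
            combo.append(rem % size)
            rem //= size
        combo.reverse()
        out.append(_render(t, axes[0][combo[0]], [a[c] for a, c in zip(axes[1:], combo[1:])]))
    return out


# ---------------------------------------------------------------------------
# embedding-based synonym lookup (shared contract with embeddings.nearest_neighbors)

_SPECIAL = re.compile(r"[^A-Za-z0-9]+")


def expand_synonyms(word: str, vectors, k: int = 10, threshold: float = 0.5,
                    min_length: int = 4) -> Tuple[List[Tuple[str, float]], bool]:
    """Embedding-neighbourhood synonyms for one keyword.

    Special characters are stripped before lookup (units such as ``a.m.`` or
    ``mmHg.`` carry punctuation).  Returns ``(matches, oov)`` where ``oov``
    distinguishes an out-of-vocabulary query from an in-vocabulary query
    with no neighbour above ``threshold``.  Retrieved tokens shorter than
    ``min_length`` characters are discarded.
    """
    from .embeddings import nearest_neighbors

    cleaned = _SPECIAL.sub("", word)
    if not cleaned:
        return [], True
    hits, oov = nearest_neighbors(cleaned, vectors, k=k, threshold=threshold)
    if min_length:
        hits = [(w, s) for w, s in hits if len(w) >= min_length]
    return hits, oov


# ---------------------------------------------------------------------------
# (C) paraphrasing

_YESNO_PREFIXES = ("Can you", "Could you", "Did you")
_WH_PREFIXES = ("When did you", "Where did you")
_POLITE_PREFIXES = ("Please, ", "I ")


def default_lexicon() -> Dict[str, List[str]]:
    text = _ilres.files("dialogforge.resources").joinpath("synonyms.yaml").read_text(encoding="utf-8")
    return {k: list(v) for k, v in yaml.safe_load(text).items()}


def _verb_forms() -> Dict[str, str]:
    text = _ilres.files("dialogforge.resources").joinpath("verb_forms.yaml").read_text(encoding="utf-8")
    return dict(yaml.safe_load(text))


def _shift_spans(entities: Sequence[EntitySpan], delta: int) -> Tuple[EntitySpan, ...]:
    return tuple(EntitySpan(e.slot, e.start + delta, e.end + delta, e.surface) for e in entities)


def _with_provenance(u: LabeledUtterance, entry: dict) -> Tuple[dict, ...]:
    return (*u.provenance, entry)


def _fill_info(u: LabeledUtterance) -> Optional[dict]:
    for p in u.provenance:
        if p.get("op") == "fill":
            return p
    return None


def _prefixed(u: LabeledUtterance, prefix: str, suffix: str, prov: dict) -> LabeledUtterance:
    v = LabeledUtterance(
        text=prefix + u.text + suffix,
        intent=u.intent,
        entities=_shift_spans(u.entities, len(prefix)),
        provenance=_with_provenance(u, prov),
    )
    v.check_spans()
    return v


def paraphrase(
    u: LabeledUtterance,
    rules: Sequence[str] = PARAPHRASE_RULES,
    lexicon: Optional[Dict[str, List[str]]] = None,
    seed: int = 0,
) -> List[LabeledUtterance]:
    """One label-preserving variant per applicable transformation rule.

    Rules: ``question`` (modal yes/no or Wh- form, seeded draw),
    ``politeness`` ("Please,"/"I" prefix), ``passive`` (template-based over
    the closed verb inventory), ``synonym`` (keyword replacement from the
    lexicon).  Entity spans are recomputed for every variant.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(u.text.encode())])
    if lexicon is None and "synonym" in rules:
        lexicon = default_lexicon()
    info = _fill_info(u) or {}
    verb = info.get("verb")
    out: List[LabeledUtterance] = []

    for rule in PARAPHRASE_RULES:
        if rule not in rules:
            continue
        if rule == "question":
            family = _YESNO_PREFIXES if rng.random() < 0.5 else _WH_PREFIXES
            p = family[rng.integers(len(family))]
            out.append(_prefixed(u, p + " ", "?", {"op": "paraphrase", "rule": "question", "prefix": p}))
        elif rule == "politeness":
            p = _POLITE_PREFIXES[rng.integers(len(_POLITE_PREFIXES))]
            out.append(_prefixed(u, p, "", {"op": "paraphrase", "rule": "politeness", "prefix": p.strip()}))
        elif rule == "passive":
            v = _passive(u, verb)
            if v is not None:
                out.append(v)
        elif rule == "synonym":
            v = _synonym(u, verb, lexicon or {}, rng)
            if v is not None:
                out.append(v)
    return out


_warned_verbs = set()


def _passive(u: LabeledUtterance, verb: Optional[str]) -> Optional[LabeledUtterance]:
    forms = _verb_forms()
    if verb is None or verb not in forms:
        if verb not in _warned_verbs:  # warn once per verb, not per utterance
            _warned_verbs.add(verb)
            logger.warning("passive rule skipped: verb %r not in participle inventory", verb)
        return None
    if not u.text.startswith(verb + " "):
        logger.warning("passive rule skipped: %r does not start with verb %r", u.text, verb)
        return None
    info = _fill_info(u) or {}
    activity = next((e for e in u.entities if e.slot == info.get("activity_slot")), None)
    if activity is None or activity.start != len(verb) + 1:
        logger.warning("passive rule skipped: activity surface not adjacent to verb in %r", u.text)
        return None
    surf = activity.surface
    be = "are" if surf.endswith("s") and not surf.endswith("ss") else "is"
    head = f"{surf} {be} {forms[verb]}"
    rest = u.text[activity.end:]
    delta = len(head) - activity.end
    entities = [EntitySpan(activity.slot, 0, len(surf), surf)]
    for e in u.entities:
        if e is activity:
            continue
        entities.append(EntitySpan(e.slot, e.start + delta, e.end + delta, e.surface))
    v = LabeledUtterance(
        text=head + rest,
        intent=u.intent,
        entities=tuple(entities),
        provenance=_with_provenance(u, {"op": "paraphrase", "rule": "passive"}),
    )
    v.check_spans()
    return v


def _synonym(u: LabeledUtterance, verb: Optional[str], lexicon: Dict[str, List[str]],
             rng: np.random.Generator) -> Optional[LabeledUtterance]:
    if verb is None or verb not in lexicon or not lexicon[verb]:
        return None
    if not u.text.startswith(verb + " "):
        return None
    alternatives = lexicon[verb]
    syn = alternatives[rng.integers(len(alternatives))]
    delta = len(syn) - len(verb)
    v = LabeledUtterance(
        text=syn + u.text[len(verb):],
        intent=u.intent,
        entities=_shift_spans(u.entities, delta),
        provenance=_with_provenance(u, {"op": "paraphrase", "rule": "synonym", "substitution": [verb, syn]}),
    )
    v.check_spans()
    return v


# ---------------------------------------------------------------------------
# corpus generation

@dataclass
class GenerationConfig:
    """Generation conditions: per-intent budgets, rule set, synonym lexicon.

    ``budgets`` defaults to the reference per-intent counts
    (:data:`DEFAULT_BUDGETS`); intents absent from the mapping receive
    ``fallback_budget``.  ``oversample`` bounds how many base fillings are
    drawn per ordering before paraphrasing and down-sampling.
    """

    budgets: Optional[Dict[str, int]] = None
    rules: Tuple[str, ...] = PARAPHRASE_RULES
    lexicon: Optional[Dict[str, List[str]]] = None
    fallback_budget: int = 100
    oversample: int = 3

    def budget_for(self, intent: str) -> int:
        table = self.budgets if self.budgets is not None else DEFAULT_BUDGETS
        return int(table.get(intent, self.fallback_budget))


def generate_corpus(o: Ontology, cfg: Optional[GenerationConfig] = None, seed: int = 0) -> Corpus:
    """Run the full shuffle -> fill -> paraphrase pipeline over an ontology.

    Deterministic under ``(o, cfg, seed)``.  Texts are globally unique; if
    an intent's attainable unique variants fall short of its budget the
    attainable maximum is emitted and the shortfall recorded on the corpus.
    """
    cfg = cfg or GenerationConfig()
    for intent in o.intents:
        if cfg.budget_for(intent.name) < 1:
            raise ValueError(f"budget for intent {intent.name!r} must be >= 1")
    lexicon = cfg.lexicon if cfg.lexicon is not None else (
        default_lexicon() if "synonym" in cfg.rules else {}
    )
    utterances: List[LabeledUtterance] = []
    shortfalls: Dict[str, int] = {}
    seen_texts = set()
    for spec in o.intents:
        budget = cfg.budget_for(spec.name)
        templates = enumerate_orderings(spec)
        per_template = max(1, math.ceil(budget * cfg.oversample / len(templates)))
        pool: List[LabeledUtterance] = []
        for idx, t in enumerate(templates):
            child_seed = (seed ^ zlib.crc32(f"{spec.name}:{idx}".encode())) & 0x7FFFFFFF
            pool.extend(fill_slots(t, o, budget=per_template, seed=child_seed))
        bases = list(pool)
        for base in bases:
            pool.extend(paraphrase(base, rules=cfg.rules, lexicon=lexicon, seed=seed))
        unique: List[LabeledUtterance] = []
        local = set()
        for u in pool:
            if u.text in seen_texts or u.text in local:
                continue
            local.add(u.text)
            unique.append(u)
        if len(unique) > budget:
            rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(spec.name.encode())])
            keep = sorted(int(i) for i in rng.choice(len(unique), size=budget, replace=False))
            chosen = [unique[i] for i in keep]
        else:
            chosen = unique
            if len(unique) < budget:
                shortfalls[spec.name] = budget - len(unique)
                logger.warning(
                    "intent %s: only %d unique variants attainable of requested %d",
                    spec.name, len(unique), budget,
                )
        seen_texts.update(u.text for u in chosen)
        utterances.extend(chosen)
    return Corpus(
        utterances=utterances,
        ontology_version=o.version,
        seed=seed,
        shortfalls=shortfalls,
    )


# ---------------------------------------------------------------------------
# corpus I/O

def write_corpus_jsonl(c: Corpus, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        header = {
            "ontology_version": c.ontology_version,
            "seed": c.seed,
            "shortfalls": c.shortfalls,
        }
        fh.write(json.dumps({"__meta__": header}, ensure_ascii=False) + "\n")
        for u in c.utterances:
            fh.write(
                json.dumps(
                    {
                        "text": u.text,
                        "intent": u.intent,
                        "entities": [
                            {"slot": e.slot, "start": e.start, "end": e.end, "surface": e.surface}
                            for e in u.entities
                        ],
                        "provenance": list(u.provenance),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_corpus_jsonl(path) -> Corpus:
    utterances: List[LabeledUtterance] = []
    meta = {"ontology_version": "unknown", "seed": -1, "shortfalls": {}}
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if "__meta__" in obj:
                meta.update(obj["__meta__"])
                continue
            u = LabeledUtterance(
                text=obj["text"],
                intent=obj["intent"],
                entities=tuple(
                    EntitySpan(e["slot"], e["start"], e["end"], e["surface"])
                    for e in obj.get("entities", [])
                ),
                provenance=tuple(obj.get("provenance", [])),
            )
            u.check_spans()
            utterances.append(u)
    return Corpus(
        utterances=utterances,
        ontology_version=meta["ontology_version"],
        seed=meta["seed"],
        shortfalls=dict(meta["shortfalls"]),
    )


def corpus_text(c: Corpus) -> str:
    """Plain-text form, one utterance per line, newline-terminated (the
    character-model training format)."""
    return "".join(u.text + "\n" for u in c.utterances)


def write_corpus_text(c: Corpus, path) -> None:
    Path(path).write_text(corpus_text(c), encoding="utf-8")
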