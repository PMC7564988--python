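"""Declarative data model for action-driven nursing-care utterances.

An :class:`Ontology` declares the intents a dialogue system must recognise
(each an action verb plus an activity class, e.g. ``add-vital``), the entity
slots that carry record information (measurement values, materials, places,
times, care targets) and the prepositional-phrase templates that connect a
slot to the utterance head.  Slot identifiers are lower-case hyphenated,
mirroring the ``@slot-name`` notation used in task-oriented NLU.

The on-disk format is a single YAML document::

    version: "1.0"
    slots:
      - name: vital-type          # identifier, unique
        kind: activity            # activity | record
        values: [blood pressure]  # surface strings, non-empty
        synonyms:                 # optional, keys must appear in values
          blood pressure: [pressure]
        number_prefixes: ["103"]  # optional; numeric measurements are
                                  # rendered as "<prefix> <value>" and the
                                  # entity span covers the whole phrase
    intents:
      - name: add-vital
        verbs: [add, set]         # non-empty; first verb renders the head
        activity_slot: vital-type # must resolve to a kind=activity slot
        record_templates:
          - {preposition: with, slot: vital-value}            # pattern 1
          - {preposition: to, modifiers: [a], slot: target}   # pattern 2
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path
from typing import Dict, List, Optional

import yaml

__all__ = [
    "EntitySlot",
    "PhraseTemplate",
    "IntentSpec",
    "Ontology",
    "OntologyFormatError",
    "OntologyValidationError",
    "load_ontology",
    "loads_ontology",
    "write_ontology",
    "dumps_ontology",
    "validate_ontology",
    "builtin_fixture",
]


class OntologyFormatError(ValueError):
    """The config file could not be parsed as an ontology document."""


class OntologyValidationError(ValueError):
    """The parsed document violates an ontology invariant."""


@dataclass(frozen=True)
class EntitySlot:
    """A typed entity slot with its surface-value inventory.

    ``kind`` separates the activity class (the direct object of the intent
    verb) from record slots (measurements, materials, times, targets).
    ``number_prefixes`` supports measurement slots whose surfaces are
    "<number> <unit>" pairs.
    """

    name: str
    kind: str  # "activity" | "record"
    values: tuple
    synonyms: Dict[str, tuple] = field(default_factory=dict)
    number_prefixes: tuple = ()

    def surfaces(self) -> List[str]:
        """All fillable surface strings: values, their synonyms, and, for
        measurement slots, every ``prefix value`` combination."""
        base: List[str] = []
        for v in self.values:
            base.append(v)
            base.extend(self.synonyms.get(v, ()))
        if not self.number_prefixes:
            return base
        return [f"{p} {s}" for p in self.number_prefixes for s in base]


@dataclass(frozen=True)
class PhraseTemplate:
    """Prepositional phrase attaching one record slot to the utterance.

    Pattern 1 is ``preposition + slot``; pattern 2 inserts one or more
    modifiers between them (``to a @target``).
    """

    preposition: str
    slot: str
    modifiers: tuple = ()
    pattern: int = 1

    def __post_init__(self):
        if self.pattern not in (1, 2):
            raise OntologyValidationError(
                f"template for slot {self.slot!r}: pattern must be 1 or 2"
            )


@dataclass(frozen=True)
class IntentSpec:
    """An action-driven intent: verbs plus an activity slot plus the record
    phrases that may accompany it."""

    name: str
    verbs: tuple
    activity_slot: str
    record_templates: tuple  # of PhraseTemplate


@dataclass(frozen=True)
class Ontology:
    intents: tuple  # of IntentSpec
    slots: tuple  # of EntitySlot
    version: str = "1.0"

    def slot(self, name: str) -> EntitySlot:
        for s in self.slots:
            if s.name == name:
                return s
        raise KeyError(name)

    def intent(self, name: str) -> IntentSpec:
        for i in self.intents:
            if i.name == name:
                return i
        raise KeyError(name)


# ---------------------------------------------------------------------------
# validation

def validate_ontology(o: Ontology) -> List[str]:
    """Return a list of human-readable issues; empty iff the ontology is valid.

    Issues are data, not exceptions: callers that require validity should
    raise on a non-empty result.
    """
    issues: List[str] = []
    slot_names = [s.name for s in o.slots]
    seen = set()
    for n in slot_names:
        if n in seen:
            issues.append(f"duplicate slot name {n!r}")
        seen.add(n)
    slots = {s.name: s for s in o.slots}

    for s in o.slots:
        if s.kind not in ("activity", "record"):
            issues.append(f"slot {s.name!r}: kind must be activity or record, got {s.kind!r}")
        if not s.values:
            issues.append(f"slot {s.name!r}: values must be non-empty")
        for key in s.synonyms:
            if key not in s.values:
                issues.append(f"slot {s.name!r}: synonym key {key!r} not among its values")

    if not o.intents:
        issues.append("ontology declares no intents")
    seen = set()
    for i in o.intents:
        if i.name in seen:
            issues.append(f"duplicate intent name {i.name!r}")
        seen.add(i.name)
        if not i.verbs:
            issues.append(f"intent {i.name!r}: verbs must be non-empty")
        act = slots.get(i.activity_slot)
        if act is None:
            issues.append(f"intent {i.name!r}: activity slot {i.activity_slot!r} not declared")
        elif act.kind != "activity":
            issues.append(f"intent {i.name!r}: activity slot {i.activity_slot!r} has kind {act.kind!r}")
        for t in i.record_templates:
            ref = slots.get(t.slot)
            if ref is None:
                issues.append(f"intent {i.name!r}: template references undeclared slot {t.slot!r}")
            elif ref.kind != "record":
                issues.append(f"intent {i.name!r}: template slot {t.slot!r} is not a record slot")
            if t.pattern == 1 and t.modifiers:
                issues.append(f"intent {i.name!r}: pattern-1 template for {t.slot!r} carries modifiers")
            if t.pattern == 2 and not t.modifiers:
                issues.append(f"intent {i.name!r}: pattern-2 template for {t.slot!r} has empty modifiers")
    return issues


# ---------------------------------------------------------------------------
# (de)serialisation

def _parse_slot(d: dict) -> EntitySlot:
    return EntitySlot(
        name=d["name"],
        kind=d.get("kind", "record"),
        values=tuple(str(v) for v in d.get("values", [])),
        synonyms={k: tuple(v) for k, v in (d.get("synonyms") or {}).items()},
        number_prefixes=tuple(str(p) for p in d.get("number_prefixes", [])),
    )


def _parse_intent(d: dict) -> IntentSpec:
    templates = []
    for t in d.get("record_templates", []):
        mods = tuple(t.get("modifiers", []) or [])
        templates.append(
            PhraseTemplate(
                preposition=t.get("preposition", ""),
                slot=t["slot"],
                modifiers=mods,
                pattern=int(t.get("pattern", 2 if mods else 1)),
            )
        )
    return IntentSpec(
        name=d["name"],
        verbs=tuple(d.get("verbs", [])),
        activity_slot=d.get("activity_slot", ""),
        record_templates=tuple(templates),
    )


def loads_ontology(text: str, source: str = "<string>") -> Ontology:
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        mark = getattr(e, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise OntologyFormatError(f"{source}: cannot parse ontology document{line}: {e}") from e
    if not isinstance(doc, dict):
        raise OntologyFormatError(f"{source}: ontology document must be a mapping")
    try:
        o = Ontology(
            intents=tuple(_parse_intent(i) for i in doc.get("intents", [])),
            slots=tuple(_parse_slot(s) for s in doc.get("slots", [])),
            version=str(doc.get("version", "1.0")),
        )
    except (KeyError, TypeError) as e:
        raise OntologyFormatError(f"{source}: malformed ontology entry: {e!r}") from e
    issues = validate_ontology(o)
    if issues:
        raise OntologyValidationError(f"{source}: " + "; ".join(issues))
    return o


def load_ontology(path) -> Ontology:
    """Load and validate an ontology config file (YAML schema above)."""
    p = Path(path)
    return loads_ontology(p.read_text(encoding="utf-8"), source=str(p))


def dumps_ontology(o: Ontology) -> str:
    doc = {
        "version": o.version,
        "slots": [
            {
                "name": s.name,
                "kind": s.kind,
                "values": list(s.values),
                **({"synonyms": {k: list(v) for k, v in s.synonyms.items()}} if s.synonyms else {}),
                **({"number_prefixes": list(s.number_prefixes)} if s.number_prefixes else {}),
            }
            for s in o.slots
        ],
        "intents": [
            {
                "name": i.name,
                "verbs": list(i.verbs),
                "activity_slot": i.activity_slot,
                "record_templates": [
                    {
                        "preposition": t.preposition,
                        "slot": t.slot,
                        "pattern": t.pattern,
                        **({"modifiers": list(t.modifiers)} if t.modifiers else {}),
                    }
                    for t in i.record_templates
                ],
            }
            for i in o.intents
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def write_ontology(o: Ontology, path) -> None:
    Path(path).write_text(dumps_ontology(o), encoding="utf-8")


def builtin_fixture() -> Ontology:
    """The packaged six-intent nursing-care ontology.

    Deterministic: loaded from a versioned resource file covering the six
    intents (add-vital, clean-oral, assist-toilet, prepare-meal, assist-bath,
    change-diaper), their activity/record slots with printed sample surfaces,
    and the shared record slots start-time, stop-time and target.
    """
    text = _ilres.files("dialogforge.resources").joinpath("fixture_ontology.yaml").read_text(
        encoding="utf-8"
    )
    return loads_ontology(text, source="fixture_ontology.yaml")
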