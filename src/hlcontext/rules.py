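"""Declarative high-level context class definitions and the direct classifier.

Each high-level context class is defined, per low-level category, by a
*required* flag (an existential restriction: a component of that category must
be present) and an *allowed* set (a universal restriction: if a component is
present, its type must be in the set).  An absent optional category satisfies
its universal restriction vacuously.  This mirrors the description-logic
semantics of the ontology (see :mod:`hlcontext.owl` for the OWL 2 export);
the direct classifier here evaluates the same definitions in memory, without
a reasoner.

Because definitions are not mutually exclusive, an instance may satisfy
several classes; the ruleset carries a priority order (specific before
general) that resolves the full ``match_set`` to a single reported label.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .model import (
    DEFAULT_VOCABULARY,
    UNIDENTIFIED,
    Category,
    HighLevelContext,
    Vocabulary,
    normalize_label,
)


class RulesetError(ValueError):
    """A ruleset configuration document violates the schema."""


@dataclass(frozen=True)
class CategoryRule:
    """Constraint on one low-level category within a class definition."""

    required: bool
    allowed: frozenset[str]

    def __post_init__(self) -> None:
        if not self.allowed:
            raise RulesetError("allowed set must be non-empty")


@dataclass(frozen=True)
class HLCDefinition:
    """One high-level context class: a rule per low-level category."""

    name: str
    activity_rule: CategoryRule
    location_rule: CategoryRule
    emotion_rule: CategoryRule
    enabled: bool = True

    def rule(self, category: Category) -> CategoryRule:
        return {
            Category.ACTIVITY: self.activity_rule,
            Category.LOCATION: self.location_rule,
            Category.EMOTION: self.emotion_rule,
        }[category]


@dataclass(frozen=True)
class RuleSet:
    """The full set of class definitions plus the label priority order."""

    definitions: tuple[HLCDefinition, ...]
    priority: tuple[str, ...]
    vocabulary: Vocabulary = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        names = [d.name for d in self.definitions]
        if len(set(names)) != len(names):
            raise RulesetError("duplicate class names in ruleset")
        if sorted(self.priority) != sorted(names):
            raise RulesetError("priority must be a permutation of the defined class names")

    def definition(self, name: str) -> HLCDefinition:
        for d in self.definitions:
            if d.name == name:
                return d
        raise KeyError(name)


def _parse_category_rule(
    class_name: str, category: Category, node: object, vocabulary: Vocabulary
) -> CategoryRule:
    key = f"classes.{class_name}.{category.value}"
    if not isinstance(node, Mapping):
        raise RulesetError(f"{key}: expected a mapping with 'required' and 'allowed'")
    unknown = set(node) - {"required", "allowed"}
    if unknown:
        raise RulesetError(f"{key}: unknown keys {sorted(unknown)}")
    required = node.get("required", False)
    if not isinstance(required, bool):
        raise RulesetError(f"{key}.required: expected a boolean")
    allowed_spec = node.get("allowed", "any")
    vocab_terms = vocabulary.terms(category)
    if allowed_spec == "any":
        allowed = vocab_terms
    elif isinstance(allowed_spec, list):
        allowed = frozenset(normalize_label(str(t)) for t in allowed_spec)
        bad = allowed - vocab_terms
        if bad:
            raise RulesetError(f"{key}.allowed: terms not in the {category.value} vocabulary: {sorted(bad)}")
    else:
        raise RulesetError(f"{key}.allowed: expected a list of terms or 'any'")
    if not allowed:
        raise RulesetError(f"{key}.allowed: must not be empty")
    return CategoryRule(required=required, allowed=frozenset(allowed))


def load_ruleset(
    source: str | Path | Mapping, vocabulary: Vocabulary = DEFAULT_VOCABULARY
) -> RuleSet:
    """Load and validate a ruleset from YAML (path, text, or parsed mapping).

    Raises :class:`RulesetError` naming the offending key on any schema
    violation: unknown vocabulary terms, missing category rules, or a priority
    list that is not a permutation of the defined class names.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml"))):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = yaml.safe_load(io.StringIO(text))
    if not isinstance(doc, Mapping):
        raise RulesetError("ruleset document must be a mapping")
    unknown = set(doc) - {"classes", "priority"}
    if unknown:
        raise RulesetError(f"unknown top-level keys {sorted(unknown)}")
    classes = doc.get("classes")
    if not isinstance(classes, Mapping) or not classes:
        raise RulesetError("classes: expected a non-empty mapping")

    definitions = []
    for name, body in classes.items():
        if not isinstance(body, Mapping):
            raise RulesetError(f"classes.{name}: expected a mapping")
        unknown = set(body) - {"activity", "location", "emotion", "enabled"}
        if unknown:
            raise RulesetError(f"classes.{name}: unknown keys {sorted(unknown)}")
        enabled = body.get("enabled", True)
        if not isinstance(enabled, bool):
            raise RulesetError(f"classes.{name}.enabled: expected a boolean")
        rules = {}
        for cat in Category:
            node = body.get(cat.value, {"required": False, "allowed": "any"})
            rules[cat] = _parse_category_rule(str(name), cat, node, vocabulary)
        definitions.append(
            HLCDefinition(
                name=str(name),
                activity_rule=rules[Category.ACTIVITY],
                location_rule=rules[Category.LOCATION],
                emotion_rule=rules[Category.EMOTION],
                enabled=enabled,
            )
        )

    priority = doc.get("priority")
    if priority is None:
        priority = [d.name for d in definitions]
    if not isinstance(priority, list) or not all(isinstance(p, str) for p in priority):
        raise RulesetError("priority: expected a list of class names")
    try:
        return RuleSet(
            definitions=tuple(definitions),
            priority=tuple(priority),
            vocabulary=vocabulary,
        )
    except RulesetError as exc:
        raise RulesetError(f"priority: {exc}") from None


def default_ruleset(vocabulary: Vocabulary = DEFAULT_VOCABULARY) -> RuleSet:
    """The shipped default ruleset (ten classes; NoHLC disabled)."""
    text = resources.files("hlcontext").joinpath("data/default_rules.yaml").read_text()
    return load_ruleset(text, vocabulary=vocabulary)


def satisfies_labels(
    definition: HLCDefinition,
    activity: Optional[str],
    location: Optional[str],
    emotion: Optional[str],
) -> bool:
    """Whether a (possibly partial) label triple satisfies a class definition."""
    for category, term in (
        (Category.ACTIVITY, activity),
        (Category.LOCATION, location),
        (Category.EMOTION, emotion),
    ):
        rule = definition.rule(category)
        if term is None:
            if rule.required:
                return False
        elif term not in rule.allowed:
            return False
    return True


def satisfies(instance: HighLevelContext, definition: HLCDefinition) -> bool:
    """Whether a closed high-level context instance satisfies a definition.

    The instance must be *closed* (its components are definitively its only
    ones); without closure, universal restrictions are not decidable under the
    open-world assumption.
    """
    if not instance.closed:
        raise ValueError(f"{instance.id}: instance lacks closure; cannot evaluate restrictions")
    return satisfies_labels(
        definition,
        instance.activity.type_label if instance.activity else None,
        instance.location.type_label if instance.location else None,
        instance.emotion.type_label if instance.emotion else None,
    )


def classify_labels(
    ruleset: RuleSet,
    activity: Optional[str] = None,
    location: Optional[str] = None,
    emotion: Optional[str] = None,
) -> tuple[frozenset[str], str]:
    """Classify a label triple: the satisfied class set and the resolved label.

    The label is the highest-priority member of the match set, or
    ``"unidentified"`` when no enabled definition matches.
    """
    matches = frozenset(
        d.name
        for d in ruleset.definitions
        if d.enabled and satisfies_labels(d, activity, location, emotion)
    )
    if not matches:
        return matches, UNIDENTIFIED
    for name in ruleset.priority:
        if name in matches:
            return matches, name
    raise AssertionError("priority does not cover match set")  # pragma: no cover


def classify_instance(instance: HighLevelContext, ruleset: RuleSet) -> tuple[frozenset[str], str]:
    """Classify a closed high-level context instance (deterministic, total)."""
    if not instance.closed:
        raise ValueError(f"{instance.id}: instance lacks closure; cannot classify")
    return classify_labels(
        ruleset,
        activity=instance.activity.type_label if instance.activity else None,
        location=instance.location.type_label if instance.location else None,
        emotion=instance.emotion.type_label if instance.emotion else None,
    )
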