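"""Core domain types for two-level context modeling.

A *low-level context* (LLC) is a primitive piece of behavioral information
recognized directly from user data — an activity, a location, or an emotion —
attached to a user and valid over a temporal interval.  A *high-level context*
(HLC) is an abstract behavioral situation (office work, sleeping, ...) composed
of at most one concurrent low-level context per category.

Validity intervals are half-open ``[start, end)``: a context is valid at its
start instant and no longer valid at its end instant.  An absent end time means
the context is still ongoing.  Timestamps are timezone-naive at second
precision and compared chronologically.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional


class Category(str, enum.Enum):
    """The three categories of low-level context."""

    ACTIVITY = "activity"
    LOCATION = "location"
    EMOTION = "emotion"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Labels a high-level context can carry before/after classification.
PENDING = "pending"
UNIDENTIFIED = "unidentified"
#: Pseudo-label used when comparing against "no previous context at all".
NO_PREVIOUS = "none"


def normalize_label(label: str) -> str:
    """Normalize a vocabulary term to lower_snake_case.

    Accepts spaced forms (``"lying down"``) and mixed case; the canonical
    internal form is ``lying_down``.
    """
    return "_".join(label.strip().lower().split())


@dataclass(frozen=True)
class Vocabulary:
    """The closed sets of recognizable low-level context types.

    The default vocabulary has 16 activities, 8 locations and 8 emotions,
    covering sedentary, daily-living and fitness activities, everyday places,
    and basic moods.  The three sets must be pairwise disjoint.
    """

    activities: frozenset[str]
    locations: frozenset[str]
    emotions: frozenset[str]

    def __post_init__(self) -> None:
        sets = [self.activities, self.locations, self.emotions]
        total = len(self.activities | self.locations | self.emotions)
        if total != sum(len(s) for s in sets):
            raise ValueError("vocabulary category sets must be pairwise disjoint")

    def terms(self, category: Category) -> frozenset[str]:
        return {
            Category.ACTIVITY: self.activities,
            Category.LOCATION: self.locations,
            Category.EMOTION: self.emotions,
        }[category]

    def category_of(self, term: str) -> Optional[Category]:
        """Return the category a term belongs to, or None if unknown."""
        for cat in Category:
            if term in self.terms(cat):
                return cat
        return None

    def __contains__(self, term: str) -> bool:
        return self.category_of(term) is not None


DEFAULT_VOCABULARY = Vocabulary(
    activities=frozenset(
        {
            "lying_down",
            "standing",
            "sitting",
            "riding_escalator",
            "riding_elevator",
            "walking",
            "running",
            "jumping",
            "hiking",
            "climbing_stairs",
            "descending_stairs",
            "cycling",
            "stretching",
            "dancing",
            "sweeping",
            "eating",
        }
    ),
    locations=frozenset(
        {"home", "office", "yard", "gym", "mall", "restaurant", "outdoors", "transport"}
    ),
    emotions=frozenset(
        {"anger", "happiness", "neutral", "sadness", "fear", "disgust", "surprise", "boredom"}
    ),
)


def parse_timestamp(value: str | datetime) -> datetime:
    """Parse an ISO-8601 / XSD dateTime lexical form into a naive datetime."""
    if isinstance(value, datetime):
        ts = value
    else:
        ts = datetime.fromisoformat(value)
    if ts.tzinfo is not None:
        ts = ts.replace(tzinfo=None)
    return ts.replace(microsecond=0)


def format_timestamp(value: datetime) -> str:
    """Serialize a timestamp as an XSD dateTime lexical form (second precision)."""
    return value.isoformat(timespec="seconds")


class DuplicateIdentifierError(ValueError):
    """A context identifier (or identifier counter) was issued twice."""


def format_identifier(kind: str, counter: int, type_suffix: Optional[str] = None) -> str:
    """Format a context identifier: ``llc_<n>[_<type>]`` or ``hlc_<n>``."""
    if kind not in ("llc", "hlc"):
        raise ValueError(f"unknown identifier kind: {kind!r}")
    if counter < 0:
        raise ValueError("identifier counter must be non-negative")
    ident = f"{kind}_{counter}"
    if type_suffix is not None:
        ident = f"{ident}_{type_suffix}"
    return ident


class IdentifierMinter:
    """Issues sequential unique context identifiers per kind.

    Low-level identifiers always carry the type label as a suffix
    (``llc_360_sitting``); high-level identifiers are bare (``hlc_72``).
    """

    def __init__(self) -> None:
        self._issued: dict[str, set[int]] = {"llc": set(), "hlc": set()}
        self._next: dict[str, int] = {"llc": 0, "hlc": 0}

    def make_identifier(self, kind: str, counter: int, type_suffix: Optional[str] = None) -> str:
        ident = format_identifier(kind, counter, type_suffix)
        if counter in self._issued[kind]:
            raise DuplicateIdentifierError(f"counter {counter} already issued for kind {kind!r}")
        self._issued[kind].add(counter)
        self._next[kind] = max(self._next[kind], counter + 1)
        return ident

    def mint(self, kind: str, type_suffix: Optional[str] = None) -> str:
        """Issue the next sequential identifier of the given kind."""
        return self.make_identifier(kind, self._next[kind], type_suffix)


@dataclass
class LowLevelContext:
    """One recognized activity, location or emotion with its validity interval."""

    id: str
    user: str
    category: Category
    type_label: str
    start: datetime
    end: Optional[datetime] = None

    def __post_init__(self) -> None:
        if not self.user:
            raise ValueError("user identifier must be non-empty")
        if self.end is not None and self.end <= self.start:
            raise ValueError(f"{self.id}: end must be strictly after start")


@dataclass
class HighLevelContext:
    """A composition of at most one low-level context per category.

    ``components`` holds the constituent low-level contexts; the instance is
    *closed*: the listed components are asserted to be its only ones, and
    categories with no component are asserted to have none.  ``label`` is
    ``"pending"`` until classification runs, then one of the defined class
    names or ``"unidentified"``; ``match_set`` records every class whose
    definition the instance satisfies.
    """

    id: str
    user: str
    components: tuple[LowLevelContext, ...]
    start: datetime
    end: Optional[datetime] = None
    label: str = PENDING
    match_set: frozenset[str] = field(default_factory=frozenset)
    closed: bool = True

    def __post_init__(self) -> None:
        if not self.user:
            raise ValueError("user identifier must be non-empty")
        if self.end is not None and self.end <= self.start:
            raise ValueError(f"{self.id}: end must be strictly after start")

    def component(self, category: Category) -> Optional[LowLevelContext]:
        """The unique component of a category, or None.

        Raises ValueError if the composition holds several components of the
        category (a malformed instance the verifier is meant to catch).
        """
        found = [c for c in self.components if c.category == category]
        if len(found) > 1:
            raise ValueError(f"{self.id}: multiple components of category {category.value}")
        return found[0] if found else None

    @property
    def activity(self) -> Optional[LowLevelContext]:
        return self.component(Category.ACTIVITY)

    @property
    def location(self) -> Optional[LowLevelContext]:
        return self.component(Category.LOCATION)

    @property
    def emotion(self) -> Optional[LowLevelContext]:
        return self.component(Category.EMOTION)


def is_valid_at(record: LowLevelContext | HighLevelContext, t: datetime) -> bool:
    """Whether a context record is valid at instant ``t``.

    Intervals are half-open: valid iff ``start <= t`` and the record either has
    no end time yet or ends strictly after ``t``.
    """
    return record.start <= t and (record.end is None or record.end > t)


def overlapping(records: Iterable[LowLevelContext]) -> bool:
    """Whether any two records in a sorted-or-not collection overlap in time."""
    items = sorted(records, key=lambda r: r.start)
    for a, b in zip(items, items[1:]):
        if a.end is None or a.end > b.start:
            return True
    return False
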