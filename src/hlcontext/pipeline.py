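"""Event-driven inference pipeline: map → synchronize → instantiate → verify →
classify → notify.

Each incoming low-level event (a recognized activity/location/emotion start,
or an explicit end) is mapped to a stored low-level context, synchronized with
the user's other contexts valid at the same instant, composed into a new
unclassified high-level context, verified for consistency, classified against
the ruleset, and finally stored — finalizing the previous high-level context
and notifying sinks only when the resolved label actually changes.

Events of the same user must be processed in arrival order; distinct users are
fully independent (the store is the only shared state).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from typing import Callable, Iterable, Optional, Sequence

from .model import (
    NO_PREVIOUS,
    UNIDENTIFIED,
    Category,
    HighLevelContext,
    LowLevelContext,
    Vocabulary,
    DEFAULT_VOCABULARY,
    format_timestamp,
    is_valid_at,
)
from .rules import RuleSet, classify_instance
from .store import ContextStore

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LLCEvent:
    """One low-level context event from a recognizer.

    A *start* event carries the recognized type label; an *end* event only
    names the category whose current context ceased.
    """

    user: str
    category: Category
    timestamp: datetime
    label: Optional[str] = None
    event_type: str = "start"

    def __post_init__(self) -> None:
        if self.event_type not in ("start", "end"):
            raise ValueError(f"unknown event type: {self.event_type!r}")
        if self.event_type == "start" and self.label is None:
            raise ValueError("start events must carry a type label")


@dataclass(frozen=True)
class Notification:
    """Emitted when the user's high-level context label changes."""

    hlc: HighLevelContext
    previous_label: str
    new_label: str
    emitted_at: datetime

    def __post_init__(self) -> None:
        if self.new_label == self.previous_label:
            raise ValueError("notification requires a label change")


class EventRejected(ValueError):
    """An event failed validation and was skipped."""


Sink = Callable[[Notification], None]


class Pipeline:
    """Orchestrates the full inference chain over a context store."""

    def __init__(
        self,
        store: Optional[ContextStore] = None,
        ruleset: Optional[RuleSet] = None,
        vocabulary: Vocabulary = DEFAULT_VOCABULARY,
        sinks: Sequence[Sink] = (),
        suppress_unidentified_notifications: bool = False,
    ) -> None:
        from .rules import default_ruleset

        self.store = store if store is not None else ContextStore()
        self.ruleset = ruleset if ruleset is not None else default_ruleset()
        self.vocabulary = vocabulary
        self.sinks = list(sinks)
        self.suppress_unidentified = suppress_unidentified_notifications
        self.rejections = 0

    # -- stage 1: map -------------------------------------------------------

    def map_llc(self, event: LLCEvent) -> LowLevelContext:
        """Map a start event to a stored low-level context instance.

        Keeps per-category disjointness: the previously valid context of the
        same category is finalized (or truncated) at the event's timestamp,
        and an out-of-order context arriving with an earlier start is spliced
        in by closing it at the next posterior start of its category.
        """
        if event.event_type != "start":
            raise EventRejected("map_llc expects a start event")
        if event.label not in self.vocabulary.terms(event.category):
            raise EventRejected(
                f"unknown {event.category.value} label: {event.label!r}"
            )
        store = self.store
        current = store.concurrent_llcs(event.user, event.timestamp).get(event.category)
        if current is not None:
            if current.start == event.timestamp:
                # zero-length intervals are forbidden: the new context replaces it
                store.remove(current.id)
                logger.debug("replaced equal-start %s with new %s event", current.id, event.category.value)
            elif current.end is None:
                store.finalize(current.id, event.timestamp)
            else:
                store.truncate(current.id, event.timestamp)
        llc = LowLevelContext(
            id=store.next_llc_id(event.label),
            user=event.user,
            category=event.category,
            type_label=event.label,
            start=event.timestamp,
        )
        store.put(llc)
        posterior = store.next_posterior_start(event.user, event.timestamp, event.category)
        if posterior is not None:
            store.finalize(llc.id, posterior)
        return llc

    def end_llc(self, event: LLCEvent) -> Optional[LowLevelContext]:
        """Finalize the open context of the event's category, if any."""
        if event.event_type != "end":
            raise EventRejected("end_llc expects an end event")
        current = self.store.concurrent_llcs(event.user, event.timestamp).get(event.category)
        if current is None:
            logger.warning(
                "end event for %s of user %s at %s with nothing open; ignored",
                event.category.value, event.user, format_timestamp(event.timestamp),
            )
            return None
        if current.start == event.timestamp:
            self.store.remove(current.id)
            return current
        if current.end is None:
            self.store.finalize(current.id, event.timestamp)
        else:
            self.store.truncate(current.id, event.timestamp)
        return current

    # -- stage 2+3: synchronize and instantiate -----------------------------

    def instantiate(
        self,
        user: str,
        start: datetime,
        components: Iterable[LowLevelContext],
    ) -> HighLevelContext:
        """Create a new unclassified (pending) high-level context instance."""
        components = tuple(components)
        for comp in components:
            if comp.user != user:
                raise ValueError(
                    f"component {comp.id} belongs to user {comp.user}, not {user}"
                )
        return HighLevelContext(
            id=self.store.next_hlc_id(),
            user=user,
            components=components,
            start=start,
        )

    # -- stage 4: verify ----------------------------------------------------

    @staticmethod
    def verify(hlc: HighLevelContext) -> list[str]:
        """Check semantic and syntactic consistency; returns violations (empty = ok)."""
        violations: list[str] = []
        if hlc.start is None:
            violations.append("missing start time")
            return violations
        for cat in Category:
            n = sum(1 for c in hlc.components if c.category == cat)
            if n > 1:
                violations.append(f"multiple {cat.value} components ({n})")
        for comp in hlc.components:
            if comp.user != hlc.user:
                violations.append(f"component {comp.id} belongs to a different user")
            if not is_valid_at(comp, hlc.start):
                violations.append(f"component {comp.id} is not valid at the context start")
        if hlc.end is not None and hlc.end <= hlc.start:
            violations.append("end time not strictly after start time")
        return violations

    # -- stage 5: classify --------------------------------------------------

    def classify(self, hlc: HighLevelContext) -> HighLevelContext:
        """Set the instance's match set and priority-resolved label."""
        if self.verify(hlc):
            raise ValueError(f"{hlc.id}: classify requires a verified instance")
        match_set, label = classify_instance(hlc, self.ruleset)
        hlc.match_set = match_set
        hlc.label = label
        return hlc

    # -- stage 6: notify ----------------------------------------------------

    def notify(self, hlc: HighLevelContext) -> Optional[Notification]:
        """Store a classified instance; finalize its predecessor; emit on change.

        A first-ever context counts as a change from ``"none"``.  When a
        posterior high-level context already exists (an out-of-order arrival),
        the new instance is immediately finalized at the posterior start and
        no notification is emitted.
        """
        store = self.store
        previous = store.previous_valid_hlc(hlc.user, hlc.start)
        if previous is not None and previous.start == hlc.start:
            # equal start: the new context supersedes the old record entirely
            store.remove(previous.id)
            previous = store.previous_valid_hlc(hlc.user, hlc.start)
        store.put(hlc)
        if previous is not None:
            if previous.end is None:
                store.finalize(previous.id, hlc.start)
            else:
                store.truncate(previous.id, hlc.start)
        posterior = store.next_posterior_start(hlc.user, hlc.start, "hlc")
        if posterior is not None:
            store.finalize(hlc.id, posterior)
            return None
        previous_label = previous.label if previous is not None else NO_PREVIOUS
        if hlc.label == previous_label:
            return None
        if hlc.label == UNIDENTIFIED and (self.suppress_unidentified or previous_label == NO_PREVIOUS):
            # a user with no identified context yet has nothing to announce
            return None
        notification = Notification(
            hlc=hlc,
            previous_label=previous_label,
            new_label=hlc.label,
            emitted_at=hlc.start,
        )
        for sink in self.sinks:
            sink(notification)
        return notification

    # -- orchestration ------------------------------------------------------

    def process_event(self, event: LLCEvent) -> Optional[Notification]:
        """Run one event through the full chain; invalid events are skipped.

        Every accepted event — a start or an end — produces a new high-level
        context reflecting the user's composition at that instant, except an
        end event that leaves no low-level context valid, which only closes
        the current high-level context.
        """
        try:
            if event.event_type == "start":
                llc = self.map_llc(event)
                anchor = llc.start
            else:
                closed = self.end_llc(event)
                if closed is None:
                    return None
                anchor = event.timestamp
        except EventRejected as exc:
            self.rejections += 1
            logger.warning("event rejected: %s", exc)
            return None

        concurrent = self.store.concurrent_llcs(event.user, anchor)
        if not concurrent:
            open_hlc = self.store.previous_valid_hlc(event.user, anchor)
            if open_hlc is not None and open_hlc.end is None:
                if open_hlc.start == anchor:
                    self.store.remove(open_hlc.id)
                else:
                    self.store.finalize(open_hlc.id, anchor)
            return None
        hlc = self.instantiate(event.user, anchor, concurrent.values())
        violations = self.verify(hlc)
        if violations:
            logger.warning("instance %s rejected by verifier: %s", hlc.id, "; ".join(violations))
            return None
        self.classify(hlc)
        return self.notify(hlc)

    def process_stream(self, events: Iterable[LLCEvent]) -> list[Notification]:
        """Process an ordered event stream; returns the emitted notifications."""
        notifications = []
        for event in events:
            note = self.process_event(event)
            if note is not None:
                notifications.append(note)
        return notifications
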