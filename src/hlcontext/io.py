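"""File formats and batch runs: JSON Lines events and notifications,
configuration, and the end-to-end `run` entry point.

Event schema (one JSON object per line)::

    {"user": "9876", "category": "activity", "label": "sitting",
     "timestamp": "2015-11-10T11:05:25"}
    {"user": "9876", "category": "emotion", "event": "end",
     "timestamp": "2015-11-10T11:06:40"}

Notification schema::

    {"user": ..., "hlc_id": ..., "previous_label": ..., "new_label": ...,
     "start": ...}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .model import Category, format_timestamp, normalize_label, parse_timestamp
from .pipeline import LLCEvent, Notification, Pipeline
from .rules import default_ruleset, load_ruleset
from .store import ContextStore


class EventFormatError(ValueError):
    """A malformed line in an event file (message carries the line number)."""


def _parse_event(obj: dict, lineno: int) -> LLCEvent:
    try:
        user = str(obj["user"])
        category = Category(str(obj["category"]))
        timestamp = parse_timestamp(str(obj["timestamp"]))
    except (KeyError, ValueError) as exc:
        raise EventFormatError(f"line {lineno}: {exc!s}") from None
    event_type = str(obj.get("event", "start"))
    label = obj.get("label")
    if label is not None:
        label = normalize_label(str(label))
    try:
        return LLCEvent(
            user=user, category=category, timestamp=timestamp, label=label, event_type=event_type
        )
    except ValueError as exc:
        raise EventFormatError(f"line {lineno}: {exc!s}") from None


def read_events(path: str | Path) -> list[LLCEvent]:
    """Read a JSON Lines event file, in file order, with line-numbered errors."""
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise EventFormatError(f"line {lineno}: invalid JSON ({exc.msg})") from None
            if not isinstance(obj, dict):
                raise EventFormatError(f"line {lineno}: expected a JSON object")
            events.append(_parse_event(obj, lineno))
    return events


def event_to_obj(event: LLCEvent) -> dict:
    obj = {
        "user": event.user,
        "category": event.category.value,
        "timestamp": format_timestamp(event.timestamp),
    }
    if event.event_type == "end":
        obj["event"] = "end"
    else:
        obj["label"] = event.label
    return obj


def write_events(events, path: str | Path) -> None:
    """Write events as JSON Lines (round-trips with :func:`read_events`)."""
    with open(path, "w") as fh:
        for event in events:
            fh.write(json.dumps(event_to_obj(event), sort_keys=True) + "\n")


def notification_to_obj(note: Notification) -> dict:
    return {
        "user": note.hlc.user,
        "hlc_id": note.hlc.id,
        "previous_label": note.previous_label,
        "new_label": note.new_label,
        "start": format_timestamp(note.emitted_at),
    }


@dataclass
class RunConfig:
    """Configuration for a batch pipeline run."""

    events_path: str | Path
    ruleset_path: Optional[str | Path] = None
    notifications_path: Optional[str | Path] = None
    snapshot_path: Optional[str | Path] = None
    owl_terminology_path: Optional[str | Path] = None
    owl_instances_path: Optional[str | Path] = None
    suppress_unidentified_notifications: bool = False
    extra: dict = field(default_factory=dict)


def run(config: RunConfig) -> dict:
    """Process an event file through the pipeline; returns summary counts.

    Summary keys: ``events``, ``hlcs``, ``notifications``, ``rejections``.
    """
    ruleset = (
        load_ruleset(Path(config.ruleset_path)) if config.ruleset_path else default_ruleset()
    )
    events = read_events(config.events_path)

    store = ContextStore()
    pipeline = Pipeline(
        store=store,
        ruleset=ruleset,
        suppress_unidentified_notifications=config.suppress_unidentified_notifications,
    )
    notifications = pipeline.process_stream(events)

    if config.notifications_path is not None:
        with open(config.notifications_path, "w") as fh:
            for note in notifications:
                fh.write(json.dumps(notification_to_obj(note), sort_keys=True) + "\n")
    if config.snapshot_path is not None:
        store.save_snapshot(config.snapshot_path)
    if config.owl_terminology_path is not None:
        from .owl import export_terminology

        export_terminology(ruleset).serialize(destination=str(config.owl_terminology_path), format="turtle")
    if config.owl_instances_path is not None:
        store.to_graph().serialize(destination=str(config.owl_instances_path), format="turtle")

    return {
        "events": len(events),
        "hlcs": len(store.hlcs()),
        "notifications": len(notifications),
        "rejections": pipeline.rejections,
    }
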