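"""Shared fixtures: the default ruleset, the worked four-event scenario, and
random closed-instance builders used by the dual-route equivalence tests."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from hlcontext import Pipeline, default_ruleset
from hlcontext.model import (
    Category,
    DEFAULT_VOCABULARY,
    HighLevelContext,
    IdentifierMinter,
    LowLevelContext,
)
from hlcontext.pipeline import LLCEvent
from hlcontext.rules import classify_instance


def t(clock: str) -> datetime:
    """Timestamp on the scenario day (2015-11-10)."""
    return datetime.fromisoformat(f"2015-11-10T{clock}")


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


@pytest.fixture()
def scenario_events() -> list[LLCEvent]:
    """The worked scenario: office at 11:03:55, boredom at 11:05:05, sitting at
    11:05:25, and the emotion ending at 11:06:40."""
    return [
        LLCEvent("9876", Category.LOCATION, t("11:03:55"), "office"),
        LLCEvent("9876", Category.EMOTION, t("11:05:05"), "boredom"),
        LLCEvent("9876", Category.ACTIVITY, t("11:05:25"), "sitting"),
        LLCEvent("9876", Category.EMOTION, t("11:06:40"), event_type="end"),
    ]


@pytest.fixture()
def scenario_run(ruleset, scenario_events):
    """Pipeline state and notifications after replaying the scenario."""
    pipeline = Pipeline(ruleset=ruleset)
    notifications = pipeline.process_stream(scenario_events)
    return pipeline, notifications


def random_closed_instances(n: int, rng: np.random.Generator, ruleset):
    """Build ``n`` random closed high-level context instances (with their
    component low-level contexts) plus the match set the direct classifier
    assigns to each.  Instances keep at least one component."""
    vocab = DEFAULT_VOCABULARY
    minter = IdentifierMinter()
    t0 = datetime(2015, 11, 10, 8, 0, 0)
    records: list = []
    expected: dict[str, set[str]] = {}
    made = 0
    while made < n:
        start = t0 + timedelta(seconds=int(rng.integers(0, 86_400)))
        components = []
        for cat in Category:
            if rng.random() < 0.8:
                terms = sorted(vocab.terms(cat))
                term = terms[rng.integers(len(terms))]
                components.append(
                    LowLevelContext(minter.mint("llc", term), "u1", cat, term, start)
                )
        if not components:
            continue
        hlc = HighLevelContext(minter.mint("hlc"), "u1", tuple(components), start)
        match_set, _ = classify_instance(hlc, ruleset)
        records.extend(components)
        records.append(hlc)
        expected[hlc.id] = set(match_set)
        made += 1
    return records, expected
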