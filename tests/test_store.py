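"""Context store: storage, temporal queries vs. brute-force scan oracles, and
SPARQL parity over the RDF export."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from hlcontext.model import (
    Category,
    DuplicateIdentifierError,
    HighLevelContext,
    LowLevelContext,
    format_timestamp,
    is_valid_at,
)
from hlcontext.store import ContextStore, sparql_previous_valid_query

from .conftest import t


# -- scan oracles (deliberately naive) ---------------------------------------

def oracle_previous_valid(records, user, probe):
    candidates = [
        (r.start, i, r)
        for i, r in enumerate(records)
        if isinstance(r, HighLevelContext) and r.user == user and is_valid_at(r, probe)
    ]
    return max(candidates)[2] if candidates else None


def oracle_concurrent(records, user, probe):
    out = {}
    for r in records:
        if isinstance(r, LowLevelContext) and r.user == user and is_valid_at(r, probe):
            out[r.category] = r
    return out


def oracle_next_start(records, user, probe, kind):
    starts = [
        r.start
        for r in records
        if r.user == user
        and r.start > probe
        and (
            (kind == "hlc" and isinstance(r, HighLevelContext))
            or (kind != "hlc" and isinstance(r, LowLevelContext) and r.category == Category(kind))
        )
    ]
    return min(starts) if starts else None


def _scenario_store():
    store = ContextStore()
    office = LowLevelContext("llc_358_office", "9876", Category.LOCATION, "office", t("11:03:55"))
    boredom = LowLevelContext("llc_359_boredom", "9876", Category.EMOTION, "boredom", t("11:05:05"))
    hlc_70 = HighLevelContext("hlc_70", "9876", (office,), t("11:03:55"), end=t("11:05:05"), label="unidentified")
    hlc_71 = HighLevelContext("hlc_71", "9876", (office, boredom), t("11:05:05"), label="unidentified")
    for rec in (office, boredom, hlc_70, hlc_71):
        store.put(rec)
    return store


def random_records(rng, n_users=3, max_per_bucket=6):
    """Random per-bucket disjoint interval chains (some open-ended)."""
    t0 = datetime(2015, 11, 10)
    records = []
    counter = 0
    for u in range(n_users):
        user = f"u{u}"
        buckets = [("hlc", None)] + [("llc", cat) for cat in Category]
        for kind, cat in buckets:
            cursor = t0 + timedelta(seconds=int(rng.integers(0, 50)))
            for _ in range(int(rng.integers(0, max_per_bucket + 1))):
                start = cursor
                if rng.random() < 0.25:
                    end = None
                else:
                    end = start + timedelta(seconds=int(rng.integers(1, 40)))
                if kind == "hlc":
                    rec = HighLevelContext(f"hlc_{counter}", user, (), start, end=end)
                else:
                    term = sorted({"sitting", "walking"} if cat is Category.ACTIVITY else
                                  {"home", "office"} if cat is Category.LOCATION else
                                  {"neutral", "anger"})[int(rng.integers(2))]
                    rec = LowLevelContext(f"llc_{counter}_{term}", user, cat, term, start, end)
                counter += 1
                records.append(rec)
                if end is None:
                    break  # an open record ends the bucket's chain
                cursor = end + timedelta(seconds=int(rng.integers(0, 20)))
    return records


class TestStorage:
    def test_put_then_get(self):
        store = _scenario_store()
        assert store.get("llc_358_office").type_label == "office"

    def test_duplicate_id_rejected(self):
        store = _scenario_store()
        with pytest.raises(DuplicateIdentifierError):
            store.put(LowLevelContext("llc_358_office", "x", Category.LOCATION, "home", t("12:00:00")))

    def test_bulk_insert_all_retrievable(self):
        store = ContextStore()
        t0 = datetime(2015, 11, 10)
        for i in range(5000):
            store.put(
                LowLevelContext(
                    f"llc_{i}_sitting", f"u{i % 100}", Category.ACTIVITY, "sitting",
                    t0 + timedelta(seconds=10 * i),
                )
            )
        assert len(store) == 5000
        assert store.get("llc_4999_sitting").start == t0 + timedelta(seconds=49990)


class TestQueries:
    def test_previous_valid_returns_open_context(self):
        store = _scenario_store()
        assert store.previous_valid_hlc("9876", t("11:05:25")).id == "hlc_71"

    def test_previous_valid_empty_store(self):
        assert ContextStore().previous_valid_hlc("9876", t("11:05:25")) is None

    def test_concurrent_at_trigger_instant(self):
        store = _scenario_store()
        result = store.concurrent_llcs("9876", t("11:05:25"))
        assert {c: r.id for c, r in result.items()} == {
            Category.LOCATION: "llc_358_office",
            Category.EMOTION: "llc_359_boredom",
        }

    def test_concurrent_excludes_half_open_boundary(self):
        store = _scenario_store()
        store.finalize("llc_359_boredom", t("11:06:40"))
        result = store.concurrent_llcs("9876", t("11:06:40"))
        assert Category.EMOTION not in result
        assert result[Category.LOCATION].id == "llc_358_office"

    def test_concurrent_before_all_records(self):
        store = _scenario_store()
        assert store.concurrent_llcs("9876", t("10:00:00")) == {}

    def test_next_posterior_start(self):
        store = _scenario_store()
        assert store.next_posterior_start("9876", t("11:04:00"), "hlc") == t("11:05:05")
        assert store.next_posterior_start("9876", t("11:06:00"), "hlc") is None

    def test_per_user_isolation(self):
        store = _scenario_store()
        other = HighLevelContext("hlc_99", "1234", (), t("11:00:00"))
        store.put(other)
        assert store.previous_valid_hlc("9876", t("11:05:25")).id == "hlc_71"
        assert store.previous_valid_hlc("1234", t("11:05:25")).id == "hlc_99"

    def test_queries_match_scan_oracles_on_randomized_stores(self):
        """All four temporal queries agree with brute-force linear scans over
        1,000 randomized stores."""
        rng = np.random.default_rng(2024)
        t0 = datetime(2015, 11, 10)
        for _ in range(1000):
            records = random_records(rng)
            store = ContextStore()
            order = rng.permutation(len(records))
            inserted = [records[i] for i in order]
            for rec in inserted:
                store.put(rec)
            for _ in range(4):
                probe = t0 + timedelta(seconds=int(rng.integers(0, 300)))
                user = f"u{int(rng.integers(3))}"
                expect_prev = oracle_previous_valid(inserted, user, probe)
                got_prev = store.previous_valid_hlc(user, probe)
                if expect_prev is None:
                    assert got_prev is None
                else:
                    # disjoint chains make the valid record unique
                    assert got_prev is expect_prev
                assert store.concurrent_llcs(user, probe) == oracle_concurrent(inserted, user, probe)
                for kind in ("hlc", "activity", "location", "emotion"):
                    assert store.next_posterior_start(user, probe, kind) == oracle_next_start(
                        inserted, user, probe, kind
                    )


class TestFinalize:
    def test_finalize_closes_at_successor_start(self):
        store = _scenario_store()
        store.finalize("hlc_71", t("11:05:25"))
        assert store.get("hlc_71").end == t("11:05:25")
        assert store.previous_valid_hlc("9876", t("11:05:25")) is None

    def test_finalize_empty_interval_rejected(self):
        store = _scenario_store()
        with pytest.raises(ValueError, match="strictly after"):
            store.finalize("hlc_71", t("11:05:05"))

    def test_double_finalize_rejected(self):
        store = _scenario_store()
        store.finalize("hlc_71", t("11:05:25"))
        with pytest.raises(ValueError, match="already finalized"):
            store.finalize("hlc_71", t("11:06:00"))


class TestSparqlParity:
    def test_previous_valid_matches_sparql_over_export(self):
        """The native previous-valid query agrees with a SPARQL engine run over
        the RDF export of the store."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            records = random_records(rng, n_users=2)
            store = ContextStore()
            for rec in records:
                store.put(rec)
            graph = store.to_graph()
            t0 = datetime(2015, 11, 10)
            for _ in range(3):
                probe = t0 + timedelta(seconds=int(rng.integers(0, 300)))
                for user in ("u0", "u1"):
                    rows = list(graph.query(sparql_previous_valid_query(user, probe)))
                    native = store.previous_valid_hlc(user, probe)
                    if native is None:
                        assert rows == []
                    else:
                        top = str(rows[0][0])
                        assert top.rsplit("#", 1)[1] == native.id

    def test_query_text_carries_both_validity_cases(self):
        text = sparql_previous_valid_query("9876", t("11:05:25"))
        assert 'FILTER ( ?starttime <= "2015-11-10T11:05:25"' in text
        assert "!BOUND(?endtime)" in text and "?endtime >" in text
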