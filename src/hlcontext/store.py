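"""In-memory indexed store of context records with temporal queries.

Records are indexed per user (and per category for low-level contexts) in
start-time order.  The store maintains two structural invariants the pipeline
relies on: per user and category, low-level intervals are pairwise disjoint;
and per user at most one high-level context is open-ended at a time.

Query semantics match the temporal patterns a SPARQL engine would evaluate
over the RDF export (see :func:`sparql_previous_valid_query`): a record is
"previous valid" at ``t`` iff it starts at or before ``t`` and either has no
end time or ends strictly after ``t``.
"""

from __future__ import annotations

import bisect
import json
import logging
from datetime import datetime
from typing import Iterator, Optional, Union

from .model import (
    Category,
    DuplicateIdentifierError,
    HighLevelContext,
    IdentifierMinter,
    LowLevelContext,
    format_timestamp,
    is_valid_at,
)

logger = logging.getLogger(__name__)

Record = Union[LowLevelContext, HighLevelContext]


class _OrderedIndex:
    """Records of one (user, kind) bucket kept sorted by (start, insertion)."""

    def __init__(self) -> None:
        self._keys: list[tuple[datetime, int]] = []
        self._records: list[Record] = []
        self._seq = 0

    def insert(self, record: Record) -> None:
        key = (record.start, self._seq)
        self._seq += 1
        pos = bisect.bisect_right(self._keys, key)
        self._keys.insert(pos, key)
        self._records.insert(pos, record)

    def remove(self, record: Record) -> None:
        idx = self._records.index(record)
        del self._records[idx]
        del self._keys[idx]

    def __iter__(self) -> Iterator[Record]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def reversed(self) -> Iterator[Record]:
        return reversed(self._records)

    def first_start_after(self, t: datetime) -> Optional[datetime]:
        pos = bisect.bisect_right(self._keys, (t, float("inf")))
        if pos < len(self._keys):
            return self._keys[pos][0]
        return None


class ContextStore:
    """Per-user, per-category indexed storage of context records."""

    def __init__(self) -> None:
        self._llc: dict[tuple[str, Category], _OrderedIndex] = {}
        self._hlc: dict[str, _OrderedIndex] = {}
        self._by_id: dict[str, Record] = {}
        self.minter = IdentifierMinter()

    # -- identifier minting -------------------------------------------------

    def next_llc_id(self, type_label: str) -> str:
        return self.minter.mint("llc", type_label)

    def next_hlc_id(self) -> str:
        return self.minter.mint("hlc")

    # -- storage ------------------------------------------------------------

    def put(self, record: Record) -> Record:
        """Store a record; duplicate identifiers are rejected."""
        if record.id in self._by_id:
            raise DuplicateIdentifierError(f"record id already stored: {record.id}")
        self._by_id[record.id] = record
        self._index_for(record).insert(record)
        return record

    def remove(self, record_id: str) -> Record:
        """Drop a record from the store (used when an equal-start record supersedes it)."""
        record = self._by_id.pop(record_id)
        self._index_for(record).remove(record)
        return record

    def _index_for(self, record: Record) -> _OrderedIndex:
        if isinstance(record, LowLevelContext):
            return self._llc.setdefault((record.user, record.category), _OrderedIndex())
        return self._hlc.setdefault(record.user, _OrderedIndex())

    def get(self, record_id: str) -> Record:
        return self._by_id[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def users(self) -> set[str]:
        return {u for u, _ in self._llc} | set(self._hlc)

    def llcs(self, user: Optional[str] = None, category: Optional[Category] = None) -> list[LowLevelContext]:
        out: list[LowLevelContext] = []
        for (u, cat), index in self._llc.items():
            if user is not None and u != user:
                continue
            if category is not None and cat != category:
                continue
            out.extend(index)  # type: ignore[arg-type]
        return out

    def hlcs(self, user: Optional[str] = None) -> list[HighLevelContext]:
        out: list[HighLevelContext] = []
        for u, index in self._hlc.items():
            if user is not None and u != user:
                continue
            out.extend(index)  # type: ignore[arg-type]
        return out

    # -- temporal queries ---------------------------------------------------

    def previous_valid_hlc(self, user: str, t: datetime) -> Optional[HighLevelContext]:
        """The user's high-level context valid at ``t``.

        Valid means ``start <= t`` and no end time yet, or an end time strictly
        after ``t``.  Ties on start are broken by latest start, then latest
        insertion.
        """
        index = self._hlc.get(user)
        if index is None:
            return None
        for record in index.reversed():
            if is_valid_at(record, t):
                return record  # type: ignore[return-value]
        return None

    def concurrent_llcs(self, user: str, t: datetime) -> dict[Category, LowLevelContext]:
        """The user's low-level context valid at ``t`` in each category.

        Disjointness makes the result unique per category; should the
        invariant ever be breached, the latest start wins and a warning is
        logged.
        """
        result: dict[Category, LowLevelContext] = {}
        for cat in Category:
            index = self._llc.get((user, cat))
            if index is None:
                continue
            valid = None
            n_valid = 0
            for record in index.reversed():
                if is_valid_at(record, t):
                    n_valid += 1
                    if valid is None:
                        valid = record
            if n_valid > 1:
                logger.warning(
                    "disjointness breach: %d %s contexts of user %s valid at %s; keeping latest start",
                    n_valid, cat.value, user, format_timestamp(t),
                )
            if valid is not None:
                result[cat] = valid  # type: ignore[assignment]
        return result

    def next_posterior_start(
        self, user: str, t: datetime, kind: Union[Category, str]
    ) -> Optional[datetime]:
        """Smallest start strictly after ``t`` among the user's records of a kind.

        ``kind`` is a low-level :class:`Category` or the string ``"hlc"``.
        """
        if kind == "hlc":
            index = self._hlc.get(user)
        else:
            index = self._llc.get((user, Category(kind)))
        if index is None:
            return None
        return index.first_start_after(t)

    # -- lifecycle ----------------------------------------------------------

    def finalize(self, record_id: str, end: datetime) -> Record:
        """Set the end time of a currently open-ended record."""
        record = self._by_id[record_id]
        if record.end is not None:
            raise ValueError(f"{record_id} is already finalized at {format_timestamp(record.end)}")
        if end <= record.start:
            raise ValueError(
                f"{record_id}: end {format_timestamp(end)} must be strictly after start "
                f"{format_timestamp(record.start)}"
            )
        record.end = end
        return record

    def truncate(self, record_id: str, end: datetime) -> Record:
        """Shorten a record so it ends at ``end`` (open or already closed).

        Used when a spliced-in earlier record forces an overlapping interval
        to give way; ``end`` must still lie strictly after the record's start.
        """
        record = self._by_id[record_id]
        if end <= record.start:
            raise ValueError(f"{record_id}: truncation point must be strictly after start")
        record.end = end
        return record

    # -- export -------------------------------------------------------------

    def snapshot(self) -> dict:
        """A JSON-serializable snapshot of every stored record."""

        def llc_obj(r: LowLevelContext) -> dict:
            return {
                "id": r.id,
                "user": r.user,
                "category": r.category.value,
                "type": r.type_label,
                "start": format_timestamp(r.start),
                "end": format_timestamp(r.end) if r.end else None,
            }

        def hlc_obj(r: HighLevelContext) -> dict:
            return {
                "id": r.id,
                "user": r.user,
                "components": [c.id for c in r.components],
                "start": format_timestamp(r.start),
                "end": format_timestamp(r.end) if r.end else None,
                "label": r.label,
                "match_set": sorted(r.match_set),
            }

        return {
            "llc": [llc_obj(r) for r in sorted(self.llcs(), key=lambda r: r.id)],
            "hlc": [hlc_obj(r) for r in sorted(self.hlcs(), key=lambda r: r.id)],
        }

    def save_snapshot(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.snapshot(), fh, indent=1)

    def to_graph(self):
        """Export every stored record to an RDF instance graph."""
        from .owl import export_instances

        return export_instances([*self.llcs(), *self.hlcs()])


def sparql_previous_valid_query(user: str, t: datetime) -> str:
    """SPARQL text for the previous-valid high-level-context lookup.

    Covers both validity cases: no end time yet, or an end time strictly after
    the probe instant.  Shaped after the query a triple-store-backed context
    manager would pose.
    """
    ts = format_timestamp(t)
    return f"""
PREFIX mmc: <http://hlcontext.example.org/context#>
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>
SELECT ?hlc ?starttime
WHERE {{
  ?hlc rdf:type mmc:HighLevelContext ;
       mmc:isContextOf mmc:user_{user} ;
       mmc:hasStartTime ?starttime .
  FILTER ( ?starttime <= "{ts}"^^xsd:dateTime )
  OPTIONAL {{ ?hlc mmc:hasEndTime ?endtime . }}
  FILTER ( !BOUND(?endtime) || ?endtime > "{ts}"^^xsd:dateTime )
}}
ORDER BY DESC(?starttime)
"""
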