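"""Lifetime-based storage of ontology version chains.

Every element, relationship and attribute value of a source is stored once,
together with the validity intervals ``[t_start, t_end)`` during which it was
part of a released version.  Any historical snapshot is reconstructed at query
time by selecting the payloads whose interval covers the requested date; this
avoids duplicating the unchanged bulk of an ontology across its (often many)
releases.  Version chains are linear: each version has at most one predecessor.

Basic diffs against the predecessor version are materialized at import time
(the common analysis access path), unless disabled for bulk loads.

Persistence is a single-file embedded SQLite database using a generic
attribute-value layout, plus a pure in-memory mode (the default).
"""

from __future__ import annotations

import datetime as _dt
import sqlite3
from dataclasses import dataclass, field
from typing import Hashable

from . import diff as _diff
from .model import Element, OntologySnapshot, Relationship, validate_snapshot

#: open-ended interval sentinel
UNBOUNDED = None

Interval = tuple[_dt.date, _dt.date | None]


@dataclass
class LifetimeRecord:
    """One payload plus the ordered, disjoint intervals during which it existed."""

    payload: Hashable
    intervals: list[Interval] = field(default_factory=list)

    def alive_at(self, t: _dt.date) -> bool:
        return any(s <= t and (e is None or t < e) for s, e in self.intervals)

    def open_interval(self) -> Interval | None:
        if self.intervals and self.intervals[-1][1] is None:
            return self.intervals[-1]
        return None

    def start(self, t: _dt.date) -> None:
        if self.open_interval() is not None:
            raise ValueError(f"payload {self.payload!r} already alive")
        self.intervals.append((t, None))

    def end(self, t: _dt.date) -> None:
        if self.open_interval() is None:
            raise ValueError(f"payload {self.payload!r} not alive")
        s, _ = self.intervals[-1]
        self.intervals[-1] = (s, t)


@dataclass
class ImportReport:
    """Outcome of one version import."""

    version_date: _dt.date
    started: int
    ended: int
    basic_diff: _diff.BasicDiff | None


class OutOfOrderError(ValueError):
    """Version dates must strictly increase along the chain."""


class VersionedSource:
    """All versions of one ontology source, stored once with lifetimes.

    Payload spaces: element identity (accession string), relationship triples,
    and ``(accession, attribute-name, value)`` triples.
    """

    def __init__(self, source_id: str):
        self.source_id = source_id
        self.version_dates: list[_dt.date] = []
        self.element_records: dict[str, LifetimeRecord] = {}
        self.relationship_records: dict[Relationship, LifetimeRecord] = {}
        self.attribute_records: dict[tuple[str, str, str], LifetimeRecord] = {}
        self.diffs: dict[_dt.date, _diff.BasicDiff] = {}  # keyed by new-version date

    # -- import ---------------------------------------------------------------

    def _live_payloads(self, records: dict) -> set:
        return {p for p, rec in records.items() if rec.open_interval() is not None}

    def import_version(self, snap: OntologySnapshot, materialize_diff: bool = True,
                       validate: bool = True) -> ImportReport:
        """Append *snap* to the version chain, opening/closing lifetimes.

        Payloads present in *snap* without an open interval get a new interval
        starting at the version date; open payloads absent from *snap* get
        their interval closed.  The basic diff against the predecessor is
        computed and stored unless *materialize_diff* is false.
        """
        t = snap.version_date
        if self.version_dates and t <= self.version_dates[-1]:
            raise OutOfOrderError(
                f"version date {t.isoformat()} not after latest {self.version_dates[-1].isoformat()}")
        if validate:
            violations = validate_snapshot(snap)
            if violations:
                raise ValueError(f"invalid snapshot at {t.isoformat()}: {violations}")

        predecessor = self.reconstruct(self.version_dates[-1]) if self.version_dates else None

        payload_sets: list[tuple[dict, set]] = [
            (self.element_records, set(snap.elements)),
            (self.relationship_records, set(snap.relationships)),
            (self.attribute_records,
             {(acc, name, v) for acc, el in snap.elements.items()
              for name, vals in el.attributes.items() for v in vals}),
        ]
        started = ended = 0
        for records, present in payload_sets:
            live = self._live_payloads(records)
            for p in present - live:
                records.setdefault(p, LifetimeRecord(p)).start(t)
                started += 1
            for p in live - present:
                records[p].end(t)
                ended += 1
        self.version_dates.append(t)

        d = None
        if predecessor is not None and materialize_diff:
            d = _diff.basic_diff(predecessor, snap)
            self.diffs[t] = d
        return ImportReport(t, started, ended, d)

    # -- reconstruction -------------------------------------------------------

    def version_at(self, t: _dt.date) -> _dt.date:
        """Latest version date ≤ *t*."""
        if not self.version_dates or t < self.version_dates[0]:
            earliest = self.version_dates[0].isoformat() if self.version_dates else "none"
            raise ValueError(f"date {t.isoformat()} precedes earliest version ({earliest})")
        return max(d for d in self.version_dates if d <= t)

    def reconstruct(self, t: _dt.date) -> OntologySnapshot:
        """Rebuild the snapshot valid at date *t* from lifetime records."""
        vdate = self.version_at(t)
        snap = OntologySnapshot(self.source_id, vdate)
        for acc, rec in self.element_records.items():
            if rec.alive_at(t):
                snap.elements[acc] = Element(acc)
        for (acc, name, value), rec in self.attribute_records.items():
            if rec.alive_at(t):
                snap.elements[acc].add_attribute(name, value)
        for rel, rec in self.relationship_records.items():
            if rec.alive_at(t):
                snap.relationships.add(rel)
        return snap

    def basic_diff_between(self, old_date: _dt.date, new_date: _dt.date) -> _diff.BasicDiff:
        """Materialized diff if available, else computed on demand."""
        if new_date in self.diffs and self.diffs[new_date].old_version[1] == old_date:
            return self.diffs[new_date]
        return _diff.basic_diff(self.reconstruct(old_date), self.reconstruct(new_date))

    # -- history --------------------------------------------------------------

    def element_history(self, accession: str) -> dict:
        """Per-attribute and relationship timelines for one concept.

        Returns ``{"accession", "lifetime", "attributes": {name: [(value,
        intervals)]}, "relationships": [(rel, intervals)]}`` ordered by first
        start date.
        """
        if accession not in self.element_records:
            raise KeyError(f"unknown accession {accession!r}")
        attrs: dict[str, list[tuple[str, list[Interval]]]] = {}
        for (acc, name, value), rec in self.attribute_records.items():
            if acc == accession:
                attrs.setdefault(name, []).append((value, list(rec.intervals)))
        for name in attrs:
            attrs[name].sort(key=lambda it: (it[1][0][0], it[0]))
        rels = sorted(
            ((rel, list(rec.intervals)) for rel, rec in self.relationship_records.items()
             if accession in (rel.source_acc, rel.target_acc)),
            key=lambda it: (it[1][0][0], it[0]))
        return {
            "accession": accession,
            "lifetime": list(self.element_records[accession].intervals),
            "attributes": attrs,
            "relationships": rels,
        }


# -- persistence ---------------------------------------------------------------

_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE versions (date TEXT PRIMARY KEY);
CREATE TABLE lifetimes (
    kind TEXT NOT NULL,            -- 'element' | 'relationship' | 'attribute'
    k1 TEXT NOT NULL,              -- accession | source acc | accession
    k2 TEXT NOT NULL DEFAULT '',   -- '' | target acc | attribute name
    k3 TEXT NOT NULL DEFAULT '',   -- '' | rel type | value
    t_start TEXT NOT NULL,
    t_end TEXT                     -- NULL = unbounded
);
CREATE INDEX idx_lifetimes ON lifetimes (kind, k1);
"""


def _iso(d: _dt.date | None) -> str | None:
    return d.isoformat() if d is not None else None


def _date(s: str | None) -> _dt.date | None:
    return _dt.date.fromisoformat(s) if s is not None else None


def save(store: VersionedSource, path: str) -> None:
    """Write *store* to a single-file SQLite database (overwrites)."""
    con = sqlite3.connect(path)
    try:
        con.executescript("DROP TABLE IF EXISTS meta; DROP TABLE IF EXISTS versions;"
                          "DROP TABLE IF EXISTS lifetimes;")
        con.executescript(_SCHEMA)
        con.execute("INSERT INTO meta VALUES ('source_id', ?)", (store.source_id,))
        con.executemany("INSERT INTO versions VALUES (?)",
                        [(d.isoformat(),) for d in store.version_dates])
        rows = []
        for acc, rec in store.element_records.items():
            rows += [("element", acc, "", "", _iso(s), _iso(e)) for s, e in rec.intervals]
        for rel, rec in store.relationship_records.items():
            rows += [("relationship", rel.source_acc, rel.target_acc, rel.rel_type,
                      _iso(s), _iso(e)) for s, e in rec.intervals]
        for (acc, name, value), rec in store.attribute_records.items():
            rows += [("attribute", acc, name, value, _iso(s), _iso(e))
                     for s, e in rec.intervals]
        con.executemany("INSERT INTO lifetimes VALUES (?,?,?,?,?,?)", rows)
        con.commit()
    finally:
        con.close()


def load(path: str) -> VersionedSource:
    """Read a store written by :func:`save`; materialized diffs are recomputed lazily."""
    con = sqlite3.connect(path)
    try:
        try:
            (source_id,) = con.execute("SELECT value FROM meta WHERE key='source_id'").fetchone()
            version_rows = con.execute("SELECT date FROM versions ORDER BY date").fetchall()
            lifetime_rows = con.execute(
                "SELECT kind,k1,k2,k3,t_start,t_end FROM lifetimes").fetchall()
        except (sqlite3.DatabaseError, TypeError) as exc:
            raise ValueError(f"corrupt store at {path}: {exc}") from exc
        store = VersionedSource(source_id)
        store.version_dates = [_dt.date.fromisoformat(d) for (d,) in version_rows]
        for kind, k1, k2, k3, ts, te in lifetime_rows:
            if kind == "element":
                payload, records = k1, store.element_records
            elif kind == "relationship":
                payload, records = Relationship(k1, k2, k3), store.relationship_records
            elif kind == "attribute":
                payload, records = (k1, k2, k3), store.attribute_records
            else:
                raise ValueError(f"corrupt store at {path}: unknown payload kind {kind!r}")
            records.setdefault(payload, LifetimeRecord(payload)).intervals.append(
                (_dt.date.fromisoformat(ts), _date(te)))
        for records in (store.element_records, store.relationship_records,
                        store.attribute_records):
            for rec in records.values():
                rec.intervals.sort(key=lambda it: it[0])
        # re-materialize diffs between adjacent versions
        for old_d, new_d in zip(store.version_dates, store.version_dates[1:]):
            store.diffs[new_d] = _diff.basic_diff(store.reconstruct(old_d),
                                                  store.reconstruct(new_d))
        return store
    finally:
        con.close()
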