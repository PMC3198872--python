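"""Generic graph-based model of ontologies and mappings.

An ontology snapshot is the state of one source at one release date: a set of
concepts (elements) identified by accession, a multi-map of attribute values
per concept, and typed directed relationships between concepts.  The model is
storage- and format-agnostic; parsing lives in :mod:`ontoevo.ontology_io` and
versioned persistence in :mod:`ontoevo.repository`.

Identity conventions
--------------------
* The accession string is the sole identity of a concept; names, definitions
  and synonyms are ordinary attributes.
* Attribute names are case-normalized (lowercase); values are kept verbatim.
  Multi-valued attributes are sets — value order never matters.
* Relationship types come from an open vocabulary normalized to lowercase
  hyphenated tokens, so OBO ``is_a`` and OWL ``subClassOf`` both become
  ``is-a``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import networkx as nx

IS_A = "is-a"

#: relationship-type spellings that normalize to ``is-a``
_ISA_ALIASES = {"is-a", "is_a", "isa", "subclassof", "subclass-of", "rdfs:subclassof"}


def normalize_rel_type(token: str) -> str:
    """Normalize a relationship-type token to the canonical vocabulary.

    Lowercases, maps underscores to hyphens, and folds the common subclass
    spellings (OBO ``is_a``, OWL ``subClassOf``) onto ``is-a``.
    """
    t = token.strip().lower().replace("_", "-")
    if t.replace("-", "") in {a.replace("-", "").replace("_", "") for a in _ISA_ALIASES}:
        return IS_A
    return t


class Relationship(NamedTuple):
    """A typed directed edge between two concepts of one snapshot."""

    source_acc: str
    target_acc: str
    rel_type: str


@dataclass
class Element:
    """A concept (or entity), identified by accession, with multi-valued attributes."""

    accession: str
    attributes: dict[str, set[str]] = field(default_factory=dict)

    def add_attribute(self, name: str, value: str) -> None:
        self.attributes.setdefault(name.strip().lower(), set()).add(value)

    def attribute(self, name: str) -> set[str]:
        """Value set for *name* (empty set if absent)."""
        return self.attributes.get(name.strip().lower(), set())

    def name(self) -> str | None:
        vals = self.attribute("name")
        return min(vals) if vals else None

    def copy(self) -> "Element":
        return Element(self.accession, {k: set(v) for k, v in self.attributes.items()})


@dataclass
class OntologySnapshot:
    """State of one ontology source at a single version date."""

    source_id: str
    version_date: _dt.date
    elements: dict[str, Element] = field(default_factory=dict)
    relationships: set[Relationship] = field(default_factory=set)

    # -- construction helpers -------------------------------------------------

    def add_element(self, accession: str, **attrs: Iterable[str] | str) -> Element:
        if accession in self.elements:
            raise ValueError(f"duplicate accession {accession!r}")
        el = Element(accession)
        for k, v in attrs.items():
            if isinstance(v, str):
                el.add_attribute(k, v)
            else:
                for item in v:
                    el.add_attribute(k, item)
        self.elements[accession] = el
        return el

    def add_relationship(self, source_acc: str, target_acc: str, rel_type: str = IS_A) -> None:
        self.relationships.add(Relationship(source_acc, target_acc, normalize_rel_type(rel_type)))

    def copy(self) -> "OntologySnapshot":
        return OntologySnapshot(
            self.source_id,
            self.version_date,
            {a: e.copy() for a, e in self.elements.items()},
            set(self.relationships),
        )

    # -- views ----------------------------------------------------------------

    def isa_graph(self) -> nx.DiGraph:
        """Directed graph of is-a edges, child → parent; includes every concept."""
        g = nx.DiGraph()
        g.add_nodes_from(self.elements)
        g.add_edges_from(
            (r.source_acc, r.target_acc) for r in self.relationships if r.rel_type == IS_A
        )
        return g

    def parents(self, accession: str) -> set[str]:
        return {
            r.target_acc
            for r in self.relationships
            if r.rel_type == IS_A and r.source_acc == accession
        }

    def children(self, accession: str) -> set[str]:
        return {
            r.source_acc
            for r in self.relationships
            if r.rel_type == IS_A and r.target_acc == accession
        }


def roots(snap: OntologySnapshot) -> set[str]:
    """Accessions with no outgoing is-a edge (top-level concepts)."""
    have_parent = {r.source_acc for r in snap.relationships if r.rel_type == IS_A}
    return set(snap.elements) - have_parent


@dataclass(frozen=True)
class Violation:
    """One broken snapshot invariant; violations are data, not exceptions."""

    rule: str
    subject: str
    detail: str = ""


def validate_snapshot(snap: OntologySnapshot) -> list[Violation]:
    """Check snapshot invariants; empty list means the snapshot is valid.

    Rules checked: non-empty accessions, relationship endpoints resolve to
    elements of the same snapshot, and the is-a subgraph is acyclic.
    """
    out: list[Violation] = []
    for acc in snap.elements:
        if not acc:
            out.append(Violation("empty-accession", acc))
    for r in snap.relationships:
        for end in (r.source_acc, r.target_acc):
            if end not in snap.elements:
                out.append(Violation("dangling-endpoint", end, f"{r.source_acc} -{r.rel_type}-> {r.target_acc}"))
    g = snap.isa_graph()
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        out.append(Violation("cycle", cyc[0][0], " -> ".join(a for a, _ in cyc)))
    return out


def snapshot_equal(a: OntologySnapshot, b: OntologySnapshot) -> bool:
    """Content equality: same elements (accession + attributes) and relationships.

    The version date and source id are metadata and are ignored, so a
    re-released identical ontology compares equal to its predecessor.
    """
    if set(a.elements) != set(b.elements):
        return False
    if a.relationships != b.relationships:
        return False
    for acc, el in a.elements.items():
        other = b.elements[acc]
        ka = {k: v for k, v in el.attributes.items() if v}
        kb = {k: v for k, v in other.attributes.items() if v}
        if ka != kb:
            return False
    return True


# -- mappings -----------------------------------------------------------------

MAPPING_TYPES = ("annotation", "ontology", "evolution")


class Correspondence(NamedTuple):
    """A typed link between one accession of each mapped source."""

    left_acc: str
    right_acc: str
    corr_type: str = "equivalence"
    confidence: float = 1.0


@dataclass
class Mapping:
    """A typed set of correspondences between two source versions.

    ``mapping_type`` is one of ``annotation`` (entity → concept links),
    ``ontology`` (concept ↔ concept alignments) or ``evolution`` (links
    between versions of one source).  ``properties`` carries provenance.
    """

    left_source: tuple[str, _dt.date | None]
    right_source: tuple[str, _dt.date | None]
    mapping_type: str
    correspondences: set[Correspondence] = field(default_factory=set)
    properties: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mapping_type not in MAPPING_TYPES:
            raise ValueError(f"mapping_type must be one of {MAPPING_TYPES}, got {self.mapping_type!r}")

    def add(self, left_acc: str, right_acc: str, corr_type: str = "equivalence",
            confidence: float = 1.0) -> None:
        if not 0.0 <= confidence <= 1.0:
            raise ValueError(f"confidence {confidence} outside [0, 1]")
        self.correspondences.add(Correspondence(left_acc, right_acc, corr_type, confidence))

    def pairs(self) -> set[tuple[str, str]]:
        return {(c.left_acc, c.right_acc) for c in self.correspondences}

    def by_left(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for c in self.correspondences:
            out.setdefault(c.left_acc, set()).add(c.right_acc)
        return out

    def by_right(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for c in self.correspondences:
            out.setdefault(c.right_acc, set()).add(c.left_acc)
        return out

    def __len__(self) -> int:
        return len(self.correspondences)
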