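"""Reading and writing ontology and mapping files.

OBO 1.2 flat files are read through :mod:`obonet` and converted to the
internal snapshot model; ``is_a`` lines and typed ``relationship:`` lines
become normalized relationships, every other term tag is absorbed as a
generic attribute (nothing is silently dropped — unmapped header tags are
counted in the parse report).  A deterministic OBO writer provides loss-free
round trips.  A minimal OWL reader extracts the named-class/subclass/label
skeleton from RDF/XML via :mod:`rdflib`.  Mappings travel as a 4-column TSV.
"""

from __future__ import annotations

import datetime as _dt
import io
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

import obonet
import rdflib
from rdflib.namespace import OWL, RDF, RDFS

from .model import IS_A, Mapping, OntologySnapshot, normalize_rel_type

#: OBO term tags that are inherently multi-valued
_MULTI_TAGS = {"synonym", "alt_id", "consider", "replaced_by", "xref", "subset",
               "is_a", "relationship", "intersection_of", "union_of", "disjoint_from"}


@dataclass
class ParseReport:
    """Bookkeeping from one parse: counts of terms, edges and skipped constructs."""

    n_terms: int = 0
    n_relationships: int = 0
    ignored_tags: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


class OboParseError(ValueError):
    pass


def _resolve_date(graph_meta: dict, override: _dt.date | None) -> _dt.date:
    if override is not None:
        return override
    for key in ("data-version", "date"):
        raw = graph_meta.get(key)
        if not raw:
            continue
        m = re.search(r"(\d{4})[-/:.](\d{2})[-/:.](\d{2})", str(raw))
        if m:
            return _dt.date(*map(int, m.groups()))
        m = re.search(r"(\d{2}):(\d{2}):(\d{4})", str(raw))  # OBO dd:mm:yyyy
        if m:
            dd, mm, yyyy = map(int, m.groups())
            return _dt.date(yyyy, mm, dd)
    raise OboParseError("no resolvable version date: pass version_date or set "
                        "data-version/date in the header")


def parse_obo(stream: IO[str] | str, version_date: _dt.date | None = None,
              source_id: str | None = None, namespace: str | None = None,
              report: ParseReport | None = None) -> OntologySnapshot:
    """Parse an OBO 1.2 document into a snapshot.

    Parameters
    ----------
    stream
        Text stream or path to an OBO file.
    version_date
        Overrides the header ``data-version``/``date``; required when the
        header carries neither.
    namespace
        If given, keep only terms whose ``namespace`` attribute equals it
        (used e.g. to isolate one sub-ontology of GO).
    report
        Optional :class:`ParseReport` filled with parse bookkeeping.
    """
    try:
        graph = obonet.read_obo(stream, ignore_obsolete=False)
    except KeyError as exc:
        raise OboParseError(f"term stanza missing required tag {exc}") from exc
    meta = graph.graph
    date = _resolve_date(meta, version_date)
    sid = source_id or str(meta.get("ontology", "ontology"))
    snap = OntologySnapshot(sid, date)
    rep = report if report is not None else ParseReport()

    kept: set[str] = set()
    for acc, data in graph.nodes(data=True):
        if namespace is not None and data.get("namespace") != namespace:
            continue
        el = snap.add_element(acc)
        kept.add(acc)
        for tag, value in data.items():
            if tag in ("is_a", "relationship"):
                continue  # edges handled below
            values = value if isinstance(value, list) else [value]
            for v in values:
                el.add_attribute(tag, str(v))
        rep.n_terms += 1
    # obonet edges run child -> parent with key = relationship type
    for child, parent, rel in graph.edges(keys=True):
        if child in kept and parent in kept:
            snap.add_relationship(child, parent, normalize_rel_type(rel))
            rep.n_relationships += 1
        elif namespace is not None:
            rep.warnings.append(f"edge {child} -{rel}-> {parent} crosses the "
                                f"namespace filter; dropped")
    for tag in meta:
        if tag not in ("ontology", "data-version", "date", "format-version"):
            rep.ignored_tags[tag] = rep.ignored_tags.get(tag, 0) + 1
    return snap


#: attributes written back as dedicated OBO tags (everything else is a
#: property_value-style generic tag, still round-trippable)
_KNOWN_TAGS = ("name", "namespace", "def", "comment", "subset", "synonym",
               "xref", "alt_id", "is_obsolete", "replaced_by", "consider",
               "created_by", "creation_date")


def write_obo(snap: OntologySnapshot, stream: IO[str]) -> None:
    """Serialize a snapshot as OBO 1.2, deterministically (stanzas and tags sorted)."""
    stream.write("format-version: 1.2\n")
    stream.write(f"data-version: {snap.version_date.isoformat()}\n")
    stream.write(f"ontology: {snap.source_id}\n")
    by_source: dict[str, list] = {}
    for rel in snap.relationships:
        by_source.setdefault(rel.source_acc, []).append(rel)
    for acc in sorted(snap.elements):
        el = snap.elements[acc]
        stream.write("\n[Term]\n")
        stream.write(f"id: {acc}\n")
        tags = sorted(el.attributes, key=lambda t: (_KNOWN_TAGS.index(t)
                      if t in _KNOWN_TAGS else len(_KNOWN_TAGS), t))
        for tag in tags:
            for value in sorted(el.attributes[tag]):
                if "\n" in value:
                    raise ValueError(f"newline in attribute value of {acc}/{tag}")
                stream.write(f"{tag}: {value}\n")
        for rel in sorted(by_source.get(acc, [])):
            if rel.rel_type == IS_A:
                stream.write(f"is_a: {rel.target_acc}\n")
            else:
                stream.write(f"relationship: {rel.rel_type.replace('-', '_')} {rel.target_acc}\n")


def dumps_obo(snap: OntologySnapshot) -> str:
    buf = io.StringIO()
    write_obo(snap, buf)
    return buf.getvalue()


# -- OWL subset ----------------------------------------------------------------

_OBO_IN_OWL_ID = rdflib.URIRef("http://www.geneontology.org/formats/oboInOwl#id")


def _iri_to_accession(iri: rdflib.URIRef) -> str:
    frag = str(iri).rsplit("#", 1)[-1].rsplit("/", 1)[-1]
    # OBO-style IRIs encode GO_0003700 for GO:0003700
    return re.sub(r"^([A-Za-z]+)_(\d+)$", r"\1:\2", frag)


def parse_owl_subset(stream: IO | str, version_date: _dt.date,
                     source_id: str = "owl-ontology",
                     report: ParseReport | None = None) -> OntologySnapshot:
    """Extract the named-class skeleton of an RDF/XML OWL document.

    Named classes become concepts (oboInOwl id if present, else the IRI
    fragment, as accession; ``rdfs:label`` as the name attribute; other
    literal annotation properties as generic attributes).  ``rdfs:subClassOf``
    between named classes becomes ``is-a``; anonymous/complex superclass
    expressions are skipped and counted in the report.
    """
    g = rdflib.Graph()
    g.parse(stream, format="xml")
    rep = report if report is not None else ParseReport()
    snap = OntologySnapshot(source_id, version_date)

    acc_of: dict[rdflib.URIRef, str] = {}
    for cls in sorted(set(g.subjects(RDF.type, OWL.Class))):
        if not isinstance(cls, rdflib.URIRef):
            continue  # anonymous class node
        obo_id = g.value(cls, _OBO_IN_OWL_ID)
        acc = str(obo_id) if obo_id is not None else _iri_to_accession(cls)
        acc_of[cls] = acc
        el = snap.add_element(acc)
        for _, pred, obj in g.triples((cls, None, None)):
            if pred in (RDF.type, RDFS.subClassOf):
                continue
            if isinstance(obj, rdflib.Literal):
                tag = "name" if pred == RDFS.label else _iri_to_accession(pred).lower()
                el.add_attribute(tag, str(obj))
        rep.n_terms += 1
    for cls, acc in acc_of.items():
        for sup in g.objects(cls, RDFS.subClassOf):
            if isinstance(sup, rdflib.URIRef) and sup in acc_of:
                snap.add_relationship(acc, acc_of[sup], IS_A)
                rep.n_relationships += 1
            else:
                rep.warnings.append(f"skipped complex superclass of {acc}")
    return snap


# -- mapping TSV ---------------------------------------------------------------

_MAPPING_HEADER = "left_acc\tright_acc\tcorr_type\tconfidence"


def read_mapping_tsv(stream: IO[str], mapping_type: str,
                     left_source: tuple[str, _dt.date | None] = ("left", None),
                     right_source: tuple[str, _dt.date | None] = ("right", None)) -> Mapping:
    """Read a 4-column mapping TSV (confidence optional, default 1.0).

    Duplicate (left, right, type) lines are deduplicated keeping the maximum
    confidence.
    """
    m = Mapping(left_source, right_source, mapping_type)
    best: dict[tuple[str, str, str], float] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if lineno == 1 and line.split("\t")[0] == "left_acc":
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected at least 2 tab-separated columns")
        left, right = parts[0], parts[1]
        corr_type = parts[2] if len(parts) > 2 and parts[2] else "equivalence"
        conf = float(parts[3]) if len(parts) > 3 and parts[3] else 1.0
        if not 0.0 <= conf <= 1.0:
            raise ValueError(f"line {lineno}: confidence {conf} outside [0, 1]")
        key = (left, right, corr_type)
        best[key] = max(best.get(key, 0.0), conf)
    for (left, right, corr_type), conf in best.items():
        m.add(left, right, corr_type, conf)
    return m


def write_mapping_tsv(m: Mapping, stream: IO[str]) -> None:
    """Write a mapping as sorted 4-column TSV (round-trip loss-free)."""
    stream.write(_MAPPING_HEADER + "\n")
    for c in sorted(m.correspondences):
        stream.write(f"{c.left_acc}\t{c.right_acc}\t{c.corr_type}\t{c.confidence:g}\n")
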