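"""Evolution mappings between ontology versions.

Two granularities of change are computed.  A *basic diff* is the set-level
comparison of two versions keyed on accession: added/deleted concepts,
added/deleted relationship triples, and attribute-value changes.  A *complex
diff* lifts the basic diff into semantically rich change operations — merge,
split, subgraph addition/deletion, leaf addition/deletion, concept moves and
obsoletions — by applying change-operation-generating rules in a fixed
priority order, each rule consuming the basic records it explains so that no
record is claimed twice.

Rule order (higher-level, metadata-evidenced operations first):

R1  toObsolete — the ``is_obsolete`` flag turns true.
R2  merge — ≥2 deleted concepts all absorbed by one surviving/added concept,
    evidenced by that concept's ``alt_id``/``replaced_by``/``consider``
    metadata (or an optional version match).
R3  split — one deleted concept replaced by ≥2 added concepts that name it in
    their ``replaced_by``/``consider`` metadata.
R4  addSubGraph / delSubGraph — a connected group of ≥2 added (deleted)
    concepts with a unique topmost member attaching to pre-existing parents.
R5  addLeaf / delLeaf — remaining single added/deleted leaves.
R6  move — a concept alive in both versions whose is-a parent set changed.
R7  chgAttValue — attribute value changes passed through from the basic diff.

Obsoletion is never counted as deletion: some ontologies only flag concepts
obsolete while others physically delete them, and the two must stay distinct.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import networkx as nx

from .model import IS_A, Element, Mapping, OntologySnapshot, Relationship

AttrRecord = tuple[str, str, str]           # (accession, attr name, value)
AttrChange = tuple[str, str, str, str]      # (accession, attr name, old, new)

#: metadata attributes that link a new concept to accessions it absorbed/replaced
MERGE_EVIDENCE_ATTRS = ("alt_id", "replaced_by", "consider")


@dataclass
class BasicDiff:
    """Low-level evolution mapping between two versions of one source."""

    old_version: tuple[str, _dt.date | None]
    new_version: tuple[str, _dt.date | None]
    addC: set[str] = field(default_factory=set)
    delC: set[str] = field(default_factory=set)
    addR: set[Relationship] = field(default_factory=set)
    delR: set[Relationship] = field(default_factory=set)
    addA: set[AttrRecord] = field(default_factory=set)
    delA: set[AttrRecord] = field(default_factory=set)
    chgAttValue: set[AttrChange] = field(default_factory=set)

    def is_empty(self) -> bool:
        return not (self.addC or self.delC or self.addR or self.delR
                    or self.addA or self.delA or self.chgAttValue)

    def counts(self) -> dict[str, int]:
        return {
            "addC": len(self.addC), "delC": len(self.delC),
            "addR": len(self.addR), "delR": len(self.delR),
            "addA": len(self.addA), "delA": len(self.delA),
            "chgAttValue": len(self.chgAttValue),
        }


def basic_diff(old: OntologySnapshot, new: OntologySnapshot) -> BasicDiff:
    """Accession-keyed set comparison of two versions.

    Attributes of concepts alive in both versions that are single-valued on
    both sides and differ become one ``chgAttValue`` record; all other
    attribute differences (including attributes of added/deleted concepts)
    become ``addA``/``delA`` records.
    """
    d = BasicDiff((old.source_id, old.version_date), (new.source_id, new.version_date))
    old_accs, new_accs = set(old.elements), set(new.elements)
    d.addC = new_accs - old_accs
    d.delC = old_accs - new_accs
    d.addR = new.relationships - old.relationships
    d.delR = old.relationships - new.relationships

    for acc in new_accs - old_accs:
        for name, vals in new.elements[acc].attributes.items():
            d.addA.update((acc, name, v) for v in vals)
    for acc in old_accs - new_accs:
        for name, vals in old.elements[acc].attributes.items():
            d.delA.update((acc, name, v) for v in vals)
    for acc in old_accs & new_accs:
        oe, ne = old.elements[acc], new.elements[acc]
        names = set(oe.attributes) | set(ne.attributes)
        for name in names:
            ov, nv = oe.attribute(name), ne.attribute(name)
            if ov == nv:
                continue
            if len(ov) == 1 and len(nv) == 1:
                d.chgAttValue.add((acc, name, next(iter(ov)), next(iter(nv))))
            else:
                d.addA.update((acc, name, v) for v in nv - ov)
                d.delA.update((acc, name, v) for v in ov - nv)
    return d


class PatchError(ValueError):
    """A basic-diff record cannot be applied to the given snapshot."""


def apply_basic_diff(old: OntologySnapshot, d: BasicDiff) -> OntologySnapshot:
    """Apply *d* as a patch; ``apply_basic_diff(old, basic_diff(old, new))`` equals *new*."""
    snap = old.copy()
    if d.new_version[1] is not None:
        snap.version_date = d.new_version[1]

    for rel in d.delR:
        if rel not in snap.relationships:
            raise PatchError(f"delR of absent relationship {rel}")
        snap.relationships.discard(rel)
    for acc, name, value in d.delA:
        el = snap.elements.get(acc)
        if el is None or value not in el.attribute(name):
            raise PatchError(f"delA of absent value ({acc}, {name}, {value})")
        el.attributes[name].discard(value)
        if not el.attributes[name]:
            del el.attributes[name]
    for acc, name, ov, nv in d.chgAttValue:
        el = snap.elements.get(acc)
        if el is None or el.attribute(name) != {ov}:
            raise PatchError(f"chgAttValue mismatch at ({acc}, {name}): expected {{{ov!r}}}")
        el.attributes[name] = {nv}
    for acc in d.delC:
        if acc not in snap.elements:
            raise PatchError(f"delC of absent concept {acc}")
        del snap.elements[acc]
    for acc in d.addC:
        if acc in snap.elements:
            raise PatchError(f"addC of already-present concept {acc}")
        snap.elements[acc] = Element(acc)
    for acc, name, value in d.addA:
        el = snap.elements.get(acc)
        if el is None:
            raise PatchError(f"addA to unknown concept {acc}")
        el.add_attribute(name, value)
    for rel in d.addR:
        if rel in snap.relationships:
            raise PatchError(f"addR of already-present relationship {rel}")
        snap.relationships.add(rel)
    return snap


# -- complex diff --------------------------------------------------------------

#: complex-operation kinds, in rule priority order
OP_KINDS = ("toObsolete", "merge", "split", "addSubGraph", "delSubGraph",
            "addLeaf", "delLeaf", "move", "chgAttValue")


@dataclass(frozen=True)
class ComplexOp:
    """One high-level change operation with kind-specific operands.

    ============  =========================================================
    kind          operands
    ============  =========================================================
    merge         sources (≥1 deleted accessions), target (surviving/added)
    split         source (deleted), targets (≥2 added accessions)
    addSubGraph   root + members (connected added concepts)
    delSubGraph   root + members (connected deleted concepts)
    addLeaf       concept
    delLeaf       concept
    move          concept, old_parents, new_parents
    toObsolete    concept
    chgAttValue   concept, attr, old, new
    ============  =========================================================
    """

    op_kind: str
    concept: str = ""
    sources: frozenset[str] = frozenset()
    targets: frozenset[str] = frozenset()
    members: frozenset[str] = frozenset()
    old_parents: frozenset[str] = frozenset()
    new_parents: frozenset[str] = frozenset()
    attr: str = ""
    old_value: str = ""
    new_value: str = ""

    def signature(self) -> tuple:
        """Canonical comparable form (kind + sorted operands)."""
        return (self.op_kind, self.concept, tuple(sorted(self.sources)),
                tuple(sorted(self.targets)), tuple(sorted(self.members)),
                tuple(sorted(self.old_parents)), tuple(sorted(self.new_parents)),
                self.attr, self.old_value, self.new_value)


@dataclass
class ComplexDiff:
    """High-level evolution mapping: ordered complex ops plus unexplained residue."""

    old_version: tuple[str, _dt.date | None]
    new_version: tuple[str, _dt.date | None]
    ops: list[ComplexOp] = field(default_factory=list)
    residual: BasicDiff = None  # type: ignore[assignment]

    def ops_of(self, kind: str) -> list[ComplexOp]:
        return [o for o in self.ops if o.op_kind == kind]

    def claimed_concepts(self) -> tuple[set[str], set[str]]:
        """(added accessions, deleted accessions) claimed by complex ops."""
        claimed_add: set[str] = set()
        claimed_del: set[str] = set()
        for op in self.ops:
            if op.op_kind == "merge":
                claimed_del |= op.sources
                claimed_add.add(op.concept)  # relevant only if the target is new
            elif op.op_kind == "split":
                claimed_del.add(op.concept)
                claimed_add |= op.targets
            elif op.op_kind == "addSubGraph":
                claimed_add |= op.members
            elif op.op_kind == "delSubGraph":
                claimed_del |= op.members
            elif op.op_kind == "addLeaf":
                claimed_add.add(op.concept)
            elif op.op_kind == "delLeaf":
                claimed_del.add(op.concept)
        return claimed_add, claimed_del


def _link_targets(acc: str, new: OntologySnapshot, attrs=MERGE_EVIDENCE_ATTRS) -> dict[str, set[str]]:
    """Map evidence-attr → set of new-version concepts listing *acc* there."""
    out: dict[str, set[str]] = {}
    for cand, el in new.elements.items():
        for name in attrs:
            if acc in el.attribute(name):
                out.setdefault(name, set()).add(cand)
    return out


def complex_diff(old: OntologySnapshot, new: OntologySnapshot,
                 version_match: Mapping | None = None,
                 match_threshold: float = 0.9) -> ComplexDiff:
    """Derive complex change operations between two versions.

    Merge/split evidence defaults to OBO-style metadata (``alt_id``,
    ``replaced_by``, ``consider``) in the new version; an optional
    *version_match* mapping (old → new accessions, e.g. from the matcher)
    supplies additional links at confidence ≥ *match_threshold*.
    """
    b = basic_diff(old, new)
    out = ComplexDiff(b.old_version, b.new_version)

    consumed_add: set[str] = set()
    consumed_del: set[str] = set()
    consumed_attr_chg: set[AttrChange] = set()
    consumed_attr_add: set[AttrRecord] = set()
    consumed_rel_add: set[Relationship] = set()
    consumed_rel_del: set[Relationship] = set()

    # R1 toObsolete: is_obsolete false/absent -> "true" on a surviving concept
    for rec in sorted(b.chgAttValue):
        acc, name, ov, nv = rec
        if name == "is_obsolete" and nv.lower() == "true" and ov.lower() != "true":
            out.ops.append(ComplexOp("toObsolete", concept=acc))
            consumed_attr_chg.add(rec)
    for rec in sorted(b.addA):
        acc, name, value = rec
        if name == "is_obsolete" and value.lower() == "true" and acc not in b.addC:
            out.ops.append(ComplexOp("toObsolete", concept=acc))
            consumed_attr_add.add(rec)

    # collect metadata/match links from each deleted concept to new concepts
    match_links: dict[str, set[str]] = {}
    if version_match is not None:
        for c in version_match.correspondences:
            if c.confidence >= match_threshold and c.left_acc in b.delC and c.right_acc in new.elements:
                match_links.setdefault(c.left_acc, set()).add(c.right_acc)

    links: dict[str, set[str]] = {}          # deleted acc -> new concepts linked to it
    alt_id_links: dict[str, set[str]] = {}   # subset with alt_id evidence (absorption)
    for acc in b.delC:
        by_attr = _link_targets(acc, new)
        tgts = set().union(*by_attr.values()) if by_attr else set()
        tgts |= match_links.get(acc, set())
        if tgts:
            links[acc] = tgts
        if by_attr.get("alt_id"):
            alt_id_links[acc] = by_attr["alt_id"]

    # R2 merge: deleted concepts with a single absorbing target, grouped by target
    merge_groups: dict[str, set[str]] = {}
    for acc, tgts in links.items():
        added_tgts = tgts & b.addC
        if len(tgts) == 1:
            merge_groups.setdefault(next(iter(tgts)), set()).add(acc)
        elif len(added_tgts) < 2:
            # multiple surviving targets: ambiguous, leave in residual
            pass
    for target in sorted(merge_groups):
        srcs = merge_groups[target] - consumed_del
        if not srcs:
            continue
        if len(srcs) >= 2 or all(target in alt_id_links.get(s, set()) for s in srcs):
            out.ops.append(ComplexOp("merge", concept=target, sources=frozenset(srcs)))
            consumed_del |= srcs
            if target in b.addC:
                consumed_add.add(target)

    # R3 split: one deleted concept linked to >=2 added concepts
    for acc in sorted(b.delC - consumed_del):
        added_tgts = links.get(acc, set()) & b.addC - consumed_add
        if len(added_tgts) >= 2:
            out.ops.append(ComplexOp("split", concept=acc, targets=frozenset(added_tgts)))
            consumed_del.add(acc)
            consumed_add |= added_tgts

    # R4 subgraphs: connected groups of >=2 unconsumed added (deleted) concepts
    for group, snap_of_group, consumed in (
        (b.addC - consumed_add, new, consumed_add),
        (b.delC - consumed_del, old, consumed_del),
    ):
        kind = "addSubGraph" if snap_of_group is new else "delSubGraph"
        sub = nx.Graph()
        sub.add_nodes_from(group)
        isa_edges = [(r.source_acc, r.target_acc)
                     for r in snap_of_group.relationships
                     if r.rel_type == IS_A and r.source_acc in group and r.target_acc in group]
        sub.add_edges_from(isa_edges)
        directed = nx.DiGraph(isa_edges)
        for comp in nx.connected_components(sub):
            if len(comp) < 2:
                continue
            topmost = sorted(c for c in comp
                             if c not in directed or not (set(directed.successors(c)) & comp))
            if len(topmost) == 1:
                root = topmost[0]
                out.ops.append(ComplexOp(kind, concept=root, members=frozenset(comp)))
                consumed |= comp
            else:
                # added/deleted forest: one subgraph per topmost node
                taken: set[str] = set()
                for root in topmost:
                    if root not in directed:
                        members = {root}
                    else:
                        members = ({root} | nx.ancestors(directed, root)) & comp
                    members -= taken
                    if len(members) >= 2:
                        out.ops.append(ComplexOp(kind, concept=root, members=frozenset(members)))
                        consumed |= members
                        taken |= members

    # R5 leaves: remaining single added/deleted concepts with no added/deleted children
    for acc in sorted(b.addC - consumed_add):
        added_children = {r.source_acc for r in new.relationships
                          if r.rel_type == IS_A and r.target_acc == acc} & b.addC
        if not added_children:
            out.ops.append(ComplexOp("addLeaf", concept=acc))
            consumed_add.add(acc)
    for acc in sorted(b.delC - consumed_del):
        deleted_children = {r.source_acc for r in old.relationships
                            if r.rel_type == IS_A and r.target_acc == acc} & b.delC
        if not deleted_children:
            out.ops.append(ComplexOp("delLeaf", concept=acc))
            consumed_del.add(acc)

    # R6 move: surviving concept whose is-a parent set changed on both sides
    alive = set(old.elements) & set(new.elements)
    for acc in sorted(alive):
        lost = {r for r in b.delR if r.rel_type == IS_A and r.source_acc == acc}
        gained = {r for r in b.addR if r.rel_type == IS_A and r.source_acc == acc}
        if lost and gained:
            out.ops.append(ComplexOp(
                "move", concept=acc,
                old_parents=frozenset(r.target_acc for r in lost),
                new_parents=frozenset(r.target_acc for r in gained)))
            consumed_rel_del |= lost
            consumed_rel_add |= gained

    # R7 chgAttValue passthrough
    for rec in sorted(b.chgAttValue - consumed_attr_chg):
        acc, name, ov, nv = rec
        out.ops.append(ComplexOp("chgAttValue", concept=acc, attr=name,
                                 old_value=ov, new_value=nv))
        consumed_attr_chg.add(rec)

    out.residual = BasicDiff(
        b.old_version, b.new_version,
        addC=b.addC - consumed_add, delC=b.delC - consumed_del,
        addR=b.addR - consumed_rel_add, delR=b.delR - consumed_rel_del,
        addA=b.addA - consumed_attr_add, delA=set(b.delA),
        chgAttValue=b.chgAttValue - consumed_attr_chg)
    return out


def diff_summary(d: BasicDiff | ComplexDiff) -> dict[str, int]:
    """Counts per change kind; subgraph kinds also report total member counts."""
    if isinstance(d, BasicDiff):
        return d.counts()
    out = {k: 0 for k in OP_KINDS}
    out["addSubGraph_members"] = 0
    out["delSubGraph_members"] = 0
    for op in d.ops:
        out[op.op_kind] += 1
        if op.op_kind in ("addSubGraph", "delSubGraph"):
            out[op.op_kind + "_members"] += len(op.members)
    return out
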