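"""Synthetic versioned ontologies with scripted, known-ground-truth changes.

The generator produces acyclic is-a DAGs with unique accessions
(``SYN:0000001``, ...) and unique pronounceable names, then evolves them by
*change scripts*: ordered lists of scripted operations (leaf/subgraph
additions and deletions, merges, splits, moves, renames, obsoletions) whose
operands — including the accessions of concepts the script will create — are
fixed at sampling time.  A script therefore doubles as the exact expected
answer for change detection: :meth:`ScriptOp.expected_complex_op` yields the
complex operation the diff of the two versions must recover.

Scripts can be sampled *non-interacting*: no two operations share an operand
concept or an affected parent, so each scripted operation maps one-to-one to
a recovered complex change.  Merge/split evidence is written into OBO-style
metadata (``alt_id`` on merge targets, ``replaced_by`` on split targets) so
the default, matcher-free change detection is exercised; pass
``metadata_evidence=False`` to omit it and exercise matcher-based evidence.

All randomness flows from an explicit per-call seed; there is no global
random state.
"""

from __future__ import annotations

import datetime as _dt
import random
from dataclasses import dataclass, field

import networkx as nx

from .diff import ComplexOp
from .model import IS_A, Mapping, OntologySnapshot, Relationship

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"

SCRIPT_OP_KINDS = ("addLeaf", "addSubGraph", "delLeaf", "delSubGraph",
                   "merge", "split", "move", "rename", "toObsolete")

#: a balanced default operation mix
DEFAULT_OP_MIX = {"addLeaf": 0.25, "addSubGraph": 0.1, "delLeaf": 0.1,
                  "delSubGraph": 0.05, "merge": 0.1, "split": 0.1,
                  "move": 0.1, "rename": 0.15, "toObsolete": 0.05}


def _accession(i: int) -> str:
    return f"SYN:{i:07d}"


def _pronounceable(rng: random.Random, n_syllables: int = 3) -> str:
    return "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
                   for _ in range(n_syllables))


class _NameFactory:
    def __init__(self, rng: random.Random, taken: set[str]):
        self.rng = rng
        self.taken = set(taken)

    def fresh(self) -> str:
        while True:
            name = " ".join(_pronounceable(self.rng) for _ in range(self.rng.randint(1, 3)))
            if name not in self.taken:
                self.taken.add(name)
                return name


def generate_base(n_concepts: int, max_parents: int = 2, seed: int = 0,
                  source_id: str = "SYN",
                  version_date: _dt.date = _dt.date(2000, 1, 1)) -> OntologySnapshot:
    """Random acyclic is-a DAG with one root, deterministic for a fixed seed."""
    if n_concepts < 1 or max_parents < 1:
        raise ValueError("n_concepts and max_parents must be >= 1")
    rng = random.Random(seed)
    names = _NameFactory(rng, set())
    snap = OntologySnapshot(source_id, version_date)
    accs = [_accession(i + 1) for i in range(n_concepts)]
    for i, acc in enumerate(accs):
        snap.add_element(acc, name=names.fresh())
        if i > 0:
            n_par = rng.randint(1, min(max_parents, i))
            for parent in rng.sample(accs[:i], n_par):
                snap.add_relationship(acc, parent, IS_A)
    return snap


@dataclass
class ScriptOp:
    """One scripted change with concrete operands (new accessions pre-allocated)."""

    kind: str
    concept: str = ""                    # primary operand (delLeaf/move/rename/... )
    parent: str = ""                     # attachment parent for additions
    members: tuple[str, ...] = ()        # subgraph members (first = root)
    member_parents: dict[str, str] = field(default_factory=dict)  # internal tree edges
    sources: tuple[str, ...] = ()        # merge sources
    targets: tuple[str, ...] = ()        # split targets / merge target (length 1)
    old_parents: tuple[str, ...] = ()    # move
    new_parents: tuple[str, ...] = ()    # move
    names: dict[str, str] = field(default_factory=dict)  # new/changed names
    old_name: str = ""

    def touched(self) -> set[str]:
        """All concepts this op reads or writes (for non-interaction checks)."""
        out = {self.concept, self.parent, *self.members, *self.sources,
               *self.targets, *self.old_parents, *self.new_parents,
               *self.member_parents.values()}
        out.discard("")
        return out

    def expected_complex_op(self) -> ComplexOp:
        """The complex change a correct diff must report for this scripted op."""
        if self.kind == "addLeaf":
            return ComplexOp("addLeaf", concept=self.concept)
        if self.kind == "delLeaf":
            return ComplexOp("delLeaf", concept=self.concept)
        if self.kind == "addSubGraph":
            return ComplexOp("addSubGraph", concept=self.members[0],
                             members=frozenset(self.members))
        if self.kind == "delSubGraph":
            return ComplexOp("delSubGraph", concept=self.members[0],
                             members=frozenset(self.members))
        if self.kind == "merge":
            return ComplexOp("merge", concept=self.targets[0],
                             sources=frozenset(self.sources))
        if self.kind == "split":
            return ComplexOp("split", concept=self.concept,
                             targets=frozenset(self.targets))
        if self.kind == "move":
            return ComplexOp("move", concept=self.concept,
                             old_parents=frozenset(self.old_parents),
                             new_parents=frozenset(self.new_parents))
        if self.kind == "rename":
            return ComplexOp("chgAttValue", concept=self.concept, attr="name",
                             old_value=self.old_name,
                             new_value=self.names[self.concept])
        if self.kind == "toObsolete":
            return ComplexOp("toObsolete", concept=self.concept)
        raise ValueError(f"unknown script op kind {self.kind!r}")


@dataclass
class ChangeScript:
    """Ordered scripted operations plus sampling provenance."""

    ops: list[ScriptOp]
    seed: int
    non_interacting: bool
    warnings: list[str] = field(default_factory=list)

    def expected_ops(self) -> list[ComplexOp]:
        return [op.expected_complex_op() for op in self.ops]

    def validate_non_interaction(self) -> list[str]:
        """Pairwise operand-set intersections; empty list iff non-interacting."""
        problems = []
        for i in range(len(self.ops)):
            for j in range(i + 1, len(self.ops)):
                shared = self.ops[i].touched() & self.ops[j].touched()
                if shared:
                    problems.append(f"ops {i} and {j} share {sorted(shared)}")
        return problems


def _next_accession_number(snap: OntologySnapshot) -> int:
    nums = [int(acc.split(":")[1]) for acc in snap.elements if acc.startswith("SYN:")]
    return (max(nums) + 1) if nums else 1


def sample_script(snap: OntologySnapshot, op_mix: dict[str, float] | None = None,
                  n_ops: int = 10, seed: int = 0,
                  non_interacting: bool = True) -> ChangeScript:
    """Sample a change script valid against *snap*, deterministic per seed.

    Operations that cannot be placed (operand pool exhausted, or an op kind
    impossible on the given snapshot) are skipped with a warning, so the
    script may be shorter than *n_ops*.
    """
    mix = dict(op_mix or DEFAULT_OP_MIX)
    total = sum(mix.values())
    if total <= 0:
        raise ValueError("op mix probabilities must sum to a positive value")
    kinds = sorted(mix)
    weights = [mix[k] / total for k in kinds]

    rng = random.Random(seed)
    names = _NameFactory(rng, {v for el in snap.elements.values()
                               for v in el.attribute("name")})
    g = snap.isa_graph()
    children = {acc: set(g.predecessors(acc)) for acc in snap.elements}
    parents = {acc: set(g.successors(acc)) for acc in snap.elements}
    root_accs = {acc for acc in snap.elements if not parents[acc]}
    next_num = _next_accession_number(snap)
    used: set[str] = set()
    dead: set[str] = set()  # deleted by an earlier op; never a valid operand
    ops: list[ScriptOp] = []
    warnings: list[str] = []

    def fresh_acc() -> str:
        nonlocal next_num
        acc = _accession(next_num)
        next_num += 1
        return acc

    def free(cands) -> list[str]:
        blocked = (used | dead) if non_interacting else dead
        return [c for c in sorted(cands) if c not in blocked]

    def pick(cands) -> str | None:
        pool = free(cands)
        return rng.choice(pool) if pool else None

    leaves = {acc for acc in snap.elements if not children[acc]} - root_accs

    def build(kind: str) -> ScriptOp | None:
        if kind == "addLeaf":
            p = pick(snap.elements)
            if p is None:
                return None
            acc = fresh_acc()
            return ScriptOp("addLeaf", concept=acc, parent=p, names={acc: names.fresh()})
        if kind == "addSubGraph":
            p = pick(snap.elements)
            if p is None:
                return None
            size = rng.randint(2, 5)
            members = tuple(fresh_acc() for _ in range(size))
            mp = {members[i]: members[rng.randrange(i)] for i in range(1, size)}
            return ScriptOp("addSubGraph", parent=p, members=members, member_parents=mp,
                            names={m: names.fresh() for m in members})
        if kind == "delLeaf":
            pool = [c for c in free(leaves) if not (parents[c] & used)] if non_interacting \
                else free(leaves)
            if not pool:
                return None
            c = rng.choice(pool)
            return ScriptOp("delLeaf", concept=c, old_parents=tuple(sorted(parents[c])))
        if kind == "delSubGraph":
            cands = []
            for r in free(set(snap.elements) - root_accs):
                desc = nx.ancestors(g, r)  # is-a descendants (edges child -> parent)
                if 1 <= len(desc) <= 4:
                    members = {r} | desc
                    if members & dead:
                        continue
                    outside = set().union(*(parents[m] for m in members)) - members
                    if non_interacting and (members | outside) & used:
                        continue
                    cands.append((r, tuple(sorted(members - {r})), tuple(sorted(outside))))
            if not cands:
                return None
            r, rest, outside = rng.choice(sorted(cands))
            return ScriptOp("delSubGraph", members=(r, *rest), old_parents=outside)
        if kind == "merge":
            k = rng.randint(2, 3)
            pool = [c for c in free(leaves) if not (parents[c] & used)] if non_interacting \
                else free(leaves)
            if len(pool) < k:
                return None
            srcs = tuple(sorted(rng.sample(pool, k)))
            target = fresh_acc()
            tgt_parents = tuple(sorted(set().union(*(parents[s] for s in srcs))))
            return ScriptOp("merge", sources=srcs, targets=(target,),
                            new_parents=tgt_parents, names={target: names.fresh()})
        if kind == "split":
            pool = [c for c in free(leaves) if not (parents[c] & used)] if non_interacting \
                else free(leaves)
            if not pool:
                return None
            s = rng.choice(pool)
            k = rng.randint(2, 3)
            tgts = tuple(fresh_acc() for _ in range(k))
            return ScriptOp("split", concept=s, targets=tgts,
                            new_parents=tuple(sorted(parents[s])),
                            names={t: names.fresh() for t in tgts})
        if kind == "move":
            pool = [c for c in free(leaves) if not (parents[c] & used)] if non_interacting \
                else free(leaves)
            if not pool:
                return None
            c = rng.choice(pool)
            q_pool = [q for q in free(set(snap.elements) - parents[c] - {c})]
            if not q_pool:
                return None
            q = rng.choice(q_pool)
            return ScriptOp("move", concept=c, old_parents=tuple(sorted(parents[c])),
                            new_parents=(q,))
        if kind == "rename":
            c = pick(snap.elements)
            if c is None:
                return None
            old = snap.elements[c].name() or ""
            return ScriptOp("rename", concept=c, old_name=old, names={c: names.fresh()})
        if kind == "toObsolete":
            c = pick(set(snap.elements) - root_accs)
            if c is None:
                return None
            return ScriptOp("toObsolete", concept=c)
        raise ValueError(f"unknown op kind {kind!r}")

    for i in range(n_ops):
        kind = rng.choices(kinds, weights)[0]
        op = build(kind)
        if op is None:
            warnings.append(f"op {i} ({kind}): no admissible operands, skipped")
            continue
        ops.append(op)
        used |= op.touched()
        if op.kind in ("delLeaf",):
            dead.add(op.concept)
        elif op.kind == "delSubGraph":
            dead.update(op.members)
        elif op.kind == "merge":
            dead.update(op.sources)
        elif op.kind == "split":
            dead.add(op.concept)
    return ChangeScript(ops, seed, non_interacting, warnings)


def apply_script(snap: OntologySnapshot, script: ChangeScript,
                 new_date: _dt.date, metadata_evidence: bool = True) -> OntologySnapshot:
    """Execute *script* on a copy of *snap*, producing the successor version.

    Merge targets list their sources as ``alt_id`` and split targets their
    source as ``replaced_by`` unless *metadata_evidence* is disabled.
    """
    out = snap.copy()
    out.version_date = new_date

    def delete_concept(acc: str) -> None:
        del out.elements[acc]
        out.relationships = {r for r in out.relationships
                             if acc not in (r.source_acc, r.target_acc)}

    for idx, op in enumerate(script.ops):
        try:
            if op.kind == "addLeaf":
                out.add_element(op.concept, name=op.names[op.concept])
                out.add_relationship(op.concept, op.parent, IS_A)
            elif op.kind == "addSubGraph":
                for m in op.members:
                    out.add_element(m, name=op.names[m])
                out.add_relationship(op.members[0], op.parent, IS_A)
                for child, parent in op.member_parents.items():
                    out.add_relationship(child, parent, IS_A)
            elif op.kind == "delLeaf":
                delete_concept(op.concept)
            elif op.kind == "delSubGraph":
                for m in op.members:
                    delete_concept(m)
            elif op.kind == "merge":
                target = op.targets[0]
                attrs: dict = {"name": op.names[target]}
                if metadata_evidence:
                    attrs["alt_id"] = list(op.sources)
                for s in op.sources:
                    delete_concept(s)
                out.add_element(target, **attrs)
                for p in op.new_parents:
                    out.add_relationship(target, p, IS_A)
            elif op.kind == "split":
                delete_concept(op.concept)
                for t in op.targets:
                    attrs = {"name": op.names[t]}
                    if metadata_evidence:
                        attrs["replaced_by"] = op.concept
                    out.add_element(t, **attrs)
                    for p in op.new_parents:
                        out.add_relationship(t, p, IS_A)
            elif op.kind == "move":
                out.relationships = {
                    r for r in out.relationships
                    if not (r.rel_type == IS_A and r.source_acc == op.concept)}
                for p in op.new_parents:
                    out.add_relationship(op.concept, p, IS_A)
            elif op.kind == "rename":
                out.elements[op.concept].attributes["name"] = {op.names[op.concept]}
            elif op.kind == "toObsolete":
                out.elements[op.concept].attributes["is_obsolete"] = {"true"}
            else:
                raise ValueError(f"unknown op kind {op.kind!r}")
        except KeyError as exc:
            raise ValueError(f"op {idx} ({op.kind}) not applicable: {exc}") from exc
    return out


def generate_annotations(snap: OntologySnapshot, n_entities: int = 50,
                         density: float = 0.1, seed: int = 0) -> Mapping:
    """Random annotation mapping: each (entity, concept) pair links with prob. *density*.

    Entities get accessions ``ENT:000001``, ...; density 1.0 links every
    entity to every concept (so every concept is annotated).  Expected link
    count is ``n_entities * density * |C|``.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    rng = random.Random(seed)
    m = Mapping(("entities", None), (snap.source_id, snap.version_date), "annotation")
    concepts = sorted(snap.elements)
    for i in range(1, n_entities + 1):
        ent = f"ENT:{i:06d}"
        for c in concepts:
            if rng.random() < density:
                m.add(ent, c, "annotates", 1.0)
    return m
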