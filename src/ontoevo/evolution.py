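"""Evolution analytics over ontology version histories.

Four families of analysis are provided on top of the version repository and
the diff component:

* **Growth statistics** — ratios of concept/relationship counts between the
  first and last version of a source (``growth_C``, ``growth_R``,
  ``growth_CR``) and per-version-pair change frequencies, absolute or
  normalized by the old version's totals.
* **Region stability** — change costs (a configurable weight per change
  kind) aggregated over *regions* (a root concept plus all its is-a
  descendants), normalized by region size, classified stable / intermediate
  / unstable, and tracked over sliding time windows.
* **Annotation propagation** — rolling entity annotations up the is-a
  hierarchy (the true-path rule), plus a demonstration-scale hypergeometric
  term-enrichment test on the propagated counts.
* **Annotation impact** — flagging annotations invalidated by complex
  changes and suggesting migrations (re-target on merge, enumerate targets
  on split, flag for removal on delete/obsolete, keep-with-notice on move).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .diff import BasicDiff, ComplexDiff, ComplexOp, complex_diff
from .model import IS_A, Mapping, OntologySnapshot
from .repository import VersionedSource


def _round2(x: float) -> float:
    """Round half-up to 2 decimals (presentation convention for growth tables)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class GrowthStats:
    """First-vs-last version growth factors of one source."""

    source_id: str
    first_date: _dt.date
    last_date: _dt.date
    c0: int
    cn: int
    r0: int
    rn: int

    @property
    def growth_C(self) -> float | None:
        return self.cn / self.c0 if self.c0 else None

    @property
    def growth_R(self) -> float | None:
        return self.rn / self.r0 if self.r0 else None

    @property
    def growth_CR(self) -> float | None:
        return (self.cn + self.rn) / (self.c0 + self.r0) if self.c0 + self.r0 else None

    def rounded(self) -> dict[str, float | None]:
        """Ratios rounded to 2 decimals for reporting (full precision kept in properties)."""
        return {k: (None if v is None else _round2(v))
                for k, v in (("growth_C", self.growth_C), ("growth_R", self.growth_R),
                             ("growth_CR", self.growth_CR))}


def growth_stats(first: OntologySnapshot, last: OntologySnapshot) -> GrowthStats:
    """Growth factors between the first and last snapshot of a source."""
    return GrowthStats(first.source_id, first.version_date, last.version_date,
                       len(first.elements), len(last.elements),
                       len(first.relationships), len(last.relationships))


def add_delete_ratio(d: BasicDiff) -> float | None:
    """|added concepts| / |deleted concepts|; None for 0/0, inf when nothing was deleted."""
    if not d.delC:
        return math.inf if d.addC else None
    return len(d.addC) / len(d.delC)


def change_frequencies(store: VersionedSource, normalize: bool = False) -> pd.DataFrame:
    """Per-adjacent-version-pair change counts from the materialized basic diffs.

    Columns: addC, delC, addR, delR, chgA (attribute adds + deletes + value
    changes).  With ``normalize``, concept and attribute columns are divided
    by the old version's concept count and relationship columns by its
    relationship count (NaN when the old count is zero).
    """
    if len(store.version_dates) < 2:
        raise ValueError("change frequencies need at least 2 versions")
    rows = []
    for old_d, new_d in zip(store.version_dates, store.version_dates[1:]):
        d = store.basic_diff_between(old_d, new_d)
        row = {"old_date": old_d, "new_date": new_d,
               "addC": len(d.addC), "delC": len(d.delC),
               "addR": len(d.addR), "delR": len(d.delR),
               "chgA": len(d.addA) + len(d.delA) + len(d.chgAttValue)}
        if normalize:
            old = store.reconstruct(old_d)
            nc, nr = len(old.elements), len(old.relationships)
            for col in ("addC", "delC", "chgA"):
                row[col] = row[col] / nc if nc else math.nan
            for col in ("addR", "delR"):
                row[col] = row[col] / nr if nr else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


# -- region stability ----------------------------------------------------------

#: default change-cost weights: information-reducing operations cost more
DEFAULT_COSTS = {
    "addC": 1.0, "addLeaf": 1.0, "addSubGraph": 1.0,   # per added concept/member
    "delC": 2.0, "delLeaf": 2.0, "delSubGraph": 2.0,   # per deleted concept/member
    "merge": 2.0, "split": 2.0, "toObsolete": 1.5,
    "move": 1.5, "chgAttValue": 0.5,
    "addR": 0.5, "delR": 0.5, "addA": 0.5, "delA": 0.5,
}


@dataclass
class CostModel:
    """Non-negative weight per change kind; unlisted kinds default to 0."""

    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COSTS))

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.weights.items() if v < 0}
        if bad:
            raise ValueError(f"negative cost weights: {bad}")

    def weight(self, kind: str) -> float:
        return self.weights.get(kind, 0.0)


@dataclass
class RegionRecord:
    root: str
    size: int
    aggregate_cost: float
    normalized_cost: float
    stability: str  # stable | intermediate | unstable


@dataclass
class RegionReport:
    window: tuple[_dt.date, _dt.date]
    regions: list[RegionRecord]

    def by_root(self) -> dict[str, RegionRecord]:
        return {r.root: r for r in self.regions}


def _op_cost_touches(op: ComplexOp, cm: CostModel) -> list[tuple[str, float]]:
    """(concept, cost) incidences of one complex op: each operand accrues the op weight."""
    w = cm.weight(op.op_kind)
    if op.op_kind in ("addSubGraph", "delSubGraph"):
        return [(m, w) for m in op.members]
    if op.op_kind == "merge":
        return [(s, w) for s in op.sources] + [(op.concept, w)]
    if op.op_kind == "split":
        return [(op.concept, w)] + [(t, w) for t in op.targets]
    # move / rename / obsoletion / leaf ops name a single concept
    return [(op.concept, w)]


def local_change_costs(d: ComplexDiff, cm: CostModel) -> dict[str, float]:
    """Weighted change cost accrued per concept by one version-pair diff.

    Complex operations charge each operand; residual relationship changes
    charge the child endpoint, residual attribute and concept changes the
    concept itself.
    """
    costs: dict[str, float] = {}

    def charge(acc: str, w: float) -> None:
        if w:
            costs[acc] = costs.get(acc, 0.0) + w

    for op in d.ops:
        for acc, w in _op_cost_touches(op, cm):
            charge(acc, w)
    r = d.residual
    for acc in r.addC:
        charge(acc, cm.weight("addC"))
    for acc in r.delC:
        charge(acc, cm.weight("delC"))
    for rel in r.addR:
        charge(rel.source_acc, cm.weight("addR"))
    for rel in r.delR:
        charge(rel.source_acc, cm.weight("delR"))
    for acc, _, _ in r.addA:
        charge(acc, cm.weight("addA"))
    for acc, _, _ in r.delA:
        charge(acc, cm.weight("delA"))
    for acc, _, _, _ in r.chgAttValue:
        charge(acc, cm.weight("chgAttValue"))
    return costs


def _classify(normalized: float, unstable_threshold: float) -> str:
    if normalized == 0.0:
        return "stable"
    if normalized >= unstable_threshold:
        return "unstable"
    return "intermediate"


def region_costs(store: VersionedSource, window: tuple[_dt.date, _dt.date],
                 cost_model: CostModel | None = None,
                 region_roots: set[str] | None = None,
                 unstable_threshold: float = 0.5) -> RegionReport:
    """Aggregate and size-normalize change costs per region over a time window.

    A region is a root concept plus all of its is-a descendants in the
    *union* of the snapshots covered by the window, so concepts deleted
    mid-window still carry their deletion cost.  Zero normalized cost means
    the region was completely stable in the window; costs at or above
    ``unstable_threshold`` per concept classify it unstable.  Region roots
    default to the children of each ontology root (the top-level categories).
    """
    cm = cost_model or CostModel()
    t_from, t_to = window
    dates = [d for d in store.version_dates if t_from <= d <= t_to]
    if len(dates) < 2:
        raise ValueError(f"window [{t_from}, {t_to}] covers {len(dates)} version(s); need >= 2")

    snaps = {d: store.reconstruct(d) for d in dates}
    union = nx.DiGraph()
    for snap in snaps.values():
        union.add_nodes_from(snap.elements)
        union.add_edges_from((r.source_acc, r.target_acc)
                             for r in snap.relationships if r.rel_type == IS_A)

    if region_roots is None:
        top = {n for n in union if union.out_degree(n) == 0}
        region_roots = {c for r in top for c in union.predecessors(r)} or top

    totals: dict[str, float] = {}
    for old_d, new_d in zip(dates, dates[1:]):
        d = complex_diff(snaps[old_d], snaps[new_d])
        for acc, w in local_change_costs(d, cm).items():
            totals[acc] = totals.get(acc, 0.0) + w

    records = []
    for root in sorted(region_roots):
        members = ({root} | nx.ancestors(union, root)) if root in union else {root}
        agg = sum(totals.get(m, 0.0) for m in members)
        norm = agg / len(members)
        records.append(RegionRecord(root, len(members), agg, norm,
                                    _classify(norm, unstable_threshold)))
    return RegionReport(window, records)


def _add_months(d: _dt.date, months: int) -> _dt.date:
    y, m = divmod((d.year * 12 + d.month - 1) + months, 12)
    day = min(d.day, [31, 29 if y % 4 == 0 and (y % 100 != 0 or y % 400 == 0) else 28,
                      31, 30, 31, 30, 31, 31, 30, 31, 30, 31][m])
    return _dt.date(y, m + 1, day)


def region_trend(store: VersionedSource, window_length: int = 6, step: int = 1,
                 cost_model: CostModel | None = None,
                 region_roots: set[str] | None = None,
                 unstable_threshold: float = 0.5) -> list[tuple[tuple[_dt.date, _dt.date], RegionReport]]:
    """Sliding-window region analysis.

    Windows are ``[start, start + window_length months)`` advanced by *step*
    months from the first version date; the last window is the one whose end
    first reaches past the last version date (so a 12-monthly-version history
    with a 6-month window and 1-month step yields 7 positions).
    """
    if not store.version_dates:
        raise ValueError("empty store")
    first, last = store.version_dates[0], store.version_dates[-1]
    if _add_months(first, window_length) > _add_months(last, step):
        raise ValueError("version history shorter than one window")
    out = []
    start = first
    while _add_months(start, window_length) <= _add_months(last, step):
        end = _add_months(start, window_length)
        # window is [start, end): inclusive upper bound for version selection
        inclusive_end = end - _dt.timedelta(days=1)
        report = region_costs(store, (start, inclusive_end), cost_model,
                              region_roots, unstable_threshold)
        out.append(((start, end), report))
        start = _add_months(start, step)
    return out


# -- annotation propagation and enrichment ------------------------------------

def propagate_annotations(snap: OntologySnapshot, annot: Mapping,
                          warnings: list[str] | None = None
                          ) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Direct and indirect (propagated) entity sets per concept.

    The indirect set of a concept is the union of the direct sets of the
    concept and all of its is-a descendants — an entity annotated to a
    concept counts for every ancestor (the true-path rule).  Annotations to
    unknown accessions are skipped with a warning.

    Returns ``(direct, indirect)`` keyed by accession; every concept appears
    in both, possibly with empty sets.
    """
    if annot.mapping_type != "annotation":
        raise ValueError(f"expected an annotation mapping, got {annot.mapping_type!r}")
    direct: dict[str, set[str]] = {acc: set() for acc in snap.elements}
    for c in annot.correspondences:
        if c.right_acc in direct:
            direct[c.right_acc].add(c.left_acc)
        elif warnings is not None:
            warnings.append(f"annotation {c.left_acc} -> unknown concept {c.right_acc}; skipped")
    g = snap.isa_graph()  # edges child -> parent
    indirect: dict[str, set[str]] = {}
    for acc in nx.topological_sort(g):  # children before parents
        s = set(direct[acc])
        for child in g.predecessors(acc):
            s |= indirect[child]
        indirect[acc] = s
    return direct, indirect


def enrichment_demo(snap: OntologySnapshot, annot: Mapping,
                    study_set: set[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment on propagated annotation counts.

    For each concept with a non-empty indirect entity set, the p-value is the
    probability of drawing at least the observed number of study entities
    when sampling ``|study|`` entities without replacement from the annotated
    universe.  Exact tail computation; intended for demonstration scale.
    """
    direct, indirect = propagate_annotations(snap, annot)
    universe = set().union(*indirect.values()) if indirect else set()
    if not universe:
        raise ValueError("empty annotated entity universe")
    missing = study_set - universe
    if missing:
        raise ValueError(f"study entities outside the annotated universe: {sorted(missing)[:5]}")
    N, n = len(universe), len(study_set)
    rows = []
    for acc in sorted(snap.elements):
        anns = indirect[acc]
        if not anns:
            continue
        K = len(anns)
        k = len(anns & study_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"accession": acc, "annotated": K, "in_study": k, "p_value": p})
    return pd.DataFrame(rows)


# -- annotation impact ---------------------------------------------------------

@dataclass(frozen=True)
class ImpactRecord:
    entity_acc: str
    concept_acc: str
    cause: str                       # op kind affecting the concept
    suggestion: str                  # retarget | choose-target | remove | keep
    targets: tuple[str, ...] = ()    # migration targets, if any


def annotation_impact(annot: Mapping, d: ComplexDiff) -> list[ImpactRecord]:
    """Flag annotations hit by complex changes and suggest migrations.

    Merge: re-target to the merge target.  Split: list all split targets (the
    user chooses).  Deletion/obsoletion: flag for removal.  Move: keep, with
    a notice that the concept's position changed.
    """
    affected: dict[str, tuple[str, str, tuple[str, ...]]] = {}
    for op in d.ops:
        if op.op_kind == "merge":
            for s in op.sources:
                affected[s] = ("merge", "retarget", (op.concept,))
        elif op.op_kind == "split":
            affected[op.concept] = ("split", "choose-target", tuple(sorted(op.targets)))
        elif op.op_kind in ("delLeaf", "delSubGraph"):
            concepts = op.members if op.op_kind == "delSubGraph" else (op.concept,)
            for c in concepts:
                affected[c] = (op.op_kind, "remove", ())
        elif op.op_kind == "toObsolete":
            affected[op.concept] = ("toObsolete", "remove", ())
        elif op.op_kind == "move":
            affected[op.concept] = ("move", "keep", ())
    for acc in d.residual.delC:
        affected.setdefault(acc, ("delC", "remove", ()))

    out = []
    for c in sorted(annot.correspondences):
        hit = affected.get(c.right_acc)
        if hit is not None:
            cause, suggestion, targets = hit
            out.append(ImpactRecord(c.left_acc, c.right_acc, cause, suggestion, targets))
    return out
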