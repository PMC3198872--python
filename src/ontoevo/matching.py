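"""Ontology matching: matcher library, matrix combination, and filters.

A match run executes one or more matchers over a pair of ontology snapshots,
each producing a sparse similarity matrix over concept pairs (values in
(0, 1]; entries below a pruning threshold ε are dropped early to bound
memory).  Matrices are combined by a set strategy (union / intersection /
majority vote) with a value-aggregation function (max / min / avg), then
filtered — by a strict confidence threshold and/or a best-bidirectional
("stable marriage") selection — into an ontology mapping.

Matchers
--------
* linguistic — best string similarity over configurable attribute value sets
  (default: name + synonyms); n-gram Dice, Levenshtein, exact, or Loom-style
  normalized-exact comparison.
* path — compares root-to-concept paths of concatenated names, so homonymous
  leaves under different parents score lower than by name alone.
* child — structural: average over one side's children of the best base
  similarity to any child of the other side.
* annotation — overlap of the entity sets annotated to each concept, scored
  by Dice, Jaccard or Cosine.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from typing import Callable

import edlib
import networkx as nx

from .model import IS_A, Mapping, OntologySnapshot

DEFAULT_PRUNING = 0.1

VersionRef = tuple[str, _dt.date | None]


def _version_ref(s: OntologySnapshot) -> VersionRef:
    return (s.source_id, s.version_date)


@dataclass
class SimilarityMatrix:
    """Sparse concept-pair similarity matrix for one version pair."""

    left_version: VersionRef
    right_version: VersionRef
    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    pruning_threshold: float = DEFAULT_PRUNING

    def set(self, left: str, right: str, sim: float) -> None:
        """Store a similarity, applying the pruning threshold."""
        if sim > 1.0 + 1e-12:
            raise ValueError(f"similarity {sim} > 1")
        if sim >= self.pruning_threshold and sim > 0.0:
            self.entries[(left, right)] = min(sim, 1.0)

    def transpose(self) -> "SimilarityMatrix":
        out = SimilarityMatrix(self.right_version, self.left_version,
                               pruning_threshold=self.pruning_threshold)
        out.entries = {(r, l): v for (l, r), v in self.entries.items()}
        return out

    def __len__(self) -> int:
        return len(self.entries)


# -- string similarity ---------------------------------------------------------

_PUNCT = re.compile(r"[^\w\s]")


def normalize_string(s: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return " ".join(_PUNCT.sub(" ", s.lower()).split())


def _ngrams(s: str, n: int, pad: bool) -> list[str]:
    if pad:
        s = "#" * (n - 1) + s + "#" * (n - 1)
    return [s[i:i + n] for i in range(max(len(s) - n + 1, 0))]


def string_sim(a: str, b: str, method: str = "ngram", n: int = 3,
               normalize: bool = True, pad: bool = True) -> float:
    """Similarity of two strings in [0, 1].

    ``ngram``: Dice coefficient over character n-gram sets (default trigrams,
    strings padded with n−1 boundary markers).  ``levenshtein``: 1 − edit
    distance / max length.  ``exact``/``loom``: 1.0 or 0.0 after
    normalization (the Loom comparison is exact match on punctuation-stripped
    lowercase strings).
    """
    if n < 1:
        raise ValueError("n-gram size must be >= 1")
    if normalize:
        a, b = normalize_string(a), normalize_string(b)
    if method in ("exact", "loom"):
        return 1.0 if a == b and a != "" else (1.0 if a == b == "" else 0.0)
    if not a or not b:
        return 1.0 if a == b else 0.0
    if method == "ngram":
        ga, gb = set(_ngrams(a, n, pad)), set(_ngrams(b, n, pad))
        if not ga and not gb:
            return 1.0 if a == b else 0.0
        return 2.0 * len(ga & gb) / (len(ga) + len(gb))
    if method == "levenshtein":
        dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
        return 1.0 - dist / max(len(a), len(b))
    raise ValueError(f"unknown string method {method!r}")


# -- matchers ------------------------------------------------------------------

DEFAULT_MATCH_ATTRS = ("name", "synonym")


def _attr_values(snap: OntologySnapshot, acc: str, attrs) -> list[str]:
    vals: list[str] = []
    for a in attrs:
        vals.extend(snap.elements[acc].attribute(a))
    return vals


def linguistic_matcher(left: OntologySnapshot, right: OntologySnapshot,
                       attrs_left=DEFAULT_MATCH_ATTRS, attrs_right=DEFAULT_MATCH_ATTRS,
                       method: str = "ngram", n: int = 3,
                       pruning: float = DEFAULT_PRUNING) -> SimilarityMatrix:
    """Best string similarity across all attribute-value pairs of two concepts."""
    m = SimilarityMatrix(_version_ref(left), _version_ref(right), pruning_threshold=pruning)
    right_vals = {acc: [normalize_string(v) for v in _attr_values(right, acc, attrs_right)]
                  for acc in right.elements}
    for la in left.elements:
        lvals = [normalize_string(v) for v in _attr_values(left, la, attrs_left)]
        if not lvals:
            continue
        for ra, rvals in right_vals.items():
            best = 0.0
            for lv in lvals:
                for rv in rvals:
                    s = string_sim(lv, rv, method, n, normalize=False)
                    if s > best:
                        best = s
                        if best >= 1.0:
                            break
                if best >= 1.0:
                    break
            m.set(la, ra, best)
    return m


def _root_paths(snap: OntologySnapshot) -> dict[str, str]:
    """Root-to-concept path strings of concatenated names.

    At each step the parent with the lexicographically smallest accession is
    followed (a single path is assumed; multi-parent concepts take the
    deterministic branch).
    """
    parents: dict[str, list[str]] = {}
    for r in snap.relationships:
        if r.rel_type == IS_A:
            parents.setdefault(r.source_acc, []).append(r.target_acc)
    paths: dict[str, str] = {}

    def path_of(acc: str) -> str:
        if acc in paths:
            return paths[acc]
        name = snap.elements[acc].name() or acc
        ps = parents.get(acc)
        val = name if not ps else path_of(min(ps)) + " / " + name
        paths[acc] = val
        return val

    for acc in snap.elements:
        path_of(acc)
    return paths


def path_matcher(left: OntologySnapshot, right: OntologySnapshot,
                 method: str = "ngram", n: int = 3,
                 pruning: float = DEFAULT_PRUNING) -> SimilarityMatrix:
    """String similarity of root-to-concept name paths (both snapshots must be acyclic)."""
    for snap in (left, right):
        if not nx.is_directed_acyclic_graph(snap.isa_graph()):
            raise ValueError("path matcher requires acyclic is-a graphs")
    lp, rp = _root_paths(left), _root_paths(right)
    m = SimilarityMatrix(_version_ref(left), _version_ref(right), pruning_threshold=pruning)
    for la, lpath in lp.items():
        for ra, rpath in rp.items():
            m.set(la, ra, string_sim(lpath, rpath, method, n))
    return m


def child_matcher(left: OntologySnapshot, right: OntologySnapshot,
                  base: SimilarityMatrix,
                  pruning: float = DEFAULT_PRUNING) -> SimilarityMatrix:
    """Average over left children of the best base similarity to any right child.

    Concepts without children score 0 (no entry).
    """
    if (base.left_version, base.right_version) != (_version_ref(left), _version_ref(right)):
        raise ValueError("base matrix covers a different version pair")
    lchildren = {acc: left.children(acc) for acc in left.elements}
    rchildren = {acc: right.children(acc) for acc in right.elements}
    m = SimilarityMatrix(_version_ref(left), _version_ref(right), pruning_threshold=pruning)
    for la, lc in lchildren.items():
        if not lc:
            continue
        for ra, rc in rchildren.items():
            if not rc:
                continue
            total = 0.0
            for c1 in lc:
                total += max((base.entries.get((c1, c2), 0.0) for c2 in rc), default=0.0)
            m.set(la, ra, total / len(lc))
    return m


_OVERLAP_FUNCS: dict[str, Callable[[int, int, int], float]] = {
    "dice": lambda x, na, nb: 2.0 * x / (na + nb),
    "jaccard": lambda x, na, nb: x / (na + nb - x),
    "cosine": lambda x, na, nb: x / (na * nb) ** 0.5,
}


def annotation_matcher(left: OntologySnapshot, right: OntologySnapshot,
                       annot_left: Mapping, annot_right: Mapping,
                       func: str = "dice",
                       pruning: float = DEFAULT_PRUNING) -> SimilarityMatrix:
    """Similarity from the overlap of entity sets annotated to each concept.

    The annotation mappings link entity accessions (left side of each
    correspondence) to concept accessions of the respective snapshot; both
    must draw entities from the same accession space.  Concepts with no
    annotated entities yield no entries.
    """
    for annot in (annot_left, annot_right):
        if annot.mapping_type != "annotation":
            raise ValueError(f"expected an annotation mapping, got {annot.mapping_type!r}")
    if func not in _OVERLAP_FUNCS:
        raise ValueError(f"unknown overlap function {func!r}")
    f = _OVERLAP_FUNCS[func]
    left_sets = {c: ents for c, ents in annot_left.by_right().items() if c in left.elements}
    right_sets = {c: ents for c, ents in annot_right.by_right().items() if c in right.elements}
    m = SimilarityMatrix(_version_ref(left), _version_ref(right), pruning_threshold=pruning)
    for la, ea in left_sets.items():
        for ra, eb in right_sets.items():
            x = len(ea & eb)
            if x:
                m.set(la, ra, f(x, len(ea), len(eb)))
    return m


# -- combination and filtering -------------------------------------------------

_AGGREGATIONS = {"max": max, "min": min, "avg": lambda vs: sum(vs) / len(vs)}


def combine(matrices: list[SimilarityMatrix], combination: str = "union",
            aggregation: str = "avg") -> SimilarityMatrix:
    """Combine matrices by set strategy and aggregate surviving pair values.

    ``union`` keeps pairs present in any matrix, ``intersection`` in all,
    ``majority`` in more than half; the surviving value aggregates over the
    matrices that contain the pair.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    if combination not in ("union", "intersection", "majority"):
        raise ValueError(f"unknown combination {combination!r}")
    agg = _AGGREGATIONS[aggregation]
    ref = (matrices[0].left_version, matrices[0].right_version)
    for m in matrices[1:]:
        if (m.left_version, m.right_version) != ref:
            raise ValueError("matrices cover different version pairs")
    out = SimilarityMatrix(*ref, pruning_threshold=0.0)
    counts: dict[tuple[str, str], list[float]] = {}
    for m in matrices:
        for pair, v in m.entries.items():
            counts.setdefault(pair, []).append(v)
    k = len(matrices)
    for pair, vals in counts.items():
        keep = (combination == "union"
                or (combination == "intersection" and len(vals) == k)
                or (combination == "majority" and len(vals) > k / 2))
        if keep:
            out.entries[pair] = agg(vals)
    return out


def filter_threshold(m: SimilarityMatrix, theta: float) -> Mapping:
    """Keep entries with similarity strictly greater than *theta* as a mapping."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    out = Mapping(m.left_version, m.right_version, "ontology",
                  properties={"filter": f"threshold>{theta:g}"})
    for (la, ra), v in m.entries.items():
        if v > theta:
            out.add(la, ra, "equivalence", v)
    return out


def filter_stable_marriage(m: SimilarityMatrix) -> Mapping:
    """Keep only mutually-best pairs; similarity ties disqualify the tied pairs.

    The result is a partial injection: every accession appears in at most one
    correspondence.
    """
    best_left: dict[str, tuple[float, str | None]] = {}
    best_right: dict[str, tuple[float, str | None]] = {}
    for (la, ra), v in m.entries.items():
        for key, other, table in ((la, ra, best_left), (ra, la, best_right)):
            cur = table.get(key)
            if cur is None or v > cur[0]:
                table[key] = (v, other)
            elif v == cur[0] and cur[1] != other:
                table[key] = (v, None)  # tie: no unique best
    out = Mapping(m.left_version, m.right_version, "ontology",
                  properties={"filter": "stable-marriage"})
    for la, (v, ra) in best_left.items():
        if ra is not None and best_right.get(ra, (None, None))[1] == la:
            out.add(la, ra, "equivalence", v)
    return out


# -- match workflow ------------------------------------------------------------

@dataclass
class MatchConfig:
    """Configuration of one match run (matchers, combination, filters, pruning).

    ``matchers`` is a list of ``(name, params)`` pairs; names are
    ``linguistic``, ``path``, ``child`` and ``annotation``.  The ``child``
    matcher bases itself on a ``linguistic`` run with the same params.
    Annotation matchers need ``annot_left``/``annot_right`` mappings in their
    params.
    """

    matchers: list[tuple[str, dict]] = field(default_factory=lambda: [("linguistic", {})])
    combination: str = "union"
    aggregation: str = "avg"
    threshold: float | None = 0.7
    stable_marriage: bool = False
    pruning: float = DEFAULT_PRUNING
    verified: Mapping | None = None  # expert-confirmed pairs, force-kept

    def __post_init__(self) -> None:
        if not self.matchers:
            raise ValueError("at least one matcher required")
        for val, name in ((self.pruning, "pruning"),):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def run_matcher(name: str, params: dict, left: OntologySnapshot,
                right: OntologySnapshot, pruning: float) -> SimilarityMatrix:
    params = dict(params)
    params.setdefault("pruning", pruning)
    if name == "linguistic":
        return linguistic_matcher(left, right, **params)
    if name == "path":
        return path_matcher(left, right, **params)
    if name == "child":
        base_params = {k: v for k, v in params.items() if k != "pruning"}
        base = linguistic_matcher(left, right, pruning=pruning, **base_params)
        return child_matcher(left, right, base, pruning=params["pruning"])
    if name == "annotation":
        return annotation_matcher(left, right, **params)
    raise ValueError(f"unknown matcher {name!r}")


def match(left: OntologySnapshot, right: OntologySnapshot,
          config: MatchConfig | None = None) -> Mapping:
    """Full match workflow: matchers → combination → threshold → stable marriage."""
    cfg = config or MatchConfig()
    matrices = [run_matcher(name, params, left, right, cfg.pruning)
                for name, params in cfg.matchers]
    combined = combine(matrices, cfg.combination, cfg.aggregation)
    if cfg.threshold is not None:
        mapping = filter_threshold(combined, cfg.threshold)
        if cfg.stable_marriage:
            pruned = SimilarityMatrix(combined.left_version, combined.right_version,
                                      pruning_threshold=0.0)
            pruned.entries = {(c.left_acc, c.right_acc): c.confidence
                              for c in mapping.correspondences}
            mapping = filter_stable_marriage(pruned)
    elif cfg.stable_marriage:
        mapping = filter_stable_marriage(combined)
    else:
        mapping = filter_threshold(combined, 0.0)
    if cfg.verified is not None:
        for c in cfg.verified.correspondences:
            mapping.correspondences.add(c)
    mapping.properties.update({
        "matchers": ",".join(name for name, _ in cfg.matchers),
        "combination": cfg.combination,
        "aggregation": cfg.aggregation,
        "threshold": "" if cfg.threshold is None else f"{cfg.threshold:g}",
        "stable_marriage": str(cfg.stable_marriage).lower(),
        "pruning": f"{cfg.pruning:g}",
    })
    return mapping


def compose(m12: Mapping, m23: Mapping, conf_rule: str = "product") -> Mapping:
    """Compose two mappings through their shared middle source.

    A correspondence (a, c) is emitted for every shared middle accession b
    with (a, b) in *m12* and (b, c) in *m23*; duplicate (a, c) pairs keep the
    maximum derived confidence.
    """
    if m12.right_source[0] != m23.left_source[0]:
        raise ValueError(f"cannot compose: {m12.right_source[0]!r} != {m23.left_source[0]!r}")
    if conf_rule not in ("product", "min"):
        raise ValueError(f"unknown confidence rule {conf_rule!r}")
    out = Mapping(m12.left_source, m23.right_source, m12.mapping_type,
                  properties={"derivation": f"composition({conf_rule})"})
    by_middle: dict[str, list] = {}
    for c in m23.correspondences:
        by_middle.setdefault(c.left_acc, []).append(c)
    best: dict[tuple[str, str], float] = {}
    for c12 in m12.correspondences:
        for c23 in by_middle.get(c12.right_acc, []):
            conf = (c12.confidence * c23.confidence if conf_rule == "product"
                    else min(c12.confidence, c23.confidence))
            key = (c12.left_acc, c23.right_acc)
            best[key] = max(best.get(key, 0.0), conf)
    for (a, c), conf in best.items():
        out.add(a, c, "equivalence", conf)
    return out
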