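# Methods

This note documents the models and procedures implemented in `ontoevo`, the
parameters that matter, the numerical and design choices made where the
design was open, and what the synthetic test conditions do and do not show
about real ontology archives.

## Data model

An ontology source version is `S_v = (E, R, A, t)`: a set of elements
identified solely by their accession string, typed directed relationships
`r = (source, type, target)`, multi-valued attributes per element, and a
release date at day granularity. Names, definitions, synonyms and obsolete
flags are ordinary attributes; nothing in the model is format-specific.
Relationship types are normalized to lowercase hyphenated tokens, so OBO
`is_a` and OWL `subClassOf` both become `is-a`, and `part_of` becomes
`part-of`. The is-a subgraph must be acyclic; the importer rejects cyclic
snapshots by default (validation can be relaxed to a warning for real-world
snapshots with transient cycles, which do occur in archives).

Mappings `M = (S_1, S_2, C, T, P)` are typed correspondence sets: type
`annotation` (entity → concept links), `ontology` (concept alignments) or
`evolution` (version-to-version links), with per-correspondence confidences
in `[0, 1]` and free-form provenance properties.

## Lifetime-based versioning

Version chains are linear: each version has exactly one predecessor. Every
payload — an element identity, a relationship triple, or an
(accession, attribute, value) triple — is stored once with a list of
disjoint validity intervals `[t_start, t_end)`; the end date is exclusive,
and the last interval may be open. Importing a version opens intervals for
payloads that newly appear and closes intervals for payloads that
disappear; reconstruction at date *t* selects the payloads whose interval
covers *t*. Payloads that disappear and later return (resurrected
accessions happen in practice) get multiple intervals; sources whose every
element has one lifetime are the special single-interval case.

Deletion is recorded purely as interval closure. Obsoletion is *not*
deletion: flagging a concept obsolete is an attribute change, and the
concept's lifetime continues. This keeps sources that only obsolete (e.g.
phenotype ontologies) distinguishable from sources that physically delete
concepts (e.g. chemistry ontologies).

Basic diffs against the predecessor are computed and cached at import time
(disable with `materialize_diff=False` for bulk loads; they are recomputed
on demand). The persistent backend is a single-file SQLite database with a
generic attribute–value schema (one `lifetimes` table for all three payload
kinds); an in-memory store is the default and is what the tests exercise.

## Basic diff and patch semantics

`basic_diff` compares two versions keyed on accession: set differences of
concepts and relationship triples, plus attribute differences. An attribute
that is single-valued on both sides and differs becomes one
`chgAttValue (accession, attr, old, new)` record; all other attribute
differences (including attributes of added/deleted concepts) become
`addA`/`delA` records. The diff is a complete patch: `apply_basic_diff`
replays it record-by-record with strict applicability checks, and the result
is content-equal to the new version. This patch property is the invariant
that everything else (lifetime reconstruction, change accounting) is tested
against.

## Complex change detection

Complex operations are derived from the basic diff by rules applied in a
fixed priority order; each rule consumes the basic records it explains so no
record is claimed twice, and anything unexplained stays in an explicit
residual:

1. **toObsolete** — the `is_obsolete` attribute turns true on a surviving
   concept.
2. **merge(sources → target)** — deleted concepts all linked to the same
   surviving or added concept. A link exists when the target lists the source
   in `alt_id`, `replaced_by` or `consider` in the new version, or when an
   optional version-match mapping links them at confidence ≥ 0.9. Two or
   more sources always qualify; a single source qualifies only with `alt_id`
   evidence (true absorption) — a lone matcher link is too weak and the
   deletion falls through to the later rules.
3. **split(source → targets)** — one deleted concept linked to ≥ 2 added
   concepts (each target lists the source in `replaced_by`/`consider`, or
   matcher links).
4. **addSubGraph / delSubGraph** — a connected group of ≥ 2 unconsumed
   added (deleted) concepts, connected among themselves via is-a, with a
   unique topmost member whose parents all pre-existed (survive). Added
   forests with several topmost members yield one subgraph per topmost node.
5. **addLeaf / delLeaf** — remaining single added/deleted concepts with no
   added/deleted is-a children.
6. **move** — a concept alive in both versions that both lost and gained
   is-a parents; pure parent additions or removals are not moves and stay in
   the residual. Non-is-a relationship changes are never moves.
7. **chgAttValue** — attribute value changes passed through.

Metadata evidence is preferred over matcher evidence because it is
deterministic and curator-authored; matcher-based linking is opt-in. The
rule order puts metadata-evidenced operations before structural grouping
before leaves/moves, so higher-level operations absorb their constituent
records first. Accounting is structural: every added/deleted accession is
claimed by exactly one operation or appears in the residual.

Where the target of a merge may be pre-existing or newly added, both are
accepted (real archives contain both). A moved subtree is reported as the
root's move; no subgraph operation is emitted for it.

## Matching

Matchers produce sparse similarity matrices with entries in `(0, 1]`;
entries below a pruning threshold ε (default **0.1**) are dropped at
construction to bound memory — ε is a memory/recall trade-off, not a
decision threshold. String comparison normalizes by lowercasing, stripping
punctuation and collapsing whitespace, then applies:

* `ngram` — Dice coefficient over character n-grams (default n = 3, strings
  padded with n−1 boundary markers so short strings still produce grams);
* `levenshtein` — `1 − d/max(|a|, |b|)` with the edit distance computed by
  edlib;
* `exact` / `loom` — equality after normalization (the Loom-style
  comparison is implemented as punctuation-insensitive exact match; this is
  an approximation of that family of matchers).

The linguistic matcher takes the **maximum** similarity over all configured
attribute-value pairs (default attributes: name and synonyms). The path
matcher concatenates names from root to concept; in multi-parent DAGs it
follows the lexicographically smallest parent accession at each step, a
deterministic stand-in for the single-path assumption. The child matcher
averages, over one concept's children, the best base similarity to any
child of the other concept (best-per-child averaging; concepts without
children yield no entry). The annotation matcher scores the overlap of the
entity sets annotated to two concepts with Dice `2x/(|A|+|B|)`, Jaccard
`x/|A∪B|` or Cosine `x/√(|A||B|)`. Note the exact ordering
`jaccard ≤ dice ≤ cosine` for non-empty overlaps: Dice divides by the
arithmetic mean of the set sizes, Cosine by the geometric mean, and the
geometric mean is never larger.

Matrix combination keeps pairs by union, intersection, or majority vote
(> half of the matrices), aggregating surviving values by max, min or
average. The confidence-threshold filter is **strict** (`similarity > θ`),
so θ = 1 always yields an empty mapping. The stable-marriage filter keeps a
pair only when each side is the *unique* best of the other; ties disqualify
both tied pairs (conservative and deterministic), and the output is a
partial injection. Expert-verified correspondences supplied in the match
configuration are force-kept with their given confidence (not reset to 1).

Mapping composition `(a,b) ∘ (b,c) → (a,c)` uses product or min confidence,
deduplicating by maximum.

## Evolution analytics

**Growth factors** are plain count ratios between the first and last
version: `growth_C = |C_n|/|C_0|`, likewise for relationships and for
concepts+relationships combined. Ratios with a zero denominator are
reported as absent. Reported values are rounded half-up to two decimals;
full precision is kept on the object. The **add/delete ratio** is
`|addC|/|delC|` (absent for 0/0, infinite when nothing was deleted), and
change frequencies can be normalized by the old version's concept
(relationship) totals to compare across ontologies of different size.

**Region stability.** A region is a root concept plus all of its is-a
descendants. Over a window of versions, each change record charges a
weighted cost to the concepts it touches: concept-level records and
single-concept operations charge the concept itself; relationship records
charge the child endpoint; merge/split charge every source/target plus the
surviving concept; subgraph operations charge every member. Default
weights: additions 1.0 per concept, deletions 2.0, merge/split 2.0,
move/obsoletion 1.5, attribute and relationship changes 0.5 — deliberately
penalizing information-reducing operations more. All weights are
configurable; the defaults are a reporting convention, not a fitted
quantity. Region membership uses the **union** of concepts alive at any
window version, so deleted members still carry their deletion cost, and the
root region's aggregate equals the total weighted cost of all changes in
the window (a conservation law the tests assert). Normalized cost is
aggregate divided by region size; a region is *stable* iff its cost is
exactly zero, *unstable* at ≥ 0.5 per concept (configurable), otherwise
intermediate. Sliding-window trends advance a `[start, start + L months)`
window by a step of *s* months from the first version date, keeping windows
while `start + L ≤ last_version + s`; twelve monthly versions with L = 6,
s = 1 give seven window positions. Default region roots are the children of
each ontology root (the top-level categories).

**Annotation propagation** implements the true-path rule: the indirect
entity set of a concept is the union of the direct sets of the concept and
all its is-a descendants, computed in one topological pass. The enrichment
demo computes the exact upper-tail hypergeometric probability
`P(X ≥ k | N, K, n)` on propagated counts via `scipy.stats.hypergeom` — no
approximation, intended for demonstration scale, without multiple-testing
correction or the refinement strategies of full enrichment tools.
**Annotation impact** flags annotations to concepts hit by complex changes:
merge → re-target to the merge target, split → list all targets and leave
the choice to the user, deletion/obsoletion → flag for removal, move → keep
with a notice.

## Synthetic data

The generator produces single-rooted acyclic is-a DAGs with accessions
`SYN:0000001…` and unique pronounceable names (so string matchers behave
non-degenerately), each node drawing 1..max_parents parents among earlier
nodes. Change scripts sample operations from a configurable mix and fix all
operands — including the accessions of concepts to be created — at sampling
time, so a script doubles as the exact expected diff. *Non-interacting*
scripts additionally guarantee that no two operations share an operand
concept or affected parent, giving a one-to-one correspondence between
scripted and recoverable operations; merges draw leaf sources, splits and
moves act on leaves, and deleted subtrees are closed under descendants.
Merge/split evidence is written into `alt_id`/`replaced_by` metadata unless
disabled. All randomness flows from explicit per-call seeds.

The test conditions use bases of 100–500 concepts, chains of 5–12 versions,
and scripts of up to 20 operations — sizes at which every property is
checked exhaustively in seconds. What passing shows: the versioning,
diff-recovery, matching and analytics machinery is exact under controlled,
non-interacting change. What it does not show: behavior on real archives
where changes interact (a renamed concept inside a moved subtree), merge
evidence is partial or wrong, and version gaps are irregular; there the
complex diff degrades gracefully (unexplained records stay in the residual)
but recovery is no longer guaranteed to be exact. The generator also makes
no attempt to match the statistical change-rate distributions of real
sources.

## Numerical and I/O notes

* Dates are `datetime.date`; all serialized dates are ISO-8601.
* Similarities are clamped to `[0, 1]`; growth rounding is decimal half-up.
* OBO reading goes through `obonet` (1.2 dialect, obsolete terms kept);
  unknown term tags are absorbed as generic attributes, and nothing is
  silently dropped. The OBO writer is deterministic (stanzas and tags
  sorted), so two writes of the same snapshot are byte-identical and file
  diffs are stable. Synonym scope markers are kept inside the value string.
* The OWL reader extracts only the named-class skeleton (classes, labels,
  literal annotations, subclass links between named classes) from RDF/XML
  via `rdflib`; complex class expressions are skipped and counted.
* Mapping files are a 4-column TSV (`left_acc`, `right_acc`, `corr_type`,
  `confidence`), deduplicated by maximum confidence on read.

## Known limitations

* Branching version histories, concurrent writers and client–server
  deployment are out of scope; the store is embedded and single-writer.
* The complex-diff rule set does not model interactions between operations
  (e.g. a move of a freshly added subtree); such cases land partly in the
  residual rather than being mis-attributed.
* Similarity-flooding-style structural matching is not implemented; the
  matcher registry is pluggable so it can be added.
* OWL support is deliberately minimal; OBO 1.4 logical constructs
  (`intersection_of`, `union_of`) are carried as opaque attributes, not
  interpreted.
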