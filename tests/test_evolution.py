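import datetime as dt
import math
import random

import networkx as nx
import pytest

from ontoevo import (
    CostModel,
    Mapping,
    VersionedSource,
    add_delete_ratio,
    annotation_impact,
    apply_script,
    basic_diff,
    change_frequencies,
    complex_diff,
    enrichment_demo,
    generate_annotations,
    generate_base,
    growth_stats,
    propagate_annotations,
    region_costs,
    region_trend,
    sample_script,
)
from ontoevo.evolution import GrowthStats, local_change_costs

from conftest import D0, D1, make_snapshot


def make_history(seed, n_versions=6, n_concepts=80, ops_per_step=4,
                 start=dt.date(2009, 1, 15)):
    """Monthly-versioned store with scripted changes."""
    store = VersionedSource("SYN")
    snap = generate_base(n_concepts, seed=seed)
    snap.version_date = start
    store.import_version(snap)
    cur = snap
    for i in range(1, n_versions):
        script = sample_script(cur, n_ops=ops_per_step, seed=seed * 100 + i)
        y, m = divmod(start.month - 1 + i, 12)
        cur = apply_script(cur, script, dt.date(start.year + y, m + 1, start.day))
        store.import_version(cur)
    return store


class TestGrowthStats:
    def test_identical_snapshots_all_ratios_one(self, chain_snapshot):
        gs = growth_stats(chain_snapshot, chain_snapshot)
        assert gs.rounded() == {"growth_C": 1.0, "growth_R": 1.0, "growth_CR": 1.0}

    def test_counts_taken_from_snapshots(self):
        first = make_snapshot(["a", "b", "c"], [("a", "c"), ("b", "c")])
        last = make_snapshot(["a", "b", "c", "d"], [("a", "c"), ("b", "c"), ("d", "c")])
        gs = growth_stats(first, last)
        assert (gs.c0, gs.cn, gs.r0, gs.rn) == (3, 4, 2, 3)
        assert gs.growth_C == pytest.approx(4 / 3)

    def test_zero_relationship_baseline_leaves_growth_r_absent(self):
        gs = GrowthStats("x", D0, D1, c0=10, cn=20, r0=0, rn=30)
        assert gs.growth_R is None
        assert gs.growth_CR == pytest.approx(5.0)

    def test_rounding_is_half_up(self):
        gs = GrowthStats("x", D0, D1, c0=200, cn=285, r0=0, rn=0)
        assert gs.rounded()["growth_C"] == 1.43  # 1.425 rounds up


class TestAddDeleteRatio:
    def test_plain_ratio(self):
        d = basic_diff(make_snapshot([f"o{i}" for i in range(5)]),
                       make_snapshot([f"n{i}" for i in range(10)]))
        # 10 added, 5 deleted
        assert add_delete_ratio(d) == 2.0

    def test_empty_diff_absent(self, chain_snapshot):
        assert add_delete_ratio(basic_diff(chain_snapshot, chain_snapshot)) is None

    def test_only_deletions_zero_and_only_additions_infinite(self):
        both = make_snapshot(["a", "b", "c"])
        fewer = make_snapshot(["a"])
        assert add_delete_ratio(basic_diff(both, fewer)) == 0.0
        assert add_delete_ratio(basic_diff(fewer, both)) == math.inf


class TestChangeFrequencies:
    def test_single_added_concept_row(self):
        store = VersionedSource("TST")
        store.import_version(make_snapshot(["A"], date=D0))
        store.import_version(make_snapshot(["A", "B"], date=D1))
        df = change_frequencies(store)
        assert len(df) == 1
        assert df.loc[0, "addC"] == 1 and df.loc[0, "delC"] == 0

    def test_normalization_divides_by_old_totals(self):
        store = VersionedSource("TST")
        store.import_version(make_snapshot([f"c{i}" for i in range(4)], date=D0))
        store.import_version(make_snapshot([f"c{i}" for i in range(5)], date=D1))
        df = change_frequencies(store, normalize=True)
        assert df.loc[0, "addC"] == pytest.approx(0.25)

    def test_identical_versions_zero_row(self):
        store = VersionedSource("TST")
        store.import_version(make_snapshot(["A"], date=D0))
        store.import_version(make_snapshot(["A"], date=D1))
        df = change_frequencies(store)
        assert df[["addC", "delC", "addR", "delR", "chgA"]].to_numpy().sum() == 0

    def test_fewer_than_two_versions_rejected(self):
        store = VersionedSource("TST")
        store.import_version(make_snapshot(["A"], date=D0))
        with pytest.raises(ValueError):
            change_frequencies(store)


class TestRegionCosts:
    def test_no_changes_all_regions_stable(self):
        store = VersionedSource("TST")
        snap = generate_base(40, seed=1)
        store.import_version(snap)
        again = snap.copy()
        again.version_date = D1
        store.import_version(again)
        rep = region_costs(store, (snap.version_date, D1))
        assert rep.regions
        for r in rep.regions:
            assert r.aggregate_cost == 0 and r.stability == "stable"

    def test_single_rename_cost_normalized_by_region_size(self):
        # region of 5 concepts under root; leaf renamed (weight 0.5 by default)
        edges = [("r1", "root"), ("m1", "r1"), ("m2", "r1"), ("m3", "m1"), ("m4", "m1")]
        old = make_snapshot(["root", "r1", "m1", "m2", "m3", "m4"], edges, date=D0)
        new = old.copy()
        new.version_date = D1
        new.elements["m4"].attributes["name"] = {"renamed"}
        store = VersionedSource("TST")
        store.import_version(old)
        store.import_version(new)
        rep = region_costs(store, (D0, D1), region_roots={"r1"})
        (r,) = rep.regions
        assert r.size == 5
        assert r.aggregate_cost == pytest.approx(0.5)
        assert r.normalized_cost == pytest.approx(0.1)
        assert r.stability == "intermediate"

    def test_root_region_conserves_total_cost(self):
        cm = CostModel()
        store = make_history(seed=7)
        window = (store.version_dates[0], store.version_dates[-1])
        rep = region_costs(store, window, cm, region_roots={"SYN:0000001"})
        total = 0.0
        for od, nd in zip(store.version_dates, store.version_dates[1:]):
            d = complex_diff(store.reconstruct(od), store.reconstruct(nd))
            total += sum(local_change_costs(d, cm).values())
        assert rep.regions[0].aggregate_cost == pytest.approx(total)

    def test_cost_monotone_in_weights(self):
        store = make_history(seed=8)
        window = (store.version_dates[0], store.version_dates[-1])
        base_costs = region_costs(store, window, CostModel()).by_root()
        heavier = CostModel({**CostModel().weights, "move": 10.0, "addC": 5.0,
                             "addLeaf": 5.0})
        heavy_costs = region_costs(store, window, heavier).by_root()
        for root, rec in base_costs.items():
            assert heavy_costs[root].aggregate_cost >= rec.aggregate_cost

    def test_window_covering_single_version_rejected(self):
        store = make_history(seed=9, n_versions=3)
        with pytest.raises(ValueError, match="need >= 2"):
            region_costs(store, (store.version_dates[0], store.version_dates[0]))


class TestRegionTrend:
    def test_twelve_monthly_versions_six_month_window_gives_seven_positions(self):
        store = make_history(seed=10, n_versions=12, ops_per_step=2)
        trend = region_trend(store, window_length=6, step=1)
        assert len(trend) == 7

    def test_stable_history_is_flat_zero(self):
        store = VersionedSource("TST")
        snap = generate_base(30, seed=2)
        snap.version_date = dt.date(2009, 1, 1)
        store.import_version(snap)
        for m in range(2, 13):
            nxt = snap.copy()
            nxt.version_date = dt.date(2009, m, 1)
            store.import_version(nxt)
            snap = nxt
        for _, rep in region_trend(store, window_length=6, step=1):
            assert all(r.normalized_cost == 0 for r in rep.regions)

    def test_changes_localized_in_time_appear_only_in_covering_windows(self):
        store = VersionedSource("TST")
        snap = generate_base(30, seed=3)
        snap.version_date = dt.date(2009, 1, 1)
        store.import_version(snap)
        for m in range(2, 13):
            nxt = snap.copy()
            nxt.version_date = dt.date(2009, m, 1)
            if m == 8:  # one burst of change between 2009-07 and 2009-08
                script = sample_script(snap, n_ops=3, seed=99)
                nxt = apply_script(snap, script, nxt.version_date)
            store.import_version(nxt)
            snap = nxt
        for (w_from, _), rep in region_trend(store, window_length=3, step=1):
            has_cost = any(r.aggregate_cost > 0 for r in rep.regions)
            covers_burst = w_from <= dt.date(2009, 7, 1) and dt.date(2009, 8, 1) < \
                dt.date(w_from.year, w_from.month + 3, 1)
            assert has_cost == covers_burst

    def test_history_shorter_than_window_rejected(self):
        store = make_history(seed=11, n_versions=3)
        with pytest.raises(ValueError, match="shorter"):
            region_trend(store, window_length=12)


def _annot(snap, links):
    m = Mapping(("ents", None), (snap.source_id, snap.version_date), "annotation")
    for ent, concept in links:
        m.add(ent, concept, "annotates")
    return m


class TestPropagation:
    def test_chain_propagates_to_ancestors(self):
        snap = make_snapshot(["a", "b", "root"], [("a", "b"), ("b", "root")])
        direct, indirect = propagate_annotations(snap, _annot(snap, [("e", "a")]))
        assert indirect == {"a": {"e"}, "b": {"e"}, "root": {"e"}}

    def test_root_annotation_does_not_reach_leaves(self):
        snap = make_snapshot(["a", "root"], [("a", "root")])
        _, indirect = propagate_annotations(snap, _annot(snap, [("e", "root")]))
        assert indirect["a"] == set()
        assert indirect["root"] == {"e"}

    def test_matches_transitive_closure_oracle_on_random_dags(self):
        for seed in range(10):
            snap = generate_base(60, max_parents=3, seed=seed)
            annot = generate_annotations(snap, n_entities=15, density=0.05, seed=seed)
            direct, indirect = propagate_annotations(snap, annot)
            g = snap.isa_graph()
            for acc in snap.elements:
                descendants = nx.ancestors(g, acc)  # child->parent edges
                want = set(direct[acc]).union(*(direct[d] for d in descendants)) \
                    if descendants else set(direct[acc])
                assert indirect[acc] == want

    def test_edge_removal_shrinks_ancestor_sets(self):
        snap = make_snapshot(["a", "b", "root"], [("a", "b"), ("b", "root")])
        annot = _annot(snap, [("e", "a")])
        _, before = propagate_annotations(snap, annot)
        cut = snap.copy()
        cut.relationships = {r for r in cut.relationships if r.source_acc != "a"}
        _, after = propagate_annotations(cut, annot)
        assert before["b"] == {"e"} and after["b"] == set()

    def test_unknown_target_skipped_with_warning(self):
        snap = make_snapshot(["a"])
        warnings = []
        _, indirect = propagate_annotations(snap, _annot(snap, [("e", "GHOST")]),
                                            warnings=warnings)
        assert indirect["a"] == set()
        assert len(warnings) == 1

    def test_indirect_superset_of_direct_and_monotone_toward_root(self):
        snap = generate_base(50, seed=5)
        annot = generate_annotations(snap, n_entities=10, density=0.1, seed=5)
        direct, indirect = propagate_annotations(snap, annot)
        for acc in snap.elements:
            assert direct[acc] <= indirect[acc]
        for acc in snap.elements:
            for parent in snap.parents(acc):
                assert indirect[acc] <= indirect[parent]


class TestEnrichment:
    def test_study_equals_universe_gives_p_one(self):
        snap = make_snapshot(["a", "root"], [("a", "root")])
        annot = _annot(snap, [("e1", "a"), ("e2", "root")])
        df = enrichment_demo(snap, annot, {"e1", "e2"})
        assert (df["p_value"] == 1.0).all()

    def test_exact_combinatorial_value(self):
        # concept annotated with exactly the 2-entity study set out of 10:
        # p = 1 / C(10,2) = 1/45
        snap = make_snapshot(["hit", "root"], [("hit", "root")])
        links = [("s1", "hit"), ("s2", "hit")] + [(f"bg{i}", "root") for i in range(8)]
        df = enrichment_demo(snap, _annot(snap, links), {"s1", "s2"})
        p_hit = df.set_index("accession").loc["hit", "p_value"]
        assert p_hit == pytest.approx(1 / 45)

    def test_invariant_to_entity_relabeling(self):
        snap = make_snapshot(["a", "b", "root"], [("a", "root"), ("b", "root")])
        links = [("e1", "a"), ("e2", "a"), ("e3", "b"), ("e4", "root")]
        relabel = {"e1": "x9", "e2": "x8", "e3": "x7", "e4": "x6"}
        df1 = enrichment_demo(snap, _annot(snap, links), {"e1", "e3"})
        df2 = enrichment_demo(
            snap, _annot(snap, [(relabel[e], c) for e, c in links]),
            {"x9", "x7"})
        assert df1["p_value"].tolist() == df2["p_value"].tolist()

    def test_empty_universe_rejected(self):
        snap = make_snapshot(["a"])
        with pytest.raises(ValueError, match="empty"):
            enrichment_demo(snap, _annot(snap, []), set())


class TestAnnotationImpact:
    def _fixture(self):
        old = make_snapshot(["B", "C", "S", "M", "U", "P", "q"],
                            [("B", "P"), ("C", "P"), ("S", "P"), ("M", "P"), ("U", "P")])
        new = make_snapshot(["D", "T1", "T2", "M", "U", "P", "q"],
                            [("D", "P"), ("T1", "P"), ("T2", "P"), ("M", "q"), ("U", "P")])
        new.elements["D"].add_attribute("alt_id", "B")
        new.elements["D"].add_attribute("alt_id", "C")
        for t in ("T1", "T2"):
            new.elements[t].add_attribute("replaced_by", "S")
        return old, new

    def test_merge_suggests_retarget(self):
        old, new = self._fixture()
        annot = _annot(old, [("e1", "B")])
        (rec,) = annotation_impact(annot, complex_diff(old, new))
        assert rec.cause == "merge" and rec.suggestion == "retarget"
        assert rec.targets == ("D",)

    def test_split_lists_all_targets_without_choosing(self):
        old, new = self._fixture()
        annot = _annot(old, [("e1", "S")])
        (rec,) = annotation_impact(annot, complex_diff(old, new))
        assert rec.cause == "split" and rec.suggestion == "choose-target"
        assert rec.targets == ("T1", "T2")

    def test_move_keeps_with_notice_and_untouched_absent(self):
        old, new = self._fixture()
        annot = _annot(old, [("e1", "M"), ("e2", "U")])
        records = annotation_impact(annot, complex_diff(old, new))
        assert [(r.concept_acc, r.suggestion) for r in records] == [("M", "keep")]
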