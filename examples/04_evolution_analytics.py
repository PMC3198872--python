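"""Evolution analytics: growth factors, change frequencies, region stability.

Builds a year of monthly releases with scripted changes, then computes
growth statistics, per-version change frequencies, and a region-stability
report that ranks top-level categories by per-concept change cost, plus a
sliding-window trend of the most active region.
"""

import datetime as dt

from ontoevo import (
    VersionedSource,
    add_delete_ratio,
    apply_script,
    change_frequencies,
    generate_base,
    growth_stats,
    region_costs,
    region_trend,
    sample_script,
)

store = VersionedSource("SYN")
snap = generate_base(n_concepts=100, seed=21)
snap.version_date = dt.date(2009, 1, 15)
store.import_version(snap)
cur = snap
for month in range(2, 13):
    script = sample_script(cur, n_ops=3, seed=2000 + month)
    cur = apply_script(cur, script, dt.date(2009, month, 15))
    store.import_version(cur)

first = store.reconstruct(store.version_dates[0])
last = store.reconstruct(store.version_dates[-1])
gs = growth_stats(first, last)
print(f"growth over 2009: concepts {gs.c0} -> {gs.cn}, "
      f"relationships {gs.r0} -> {gs.rn}")
print("growth factors (last/first):", gs.rounded())

df = change_frequencies(store)
print(f"\nchange frequencies across {len(df)} version pairs "
      f"(totals: {df[['addC', 'delC', 'addR', 'delR', 'chgA']].sum().to_dict()})")
d = store.basic_diff_between(store.version_dates[0], store.version_dates[-1])
print("add-delete ratio first vs last version:", add_delete_ratio(d))

report = region_costs(store, (store.version_dates[0], store.version_dates[-1]))
print("\nregion stability over the whole year (top-level categories):")
for rec in sorted(report.regions, key=lambda r: -r.normalized_cost)[:5]:
    print(f"  {rec.root}: size {rec.size:3d}, cost {rec.aggregate_cost:6.1f}, "
          f"per-concept {rec.normalized_cost:.2f} -> {rec.stability}")
# Zero cost per concept = stable; >= 0.5 per concept (default) = unstable.

trend = region_trend(store, window_length=6, step=1)
print(f"\nsliding 6-month window, 1-month step: {len(trend)} positions")
root = max(report.regions, key=lambda r: r.aggregate_cost).root
print(f"per-window normalized cost of the most active region ({root}):")
for (w_from, w_to), rep in trend:
    rec = rep.by_root().get(root)
    cost = rec.normalized_cost if rec else 0.0
    print(f"  [{w_from} .. {w_to}): {cost:.2f}")
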