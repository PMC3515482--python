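"""Single-linkage clustering of categories by gene-set overlap.

Categories selected by an enrichment screen often share genes; clustering
their Jaccard similarity matrix groups them into families that represent
one underlying signal each, which is how a hit list is condensed for
interpretation.
"""

from pathgwas.replication import cluster_categories

# four families of overlapping gene sets: each family shares a core
sets = {}
for k in range(4):
    core = {f"chrn{i}" for i in range(12)}
    sets[f"receptor{k}"] = frozenset(core | {f"r{k}_{j}" for j in range(2)})
for k in range(3):
    core = {f"or{i}" for i in range(200)}
    sets[f"sensory{k}"] = frozenset(core | {f"s{k}_{j}" for j in range(25)})
for k in range(3):
    core = {f"rpl{i}" for i in range(60)}
    sets[f"ribosome{k}"] = frozenset(core | {f"b{k}_{j}" for j in range(6)})
for k in range(2):
    core = {f"rbp{i}" for i in range(8)}
    sets[f"binding{k}"] = frozenset(core | {f"x{k}_{j}" for j in range(1)})

ids, Z, labels = cluster_categories(sets, metric="jaccard", cut_height=0.9)
clusters: dict = {}
for cid, lab in zip(ids, labels):
    clusters.setdefault(int(lab), []).append(cid)
print("flat clusters at distance 0.9 (1 - Jaccard):")
for lab, members in sorted(clusters.items()):
    print(f"  cluster {lab}: {sorted(members)}")
print(f"\nfirst merge at distance {Z[0, 2]:.3f}, last at {Z[-1, 2]:.3f}")
# identical gene sets merge at distance 0; disjoint families only at 1.
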