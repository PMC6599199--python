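"""Metabolic-network expression overlay.

Maps DEGs onto reaction nodes through ortholog IDs, computes each node's
pooled fold-change log2(sum FPKM derived / sum FPKM reference) over its
DEG-mapped genes, colors nodes red/blue/grey, and reports local clustering
coefficients.
"""

import polysweep as ps

cfg = ps.ExprSimConfig(
    clusters=[("WEAm", 12), ("R", 12)], n_genes=600, de_fraction=0.15, seed=5
)
expr, _ = ps.simulate_expression(cfg)
annotation, ortholog, network = ps.make_annotation_and_network(
    cfg.n_genes, {"A01": 5_000_000, "C01": 5_000_000},
    mean_genes_per_node=3.0, seed=6,
)
expr.ortholog = ortholog

deg = ps.call_degs(expr, "WEAm", "R")
nodes = ps.node_fold_change(expr, network, deg, "WEAm", "R")
coeffs = ps.local_clustering(network)

counts = nodes["color"].value_counts().to_dict()
print(f"{network.number_of_nodes()} reaction nodes, "
      f"{network.number_of_edges()} edges")
print(f"node colors: {counts}  (red = overexpressed in R, blue = under, "
      "grey = no DEG-mapped orthologs)")
top = nodes.dropna(subset=["fold_change"]).reindex(
    nodes["fold_change"].abs().sort_values(ascending=False).index
).head(3)
for node, row in top.iterrows():
    print(f"  {node}: fold_change {row.fold_change:+.2f} ({row.color}, "
          f"{int(row.n_genes)} genes, clustering {coeffs[node]:.2f})")
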