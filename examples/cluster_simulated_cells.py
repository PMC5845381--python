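"""Cluster a simulated expression matrix with planted cell types.

Three types, each with 8 strong marker genes. The pipeline log-transforms
the counts, builds a correlation-distance dendrogram, splits, and cleans
up. The summary shows the per-stage adjusted Rand index against the
planted labels.
"""

import dendrosplit as ds

spec = ds.SyntheticSpec(
    n_types=3,
    cells_per_type=(40, 40, 40),
    n_genes=120,
    markers_per_type=8,
    marker_log_fold=1.5,
    dropout_rate=0.0,
    seed=1,
)
X, truth = ds.simulate_scrna(spec)

config = ds.DendroSplitConfig(split_threshold=20, merge_threshold=10)
result = ds.run_dendrosplit(X, config, truth=truth)

s = result.summary
print(f"cells x genes after preprocessing: {s['n_cells']} x {s['n_genes']}")
print(f"clusters after split step : {s['n_clusters_split']} (ARI {s['ari_split']:.3f})")
print(f"clusters after merge step : {s['n_clusters_final']} (ARI {s['ari_final']:.3f})")
print(f"cluster sizes             : {s['cluster_sizes']}")
best = result.history.records[0].genes[0]
print(f"root split justified by   : {best[0]} (log10 p = {best[1]:.1f})")
# The root split's best gene is one of the planted markers: the clustering
# decision is directly attributable to a differentially expressed gene.
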