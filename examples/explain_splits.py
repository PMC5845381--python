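"""Render the gene-level justification of every split and merge.

The history is the interpretability contract: each accepted split stores
the genes that best separate its two halves, and each merge stores the
genes that least distinguished the merged pair.
"""

import dendrosplit as ds

spec = ds.SyntheticSpec(
    n_types=3, cells_per_type=(40, 40, 40), n_genes=120,
    markers_per_type=8, marker_log_fold=1.5, dropout_rate=0.0, seed=2,
)
X, truth = ds.simulate_scrna(spec)
result = ds.run_dendrosplit(
    X, ds.DendroSplitConfig(split_threshold=20, merge_threshold=10)
)

print("== split step ==")
for rec in result.history.records:
    line = f"{rec.name:8s} [{rec.decision}] n={len(rec.member_cells)}"
    if rec.score is not None:
        line += f" score={rec.score:.3g}"
    if rec.genes:
        g, lp, t = rec.genes[0]
        line += f"  best gene: {g} (log10 p={lp:.3g}, t={t:.3g})"
    print(line)

print("== merge step ==")
if not result.merge_records:
    print("(no merges: every cluster pair is separated above the threshold)")
for m in result.merge_records:
    print(f"{m.cluster_a} + {m.cluster_b} -> {m.result_name} "
          f"score={m.score:.3g} best gene: {m.best_gene}")
# Cluster names encode dendrogram position: "rRL" is the left child of the
# right child of the root.
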