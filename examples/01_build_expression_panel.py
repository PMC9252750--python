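"""Build a cell-type expression panel from single-cell UMI counts.

Generates a designed single-cell fixture in which every construction
rule fires — a plain cluster, two same-labeled clusters that must be
merged, an undersized cluster, an unlabeled cluster, a diseased sample
and a shallowly sequenced cluster — then filters and aggregates it.
"""

import dese

config = dese.SimulationConfig(seed=1)
counts, annotation, manifest = dese.simulate_sc_counts(config)
print(f"raw matrix: {counts.values.shape[0]} genes x {counts.values.shape[1]} cells")

filtered = dese.filter_cells(counts, min_umi=300)
print(f"after UMI filter (>= 300): {filtered.values.shape[1]} cells")

panel = dese.pseudobulk_clusters(filtered, annotation, min_cells=15, top_fraction=0.10)
print(f"surviving cell-type columns: {panel.columns}")
print(f"designed survivors:         {manifest['expected_columns']}")
print(f"column totals (CPM): {panel.values.sum(axis=0).round(3).tolist()}")

# The surviving columns are the clusters that kept >= 15 adequately
# sequenced, labeled, healthy cells after merging same-labeled clusters;
# each column is a CPM profile (sums to 1e6) of its top-10%-depth cells.
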