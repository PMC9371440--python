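"""Link cell states across time windows into a lineage DAG.

Cells are split into non-overlapping 2-h windows by age, clustered per
window, and clusters of adjacent windows are connected by the median
proportion of nearest parent-window neighbours per parent state; per
child only the strongest edge above 0.2 survives.
"""

import numpy as np
import pandas as pd

import embryochron as ec

tree = ec.binary_lineage_tree((1, 2, 4, 5), (0.0, 2.0, 4.0, 6.0, 8.0))
cfg = ec.AtlasConfig(
    windows=[ec.CollectionWindow(i, 2.0 * i, 2.0 * i + 2) for i in range(4)],
    cells_per_window_rna=500, cells_per_window_atac=10, n_genes=300,
    n_background_peaks=20, lineage_tree=tree, lineage_marker_frac=0.5,
    contamination_rate=0.0, contaminated_windows=(), max_age_h=8.0,
    onset_range_h=(0.5, 7.0))
atlas = ec.simulate_atlas(cfg, seed=11)

X = atlas.rna.X
ages = atlas.rna.obs["true_age_h"].to_numpy()
win = ec.window_partition(ages, 2.0, 8.0)

labels = {}
for w in range(4):
    idx = np.flatnonzero(win == w)
    labels[w] = (idx, ec.cluster_window(X[idx], "rna", n_components=20, seed=0))

tables = {}
for w in range(3):
    ip, lp = labels[w]
    ic, lc = labels[w + 1]
    ep, ech = ec.coembed_adjacent(X[ip], X[ic], "rna", seed=0)
    tables[(w, w + 1)] = ec.link_edge_weights(ep, ech, lp, lc, k_neighbors=30)

dag = ec.build_lineage_dag(tables, threshold=0.2)
print(f"DAG: {dag.number_of_nodes()} states, {dag.number_of_edges()} edges "
      f"(planted tree has {tree.n_states} states, {len(tree.edges())} edges)")
edges = pd.DataFrame(
    [(p, c, round(d['weight'], 2)) for p, c, d in dag.edges(data=True)],
    columns=["parent (window, cluster)", "child", "weight"])
print(edges.to_string(index=False))
# Each edge says: the child state's cells sit, in the joint embedding,
# nearest to cells of that parent state — a state-level ancestry call.
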