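"""Simulate a small staged-collection embryo atlas and look inside it.

Cells are drawn from 11 overlapping collection windows spanning 0-20 h;
each carries a latent true age, a lineage state from a planted branching
tree, and sparse RNA/ATAC counts driven by maternal / zygotic / transient /
constant gene kinetics.
"""

import numpy as np

import embryochron as ec

cfg = ec.AtlasConfig(cells_per_window_rna=300, cells_per_window_atac=150,
                     n_genes=200, n_background_peaks=80)
atlas = ec.simulate_atlas(cfg, seed=1)

lib = np.asarray(atlas.rna.X.sum(axis=1)).ravel()
print(f"RNA: {atlas.rna.n_obs} cells x {atlas.rna.n_vars} genes, "
      f"median {np.median(lib):.0f} UMIs/cell")
lib_a = np.asarray(atlas.atac.X.sum(axis=1)).ravel()
print(f"ATAC: {atlas.atac.n_obs} cells x {atlas.atac.n_vars} peaks, "
      f"median {np.median(lib_a):.0f} reads/cell")
print(f"windows: {[(w.start_h, w.end_h) for w in atlas.windows]}")
print(atlas.rna.var["class"].value_counts().to_string())
w0 = atlas.rna.obs.query("window_index == 0")
print(f"planted old-embryo contamination in 0-2 h window: "
      f"{w0.is_contaminant.mean():.1%} of {len(w0)} cells")
# The kinetic classes above drive every downstream analysis; the window
# label is the only age supervision a model will ever see.
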