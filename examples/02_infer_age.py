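"""Infer absolute nuclear age from window-center supervision.

Trains a lasso regressor to predict each nucleus's collection-window
center hour from its normalized expression profile, calibrates the
window means, and evaluates on a held-out partition.
"""

import numpy as np

import embryochron as ec

cfg = ec.AtlasConfig(cells_per_window_rna=400, cells_per_window_atac=50,
                     n_genes=300)
atlas = ec.simulate_atlas(cfg, seed=1)
obs, X = atlas.rna.obs, atlas.rna.X
ids = list(atlas.rna.var_names)
centers = {w.index: w.center_h for w in atlas.windows}
y = obs["window_index"].map(centers).to_numpy()
widx = obs["window_index"].to_numpy()

parts = ec.partition_cells(widx, 11, seed=1)
train, test = parts != 10, parts == 10
feats = ec.select_time_features(X[train], ids, y[train], 150)
cols = [ids.index(f) for f in feats]

model = ec.fit_lasso_age(X[train][:, cols], feats, y[train], widx[train],
                         atlas.windows, n_folds=5, seed=1)
model = ec.calibrate_age_model(model, X[train][:, cols], feats, widx[train])

pred = ec.predict_age(model, X[test][:, cols], feats)
wins = [atlas.windows[w] for w in widx[test]]
metrics = ec.evaluate_age(pred, wins)
baseline = ec.evaluate_age(np.full(test.sum(), y[train].mean()), wins)
print(f"held-out MSE {metrics.mse:.2f} h^2 "
      f"(mean-age baseline {baseline.mse:.2f} h^2)")
print(f"proportion of predictions inside their collection window: "
      f"{metrics.proportion_correct:.2f}")
# An informative model should shrink MSE far below the baseline and put
# most predictions back inside the (2-4 h wide) window they came from.

# sex from the chrX read fraction
labels, params = ec.classify_sex_gmm(obs["chrX_fraction"].to_numpy(), seed=1)
acc = (labels == obs["sex"].to_numpy()).mean()
print(f"chrX-fraction sex classification accuracy: {acc:.3f} "
      f"(component means {np.round(params['means'], 4)})")
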