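"""Planted-truth validation experiments.

Each function simulates a synthetic atlas (or targeted scenario) with
known ground truth, runs the corresponding pipeline stage end to end, and
returns the recovery metrics as a plain dict.  They are the package's
self-validation: the same experiments back the acceptance tests and the
reproduction script.

Problem sizes are chosen to finish in minutes on one CPU while leaving
enough cells/genes for the statistics to be stable; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from . import age as _age
from . import chrono as _chrono
from . import lineage as _lineage
from . import multiome as _multiome
from . import simulate as _sim
from . import tf_activity as _tf
from . import timewarp as _tw


def _fit_both_models(atlas, n_features: int, n_folds: int, seed: int,
                     calibrate: bool = True):
    obs, X = atlas.rna.obs, atlas.rna.X
    ids = list(atlas.rna.var_names)
    centers = {w.index: w.center_h for w in atlas.windows}
    y = obs["window_index"].map(centers).to_numpy()
    widx = obs["window_index"].to_numpy()
    parts = _age.partition_cells(widx, 11, seed=seed)
    train, test = parts != 10, parts == 10
    feats = _age.select_time_features(X[train], ids, y[train], n_features)
    cols = [ids.index(f) for f in feats]
    models = {}
    for kind, fit in (("lasso", _age.fit_lasso_age), ("nn", _age.fit_nn_age)):
        m = fit(X[train][:, cols], feats, y[train], widx[train], atlas.windows,
                n_folds=n_folds, seed=seed)
        if calibrate:
            m = _age.calibrate_age_model(m, X[train][:, cols], feats,
                                         widx[train])
        models[kind] = m
    return models, feats, cols, y, widx, train, test


def age_recovery_benchmark(seed: int = 1, cells_per_window: int = 1820,
                           n_features: int = 300, n_folds: int = 10) -> dict:
    """Held-out age recovery on the default 11-window atlas.

    Trains lasso and NN regressors on 10 of 11 window-balanced partitions
    and evaluates on the 11th: MSE relative to the mean-age baseline,
    proportion of predictions inside their collection window, per-window
    calibration, and recovery of the planted old-embryo contamination of
    the 0-2 h window.
    """
    cfg = _sim.AtlasConfig(cells_per_window_rna=cells_per_window,
                           cells_per_window_atac=50)
    atlas = _sim.simulate_atlas(cfg, seed=seed)
    models, feats, cols, y, widx, train, test = _fit_both_models(
        atlas, n_features, n_folds, seed)
    X = atlas.rna.X
    wins = [atlas.windows[w] for w in widx[test]]
    base = _age.evaluate_age(np.full(int(test.sum()), y[train].mean()), wins)
    out = {"n_cells": int(atlas.rna.n_obs), "baseline_mse": base.mse}
    for kind, model in models.items():
        pred = _age.predict_age(model, X[test][:, cols], feats)
        m = _age.evaluate_age(pred, wins)
        out[f"{kind}_mse"] = m.mse
        out[f"{kind}_mse_ratio"] = m.mse / base.mse
        out[f"{kind}_proportion_correct"] = m.proportion_correct
        out[f"{kind}_max_abs_window_error_h"] = \
            float(m.per_window_mean_error.abs().max())
    # contamination of the earliest window, NN model over all its cells
    w0 = widx == 0
    pred0 = _age.predict_age(models["nn"], X[w0][:, cols], feats)
    out["contamination_estimate"] = _age.contamination_fraction(pred0, 4.0)
    out["contamination_planted"] = float(cfg.contamination_rate)
    true0 = atlas.rna.obs["true_age_h"].to_numpy()[w0]
    out["contamination_true_ge_4h"] = float(np.mean(true0 >= 4.0))
    return out


def nonlinear_model_comparison(seed: int = 5, cells_per_window: int = 900,
                               n_features: int = 200, n_folds: int = 10) -> dict:
    """NN vs lasso on purely logistic/pulse (switch-like) kinetics."""
    rng = np.random.default_rng(seed)
    kin = [_sim.KineticParams(f"z{i:03d}", "zygotic",
                              onset_h=float(rng.uniform(1, 17)),
                              rate=float(rng.uniform(2.0, 4.0)),
                              amplitude=float(rng.lognormal(0, 0.6)))
           for i in range(150)]
    kin += [_sim.KineticParams(f"t{i:03d}", "transient",
                               onset_h=float(rng.uniform(1, 18)),
                               rate=float(rng.uniform(0.8, 2.0)),
                               amplitude=float(rng.lognormal(0, 0.6)))
            for i in range(150)]
    cfg = _sim.AtlasConfig(cells_per_window_rna=cells_per_window,
                           cells_per_window_atac=10, kinetics=kin,
                           n_background_peaks=10,
                           lineage_tree=_sim.binary_lineage_tree((1,), (0.0, 20.0)),
                           contamination_rate=0.0, contaminated_windows=())
    atlas = _sim.simulate_atlas(cfg, seed=seed)
    models, feats, cols, y, widx, train, test = _fit_both_models(
        atlas, n_features, n_folds, seed, calibrate=False)
    X = atlas.rna.X
    wins = [atlas.windows[w] for w in widx[test]]
    out = {"n_cells": int(atlas.rna.n_obs)}
    for kind, model in models.items():
        pred = _age.predict_age(model, X[test][:, cols], feats)
        out[f"{kind}_mse"] = _age.evaluate_age(pred, wins).mse
    return out


def zga_pioneer_benchmark(seed: int = 2, n_zga_genes: int = 50,
                          n_rna_cells: int = 15000,
                          n_atac_cells: int = 12000) -> dict:
    """ZGA onset ordering (5-min bins) and pioneer lead (1-min bins).

    Plants ``n_zga_genes`` zygotic genes with distinct onsets in
    [0.5, 2] h over a 0-3 h collection, on top of a constant maternal-like
    pool that keeps per-cell totals stable; alternating genes carry a
    0.5 h accessibility lead at their linked regions.
    """
    onsets = np.linspace(0.5, 2.0, n_zga_genes)
    kin = [_sim.KineticParams(f"g{i:04d}", "zygotic", onset_h=float(t),
                              rate=6.0, amplitude=2.0,
                              access_lead_h=0.5 if i % 2 == 0 else 0.0)
           for i, t in enumerate(onsets)]
    kin += [_sim.KineticParams(f"bg{i:03d}", "constant", amplitude=4.0)
            for i in range(2 * n_zga_genes)]
    cfg = _sim.AtlasConfig(windows=[_sim.CollectionWindow(0, 0.0, 3.0)],
                           cells_per_window_rna=n_rna_cells,
                           cells_per_window_atac=n_atac_cells,
                           kinetics=kin, n_background_peaks=300,
                           lineage_tree=_sim.binary_lineage_tree((1,), (0.0, 20.0)),
                           contamination_rate=0.0, contaminated_windows=())
    atlas = _sim.simulate_atlas(cfg, seed=seed)
    ids = list(atlas.rna.var_names)

    ages = atlas.rna.obs["true_age_h"].to_numpy()
    bins5 = _chrono.fine_bins(ages, 5.0, (0.0, 3.0))
    prof = _chrono.smooth_profile(
        _chrono.pseudobulk_profile(atlas.rna.X, ids, bins5, 5.0, (0.0, 3.0)), 5)
    est = [_chrono.onset_time(prof.values[i], prof.bin_edges)
           for i in range(n_zga_genes)]
    rho = float(spearmanr(onsets, est).statistic)

    ages_a = atlas.atac.obs["true_age_h"].to_numpy()
    act = _chrono.smooth_profile(
        _chrono.aggregate_region_accessibility(
            atlas.atac.X, list(atlas.atac.var_names), atlas.gene_regions,
            _chrono.fine_bins(ages_a, 1.0, (0.0, 3.0)), 1.0, (0.0, 3.0)), 9)
    expr1 = _chrono.smooth_profile(
        _chrono.pseudobulk_profile(atlas.rna.X, ids,
                                   _chrono.fine_bins(ages, 1.0, (0.0, 3.0)),
                                   1.0, (0.0, 3.0)), 9)
    gpos = {g: i for i, g in enumerate(expr1.feature_ids)}
    apos = {g: i for i, g in enumerate(act.feature_ids)}
    leads, zero_leads = [], []
    for k in kin[:n_zga_genes]:
        eo = _chrono.onset_time(expr1.values[gpos[k.feature_id]], expr1.bin_edges)
        ao = _chrono.onset_time(act.values[apos[k.feature_id]], act.bin_edges)
        (leads if k.access_lead_h > 0 else zero_leads).append(eo - ao)
    return {"n_zga_genes": n_zga_genes,
            "onset_spearman": rho,
            "pioneer_median_lead_h": float(np.median(leads)),
            "zero_lead_median_h": float(np.median(zero_leads)),
            "planted_lead_h": 0.5}


def lineage_recovery_benchmark(seed: int = 11, cells_per_window: int = 600,
                               k_neighbors: int = 30,
                               threshold: float = 0.2) -> dict:
    """Recovery of a planted 12-state lineage tree over four 2-h windows.

    Clusters each window, links adjacent windows by median
    nearest-neighbour proportions, thresholds at 0.2, and scores the
    state-level edge set (clusters mapped to their majority planted
    state) against the tree.
    """
    tree = _sim.binary_lineage_tree((1, 2, 4, 5), (0.0, 2.0, 4.0, 6.0, 8.0))
    windows = [_sim.CollectionWindow(i, 2.0 * i, 2.0 * i + 2) for i in range(4)]
    cfg = _sim.AtlasConfig(windows=windows, cells_per_window_rna=cells_per_window,
                           cells_per_window_atac=10, n_genes=400,
                           n_background_peaks=20, lineage_tree=tree,
                           lineage_marker_frac=0.5, contamination_rate=0.0,
                           contaminated_windows=(), max_age_h=8.0,
                           onset_range_h=(0.5, 7.0))
    atlas = _sim.simulate_atlas(cfg, seed=seed)
    X = atlas.rna.X
    obs = atlas.rna.obs
    win = _lineage.window_partition(obs["true_age_h"].to_numpy(), 2.0, 8.0)
    labels = {}
    for w in range(4):
        idx = np.flatnonzero(win == w)
        labels[w] = (idx, _lineage.cluster_window(X[idx], "rna",
                                                  n_components=20, seed=seed))
    tables = {}
    for w in range(3):
        ip, lp = labels[w]
        ic, lc = labels[w + 1]
        ep, ech = _lineage.coembed_adjacent(X[ip], X[ic], "rna", seed=seed)
        tables[(w, w + 1)] = _lineage.link_edge_weights(
            ep, ech, lp, lc, k_neighbors=k_neighbors)
    dag = _lineage.build_lineage_dag(tables, threshold)

    state_of = {}
    lin = obs["lineage"].to_numpy()
    for w in range(4):
        idx, lab = labels[w]
        for c in np.unique(lab):
            vals, cnt = np.unique(lin[idx][lab == c], return_counts=True)
            state_of[(w, c)] = vals[cnt.argmax()]
    true_edges = set(tree.edges())
    pred = [(state_of[p], state_of[c]) for p, c in dag.edges()]
    tp = sum(e in true_edges for e in pred)
    import networkx as nx
    return {"n_states_planted": tree.n_states,
            "n_edges_planted": len(true_edges),
            "n_edges_predicted": len(pred),
            "edge_precision": tp / len(pred) if pred else 0.0,
            "edge_recall": len({e for e in pred if e in true_edges})
            / len(true_edges),
            "max_in_degree": max((dag.in_degree(n) for n in dag.nodes),
                                 default=0),
            "is_acyclic": bool(nx.is_directed_acyclic_graph(dag))}


def nnls_linkage_benchmark(seed: int = 6, n_pairs: int = 10,
                           threshold: float = 0.1) -> dict:
    """Recovery of planted matched RNA/ATAC cluster pairs by NNLS."""
    rna, act = _sim.simulate_matched_cluster_profiles(n_pairs=n_pairs,
                                                      noise_sd=0.05, seed=seed)
    coef_r, _ = _multiome.nnls_decompose(rna, act)
    coef_a, _ = _multiome.nnls_decompose(act, rna)
    links = _multiome.link_clusters(coef_r, coef_a, threshold)
    partners = _multiome.best_partners(links)
    correct = sum(partners[f"rna_c{i}"] == f"atac_c{i}" for i in range(n_pairs))
    linked = links[links.linked]
    false = int(sum(a[6:] != r[5:] for a, r in
                    zip(linked.atac_cluster, linked.rna_cluster)))
    return {"n_pairs": n_pairs,
            "correct_best_partners": int(correct),
            "false_links": false,
            "linked_pairs": int(len(linked))}


def tf_model_benchmark(seed: int = 6, n_null_replicates: int = 100) -> dict:
    """Sign recovery for planted activators/repressors, exactness of the
    consecutive-window filter, and the null false-flag rate."""
    sc = _sim.simulate_tf_scenario(n_activators=5, n_repressors=5, n_null=10,
                                   n_windows=9, seed=seed)
    truth = sc["truth"]
    pairs = [(c, c) for c in sc["clusters"].index]
    corr = _tf.expr_motif_correlation(pairs, sc["expression"], sc["deviation"])
    act = corr[truth.role == "activator"]
    rep = corr[truth.role == "repressor"]
    signs_ok = int((act > 0).sum() + (rep < 0).sum())
    table = _tf.germlayer_time_model(sc["deviation"], sc["expression"],
                                     sc["clusters"])
    runs = _tf.consecutive_window_filter(table, 3)
    planted = {(t, r["germ_layer"], int(r["start_window"]))
               for t, r in truth.iterrows() if r["role"] != "null"}
    got = {(r["tf"], r["germ_layer"], int(r["start_window"]))
           for _, r in runs.iterrows()}

    reps_flagged = 0
    frac_flagged = []
    for rep_i in range(n_null_replicates):
        null = _sim.simulate_tf_scenario(n_activators=0, n_repressors=0,
                                         n_null=10, n_windows=9,
                                         seed=seed * 1000 + rep_i)
        t = _tf.germlayer_time_model(null["deviation"], null["expression"],
                                     null["clusters"])
        frac_flagged.append(float(t["significant"].mean()))
        if t["significant"].any():
            reps_flagged += 1
    return {"sign_recovery": signs_ok,
            "n_planted_tfs": 10,
            "activator_min_corr": float(act.min()),
            "repressor_max_corr": float(rep.max()),
            "run_filter_exact": bool(planted == got),
            "null_replicates": n_null_replicates,
            "null_flag_rate": reps_flagged / n_null_replicates,
            "null_mean_fraction_flagged": float(np.mean(frac_flagged))}


def dtw_module_benchmark(seed: int = 3, genes_per_class: int = 200) -> dict:
    """Recovery of four planted kinetic classes by DTW module clustering."""
    rng = np.random.default_rng(seed)
    centers = np.linspace(4, 20, 60)
    specs = [("maternal", 0.0), ("zygotic", 8.0), ("transient", 12.0),
             ("zygotic", 16.0)]
    rows, truth, ids = [], [], []
    for c, (klass, onset) in enumerate(specs):
        for i in range(genes_per_class):
            k = _sim.KineticParams(
                f"m{c}_g{i}", klass,
                onset_h=max(0.1, onset + rng.normal(0, 0.4)),
                rate=1.5 if klass != "maternal" else 0.3, amplitude=1.0)
            rows.append(_sim.expression_mean(k, centers)
                        + rng.normal(0, 0.05, len(centers)))
            truth.append(c)
            ids.append(k.feature_id)
    prof = pd.DataFrame(rows, index=ids, columns=centers)
    scaled = _tw.normalize_over_time(prof)
    edges = np.append(centers, centers[-1] + (centers[1] - centers[0]))
    labels, _ = _tw.dtw_cluster(scaled, k=4, bin_edges=edges)
    return {"n_genes": len(scaled),
            "module_ari": float(adjusted_rand_score(truth, labels.to_numpy())),
            "module_sizes": labels.value_counts().sort_index().tolist()}
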