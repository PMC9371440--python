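"""TF motif-activity modeling across clusters, germ layers and time.

Motif deviations are a simplified chromVAR-style statistic: for each TF
motif and cluster, the observed fraction of the cluster's reads falling in
motif-hit peaks is compared with the expectation under the all-cluster
mean profile, and the relative deviation is z-scored against random peak
sets matched on mean-accessibility decile.  Deviations are then related to
TF expression over linked RNA/ATAC cluster pairs (activators correlate
positively, repressors negatively), and a per-window interaction model
nominates the germ layer and time window in which a TF becomes active.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SIGNIFICANCE_ALPHA = 1e-3


@dataclass
class DeviationMatrix:
    """TF x cluster accessibility-deviation z-scores."""

    values: pd.DataFrame
    background: dict = field(default_factory=dict)


def motif_deviation(cluster_peak_counts: pd.DataFrame, motif_hits: pd.DataFrame,
                    n_background: int = 50, seed: int = 0) -> DeviationMatrix:
    """Background-normalized motif accessibility deviations.

    Parameters
    ----------
    cluster_peak_counts : clusters x peaks raw read sums
    motif_hits : peaks x TFs binary table (same peak universe)
    n_background : random accessibility-matched peak sets for z-scoring

    A motif hitting every peak deviates by exactly 0 in every cluster.
    Motifs with zero hit peaks are dropped with a warning.
    """
    C = cluster_peak_counts.to_numpy(dtype=float)
    peaks = list(cluster_peak_counts.columns)
    hits = motif_hits.reindex(peaks).fillna(0).to_numpy() > 0
    cluster_totals = C.sum(axis=1)
    if np.any(cluster_totals == 0):
        raise ValueError("cluster with zero reads")
    grand = C.sum(axis=0)
    pbar = grand / grand.sum()                     # mean profile over peaks

    deciles = pd.qcut(pd.Series(pbar).rank(method="first"), 10,
                      labels=False).to_numpy()
    rng = np.random.default_rng(seed)
    obs_frac = C / cluster_totals[:, None]         # clusters x peaks

    def raw_dev(mask: np.ndarray) -> np.ndarray:
        exp = pbar[mask].sum()
        if exp == 0:
            return np.full(C.shape[0], np.nan)
        obs = obs_frac[:, mask].sum(axis=1)
        return (obs - exp) / exp

    tf_rows, tf_ids = [], []
    for tf in motif_hits.columns:
        mask = hits[:, motif_hits.columns.get_loc(tf)]
        if not mask.any():
            warnings.warn(f"motif {tf!r} hits no peaks; dropped")
            continue
        raw = raw_dev(mask)
        counts_per_decile = np.bincount(deciles[mask], minlength=10)
        bg = np.empty((n_background, C.shape[0]))
        for b in range(n_background):
            sel = np.zeros(len(peaks), dtype=bool)
            for dec in range(10):
                need = counts_per_decile[dec]
                if need == 0:
                    continue
                pool = np.flatnonzero(deciles == dec)
                sel[rng.choice(pool, size=need, replace=False)] = True
            bg[b] = raw_dev(sel)
        mu, sd = bg.mean(axis=0), bg.std(axis=0, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (raw - mu) / sd
        z[~np.isfinite(z)] = 0.0
        tf_rows.append(z)
        tf_ids.append(tf)
    values = pd.DataFrame(tf_rows, index=pd.Index(tf_ids, name="tf"),
                          columns=cluster_peak_counts.index)
    return DeviationMatrix(values=values,
                           background={"n_background": n_background,
                                       "matching": "mean-accessibility decile",
                                       "seed": seed})


def top_variable_motifs(deviations: pd.DataFrame, n: int) -> list[str]:
    """The n motifs with highest deviation variance across clusters."""
    if n > len(deviations):
        raise ValueError("n exceeds the number of TFs")
    var = deviations.var(axis=1)
    order = sorted(deviations.index, key=lambda t: (-var[t], t))
    return order[:n]


def expr_motif_correlation(linked_pairs: list[tuple], expression: pd.DataFrame,
                           deviations: pd.DataFrame,
                           method: str = "pearson") -> pd.Series:
    """Correlate each TF's expression with its motif deviation over linked
    cluster pairs.

    ``linked_pairs`` is a list of (rna_cluster, atac_cluster);
    ``expression`` is TFs x RNA clusters, ``deviations`` TFs x ATAC
    clusters.  TFs with zero expression variance across the pairs get NaN.
    """
    if len(linked_pairs) < 3:
        raise ValueError("need at least 3 linked pairs")
    rna_cols = [p[0] for p in linked_pairs]
    atac_cols = [p[1] for p in linked_pairs]
    out = {}
    for tf in deviations.index:
        if tf not in expression.index:
            out[tf] = np.nan
            continue
        x = expression.loc[tf, rna_cols].to_numpy(dtype=float)
        y = deviations.loc[tf, atac_cols].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            out[tf] = np.nan
            continue
        if method == "pearson":
            out[tf] = float(stats.pearsonr(x, y)[0])
        elif method == "spearman":
            out[tf] = float(stats.spearmanr(x, y)[0])
        else:
            raise ValueError(f"unknown method {method!r}")
    return pd.Series(out, name=f"{method}_r")


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (FDR)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def _ols_interaction(dev: np.ndarray, expr: np.ndarray, in_layer: np.ndarray):
    """OLS of deviation on [1, expr, expr * 1(layer)]; returns the
    interaction estimate and its two-sided p, or None if singular."""
    X = np.column_stack([np.ones_like(expr), expr, expr * in_layer])
    if np.linalg.matrix_rank(X) < X.shape[1] or len(dev) <= X.shape[1]:
        return None
    beta, res, *_ = np.linalg.lstsq(X, dev, rcond=None)
    fitted = X @ beta
    dof = len(dev) - X.shape[1]
    s2 = float(((dev - fitted) ** 2).sum() / dof)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(s2 * XtX_inv[2, 2])
    if se == 0:
        p = 0.0 if beta[2] != 0 else 1.0
    else:
        t = beta[2] / se
        p = float(2 * stats.t.sf(abs(t), dof))
    return float(beta[2]), p


def germlayer_time_model(deviations: pd.DataFrame, expression: pd.DataFrame,
                         cluster_meta: pd.DataFrame,
                         alpha: float = SIGNIFICANCE_ALPHA,
                         min_clusters_per_window: int = 4) -> pd.DataFrame:
    """Per (TF, germ layer, window) interaction effects with joint BH.

    For each window with enough clusters and >= 2 germ layers, each TF's
    motif deviation across that window's clusters is regressed on its
    expression plus an expression x layer-membership interaction; the
    interaction coefficient is the layer-and-time-specific activity
    effect.  BH correction is applied once over all tests; significance is
    adjusted p < ``alpha``.

    ``cluster_meta`` must carry 'window' and 'germ_layer' per cluster id;
    both deviations and expression are TFs x clusters on those ids.
    """
    if cluster_meta["germ_layer"].nunique() < 2:
        raise ValueError("need >= 2 germ layers")
    rows = []
    for w in sorted(cluster_meta["window"].unique()):
        cl = cluster_meta.index[cluster_meta["window"] == w]
        cl = cl.intersection(deviations.columns).intersection(expression.columns)
        layers = cluster_meta.loc[cl, "germ_layer"]
        if len(cl) < min_clusters_per_window or layers.nunique() < 2:
            continue
        for tf in deviations.index:
            if tf not in expression.index:
                continue
            dev = deviations.loc[tf, cl].to_numpy(dtype=float)
            expr = expression.loc[tf, cl].to_numpy(dtype=float)
            for g in sorted(layers.unique()):
                in_layer = (layers == g).to_numpy(dtype=float)
                if in_layer.all() or not in_layer.any():
                    continue
                fit = _ols_interaction(dev, expr, in_layer)
                if fit is None:
                    rows.append((tf, g, int(w), np.nan, np.nan, "singular design"))
                    continue
                effect, p = fit
                rows.append((tf, g, int(w), effect, p, ""))
    table = pd.DataFrame(rows, columns=["tf", "germ_layer", "window", "effect",
                                        "p", "note"])
    table["p_adj"] = np.nan
    tested = table["p"].notna()
    if tested.any():
        table.loc[tested, "p_adj"] = benjamini_hochberg(table.loc[tested, "p"])
    table["significant"] = table["p_adj"] < alpha
    table["sign"] = np.sign(table["effect"]).fillna(0).astype(int)
    return table


def consecutive_window_filter(effects: pd.DataFrame, min_run: int = 3
                              ) -> pd.DataFrame:
    """Keep (TF, layer) pairs with >= min_run consecutive significant,
    sign-consistent windows; report each run's start window (the window
    from which the TF initiates its activity)."""
    out = []
    for (tf, g), grp in effects.groupby(["tf", "germ_layer"]):
        grp = grp.sort_values("window")
        run: list[tuple[int, int]] = []
        best = None
        for _, r in grp.iterrows():
            w, sig, sgn = int(r["window"]), bool(r["significant"]), int(r["sign"])
            if sig and sgn != 0 and (not run or (w == run[-1][0] + 1
                                                 and sgn == run[-1][1])):
                run.append((w, sgn))
            elif sig and sgn != 0:
                run = [(w, sgn)]
            else:
                run = []
            if len(run) >= min_run and (best is None or len(run) > best[2]):
                best = (run[0][0], run[0][1], len(run))
        if best is not None:
            out.append((tf, g, best[0], best[2], best[1]))
    return pd.DataFrame(out, columns=["tf", "germ_layer", "start_window",
                                      "run_length", "sign"])
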