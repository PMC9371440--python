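"""Temporal gene modules by dynamic time warping.

Lineage-restricted genes are clustered into successive waves of expression:
profiles over inferred-time bins are min-max scaled, pairwise DTW distances
are computed (classic dynamic program, absolute-difference local cost,
unit match/insert/delete steps), and average-linkage hierarchical
clustering cut at k groups yields modules ordered by onset.  A companion
lag estimator compares expression against accessibility-derived gene
activity to detect pioneer-style "chromatin opens first" behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .chrono import onset_time


def select_variable_genes(profiles: pd.DataFrame, n: int) -> list[str]:
    """The n genes with highest profile variance across time bins
    (ties broken by gene id)."""
    if n > len(profiles):
        raise ValueError("n exceeds the number of genes")
    var = profiles.var(axis=1)
    order = sorted(profiles.index, key=lambda g: (-var[g], g))
    return order[:n]


def normalize_over_time(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-gene min-max scaling to [0, 1]; zero-range genes are dropped."""
    lo = profiles.min(axis=1)
    hi = profiles.max(axis=1)
    rng = hi - lo
    flat = rng == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant gene(s) dropped")
    kept = profiles.loc[~flat]
    return kept.sub(lo[~flat], axis=0).div(rng[~flat], axis=0)


@njit(cache=True)
def _dtw_dp(x: np.ndarray, y: np.ndarray, band: int) -> float:
    n, m = len(x), len(y)
    INF = 1e300
    D = np.full((n + 1, m + 1), INF)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        jlo, jhi = 1, m
        if band > 0:
            jlo = max(1, i - band)
            jhi = min(m, i + band)
        for j in range(jlo, jhi + 1):
            cost = abs(x[i - 1] - y[j - 1])
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = cost + best
    return D[n, m]


def dtw_distance(x, y, band: int | None = None) -> float:
    """Classic DTW distance with absolute-difference local cost.

    Unit steps (match / insert / delete), no warping-band constraint by
    default (``band`` enables a Sakoe-Chiba band of that half-width).
    Symmetric in its arguments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("series must be nonempty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series must be finite")
    return float(_dtw_dp(x, y, -1 if band is None else int(band)))


def dtw_distance_matrix(profiles: np.ndarray, band: int | None = None) -> np.ndarray:
    """Condensed pairwise DTW distances over profile rows."""
    P = np.ascontiguousarray(profiles, dtype=float)
    n = P.shape[0]
    out = np.empty(n * (n - 1) // 2)
    b = -1 if band is None else int(band)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            out[idx] = _dtw_dp(P[i], P[j], b)
            idx += 1
    return out


@dataclass
class TemporalModule:
    """One temporal wave of gene expression (modules ordered by onset)."""

    module_id: int
    members: list[str]
    mean_curve: np.ndarray


def dtw_cluster(scaled: pd.DataFrame, k: int = 4, bin_edges=None,
                band: int | str | None = "auto"
                ) -> tuple[pd.Series, list[TemporalModule]]:
    """Average-linkage hierarchical clustering of DTW distances, cut at k.

    ``band="auto"`` (default) applies a Sakoe-Chiba band of 10% of the
    series length: unbounded warping makes DTW nearly blind to pure time
    shifts between monotone curves, whereas successive expression waves
    differ precisely in timing, so warping is restricted to local
    stretches.  Pass ``band=None`` for unconstrained DTW.

    Module ids 1..k follow ascending median onset (half-max crossing of
    the scaled profile), so module 1 is the earliest expression wave.
    Returns (labels per gene, list of TemporalModule).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(scaled):
        raise ValueError("k exceeds the number of genes")
    edges = (np.asarray(bin_edges, dtype=float) if bin_edges is not None
             else np.arange(scaled.shape[1] + 1, dtype=float))
    if band == "auto":
        band = max(1, scaled.shape[1] // 10)
    cond = dtw_distance_matrix(scaled.to_numpy(), band=band)
    Z = linkage(cond, method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    onsets = {}
    for c in np.unique(raw):
        members = np.flatnonzero(raw == c)
        onsets[c] = float(np.median([onset_time(scaled.iloc[m].to_numpy(), edges)
                                     for m in members]))
    order = sorted(onsets, key=lambda c: (onsets[c], c))
    relabel = {c: rank + 1 for rank, c in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=scaled.index,
                       name="module")
    modules = [TemporalModule(m, list(labels.index[labels == m]),
                              scaled.loc[labels == m].mean(axis=0).to_numpy())
               for m in range(1, len(order) + 1)]
    return labels, modules


def module_summary(scaled: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-module mean curve (modules x bins)."""
    if labels.empty:
        raise ValueError("no modules")
    return scaled.groupby(labels).mean()


def equal_count_bins(ages_h: np.ndarray, values: np.ndarray, n_bins: int):
    """Average ``values`` within n_bins equal-count partitions of age order.

    Returns (bin_mean_age, bin_mean_value).
    """
    ages = np.asarray(ages_h, dtype=float)
    vals = np.asarray(values, dtype=float)
    if len(ages) < n_bins:
        raise ValueError("fewer cells than bins")
    order = np.argsort(ages, kind="stable")
    splits = np.array_split(order, n_bins)
    return (np.array([ages[s].mean() for s in splits]),
            np.array([vals[s].mean() for s in splits]))


def lag_compare(expr_curve: np.ndarray, activity_curve: np.ndarray,
                bin_width_h: float, max_shift: int | None = None,
                min_corr: float = 0.5):
    """Timing lag between expression and accessibility-derived activity.

    Both curves (same uniform-ish grid) are min-max scaled; the lag is the
    cross-correlation argmax over integer shifts, in hours.  Positive lag
    means accessibility precedes expression (pioneer-style), negative that
    expression leads.  Returns (lag_h, peak_correlation, low_confidence)
    where ``low_confidence`` flags a peak correlation below ``min_corr``
    (e.g. anti-correlated curves).
    """
    e = np.asarray(expr_curve, dtype=float)
    a = np.asarray(activity_curve, dtype=float)
    if e.shape != a.shape or e.ndim != 1:
        raise ValueError("curves must be 1-D and equally long")
    if np.ptp(e) == 0 or np.ptp(a) == 0:
        raise ValueError("flat curve: lag undefined")
    e = (e - e.min()) / np.ptp(e)
    a = (a - a.min()) / np.ptp(a)
    n = len(e)
    if max_shift is None:
        max_shift = n // 2
    best_s, best_r = 0, -np.inf
    for s in range(-max_shift, max_shift + 1):
        # corr(expr[t + s], act[t]): positive s = activity earlier
        if s >= 0:
            xe, xa = e[s:], a[:n - s]
        else:
            xe, xa = e[:n + s], a[-s:]
        if len(xe) < 3 or np.std(xe) == 0 or np.std(xa) == 0:
            continue
        r = float(np.corrcoef(xe, xa)[0, 1])
        if r > best_r or (r == best_r and abs(s) < abs(best_s)):
            best_r, best_s = r, s
    return best_s * bin_width_h, best_r, bool(best_r < min_corr)


def lag_from_cells(expr_values, expr_ages, act_values, act_ages,
                   n_bins: int = 100, min_corr: float = 0.5):
    """Cell-level convenience wrapper around :func:`lag_compare`.

    Bins both modalities into ``n_bins`` equal-count partitions by
    inferred age over their shared span, min-max scales, and estimates the
    lag; the bin width used for the hour conversion is span / n_bins.
    """
    lo = max(np.min(expr_ages), np.min(act_ages))
    hi = min(np.max(expr_ages), np.max(act_ages))
    if hi <= lo:
        raise ValueError("modalities share no age span")
    em = (np.asarray(expr_ages) >= lo) & (np.asarray(expr_ages) <= hi)
    am = (np.asarray(act_ages) >= lo) & (np.asarray(act_ages) <= hi)
    _, e = equal_count_bins(np.asarray(expr_ages)[em],
                            np.asarray(expr_values)[em], n_bins)
    _, a = equal_count_bins(np.asarray(act_ages)[am],
                            np.asarray(act_values)[am], n_bins)
    return lag_compare(e, a, bin_width_h=(hi - lo) / n_bins, min_corr=min_corr)
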