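"""Fine-time pseudobulk dynamics over inferred nuclear ages.

Once every nucleus carries a predicted absolute age, cells can be pooled
into minute-scale bins (far finer than any collection window), yielding
continuous pseudobulk trajectories: the substrate for zygotic-genome-
activation ordering and pioneer-factor (accessibility-leads-expression)
analyses.  Empty fine bins are recorded as missing, never as zero — sparse
early collections routinely leave minute bins empty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans


@dataclass
class TemporalProfile:
    """feature x bin real matrix over a uniform grid of age bins.

    ``values`` may contain NaN columns (empty bins).  ``bin_edges`` has one
    more entry than there are bins.
    """

    feature_ids: list[str]
    bin_edges: np.ndarray
    values: np.ndarray
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.bin_edges) - 1):
            raise ValueError("values shape does not match features x bins")
        steps = np.diff(self.bin_edges)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError("bin_edges must be strictly increasing and uniform")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_left_h(self) -> np.ndarray:
        return self.bin_edges[:-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.bin_left_h)


def fine_bins(ages_h: np.ndarray, increment_min: float,
              range_h: tuple[float, float] = (0.0, 2.0)) -> np.ndarray:
    """Assign each cell to a fine age bin; -1 for ages outside the range.

    ``bin = floor((age - start) * 60 / increment_min)``; an age exactly at
    the range end closes into the last bin.
    """
    if increment_min <= 0:
        raise ValueError("increment_min must be positive")
    start, end = range_h
    span_min = (end - start) * 60.0
    n_bins = span_min / increment_min
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("increment must divide the range")
    n_bins = int(round(n_bins))
    ages = np.asarray(ages_h, dtype=float)
    idx = np.floor((ages - start) * 60.0 / increment_min).astype(int)
    idx[ages == end] = n_bins - 1
    idx[(ages < start) | (ages > end)] = -1
    return idx


def _bin_edges(increment_min: float, range_h: tuple[float, float]) -> np.ndarray:
    start, end = range_h
    n = int(round((end - start) * 60.0 / increment_min))
    return start + np.arange(n + 1) * increment_min / 60.0


def pseudobulk_profile(X, feature_ids, bin_index: np.ndarray,
                       increment_min: float, range_h: tuple[float, float],
                       scale: float = 1e4, pseudocount: float = 1.0,
                       log: bool = True) -> TemporalProfile:
    """Sum counts per bin, depth-normalize per bin, log-transform.

    Cells with ``bin_index < 0`` are ignored.  Bins with no member cells
    become NaN columns.
    """
    X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
    bin_index = np.asarray(bin_index)
    edges = _bin_edges(increment_min, range_h)
    n_bins = len(edges) - 1
    member = bin_index >= 0
    if not member.any():
        raise ValueError("all bins are empty")
    # bins x cells indicator, so sums are one sparse product
    rows = bin_index[member]
    cols = np.flatnonzero(member)
    ind = sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                        shape=(n_bins, X.shape[0]))
    sums = np.asarray((ind @ X).todense(), dtype=float)   # bins x features
    occupied = np.asarray(ind.sum(axis=1)).ravel() > 0
    totals = sums.sum(axis=1)
    vals = np.full_like(sums, np.nan)
    nz = occupied & (totals > 0)
    vals[nz] = sums[nz] * (scale / totals[nz])[:, None]
    vals[occupied & (totals == 0)] = 0.0
    if log:
        vals = np.log(vals + pseudocount)
    return TemporalProfile(list(feature_ids), edges, vals.T,
                           normalization={"scale": scale,
                                          "pseudocount": pseudocount, "log": log})


def smooth_profile(profile: TemporalProfile, window_bins: int = 5) -> TemporalProfile:
    """Centered moving average along bins, ignoring missing bins."""
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError("window_bins must be odd and >= 1")
    if window_bins == 1:
        return TemporalProfile(list(profile.feature_ids), profile.bin_edges.copy(),
                               profile.values.copy(), dict(profile.normalization))
    half = window_bins // 2
    v = profile.values
    out = np.full_like(v, np.nan)
    for b in range(v.shape[1]):
        lo, hi = max(0, b - half), min(v.shape[1], b + half + 1)
        window = v[:, lo:hi]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[:, b] = np.nanmean(window, axis=1)
    return TemporalProfile(list(profile.feature_ids), profile.bin_edges.copy(),
                           out, dict(profile.normalization))


def aggregate_region_accessibility(X, peak_ids, gene_regions: dict[str, list[str]],
                                   bin_index: np.ndarray, increment_min: float,
                                   range_h: tuple[float, float],
                                   scale: float = 1e4, pseudocount: float = 1.0,
                                   log: bool = True) -> TemporalProfile:
    """Per-gene accessibility: sum of member-peak normalized pseudobulk.

    Peaks are pseudobulked and depth-normalized per bin first, then summed
    within each gene's linked region set (genes with empty region sets are
    dropped with a warning); the log transform is applied after summation.
    """
    peak_profile = pseudobulk_profile(X, list(peak_ids), bin_index,
                                      increment_min, range_h, scale=scale,
                                      pseudocount=pseudocount, log=False)
    pos = {p: i for i, p in enumerate(peak_profile.feature_ids)}
    genes, rows = [], []
    for gene, regions in gene_regions.items():
        idx = [pos[p] for p in regions if p in pos]
        if not idx:
            warnings.warn(f"gene {gene!r} has no linked regions; dropped")
            continue
        genes.append(gene)
        rows.append(peak_profile.values[idx].sum(axis=0))
    if not genes:
        raise ValueError("no gene has any linked region")
    vals = np.vstack(rows)
    if log:
        vals = np.log(vals + pseudocount)
    return TemporalProfile(genes, peak_profile.bin_edges, vals,
                           normalization={"scale": scale,
                                          "pseudocount": pseudocount, "log": log})


def onset_time(values: np.ndarray, bin_edges: np.ndarray) -> float:
    """Half-max crossing: left edge of the first bin reaching half of the
    profile maximum (computed over non-missing bins)."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if not finite.any() or np.nanmax(v) <= 0:
        raise ValueError("profile has no positive maximum")
    half = np.nanmax(v) / 2.0
    idx = np.flatnonzero(finite & (v >= half))[0]
    return float(np.asarray(bin_edges)[idx])


def temporal_gene_clusters(profile: TemporalProfile, k: int, seed: int = 0,
                           smooth_window: int = 5) -> pd.Series:
    """k-means temporal clusters on smoothed, per-feature z-scored profiles.

    Cluster labels are renumbered 1..k by ascending median onset time
    (half-max crossing of the smoothed profile), so cluster 1 is the
    earliest temporal program.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(profile.feature_ids):
        raise ValueError("k exceeds number of features")
    smoothed = smooth_profile(profile, smooth_window)
    v = smoothed.values
    keep_bins = np.all(np.isfinite(v), axis=0)
    if not keep_bins.any():
        raise ValueError("no bin is observed for every feature")
    v = v[:, keep_bins]
    mu, sd = v.mean(axis=1, keepdims=True), v.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature(s); remove constant profiles")
    z = (v - mu) / sd
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(z)
    if len(np.unique(raw)) < k:
        raise ValueError("degenerate profiles: fewer than k distinct clusters")
    onsets = []
    edges = smoothed.bin_edges[:-1][keep_bins]
    full_edges = np.append(edges, edges[-1] + np.diff(profile.bin_edges)[0])
    for c in range(k):
        members = np.flatnonzero(raw == c)
        ons = [onset_time(v[m] - v[m].min() + 1e-12, full_edges) for m in members]
        onsets.append(np.median(ons))
    order = np.argsort(onsets, kind="stable")
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    return pd.Series([relabel[int(c)] for c in raw], index=profile.feature_ids,
                     name="temporal_cluster")
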