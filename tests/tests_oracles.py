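"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity by the most literal method available
(path enumeration, all-pairs distances, direct interval comparison,
dense grid search) so the optimized implementations can be checked
against them exactly.
"""

import numpy as np
import pandas as pd
import scipy.sparse as sp


def dtw_bruteforce(x, y):
    """Exhaustive enumeration of all monotone warping paths (tiny series)."""
    n, m = len(x), len(y)
    best = [np.inf]

    def walk(i, j, acc):
        acc = acc + abs(x[i] - y[j])
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def brute_force_edge_weights(parent_emb, child_emb, parent_states,
                             child_states, k):
    """All pairwise distances, explicit sort with index tie-break, manual
    median of per-cell neighbour proportions."""
    rows = []
    child_states = np.asarray(child_states)
    parent_states = np.asarray(parent_states)
    k = min(k, len(parent_emb))
    for cs in np.unique(child_states):
        members = np.flatnonzero(child_states == cs)
        props = {ps: [] for ps in np.unique(parent_states)}
        for m in members:
            d = [(float(np.linalg.norm(child_emb[m] - parent_emb[j])), j)
                 for j in range(len(parent_emb))]
            d.sort()
            labs = [parent_states[j] for _, j in d[:k]]
            for ps in props:
                props[ps].append(sum(1 for l in labs if l == ps) / k)
        for ps in props:
            rows.append((ps, cs, float(np.median(props[ps]))))
    return pd.DataFrame(rows, columns=["parent_state", "child_state",
                                       "weight"])


def bh_stepup(p):
    """Brute-force Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def naive_gene_activity(X, peaks, genes, flank_bp):
    """Per-gene interval overlap by direct pairwise comparison."""
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    out = {}
    for gid, g in genes.iterrows():
        tss = g["start"] if g["strand"] == "+" else g["end"] - 1
        regions = [(g["start"], g["end"]),
                   (max(0, tss - flank_bp), tss + flank_bp)]
        score = np.zeros(X.shape[0])
        for j, (pid, p) in enumerate(peaks.iterrows()):
            if p["chrom"] != g["chrom"]:
                continue
            if any(p["start"] < hi and p["end"] > lo for lo, hi in regions):
                score += X[:, j]
        out[gid] = score
    return out


def grid_search_simplex(target, sources, step=0.01):
    """Best mixture weights on the simplex (x best nonnegative scale)."""
    k = sources.shape[0]
    best, best_w = np.inf, None
    grid = np.arange(0.0, 1.0 + step / 2, step)
    if k == 2:
        combos = [(w, 1 - w) for w in grid]
    else:
        combos = [(w1, w2, 1 - w1 - w2) for w1 in grid
                  for w2 in grid if w1 + w2 <= 1 + 1e-12]
    for w in combos:
        m = np.asarray(w) @ sources
        denom = float(m @ m)
        c = max(0.0, float(target @ m) / denom) if denom > 0 else 0.0
        r = float(((target - c * m) ** 2).sum())
        if r < best:
            best, best_w = r, np.asarray(w)
    return best_w
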