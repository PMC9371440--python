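"""Cross-window cell-state lineage graphs.

Cells are partitioned into non-overlapping inferred-age windows, clustered
per window, and clusters of adjacent windows are linked: for every cell of
a "child" (later) window state, the proportion of its k nearest
parent-window neighbours (in a joint embedding) that belongs to each
parent state is computed, and the median of those proportions over the
child state's cells is the candidate edge weight.  Per child state only
the maximum-weight edge is retained, and only if it exceeds the threshold
(default 0.2, strict), which yields an acyclic directed graph by
construction.
"""

from __future__ import annotations

import warnings

import igraph
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA, TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .age import Preprocess

DEFAULT_EDGE_THRESHOLD = 0.2
DEFAULT_K_NEIGHBORS = 30
DEFAULT_MIN_STATE_SIZE = 20


def window_partition(ages_h: np.ndarray, width_h: float = 2.0,
                     max_age_h: float = 18.0) -> np.ndarray:
    """Non-overlapping window label per cell: floor(age / width).

    Windows are left-closed; cells older than ``max_age_h`` are excluded
    (label -1), mirroring the exclusion of predictions beyond 18 h where
    model edge effects dominate.
    """
    if width_h <= 0:
        raise ValueError("width_h must be positive")
    if abs(max_age_h / width_h - round(max_age_h / width_h)) > 1e-9:
        raise ValueError("width_h must divide max_age_h")
    ages = np.asarray(ages_h, dtype=float)
    labels = np.floor(ages / width_h).astype(int)
    labels[(ages > max_age_h) | (ages < 0)] = -1
    # ages exactly at max_age belong to the last window
    labels[ages == max_age_h] = int(round(max_age_h / width_h)) - 1
    return labels


def _reduce(X, modality: str, n_components: int, seed: int) -> np.ndarray:
    """Log-normalize + PCA for RNA-like data; binarize + TF-IDF + SVD for
    ATAC-like data."""
    n_components = min(n_components, X.shape[0] - 1, X.shape[1] - 1)
    if n_components < 1:
        raise ValueError("too few cells/features to embed")
    if modality == "rna":
        Xn = Preprocess().transform(X)
        return PCA(n_components=n_components, random_state=seed).fit_transform(Xn)
    if modality == "atac":
        B = sp.csr_matrix(X).sign().astype(float)
        tf = sp.diags(1.0 / np.maximum(np.asarray(B.sum(axis=1)).ravel(), 1.0)) @ B
        df = np.asarray(B.sum(axis=0)).ravel()
        idf = np.log(1.0 + B.shape[0] / np.maximum(df, 1.0))
        tfidf = tf @ sp.diags(idf)
        return TruncatedSVD(n_components=n_components,
                            random_state=seed).fit_transform(tfidf)
    raise ValueError(f"unknown modality {modality!r}")


def cluster_window(X, modality: str = "rna", n_components: int = 30,
                   n_neighbors: int = 15, resolution: float = 1.0,
                   seed: int = 0) -> np.ndarray:
    """Cluster one window's cells: reduction, kNN graph, modularity
    (Leiden) community detection.  Seeded and deterministic."""
    n_cells = X.shape[0]
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if n_neighbors >= n_cells:
        warnings.warn(f"n_neighbors={n_neighbors} >= {n_cells} cells; lowering")
        n_neighbors = n_cells - 1
    emb = _reduce(X, modality, n_components, seed)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx)
             for j in row[1:]}
    g = igraph.Graph(n=n_cells, edges=sorted(edges))
    part = leidenalg.find_partition(g, leidenalg.RBConfigurationVertexPartition,
                                    resolution_parameter=resolution, seed=seed)
    return np.asarray(part.membership)


def coembed_adjacent(X_parent, X_child, modality: str = "rna",
                     n_components: int = 30, seed: int = 0):
    """Jointly embed the cells of two adjacent windows.

    Returns (parent_coords, child_coords) in the shared reduced space.
    """
    if X_parent.shape[1] != X_child.shape[1]:
        raise ValueError("parent and child matrices must share a feature space")
    stack = sp.vstack if sp.issparse(X_parent) else np.vstack
    X = stack([X_parent, X_child])
    total = X.shape[0]
    if n_components >= total:
        warnings.warn(f"n_components={n_components} >= {total} cells; capping")
        n_components = total - 1
    emb = _reduce(X, modality, n_components, seed)
    return emb[:X_parent.shape[0]], emb[X_parent.shape[0]:]


def link_edge_weights(parent_emb: np.ndarray, child_emb: np.ndarray,
                      parent_states: np.ndarray, child_states: np.ndarray,
                      k_neighbors: int = DEFAULT_K_NEIGHBORS,
                      min_state_size: int = DEFAULT_MIN_STATE_SIZE
                      ) -> pd.DataFrame:
    """Median nearest-neighbour-proportion weights between adjacent windows.

    For each child cell, its ``k`` nearest parent cells (Euclidean; ties
    broken by ascending parent index) define per-parent-state proportions;
    the edge weight parent->child_state is the median proportion over the
    child state's cells.  States smaller than ``min_state_size`` (either
    side) are excluded.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    parent_emb = np.asarray(parent_emb, dtype=float)
    child_emb = np.asarray(child_emb, dtype=float)
    if parent_emb.shape[0] == 0:
        raise ValueError("no parent cells")
    parent_states = np.asarray(parent_states)
    child_states = np.asarray(child_states)
    k = min(k_neighbors, parent_emb.shape[0])

    p_labels, p_counts = np.unique(parent_states, return_counts=True)
    keep_parent = set(p_labels[p_counts >= min_state_size])
    dropped = sorted(set(p_labels) - keep_parent)
    if dropped:
        warnings.warn(f"parent states below min size excluded: {dropped}")

    # k nearest parents per child cell with deterministic index tie-break
    rows = []
    chunk = 2048
    label_of = pd.Series(parent_states)
    state_list = sorted(keep_parent, key=str)
    state_pos = {s: i for i, s in enumerate(state_list)}
    prop = np.zeros((child_emb.shape[0], len(state_list)))
    for lo in range(0, child_emb.shape[0], chunk):
        d = cdist(child_emb[lo:lo + chunk], parent_emb)
        order = np.lexsort((np.tile(np.arange(parent_emb.shape[0]), (d.shape[0], 1)),
                            d), axis=1)[:, :k]
        for r in range(order.shape[0]):
            labs = label_of.iloc[order[r]].to_numpy()
            for s, cnt in zip(*np.unique(labs, return_counts=True)):
                if s in state_pos:
                    prop[lo + r, state_pos[s]] = cnt / k

    for cs in np.unique(child_states):
        members = np.flatnonzero(child_states == cs)
        if len(members) == 0:
            warnings.warn(f"child state {cs!r} has no cells; skipped")
            continue
        if len(members) < min_state_size:
            warnings.warn(f"child state {cs!r} below min size; skipped")
            continue
        med = np.median(prop[members], axis=0)
        for s in state_list:
            rows.append((s, cs, float(med[state_pos[s]])))
    return pd.DataFrame(rows, columns=["parent_state", "child_state", "weight"])


def build_lineage_dag(weight_tables: dict[tuple[int, int], pd.DataFrame],
                      threshold: float = DEFAULT_EDGE_THRESHOLD) -> nx.DiGraph:
    """Assemble the cross-window DAG from per-adjacent-pair weight tables.

    ``weight_tables`` maps (parent_window, child_window) to the output of
    :func:`link_edge_weights`.  Per child state only its maximum-weight
    incoming edge survives, and only when the weight strictly exceeds the
    threshold; ties break toward the smaller parent label.  Nodes are
    ``(window, state)`` tuples; the graph is acyclic because every edge
    points forward in time.
    """
    dag = nx.DiGraph(threshold=threshold)
    for (wp, wc), table in sorted(weight_tables.items()):
        if wc <= wp:
            raise ValueError(f"pair ({wp}, {wc}): parent window must precede child")
        for _, row in table.iterrows():
            dag.add_node((wp, row["parent_state"]))
            dag.add_node((wc, row["child_state"]))
        for cs, group in table.groupby("child_state"):
            g = group.sort_values(["weight", "parent_state"],
                                  ascending=[False, True],
                                  key=lambda s: s.astype(str) if s.name == "parent_state" else s)
            best = g.iloc[0]
            if best["weight"] > threshold:
                dag.add_edge((wp, best["parent_state"]), (wc, cs),
                             weight=float(best["weight"]))
    assert nx.is_directed_acyclic_graph(dag)
    return dag


def dag_edge_set(dag: nx.DiGraph) -> set[tuple]:
    """Edges as ((parent_window, parent_state), (child_window, child_state))."""
    return set(dag.edges())
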