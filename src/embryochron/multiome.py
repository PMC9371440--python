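"""RNA <-> ATAC cluster integration.

Gene activity scores summarize accessibility as an expression proxy: the
sum of ATAC reads over peaks overlapping the gene body or the 2 kb
flanking the TSS.  Cluster-level expression profiles are then decomposed
as nonnegative mixtures of the other modality's cluster profiles (NNLS),
in both directions; cluster pairs whose mixture coefficients exceed the
threshold (default 0.1, strict) in both directions are called linked.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree
from scipy.optimize import nnls as _nnls

DEFAULT_FLANK_BP = 2000
DEFAULT_LINK_THRESHOLD = 0.1


def gene_activity_scores(X, peaks: pd.DataFrame, genes: pd.DataFrame,
                         flank_bp: int = DEFAULT_FLANK_BP):
    """Sum ATAC reads over each gene's body plus TSS-flanking region.

    Parameters
    ----------
    X : cells x peaks count matrix (rows align with ``peaks`` order)
    peaks : DataFrame indexed by peak id with chrom/start/end (0-based,
        half-open)
    genes : DataFrame indexed by gene id with chrom/start/end/strand
    flank_bp : half-width of the TSS flank; the scored region is
        ``union(gene body, [TSS - flank, TSS + flank))`` clipped at 0.

    A peak overlapping the region by any amount is counted in full.  Genes
    on chromosomes absent from the peak table are dropped with a warning.

    Returns
    -------
    (scores, gene_ids) : cells x genes sparse matrix and the retained ids.
    """
    X = sp.csr_matrix(X)
    trees: dict[str, IntervalTree] = {}
    for pos, (pid, row) in enumerate(peaks.iterrows()):
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            int(row["start"]), int(row["end"]), pos)

    membership_rows, membership_cols = [], []
    gene_ids = []
    for gi, (gid, row) in enumerate(genes.iterrows()):
        chrom = row["chrom"]
        if chrom not in trees:
            warnings.warn(f"gene {gid!r} on chromosome {chrom!r} with no peaks; dropped")
            continue
        start, end = int(row["start"]), int(row["end"])
        tss = start if row["strand"] == "+" else end - 1
        f_lo, f_hi = max(0, tss - flank_bp), tss + flank_bp
        hits = set()
        for lo, hi in _union_intervals([(start, end), (f_lo, f_hi)]):
            for iv in trees[chrom].overlap(lo, hi):
                hits.add(iv.data)
        gene_ids.append(gid)
        for p in sorted(hits):
            membership_rows.append(p)
            membership_cols.append(len(gene_ids) - 1)
    M = sp.csr_matrix((np.ones(len(membership_rows)),
                       (membership_rows, membership_cols)),
                      shape=(len(peaks), len(gene_ids)))
    return X @ M, gene_ids


def _union_intervals(ivs):
    ivs = sorted((lo, hi) for lo, hi in ivs if hi > lo)
    out = []
    for lo, hi in ivs:
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def cluster_profiles(X, feature_ids, labels: np.ndarray, scale: float = 1e4,
                     pseudocount: float = 1.0, log: bool = True) -> pd.DataFrame:
    """Cluster x feature pseudobulk profiles: sum, depth-normalize, log."""
    X = sp.csr_matrix(X)
    labels = np.asarray(labels)
    clusters = pd.unique(labels)
    rows = []
    for c in clusters:
        members = np.flatnonzero(labels == c)
        if len(members) == 0:
            raise ValueError(f"cluster {c!r} is empty")
        s = np.asarray(X[members].sum(axis=0)).ravel().astype(float)
        total = s.sum()
        if total > 0:
            s *= scale / total
        if log:
            s = np.log(s + pseudocount)
        rows.append(s)
    return pd.DataFrame(rows, index=pd.Index(clusters, name="cluster"),
                        columns=list(feature_ids))


def nnls_decompose(targets: pd.DataFrame, sources: pd.DataFrame,
                   rescale: bool = True):
    """Express each target profile as a nonnegative mixture of sources.

    Profiles are restricted to the shared gene space, with zero-variance
    genes dropped.  Per target row ``t``: ``argmin_{b >= 0} ||t - S^T b||``;
    coefficients are rescaled to unit sum (mixture proportions) unless
    ``rescale=False``.

    Returns (coef, residual): targets x sources DataFrame and a residual
    Series (of the unrescaled fit).
    """
    shared = targets.columns.intersection(sources.columns)
    if len(shared) == 0:
        raise ValueError("targets and sources share no features")
    T = targets[shared].to_numpy(dtype=float)
    S = sources[shared].to_numpy(dtype=float)
    var = np.concatenate([T, S]).var(axis=0)
    keep = var > 0
    T, S = T[:, keep], S[:, keep]
    coef = np.zeros((T.shape[0], S.shape[0]))
    resid = np.zeros(T.shape[0])
    for i in range(T.shape[0]):
        if not np.any(T[i]):
            warnings.warn(f"target {targets.index[i]!r} is all zero")
            resid[i] = 0.0
            continue
        coef[i], resid[i] = _nnls(S.T, T[i])
    if rescale:
        sums = coef.sum(axis=1, keepdims=True)
        np.divide(coef, sums, out=coef, where=sums > 0)
    return (pd.DataFrame(coef, index=targets.index, columns=sources.index),
            pd.Series(resid, index=targets.index, name="residual"))


def link_clusters(coef_rna_from_atac: pd.DataFrame,
                  coef_atac_from_rna: pd.DataFrame,
                  threshold: float = DEFAULT_LINK_THRESHOLD,
                  both_directions: bool = True) -> pd.DataFrame:
    """Call linked RNA/ATAC cluster pairs from bidirectional NNLS.

    ``coef_rna_from_atac``: RNA clusters x ATAC clusters (expression
    decomposed over gene-activity sources); ``coef_atac_from_rna`` the
    reverse.  The combined score is the mean of the two directional
    coefficients; a pair is linked iff both (default) or either
    (``both_directions=False``) directional coefficient strictly exceeds
    the threshold.
    """
    r_from_a = coef_rna_from_atac
    a_from_r = coef_atac_from_rna
    rows = []
    for r in r_from_a.index:
        for a in r_from_a.columns:
            c1 = float(r_from_a.loc[r, a])
            c2 = float(a_from_r.loc[a, r]) if (a in a_from_r.index and
                                               r in a_from_r.columns) else np.nan
            combined = np.nanmean([c1, c2])
            if both_directions:
                linked = (c1 > threshold) and (c2 > threshold)
            else:
                linked = (c1 > threshold) or (c2 > threshold)
            rows.append((a, r, c2, c1, float(combined), bool(linked)))
    return pd.DataFrame(rows, columns=["atac_cluster", "rna_cluster",
                                       "coef_a2r", "coef_r2a", "combined",
                                       "linked"])


def best_partners(links: pd.DataFrame) -> pd.Series:
    """Per RNA cluster, the ATAC cluster with maximal combined score."""
    idx = links.groupby("rna_cluster")["combined"].idxmax()
    out = links.loc[idx].set_index("rna_cluster")["atac_cluster"]
    return out
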