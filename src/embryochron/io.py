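"""On-disk layout for synthetic atlases: text formats only.

A written atlas directory contains::

    rna.mtx, atac.mtx          sparse cell x feature counts (matrix market)
    rna_cells.tsv, atac_cells.tsv   per-cell metadata
    genes.tsv                  gene models (0-based half-open, with strand)
    peaks.bed                  peak intervals (BED, 0-based half-open)
    windows.tsv                collection-window schedule
    motif_hits.tsv             peak x TF binary table
    gene_regions.tsv           gene -> linked-peak mapping
    truth/kinetics.tsv         planted per-gene kinetic parameters
    truth/tf_truth.tsv         planted TF roles
    truth/lineage_epochs.tsv, truth/lineage_states.tsv   planted tree

``read_atlas(write_atlas(a)) == a`` on all fields.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .simulate import (CollectionWindow, KineticParams, LineageTree,
                       SyntheticAtlas)

_REQUIRED = ["rna.mtx", "atac.mtx", "rna_cells.tsv", "atac_cells.tsv",
             "genes.tsv", "peaks.bed", "windows.tsv", "motif_hits.tsv",
             "gene_regions.tsv", "truth/kinetics.tsv", "truth/tf_truth.tsv",
             "truth/lineage_epochs.tsv", "truth/lineage_states.tsv"]


def write_atlas(atlas: SyntheticAtlas, directory) -> Path:
    """Write an atlas to ``directory`` (created if absent); returns the path."""
    d = Path(directory)
    (d / "truth").mkdir(parents=True, exist_ok=True)

    sio.mmwrite(d / "rna.mtx", sp.coo_matrix(atlas.rna.X))
    sio.mmwrite(d / "atac.mtx", sp.coo_matrix(atlas.atac.X))
    atlas.rna.obs.to_csv(d / "rna_cells.tsv", sep="\t")
    atlas.atac.obs.to_csv(d / "atac_cells.tsv", sep="\t")
    atlas.rna.var.to_csv(d / "genes.tsv", sep="\t")

    peaks = atlas.atac.var
    with open(d / "peaks.bed", "w") as fh:
        for pid, row in peaks.iterrows():
            fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t{pid}\n")
    peaks.drop(columns=["chrom", "start", "end"]).to_csv(d / "peaks_meta.tsv", sep="\t")

    pd.DataFrame(
        [(w.index, w.start_h, w.end_h, w.center_h) for w in atlas.windows],
        columns=["index", "start_h", "end_h", "center_h"],
    ).to_csv(d / "windows.tsv", sep="\t", index=False)

    atlas.motif_hits.to_csv(d / "motif_hits.tsv", sep="\t")
    pd.DataFrame(
        [(g, "|".join(ps)) for g, ps in atlas.gene_regions.items()],
        columns=["gene_id", "peak_ids"],
    ).to_csv(d / "gene_regions.tsv", sep="\t", index=False)

    pd.DataFrame(
        [(k.feature_id, k.klass, k.onset_h, k.rate, k.amplitude,
          "" if k.lineage_mask is None else "|".join(sorted(k.lineage_mask)),
          k.access_lead_h) for k in atlas.kinetics],
        columns=["feature_id", "class", "onset_h", "rate", "amplitude",
                 "lineage_mask", "access_lead_h"],
    ).to_csv(d / "truth" / "kinetics.tsv", sep="\t", index=False)
    atlas.tf_truth.to_csv(d / "truth" / "tf_truth.tsv", sep="\t")

    tree = atlas.lineage_tree
    pd.DataFrame({"bound_h": list(tree.epoch_bounds)}).to_csv(
        d / "truth" / "lineage_epochs.tsv", sep="\t", index=False)
    rows = [(e, s, tree.parent.get(s) or "")
            for e, labels in enumerate(tree.states) for s in labels]
    pd.DataFrame(rows, columns=["epoch", "state", "parent"]).to_csv(
        d / "truth" / "lineage_states.tsv", sep="\t", index=False)
    return d


def _require(d: Path, rel: str) -> Path:
    p = d / rel
    if not p.exists():
        raise FileNotFoundError(f"atlas directory is missing {p}")
    return p


def read_atlas(directory) -> SyntheticAtlas:
    """Read an atlas written by :func:`write_atlas`."""
    d = Path(directory)
    for rel in _REQUIRED:
        _require(d, rel)

    X_rna = sp.csr_matrix(sio.mmread(d / "rna.mtx")).astype(np.int32)
    X_atac = sp.csr_matrix(sio.mmread(d / "atac.mtx")).astype(np.int32)
    rna_obs = pd.read_csv(d / "rna_cells.tsv", sep="\t", index_col=0,
                          float_precision="round_trip")
    atac_obs = pd.read_csv(d / "atac_cells.tsv", sep="\t", index_col=0,
                           float_precision="round_trip")
    genes = pd.read_csv(d / "genes.tsv", sep="\t", index_col=0,
                        keep_default_na=False)

    bed = pd.read_csv(d / "peaks.bed", sep="\t", header=None,
                      names=["chrom", "start", "end", "peak_id"]).set_index("peak_id")
    peaks_meta = pd.read_csv(d / "peaks_meta.tsv", sep="\t", index_col=0,
                             keep_default_na=False)
    peaks = bed.join(peaks_meta)

    win_df = pd.read_csv(d / "windows.tsv", sep="\t")
    windows = [CollectionWindow(int(r["index"]), float(r["start_h"]), float(r["end_h"]))
               for _, r in win_df.iterrows()]

    motif_hits = pd.read_csv(d / "motif_hits.tsv", sep="\t", index_col=0).astype(np.int8)
    gr = pd.read_csv(d / "gene_regions.tsv", sep="\t", keep_default_na=False)
    gene_regions = {r["gene_id"]: (r["peak_ids"].split("|") if r["peak_ids"] else [])
                    for _, r in gr.iterrows()}

    kin = pd.read_csv(d / "truth" / "kinetics.tsv", sep="\t",
                      keep_default_na=False, float_precision="round_trip")
    kinetics = [KineticParams(
        feature_id=str(r["feature_id"]), klass=str(r["class"]),
        onset_h=float(r["onset_h"]), rate=float(r["rate"]),
        amplitude=float(r["amplitude"]),
        lineage_mask=(frozenset(str(r["lineage_mask"]).split("|"))
                      if str(r["lineage_mask"]) else None),
        access_lead_h=float(r["access_lead_h"])) for _, r in kin.iterrows()]
    tf_truth = pd.read_csv(d / "truth" / "tf_truth.tsv", sep="\t", index_col=0,
                           keep_default_na=False)  # 'null' is a TF role

    bounds = tuple(pd.read_csv(d / "truth" / "lineage_epochs.tsv",
                               sep="\t")["bound_h"].astype(float))
    st = pd.read_csv(d / "truth" / "lineage_states.tsv", sep="\t",
                     keep_default_na=False)
    states = tuple(tuple(st.loc[st["epoch"] == e, "state"])
                   for e in sorted(st["epoch"].unique()))
    parent = {r["state"]: (r["parent"] or None) for _, r in st.iterrows()}
    tree = LineageTree(bounds, states, parent)

    rna = ad.AnnData(X=X_rna, obs=rna_obs, var=genes)
    atac = ad.AnnData(X=X_atac, obs=atac_obs, var=peaks)
    return SyntheticAtlas(rna=rna, atac=atac, windows=windows, kinetics=kinetics,
                          lineage_tree=tree, gene_regions=gene_regions,
                          motif_hits=motif_hits, tf_truth=tf_truth)
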