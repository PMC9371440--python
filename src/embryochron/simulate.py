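"""Synthetic multi-window embryo atlas generator.

Emulates the structure of a staged-collection single-nucleus atlas of
Drosophila embryogenesis: embryos are harvested in overlapping timed
windows spanning 0-20 h, every nucleus carries only its window label while
its true developmental age is latent, and the two modalities (sparse
RNA-like UMI counts and ATAC-like read counts over peaks) share planted
gene kinetics.  Everything downstream of raw sequencing is exercised on
these atlases, with full ground truth recorded.

Kinetic classes
---------------
``maternal``   amplitude * exp(-rate * age)           (deposited, decaying)
``zygotic``    amplitude * logistic(rate*(age-onset)) (switch-like onset)
``transient``  amplitude * exp(-((age-onset)*rate)^2/2)  (pulse)
``constant``   amplitude                              (housekeeping)

Accessibility follows the same functional form with the onset shifted
earlier by ``access_lead_h`` (floored at 0), which plants pioneer-factor
behaviour: chromatin at a region can open before its gene turns on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

MAX_AGE_H = 20.0

KINETIC_CLASSES = ("maternal", "zygotic", "transient", "constant")

CHROMS = ("chr2L", "chr2R", "chr3L", "chr3R", "chrX")


@dataclass(frozen=True)
class CollectionWindow:
    """A timed embryo-collection interval; the supervision label source."""

    index: int
    start_h: float
    end_h: float

    def __post_init__(self) -> None:
        if not self.start_h < self.end_h:
            raise ValueError(f"window {self.index}: start_h must be < end_h")

    @property
    def center_h(self) -> float:
        return 0.5 * (self.start_h + self.end_h)

    def contains(self, age_h) -> np.ndarray:
        return (np.asarray(age_h) >= self.start_h) & (np.asarray(age_h) <= self.end_h)


#: boundaries of the default 11-window schedule: 2-h collections early to
#: capture rapid transitions, 4-h collections from 3 h onward, overlapping,
#: jointly covering 0-20 h.
DEFAULT_WINDOW_BOUNDS = (
    (0, 2), (1, 3), (2, 4), (3, 7), (5, 9), (7, 11),
    (9, 13), (11, 15), (13, 17), (15, 19), (16, 20),
)


def default_window_schedule() -> list[CollectionWindow]:
    """The default 11 overlapping collection windows covering 0-20 h."""
    return [CollectionWindow(i, float(a), float(b))
            for i, (a, b) in enumerate(DEFAULT_WINDOW_BOUNDS)]


def sample_collection(window: CollectionWindow, n: int, contamination_rate: float = 0.0,
                      max_age: float = MAX_AGE_H, seed: int | np.random.Generator = 0):
    """Draw true ages for one collection.

    Non-contaminant ages are uniform within the window; contaminants model
    older embryos stuck in the collection and are uniform on
    ``(window.end_h, max_age]``.

    Returns
    -------
    ages : (n,) float array
    is_contaminant : (n,) bool array
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= contamination_rate < 1.0:
        raise ValueError("contamination_rate must be in [0, 1)")
    if contamination_rate > 0 and window.end_h >= max_age:
        raise ValueError(
            f"window {window.index} ends at {window.end_h} h >= max_age "
            f"{max_age} h: no room for old-embryo contaminants")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    is_contaminant = rng.random(n) < contamination_rate
    ages = rng.uniform(window.start_h, window.end_h, size=n)
    n_cont = int(is_contaminant.sum())
    if n_cont:
        ages[is_contaminant] = rng.uniform(window.end_h, max_age, size=n_cont)
    return ages, is_contaminant


@dataclass(frozen=True)
class KineticParams:
    """Planted kinetics of one feature (gene, or peak via its linked gene)."""

    feature_id: str
    klass: str
    onset_h: float = 0.0
    rate: float = 1.0
    amplitude: float = 1.0
    lineage_mask: frozenset[str] | None = None  # None = active everywhere
    access_lead_h: float = 0.0

    def __post_init__(self) -> None:
        if self.klass not in KINETIC_CLASSES:
            raise ValueError(f"unknown kinetic class {self.klass!r}")
        if self.amplitude < 0 or self.rate <= 0 or self.access_lead_h < 0:
            raise ValueError("require amplitude >= 0, rate > 0, access_lead_h >= 0")


def _kinetic_mean(klass: str, onset_h: float, rate: float, amplitude: float,
                  age_h) -> np.ndarray:
    age = np.asarray(age_h, dtype=float)
    if klass == "maternal":
        return amplitude * np.exp(-rate * age)
    if klass == "zygotic":
        return amplitude / (1.0 + np.exp(-rate * (age - onset_h)))
    if klass == "transient":
        return amplitude * np.exp(-0.5 * ((age - onset_h) * rate) ** 2)
    if klass == "constant":
        return amplitude * np.ones_like(age)
    raise ValueError(f"unknown kinetic class {klass!r}")


def expression_mean(params: KineticParams, age_h) -> np.ndarray:
    """Expected expression of a feature at given age(s) in hours."""
    return _kinetic_mean(params.klass, params.onset_h, params.rate,
                         params.amplitude, age_h)


def accessibility_mean(params: KineticParams, age_h) -> np.ndarray:
    """Expected accessibility: same form, onset led by ``access_lead_h``.

    The shifted onset is floored at 0 h (chromatin cannot open before
    fertilization).
    """
    onset = max(0.0, params.onset_h - params.access_lead_h)
    return _kinetic_mean(params.klass, onset, params.rate, params.amplitude, age_h)


# ---------------------------------------------------------------------------
# lineage tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineageTree:
    """Planted branching cell states over age epochs.

    ``epoch_bounds`` are increasing hour boundaries covering [0, max age];
    epoch ``e`` spans ``[epoch_bounds[e], epoch_bounds[e+1])``.  ``states``
    lists the state labels present in each epoch; ``parent`` maps each
    non-root state to its state in the previous epoch.
    """

    epoch_bounds: tuple[float, ...]
    states: tuple[tuple[str, ...], ...]
    parent: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.states) != len(self.epoch_bounds) - 1:
            raise ValueError("need one state list per epoch")
        seen = set()
        for epoch, labels in enumerate(self.states):
            for s in labels:
                if s in seen:
                    raise ValueError(f"duplicate state label {s!r}")
                seen.add(s)
                p = self.parent.get(s)
                if epoch == 0:
                    if p is not None:
                        raise ValueError(f"root-epoch state {s!r} cannot have a parent")
                elif p not in self.states[epoch - 1]:
                    raise ValueError(f"state {s!r}: parent {p!r} not in previous epoch")

    @property
    def n_states(self) -> int:
        return sum(len(s) for s in self.states)

    def all_states(self) -> list[str]:
        return [s for labels in self.states for s in labels]

    def epoch_of_age(self, age_h: float) -> int:
        e = int(np.searchsorted(self.epoch_bounds, age_h, side="right")) - 1
        return min(max(e, 0), len(self.states) - 1)

    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c, p in self.parent.items() if p is not None]

    def descendants(self, state: str) -> frozenset[str]:
        """The state itself plus every state descending from it."""
        out = {state}
        changed = True
        while changed:
            changed = False
            for child, par in self.parent.items():
                if par in out and child not in out:
                    out.add(child)
                    changed = True
        return frozenset(out)


def binary_lineage_tree(states_per_epoch=(1, 2, 4), epoch_bounds=(0.0, 6.0, 12.0, 20.0),
                        prefix: str = "S") -> LineageTree:
    """A simple planted tree: each epoch's states split from the previous
    epoch's states in order (round-robin parents), e.g. (1, 2, 4) -> binary."""
    states, parent = [], {}
    for e, k in enumerate(states_per_epoch):
        labels = tuple(f"{prefix}{e}.{j}" for j in range(k))
        states.append(labels)
        for j, s in enumerate(labels):
            parent[s] = None if e == 0 else states[e - 1][j % len(states[e - 1])]
    return LineageTree(tuple(float(b) for b in epoch_bounds), tuple(states), parent)


# ---------------------------------------------------------------------------
# atlas configuration
# ---------------------------------------------------------------------------

@dataclass
class AtlasConfig:
    """Study conditions of the synthetic atlas.

    Defaults mirror the profiled design at toy scale: 11 overlapping
    windows over 0-20 h, ~20,000 RNA-like cells, sparse UMI counts with a
    median depth of 399, old-embryo contamination of the earliest window,
    maternal / zygotic / transient / constant gene kinetics, a planted
    branching lineage, accessibility leading expression for a subset of
    zygotic genes, and chrX read-fraction sex dimorphism.
    """

    windows: list[CollectionWindow] = field(default_factory=default_window_schedule)
    cells_per_window_rna: int = 1820
    cells_per_window_atac: int = 500
    n_genes: int = 500
    kinetics: list[KineticParams] | None = None   # explicit plant; else drawn
    class_mix: dict[str, float] = field(default_factory=lambda: {
        "maternal": 0.28, "zygotic": 0.37, "transient": 0.15, "constant": 0.20})
    onset_range_h: tuple[float, float] = (0.5, 16.0)
    peaks_per_gene: int = 2
    n_background_peaks: int = 200
    lineage_tree: LineageTree = field(default_factory=binary_lineage_tree)
    lineage_marker_frac: float = 0.12     # fraction of genes made state-restricted
    pioneer_frac: float = 0.2             # fraction of zygotic genes with lead
    pioneer_lead_h: float = 0.5
    depth_rna: float = 399.0              # target median UMIs per RNA cell
    depth_atac: float | None = None       # default: 5206/110185 reads per peak
    depth_sigma: float = 0.35             # log-normal library-size spread
    dispersion: float = 0.5               # NB dispersion; 0 -> Poisson
    contamination_rate: float = 0.03      # planted in contaminated_windows
    contaminated_windows: tuple[int, ...] = (0,)
    n_tfs: int = 20
    motif_hit_rate: float = 0.1
    chrx_means: tuple[float, float] = (0.04, 0.02)   # (XX, XY)
    chrx_sd: float = 0.004
    max_age_h: float = MAX_AGE_H

    def __post_init__(self) -> None:
        if self.kinetics is not None:
            self.n_genes = len(self.kinetics)
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        unknown = set(self.class_mix) - set(KINETIC_CLASSES)
        if unknown:
            raise ValueError(f"unknown kinetic classes in class_mix: {sorted(unknown)}")
        if self.depth_atac is None:
            n_peaks = self.n_genes * self.peaks_per_gene + self.n_background_peaks
            self.depth_atac = (5206.0 / 110185.0) * n_peaks


@dataclass
class SyntheticAtlas:
    """Ground-truth twin of a staged-collection multiome atlas."""

    rna: ad.AnnData
    atac: ad.AnnData
    windows: list[CollectionWindow]
    kinetics: list[KineticParams]
    lineage_tree: LineageTree
    gene_regions: dict[str, list[str]]       # gene -> linked peak ids
    motif_hits: pd.DataFrame                 # peaks x TFs, 0/1
    tf_truth: pd.DataFrame                   # per-TF role/germ_layer/start_window
    config: AtlasConfig | None = None

    def kinetics_by_id(self) -> dict[str, KineticParams]:
        return {k.feature_id: k for k in self.kinetics}


def _draw_kinetics(cfg: AtlasConfig, rng: np.random.Generator) -> list[KineticParams]:
    classes = list(cfg.class_mix)
    probs = np.array([cfg.class_mix[c] for c in classes])
    # deterministic composition: fixed counts per class, shuffled assignment
    counts = np.floor(probs * cfg.n_genes).astype(int)
    counts[0] += cfg.n_genes - counts.sum()
    assignment = np.repeat(classes, counts)
    rng.shuffle(assignment)

    tree = cfg.lineage_tree
    nodes = tree.all_states()
    n_markers = int(round(cfg.lineage_marker_frac * cfg.n_genes))
    marker_idx = set(rng.choice(cfg.n_genes, size=n_markers, replace=False).tolist())

    params = []
    lo, hi = cfg.onset_range_h
    for i in range(cfg.n_genes):
        klass = str(assignment[i])
        onset = float(rng.uniform(lo, hi)) if klass in ("zygotic", "transient") else 0.0
        if klass == "maternal":
            rate = float(rng.uniform(0.3, 1.0))
        elif klass == "transient":
            rate = float(rng.uniform(0.5, 1.5))
        else:
            rate = float(rng.uniform(0.8, 2.0))
        amplitude = float(rng.lognormal(mean=0.0, sigma=0.8))
        mask = None
        if i in marker_idx and klass in ("zygotic", "constant"):
            node = nodes[int(rng.integers(len(nodes)))]
            mask = tree.descendants(node)
            amplitude *= 3.0  # markers are strong, as real cell-type markers are
        lead = 0.0
        if klass == "zygotic" and rng.random() < cfg.pioneer_frac:
            lead = cfg.pioneer_lead_h
        params.append(KineticParams(
            feature_id=f"g{i:04d}", klass=klass, onset_h=onset, rate=rate,
            amplitude=amplitude, lineage_mask=mask, access_lead_h=lead))
    return params


def _feature_tables(cfg: AtlasConfig, kinetics: list[KineticParams],
                    rng: np.random.Generator):
    """Gene models (TSV-style intervals) and peak intervals on toy chromosomes."""
    n = len(kinetics)
    chroms = [CHROMS[i % len(CHROMS)] for i in range(n)]
    starts = 10_000 + 10_000 * (np.arange(n) // len(CHROMS))
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    genes = pd.DataFrame({
        "chrom": chroms,
        "start": starts,
        "end": starts + 2_000,
        "strand": strands,
        "class": [k.klass for k in kinetics],
        "onset_h": [k.onset_h for k in kinetics],
        "rate": [k.rate for k in kinetics],
        "amplitude": [k.amplitude for k in kinetics],
        "access_lead_h": [k.access_lead_h for k in kinetics],
        "lineage_mask": ["" if k.lineage_mask is None else
                         "|".join(sorted(k.lineage_mask)) for k in kinetics],
    }, index=pd.Index([k.feature_id for k in kinetics], name="gene_id"))

    peak_rows, gene_regions = [], {}
    for gi, k in enumerate(kinetics):
        ids = []
        for j in range(cfg.peaks_per_gene):
            pid = f"p{gi:04d}_{j}"
            # linked peaks sit in the gene body / promoter flank
            off = 500 * j
            peak_rows.append((pid, genes.iloc[gi]["chrom"],
                              int(genes.iloc[gi]["start"]) - 500 + off,
                              int(genes.iloc[gi]["start"]) + off, k.feature_id))
            ids.append(pid)
        gene_regions[k.feature_id] = ids
    for b in range(cfg.n_background_peaks):
        peak_rows.append((f"bg{b:04d}", CHROMS[b % len(CHROMS)],
                          1_000_000 + 1_000 * b, 1_000_500 + 1_000 * b, ""))
    peaks = pd.DataFrame(peak_rows, columns=["peak_id", "chrom", "start", "end",
                                             "linked_gene"]).set_index("peak_id")
    return genes, peaks, gene_regions


def _mean_matrix(kinetics: list[KineticParams], ages: np.ndarray,
                 lineages: np.ndarray, accessibility: bool) -> np.ndarray:
    """cells x features expected counts (before depth scaling)."""
    n_cells, n_feat = len(ages), len(kinetics)
    mu = np.empty((n_cells, n_feat))
    for j, k in enumerate(kinetics):
        fn = accessibility_mean if accessibility else expression_mean
        mu[:, j] = fn(k, ages)
        if k.lineage_mask is not None:
            mu[~np.isin(lineages, list(k.lineage_mask)), j] = 0.0
    return mu


def _sample_counts(mu: np.ndarray, depth_target: float, depth_sigma: float,
                   dispersion: float, rng: np.random.Generator) -> sp.csr_matrix:
    """Negative-binomial (gamma-Poisson) draws around depth-scaled means."""
    totals = mu.sum(axis=1)
    totals[totals == 0] = 1.0
    factor = depth_target * np.exp(rng.normal(0.0, depth_sigma, size=mu.shape[0]))
    lam = mu * (factor / totals)[:, None]
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, lam * dispersion)
    counts = rng.poisson(lam)
    return sp.csr_matrix(counts.astype(np.int32))


def _simulate_cells(cfg: AtlasConfig, modality: str, n_per_window: int,
                    kinetics: list[KineticParams], rng: np.random.Generator):
    tree = cfg.lineage_tree
    rows = []
    for w in cfg.windows:
        rate = cfg.contamination_rate if w.index in cfg.contaminated_windows else 0.0
        ages, contam = sample_collection(w, n_per_window, rate, cfg.max_age_h, rng)
        for a, c in zip(ages, contam):
            epoch = tree.epoch_of_age(a)
            lineage = tree.states[epoch][int(rng.integers(len(tree.states[epoch])))]
            rows.append((w.index, float(a), bool(c), lineage))
    meta = pd.DataFrame(rows, columns=["window_index", "true_age_h",
                                       "is_contaminant", "lineage"])
    meta.index = pd.Index([f"{modality}_{i:06d}" for i in range(len(meta))],
                          name="cell_id")
    meta["germ_layer"] = [_germ_layer_of(s, tree) for s in meta["lineage"]]
    sex = np.where(rng.random(len(meta)) < 0.5, "XX", "XY")
    mu_x = np.where(sex == "XX", cfg.chrx_means[0], cfg.chrx_means[1])
    frac = np.clip(rng.normal(mu_x, cfg.chrx_sd), 0.0, 1.0)
    meta["sex"] = sex
    meta["chrX_fraction"] = frac

    mu = _mean_matrix(kinetics, meta["true_age_h"].to_numpy(),
                      meta["lineage"].to_numpy(), accessibility=(modality == "atac"))
    depth = cfg.depth_atac if modality == "atac" else cfg.depth_rna
    X = _sample_counts(mu, float(depth), cfg.depth_sigma, cfg.dispersion, rng)
    return X, meta


_GERM_LAYERS = ("ectoderm", "mesoderm", "endoderm")


def _germ_layer_of(state: str, tree: LineageTree) -> str:
    """Deterministic germ-layer labels: top-level branch index mod 3."""
    s = state
    while tree.parent.get(s) is not None and tree.parent[tree.parent[s]] is not None:
        s = tree.parent[s]
    for labels in tree.states:
        if s in labels:
            return _GERM_LAYERS[labels.index(s) % len(_GERM_LAYERS)]
    return _GERM_LAYERS[0]


def simulate_atlas(config: AtlasConfig | None = None, seed: int = 0) -> SyntheticAtlas:
    """Simulate a full RNA+ATAC atlas with planted ground truth.

    Counts are negative-binomial around depth-scaled kinetic means (Poisson
    when ``dispersion=0``); lineage-restricted features are zeroed outside
    their planted states; the whole atlas is reproducible under ``seed``.
    """
    cfg = config if config is not None else AtlasConfig()
    rng = np.random.default_rng(seed)
    kinetics = (list(cfg.kinetics) if cfg.kinetics is not None
                else _draw_kinetics(cfg, rng))
    known_states = set(cfg.lineage_tree.all_states())
    for k in kinetics:
        if k.lineage_mask is not None and not set(k.lineage_mask) <= known_states:
            raise ValueError(f"feature {k.feature_id}: lineage_mask references "
                             f"states unknown to the lineage tree")
    genes, peaks, gene_regions = _feature_tables(cfg, kinetics, rng)

    # peak-level kinetics inherit the linked gene's, accessibility-shifted;
    # background peaks are weakly, constantly accessible.
    kin_by_id = {k.feature_id: k for k in kinetics}
    peak_kinetics = []
    for pid, row in peaks.iterrows():
        g = row["linked_gene"]
        if g:
            k = kin_by_id[g]
            peak_kinetics.append(replace(k, feature_id=str(pid)))
        else:
            peak_kinetics.append(KineticParams(str(pid), "constant", amplitude=0.3))

    X_rna, rna_meta = _simulate_cells(cfg, "rna", cfg.cells_per_window_rna,
                                      kinetics, rng)
    X_atac, atac_meta = _simulate_cells(cfg, "atac", cfg.cells_per_window_atac,
                                        peak_kinetics, rng)

    motif = (rng.random((len(peaks), cfg.n_tfs)) < cfg.motif_hit_rate).astype(np.int8)
    tf_ids = [f"TF{t:02d}" for t in range(cfg.n_tfs)]
    motif_hits = pd.DataFrame(motif, index=peaks.index, columns=tf_ids)
    roles = np.array(["activator", "repressor", "null"])[
        rng.integers(0, 3, size=cfg.n_tfs)]
    tf_truth = pd.DataFrame({
        "role": roles,
        "germ_layer": [ _GERM_LAYERS[int(i)] for i in rng.integers(0, 3, cfg.n_tfs)],
        "start_window": rng.integers(0, max(len(cfg.windows) - 3, 1), cfg.n_tfs),
    }, index=pd.Index(tf_ids, name="tf"))

    rna = ad.AnnData(X=X_rna, obs=rna_meta, var=genes)
    atac = ad.AnnData(X=X_atac, obs=atac_meta,
                      var=peaks.assign(**{"class": [k.klass for k in peak_kinetics]}))
    return SyntheticAtlas(rna=rna, atac=atac, windows=list(cfg.windows),
                          kinetics=kinetics, lineage_tree=cfg.lineage_tree,
                          gene_regions=gene_regions, motif_hits=motif_hits,
                          tf_truth=tf_truth, config=cfg)


# ---------------------------------------------------------------------------
# targeted scenario generators
# ---------------------------------------------------------------------------

def simulate_matched_cluster_profiles(n_pairs: int = 10, n_genes: int = 300,
                                      noise_sd: float = 0.05, seed: int = 0):
    """Matched RNA-expression / ATAC-gene-activity cluster profiles.

    Each of ``n_pairs`` cell states gets a distinct nonnegative program over
    ``n_genes``; the RNA profile and the gene-activity profile of the same
    state share the program up to multiplicative noise, planting a known
    1:1 correspondence for the NNLS linkage to recover.

    Returns (rna_profiles, activity_profiles) as cluster x gene DataFrames
    with matching row order = the planted correspondence.
    """
    rng = np.random.default_rng(seed)
    programs = rng.gamma(shape=0.5, scale=2.0, size=(n_pairs, n_genes))
    genes = [f"g{i:04d}" for i in range(n_genes)]
    def noisy(base):
        return base * np.exp(rng.normal(0.0, noise_sd, size=base.shape))
    rna = pd.DataFrame(noisy(programs), columns=genes,
                       index=[f"rna_c{i}" for i in range(n_pairs)])
    act = pd.DataFrame(noisy(programs), columns=genes,
                       index=[f"atac_c{i}" for i in range(n_pairs)])
    return rna, act


def simulate_tf_scenario(n_activators: int = 5, n_repressors: int = 5,
                         n_null: int = 10, n_windows: int = 9,
                         clusters_per_layer: int = 4, noise_sd: float = 0.02,
                         effect: float = 2.0, seed: int = 0):
    """Cluster-level TF expression / motif-deviation tables with planted truth.

    Each non-null TF acts in one germ layer from one start window onward:
    there its motif deviation tracks its own expression (positively for
    activators, negatively for repressors); elsewhere, and for null TFs,
    deviations are independent noise.

    Returns dict with 'expression' and 'deviation' (tf x cluster DataFrames),
    'clusters' (cluster metadata: window, germ_layer) and 'truth'.
    """
    rng = np.random.default_rng(seed)
    layers = list(_GERM_LAYERS)
    clusters = []
    for w in range(n_windows):
        for layer in layers:
            for j in range(clusters_per_layer):
                clusters.append((f"w{w}_{layer[:3]}{j}", w, layer))
    meta = pd.DataFrame(clusters, columns=["cluster", "window", "germ_layer"]
                        ).set_index("cluster")

    n_tf = n_activators + n_repressors + n_null
    tf_ids = [f"TF{t:02d}" for t in range(n_tf)]
    roles = (["activator"] * n_activators + ["repressor"] * n_repressors
             + ["null"] * n_null)
    truth = pd.DataFrame({"role": roles}, index=pd.Index(tf_ids, name="tf"))
    truth["germ_layer"] = [layers[t % len(layers)] for t in range(n_tf)]
    truth["start_window"] = [2 + (t % max(n_windows - 4, 1)) for t in range(n_tf)]

    expr = pd.DataFrame(rng.uniform(0.5, 1.0, size=(n_tf, len(meta))),
                        index=truth.index, columns=meta.index)
    dev = pd.DataFrame(rng.normal(0.0, noise_sd, size=(n_tf, len(meta))),
                       index=truth.index, columns=meta.index)
    for tf, row in truth.iterrows():
        if row["role"] == "null":
            continue
        sign = 1.0 if row["role"] == "activator" else -1.0
        active = (meta["germ_layer"] == row["germ_layer"]) & \
                 (meta["window"] >= row["start_window"])
        cols = meta.index[active]
        expr.loc[tf, cols] = rng.uniform(1.5, 2.5, size=active.sum())
        dev.loc[tf, cols] += sign * effect * expr.loc[tf, cols].to_numpy()
    return {"expression": expr, "deviation": dev, "clusters": meta, "truth": truth}
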