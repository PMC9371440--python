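"""Per-nucleus latent-attribute inference from profiles.

Absolute developmental age is learned by regressing a nucleus's normalized
profile onto the center hour of its collection window — the only age
supervision available when embryos are harvested in timed windows.  Two
regressor families are provided: an L1-penalized linear model (lasso) and
a feedforward neural network, both selected by seeded k-fold
cross-validation stratified by window.  Sex is classified from the chrX
read fraction with a two-component Gaussian mixture.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.linear_model import Lasso
from sklearn.mixture import GaussianMixture
from sklearn.neural_network import MLPRegressor

from .simulate import CollectionWindow

MODEL_FORMAT_VERSION = 1

DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.logspace(-3, 0, 7))
DEFAULT_NN_GRID = tuple({"hidden": (h, 64), "lr": lr}
                        for h in (64, 128) for lr in (1e-2, 1e-3))


@dataclass
class Preprocess:
    """Frozen preprocessing recipe replayed identically at predict time.

    Depth-normalize each cell to ``scale`` total counts, add ``pseudocount``
    and log-transform; ATAC-like input is binarized first.
    """

    scale: float = 1e4
    pseudocount: float = 1.0
    log: bool = True
    binarize: bool = False

    def transform(self, X) -> np.ndarray:
        X = sp.csr_matrix(X, dtype=float) if sp.issparse(X) else \
            np.asarray(X, dtype=float)
        if self.binarize:
            X = (X > 0).astype(float) if not sp.issparse(X) else \
                X.sign()
        totals = np.asarray(X.sum(axis=1)).ravel()
        if np.any(totals == 0):
            totals = np.where(totals == 0, 1.0, totals)
        if sp.issparse(X):
            X = sp.diags(self.scale / totals) @ X
            X = np.asarray(X.todense())
        else:
            X = X * (self.scale / totals)[:, None]
        if self.log:
            X = np.log(X + self.pseudocount)
        return X


@dataclass
class AgeModel:
    """A fitted age regressor plus everything needed to replay it."""

    kind: str                              # "lasso" | "nn"
    feature_ids: list[str]
    preprocess: Preprocess
    estimator: object
    training_windows: list[CollectionWindow]
    cv_record: pd.DataFrame
    max_age_h: float = 20.0
    calibration: tuple | None = None   # (bin mid-ages, corrected ages)
    version: int = MODEL_FORMAT_VERSION

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "AgeModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, AgeModel) or model.version != MODEL_FORMAT_VERSION:
            raise ValueError(f"{path}: not an AgeModel of format "
                             f"version {MODEL_FORMAT_VERSION}")
        return model


@dataclass
class AgeMetrics:
    mse: float
    proportion_correct: float
    per_window_mean_error: pd.Series   # window index -> mean (pred - center)


# ---------------------------------------------------------------------------
# partitioning and feature selection
# ---------------------------------------------------------------------------

def partition_cells(window_index: np.ndarray, n_partitions: int,
                    seed: int = 0) -> np.ndarray:
    """Split cells into partitions evenly subsampled with respect to time.

    Within every collection window partition sizes differ by at most one;
    assignment is a seeded shuffle followed by round-robin.
    """
    window_index = np.asarray(window_index)
    if n_partitions < 2:
        raise ValueError("n_partitions must be >= 2")
    rng = np.random.default_rng(seed)
    labels = np.empty(len(window_index), dtype=int)
    for w in np.unique(window_index):
        idx = np.flatnonzero(window_index == w)
        if len(idx) < n_partitions:
            raise ValueError(f"window {w} has {len(idx)} cells < "
                             f"{n_partitions} partitions")
        idx = rng.permutation(idx)
        labels[idx] = np.arange(len(idx)) % n_partitions
    return labels


def _feature_target_correlation(Xn: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = Xn - Xn.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / denom
    return r


def select_time_features(X, feature_ids, window_centers: np.ndarray,
                         n_features: int, preprocess: Preprocess | None = None
                         ) -> list[str]:
    """Features most correlated (|Pearson r|) with developmental time.

    Correlation is computed on preprocessed values against the window center
    of each training cell; zero-variance features are excluded; ties break
    by feature id.
    """
    feature_ids = list(feature_ids)
    if n_features > len(feature_ids):
        raise ValueError("n_features exceeds available features")
    pp = preprocess or Preprocess()
    Xn = pp.transform(X)
    r = _feature_target_correlation(Xn, np.asarray(window_centers, dtype=float))
    variances = Xn.var(axis=0)
    r[variances == 0] = np.nan
    if np.all(np.isnan(r)):
        raise ValueError("all features have zero variance")
    order = sorted(range(len(feature_ids)),
                   key=lambda j: (-(0.0 if np.isnan(r[j]) else abs(r[j])),
                                  feature_ids[j]))
    keep = [j for j in order if not np.isnan(r[j])][:n_features]
    return [feature_ids[j] for j in keep]


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _stratified_folds(window_index: np.ndarray, n_folds: int,
                      seed: int) -> np.ndarray:
    """Fold labels balanced within each window (reuses partition_cells)."""
    return partition_cells(window_index, n_folds, seed=seed)


def fit_lasso_age(X, feature_ids, targets: np.ndarray, window_index: np.ndarray,
                  training_windows: list[CollectionWindow],
                  lambda_grid=DEFAULT_LAMBDA_GRID, n_folds: int = 10,
                  seed: int = 0, preprocess: Preprocess | None = None,
                  max_age_h: float = 20.0) -> AgeModel:
    """L1-penalized linear age regression with seeded, window-stratified CV."""
    lambda_grid = list(lambda_grid)
    if not lambda_grid:
        raise ValueError("lambda_grid must be nonempty")
    pp = preprocess or Preprocess()
    Xn = pp.transform(X)
    y = np.asarray(targets, dtype=float)
    folds = _stratified_folds(np.asarray(window_index), n_folds, seed)

    # warm-start path: per fold, fit lambdas in descending order
    lam_desc = sorted(set(lambda_grid), reverse=True)
    cv_err = {lam: [] for lam in lam_desc}
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        est = Lasso(alpha=lam_desc[0], max_iter=5000, warm_start=True, tol=1e-3)
        for lam in lam_desc:
            est.set_params(alpha=lam)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Xn[tr], y[tr])
            cv_err[lam].append(float(np.mean((est.predict(Xn[te]) - y[te]) ** 2)))
    cv = pd.DataFrame([{"lambda": lam, "cv_mse": float(np.mean(cv_err[lam]))}
                       for lam in lambda_grid])
    best = float(cv.loc[cv["cv_mse"].idxmin(), "lambda"])
    est = Lasso(alpha=best, max_iter=10000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Xn, y)
    return AgeModel(kind="lasso", feature_ids=list(feature_ids), preprocess=pp,
                    estimator=est, training_windows=list(training_windows),
                    cv_record=cv, max_age_h=max_age_h)


def fit_nn_age(X, feature_ids, targets: np.ndarray, window_index: np.ndarray,
               training_windows: list[CollectionWindow],
               hyper_grid=DEFAULT_NN_GRID, n_folds: int = 10, seed: int = 0,
               preprocess: Preprocess | None = None, max_age_h: float = 20.0,
               max_iter: int = 200, cv_subsample: int | None = 5000) -> AgeModel:
    """Feedforward (squared-error) age regressor with seeded CV model search.

    The hyperparameter search runs on a window-stratified subsample of at
    most ``cv_subsample`` cells; the winning configuration is refit on the
    full training set.
    """
    hyper_grid = list(hyper_grid)
    if not hyper_grid:
        raise ValueError("hyper_grid must be nonempty")
    pp = preprocess or Preprocess()
    Xn = pp.transform(X)
    y = np.asarray(targets, dtype=float)
    widx = np.asarray(window_index)

    sub = np.arange(len(y))
    if cv_subsample is not None and len(y) > cv_subsample:
        rng = np.random.default_rng(seed)
        keep = []
        quota = cv_subsample // len(np.unique(widx))
        for w in np.unique(widx):
            idx = np.flatnonzero(widx == w)
            keep.append(rng.choice(idx, size=min(quota, len(idx)), replace=False))
        sub = np.sort(np.concatenate(keep))
    folds = _stratified_folds(widx[sub], n_folds, seed)

    # early stopping needs a validation score that can improve; a constant
    # target keeps R^2 flat and would halt training immediately
    use_es = bool(np.std(y) > 0)

    def make(params, rs):
        return MLPRegressor(hidden_layer_sizes=tuple(params["hidden"]),
                            learning_rate_init=params["lr"], activation="relu",
                            solver="adam", max_iter=max_iter, tol=1e-5,
                            early_stopping=use_es,
                            n_iter_no_change=10 if use_es else max_iter,
                            validation_fraction=0.1, random_state=rs)

    records = []
    for gi, params in enumerate(hyper_grid):
        errs = []
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            est = make(params, seed + gi)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Xn[sub][tr], y[sub][tr])
            if not np.isfinite(est.loss_):
                raise RuntimeError(f"non-finite training loss for {params}")
            errs.append(float(np.mean((est.predict(Xn[sub][te]) - y[sub][te]) ** 2)))
        records.append({**{k: str(v) for k, v in params.items()},
                        "cv_mse": float(np.mean(errs)), "_grid_index": gi})
    cv = pd.DataFrame(records)
    best = hyper_grid[int(cv.loc[cv["cv_mse"].idxmin(), "_grid_index"])]
    est = make(best, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Xn, y)
    if not np.isfinite(est.loss_):
        raise RuntimeError(f"non-finite training loss for {best}")
    return AgeModel(kind="nn", feature_ids=list(feature_ids), preprocess=pp,
                    estimator=est, training_windows=list(training_windows),
                    cv_record=cv.drop(columns="_grid_index"), max_age_h=max_age_h)


# ---------------------------------------------------------------------------
# prediction and evaluation
# ---------------------------------------------------------------------------

def _align_features(X, feature_ids, model: AgeModel):
    feature_ids = list(feature_ids)
    pos = {f: j for j, f in enumerate(feature_ids)}
    missing = [f for f in model.feature_ids if f not in pos]
    if missing:
        raise ValueError(f"input is missing model features: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    cols = [pos[f] for f in model.feature_ids]
    return X[:, cols] if sp.issparse(X) else np.asarray(X)[:, cols]


def predict_age(model: AgeModel, X, feature_ids) -> np.ndarray:
    """Predicted absolute age (hours) per cell, clipped to [0, max_age_h].

    Features are realigned to the model's frozen feature list; extra
    features are ignored, missing ones raise.  Note: the frozen per-cell
    depth normalization is computed on the model's features only, so the
    prediction is invariant to features outside ``model.feature_ids``.
    """
    Xa = _align_features(X, feature_ids, model)
    Xn = model.preprocess.transform(Xa)
    pred = np.asarray(model.estimator.predict(Xn), dtype=float)
    pred = np.clip(pred, 0.0, model.max_age_h)
    if model.calibration is not None:
        mids, g = model.calibration
        pred = np.clip(np.interp(pred, mids, g), 0.0, model.max_age_h)
    return pred


def predict_bulk_age(model: AgeModel, bulk, feature_ids) -> np.ndarray:
    """Age a bulk sample: feature totals pushed through the per-cell recipe
    as a single pseudo-cell."""
    B = np.atleast_2d(np.asarray(bulk, dtype=float))
    totals = B.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("bulk sample with zero total counts")
    return predict_age(model, B, feature_ids)


def evaluate_age(predicted: np.ndarray, windows_per_cell: list[CollectionWindow],
                 mode: str = "membership") -> AgeMetrics:
    """MSE against window centers and the proportion of correct predictions.

    ``mode='membership'`` (default): a prediction is correct when it falls
    inside its originating collection window, bounds inclusive.
    ``mode='nearest_center'``: correct when the nearest training-window
    center is the cell's own window center.
    """
    pred = np.asarray(predicted, dtype=float)
    if len(pred) != len(windows_per_cell):
        raise ValueError("length mismatch between predictions and windows")
    centers = np.array([w.center_h for w in windows_per_cell])
    mse = float(np.mean((pred - centers) ** 2))
    if mode == "membership":
        starts = np.array([w.start_h for w in windows_per_cell])
        ends = np.array([w.end_h for w in windows_per_cell])
        correct = (pred >= starts) & (pred <= ends)
    elif mode == "nearest_center":
        uniq = np.unique(centers)
        nearest = uniq[np.argmin(np.abs(pred[:, None] - uniq[None, :]), axis=1)]
        correct = nearest == centers
    else:
        raise ValueError(f"unknown mode {mode!r}")
    widx = np.array([w.index for w in windows_per_cell])
    err = pd.Series(pred - centers).groupby(widx).mean()
    err.index.name = "window_index"
    return AgeMetrics(mse=mse, proportion_correct=float(np.mean(correct)),
                      per_window_mean_error=err)


def contamination_fraction(predicted: np.ndarray, age_threshold_h: float) -> float:
    """Fraction of a window's cells with predicted age >= threshold."""
    pred = np.asarray(predicted, dtype=float)
    if pred.size == 0:
        raise ValueError("no cells supplied")
    return float(np.mean(pred >= age_threshold_h))


def filter_by_age(predicted: np.ndarray, max_age_h: float = 18.0) -> np.ndarray:
    """Boolean mask keeping cells with predicted age <= max_age_h
    (predictions strictly above the cutoff are excluded)."""
    return np.asarray(predicted, dtype=float) <= max_age_h


def calibrate_age_model(model: AgeModel, X, feature_ids,
                        window_index: np.ndarray, n_bins: int = 40,
                        smoothness: float = 0.3) -> AgeModel:
    """Anchor window-mean predictions to the collection-window centers.

    Regressors trained on center-hour labels are systematically compressed
    at the extremes of the time course: where several overlapping windows
    cover the same true age, the expected label is an average of their
    centers, so mean predictions for the first and last windows are pulled
    inward (the same edge effect seen as depleted early/late inferred ages
    on real collections).  This step estimates a smooth monotone-ish
    correction curve g such that, on the training cells, the per-window
    mean of g(prediction) matches each window's center hour: predictions
    are histogrammed on ``n_bins`` age bins, the window x bin occupancy
    matrix A and center vector c define the linear system A g = c, and g
    is solved ridge-style with a second-difference roughness penalty
    ``smoothness`` around the identity curve.

    Returns a copy of the model with the calibration curve attached;
    :func:`predict_age` applies it automatically.
    """
    pred = predict_age(model, X, feature_ids)
    widx = np.asarray(window_index)
    edges = np.linspace(0.0, model.max_age_h, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    binned = np.clip(np.digitize(pred, edges) - 1, 0, n_bins - 1)
    centers = {w.index: w.center_h for w in model.training_windows}
    wins = sorted(set(widx))
    A = np.zeros((len(wins), n_bins))
    c = np.zeros(len(wins))
    for i, w in enumerate(wins):
        counts = np.bincount(binned[widx == w], minlength=n_bins)
        A[i] = counts / counts.sum()
        c[i] = centers[w]
    D = np.diff(np.eye(n_bins), 2, axis=0)
    M = np.vstack([A, np.sqrt(smoothness) * D])
    rhs = np.concatenate([c - A @ mids, np.zeros(D.shape[0])])
    delta, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    import dataclasses
    return dataclasses.replace(model, calibration=(mids, mids + delta))


# ---------------------------------------------------------------------------
# sex classification
# ---------------------------------------------------------------------------

def classify_sex_gmm(chrx_fraction: np.ndarray, seed: int = 0):
    """Two-component Gaussian mixture on the chrX read fraction.

    The higher-mean component is labelled XX (two X chromosomes yield a
    larger share of chrX-mapped reads).  Returns (labels, params) with
    ``params`` holding component means, sds and weights.
    """
    x = np.asarray(chrx_fraction, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need at least 2 cells")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("chrX fractions must lie in [0, 1]")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all chrX fractions identical")
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3,
                         reg_covar=1e-10)
    gm.fit(x[:, None])
    means = gm.means_.ravel()
    xx_comp = int(np.argmax(means))
    hard = gm.predict(x[:, None])
    labels = np.where(hard == xx_comp, "XX", "XY")
    params = {"means": means, "sds": np.sqrt(gm.covariances_.ravel()),
              "weights": gm.weights_.ravel(), "xx_component": xx_comp}
    return labels, params
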