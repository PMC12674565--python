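"""Random-forest isoscape: fitting, repeated k-fold evaluation, importance,
partial dependence, and raster prediction with quantile-forest uncertainty.

The uncertainty surface follows the quantile-regression-forest construction:
the fitted forest's leaves retain the training responses, a prediction
point's conditional distribution is the leaf-weight-averaged empirical
distribution of those responses, and the reported standard deviation is half
the width of the central 68.27% interval of that distribution.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .covariates import CovariateMatrix
from .grids import RasterGrid

#: central 68.27% interval bounds (mean +/- one sigma of a normal)
SIGMA_QUANTILES = (0.158655, 0.841345)


@dataclasses.dataclass
class FittedIsoscapeModel:
    """A trained forest plus everything needed to reuse and audit it."""

    model: RandomForestRegressor
    covariate_names: list[str]
    X_train: np.ndarray
    y_train: np.ndarray
    seed: int
    training_ranges: dict[str, tuple[float, float]]
    cv_metrics: dict | None = None
    _leaf_cache: tuple | None = dataclasses.field(default=None, repr=False)

    @property
    def n_trees(self) -> int:
        return self.model.n_estimators

    def importance(self) -> pd.Series:
        """Node-impurity importances normalised to sum to 1, descending."""
        imp = np.asarray(self.model.feature_importances_, dtype=float)
        total = imp.sum()
        if total > 0:
            imp = imp / total
        return pd.Series(imp, index=self.covariate_names).sort_values(ascending=False)


@dataclasses.dataclass
class IsoscapeProduct:
    prediction: RasterGrid
    sd: RasterGrid
    metadata: dict

    def __post_init__(self) -> None:
        if not self.prediction.same_geometry(self.sd):
            raise ValueError("prediction and sd rasters are not aligned")
        sd_vals = self.sd.values[np.isfinite(self.sd.values)]
        if sd_vals.size and sd_vals.min() < 0:
            raise ValueError("negative sd cell")


def _matrix_xy(matrix: CovariateMatrix | pd.DataFrame, names, response=None):
    if isinstance(matrix, CovariateMatrix):
        frame = matrix.frame()
        y = matrix.response
    else:
        frame = matrix
        y = np.asarray(response, dtype=float)
    missing = [n for n in names if n not in frame.columns]
    if missing:
        raise KeyError(f"covariates not in matrix: {missing}")
    return frame[list(names)].to_numpy(dtype=float), y


def make_forest(n_trees: int, seed: int, n_features: int) -> RandomForestRegressor:
    """Regression forest with bootstrap bagging and p/3 split candidates.

    Minimum leaf size 2 balances the two calibration demands on the
    leaf-weight quantile construction: singleton leaves under-disperse the
    conditional distribution (intervals too narrow), large leaves mix
    signal variation into it (intervals too wide).
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, n_features // 3) / n_features,
        min_samples_leaf=2,
        bootstrap=True,
        oob_score=False,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )


def fit_rf(matrix: CovariateMatrix | pd.DataFrame, selected: list[str],
           n_trees: int = 3000, seed: int = 0,
           response=None) -> FittedIsoscapeModel:
    """Fit the isoscape forest on the selected covariates."""
    X, y = _matrix_xy(matrix, selected, response)
    rf = make_forest(n_trees, seed, X.shape[1])
    rf.fit(X, y)
    ranges = {n: (float(X[:, k].min()), float(X[:, k].max()))
              for k, n in enumerate(selected)}
    return FittedIsoscapeModel(rf, list(selected), X, y, seed, ranges)


def oob_mse(matrix, selected, n_trees: int = 100, seed: int = 0, response=None) -> float:
    """Out-of-bag mean-squared error of a forest on the given covariates."""
    X, y = _matrix_xy(matrix, selected, response)
    rf = make_forest(n_trees, seed, X.shape[1])
    rf.set_params(oob_score=True)
    rf.fit(X, y)
    pred = rf.oob_prediction_
    ok = np.isfinite(pred)
    return float(np.mean((y[ok] - pred[ok]) ** 2))


def cross_validate(matrix, selected, k: int = 10, repeats: int = 5,
                   n_trees: int = 3000, seed: int = 0, response=None) -> dict:
    """Repeated k-fold CV; RMSE pooled over folds, R^2 = 1 - SSE/SST held-out."""
    X, y = _matrix_xy(matrix, selected, response)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.SeedSequence(seed)
    per_repeat = []
    for r, child in enumerate(rng.spawn(repeats)):
        rs = int(child.generate_state(1)[0] % (2**31))
        pred = np.empty(n)
        for train, test in KFold(k, shuffle=True, random_state=rs).split(X):
            rf = make_forest(n_trees, rs + 1, X.shape[1])
            rf.fit(X[train], y[train])
            pred[test] = rf.predict(X[test])
        sse = float(np.sum((y - pred) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        per_repeat.append({
            "repeat": r,
            "rmse": float(np.sqrt(sse / n)),
            "r2": 1.0 - sse / sst if sst > 0 else float("nan"),
        })
    return {
        "rmse": float(np.mean([p["rmse"] for p in per_repeat])),
        "r2": float(np.mean([p["r2"] for p in per_repeat])),
        "per_repeat": per_repeat,
        "k": k,
        "repeats": repeats,
    }


def partial_dependence(model: FittedIsoscapeModel, covariate: str,
                       n_points: int = 25) -> pd.DataFrame:
    """Mean prediction as one covariate sweeps its training range."""
    if covariate not in model.covariate_names:
        raise KeyError(f"{covariate!r} is not a model covariate")
    k = model.covariate_names.index(covariate)
    lo, hi = model.training_ranges[covariate]
    grid = np.linspace(lo, hi, n_points)
    out = np.empty(n_points)
    X = model.X_train.copy()
    for i, v in enumerate(grid):
        X[:, k] = v
        out[i] = float(model.model.predict(X).mean())
    return pd.DataFrame({covariate: grid, "prediction": out})


# -- quantile-forest machinery ----------------------------------------------

def _leaf_structure(model: FittedIsoscapeModel):
    """Per-tree leaf membership of the training set, cached on the model."""
    if model._leaf_cache is None:
        train_leaves = model.model.apply(model.X_train)  # (n_train, n_trees)
        order = np.argsort(model.y_train, kind="stable")
        model._leaf_cache = (train_leaves, order, model.y_train[order])
    return model._leaf_cache


def conditional_quantiles(model: FittedIsoscapeModel, X: np.ndarray,
                          quantiles=SIGMA_QUANTILES,
                          chunk: int = 512) -> np.ndarray:
    """Quantiles of the forest's conditional response distribution.

    Each training observation receives weight 1/(leaf size * n_trees) in
    every tree whose leaf it shares with the query point; quantiles are read
    from the weighted empirical CDF (left-continuous inverse).
    Returns an array of shape (len(X), len(quantiles)).
    """
    X = np.asarray(X, dtype=float)
    train_leaves, order, y_sorted = _leaf_structure(model)
    train_leaves = train_leaves[order]
    n_train, n_trees = train_leaves.shape
    qs = np.asarray(quantiles, dtype=float)
    out = np.empty((X.shape[0], qs.size))
    for start in range(0, X.shape[0], chunk):
        Xc = X[start:start + chunk]
        pred_leaves = model.model.apply(Xc)          # (m, n_trees)
        W = np.zeros((Xc.shape[0], n_train))
        for t in range(n_trees):
            tl = train_leaves[:, t]
            # map leaf ids to contiguous codes for bincount-style counting
            uniq, codes = np.unique(tl, return_inverse=True)
            counts = np.bincount(codes)
            pl = np.searchsorted(uniq, pred_leaves[:, t])
            pl = np.clip(pl, 0, uniq.size - 1)
            hit = uniq[pl] == pred_leaves[:, t]
            inv_count = 1.0 / counts
            # weight of train i for query q: (same leaf) / leaf count
            W += np.where(hit[:, None], (codes[None, :] == pl[:, None]) * inv_count[codes][None, :], 0.0)
        W /= n_trees
        cdf = np.cumsum(W, axis=1)
        for qi, q in enumerate(qs):
            idx = np.sum(cdf < q - 1e-12, axis=1)
            out[start:start + chunk, qi] = y_sorted[np.clip(idx, 0, n_train - 1)]
    return out


def conditional_sd(model: FittedIsoscapeModel, X: np.ndarray,
                   quantile_pair=SIGMA_QUANTILES) -> np.ndarray:
    """Half-width of the central 68.27% conditional interval."""
    q = conditional_quantiles(model, X, quantile_pair)
    return (q[:, 1] - q[:, 0]) / 2.0


def predict_raster(model: FittedIsoscapeModel, stack: dict[str, RasterGrid],
                   quantile_pair=SIGMA_QUANTILES) -> IsoscapeProduct:
    """Predict ratio + SD rasters over an aligned covariate stack.

    A cell missing any covariate is nodata in both outputs.  Cells are
    processed in fixed row-major order so the product is bit-stable.
    """
    missing = [n for n in model.covariate_names if n not in stack]
    if missing:
        raise KeyError(f"stack lacks covariates: {missing}")
    grids = [stack[n] for n in model.covariate_names]
    ref = grids[0]
    for g in grids[1:]:
        if not g.same_geometry(ref):
            raise ValueError("covariate rasters are not aligned")
    cube = np.stack([g.values for g in grids], axis=-1)  # (ny, nx, p)
    valid = np.all(np.isfinite(cube), axis=-1)
    pred = np.full(ref.shape, np.nan)
    sd = np.full(ref.shape, np.nan)
    if valid.any():
        Xv = cube[valid]
        pred[valid] = model.model.predict(Xv)
        sd[valid] = conditional_sd(model, Xv, quantile_pair)
    return IsoscapeProduct(
        prediction=ref.like(pred),
        sd=ref.like(sd),
        metadata={
            "learner": "random-forest",
            "n_trees": model.n_trees,
            "covariates": model.covariate_names,
            "quantile_pair": list(quantile_pair),
            "seed": model.seed,
        },
    )
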