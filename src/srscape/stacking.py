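"""Stacked-ensemble (super-learner) isoscape with oblique geographic
coordinates and spatially blocked cross-validation.

Five base learners (random forest, gradient boosting, support-vector
regression, a feed-forward neural network, and an elastic-net linear model)
are trained on covariates augmented with oblique coordinates — rotated
linear combinations of projected site coordinates that let the ensemble
absorb broad-scale spatial trend.  A linear meta-learner is fit on
out-of-fold base predictions only; evaluation uses five spatially blocked
folds (k-means on projected coordinates) so that no training point shares a
block with a held-out point.
"""

from __future__ import annotations

import copy
import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNetCV
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .forest import (FittedIsoscapeModel, IsoscapeProduct, conditional_sd,
                     fit_rf)
from .grids import EARTH_RADIUS_KM, RasterGrid

DEFAULT_ANGLES = (0.0, 45.0, 90.0, 135.0)


def laea_project(lon, lat, lon0: float, lat0: float):
    """Spherical Lambert azimuthal equal-area projection, km."""
    lon, lat = np.radians(np.asarray(lon, float)), np.radians(np.asarray(lat, float))
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    dlam = lon - lam0
    denom = 1.0 + np.sin(phi0) * np.sin(lat) + np.cos(phi0) * np.cos(lat) * np.cos(dlam)
    k = np.sqrt(2.0 / np.maximum(denom, 1e-12))
    x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(dlam)
    y = EARTH_RADIUS_KM * k * (np.cos(phi0) * np.sin(lat) - np.sin(phi0) * np.cos(lat) * np.cos(dlam))
    return x, y


def oblique_coordinates(x, y, angles_deg=DEFAULT_ANGLES) -> pd.DataFrame:
    """c_theta = x cos(theta) + y sin(theta) for each angle, as named columns."""
    angles = list(angles_deg)
    if not angles:
        warnings.warn("empty oblique-angle set: no spatial features added")
        return pd.DataFrame(index=range(len(np.atleast_1d(x))))
    for a in angles:
        if not (0.0 <= a < 180.0):
            raise ValueError(f"angle {a} outside [0, 180)")
    x, y = np.asarray(x, float), np.asarray(y, float)
    cols = {f"oblique_{a:g}": x * np.cos(np.radians(a)) + y * np.sin(np.radians(a))
            for a in angles}
    return pd.DataFrame(cols)


def make_base_learners(seed: int, rf_trees: int = 500) -> dict:
    """The default base-learner set.

    Scale-sensitive learners (SVR, neural net, elastic net) standardise both
    features and target: an 87Sr/86Sr response has an SD of ~1e-3, far below
    the default loss scales of those learners (e.g. SVR's epsilon tube).
    Tree ensembles are scale-equivariant and run raw.
    """
    rs = int(seed) % (2**31)

    def scaled(est):
        return TransformedTargetRegressor(
            regressor=make_pipeline(StandardScaler(), est),
            transformer=StandardScaler())

    return {
        "rf": RandomForestRegressor(n_estimators=rf_trees, random_state=rs, n_jobs=1),
        "gbm": GradientBoostingRegressor(random_state=rs),
        "svr": scaled(SVR()),
        "nnet": scaled(MLPRegressor(hidden_layer_sizes=(64,), max_iter=2000,
                                    random_state=rs)),
        "enet": scaled(ElasticNetCV(l1_ratio=[0.1, 0.5, 0.9, 1.0],
                                    cv=5, random_state=rs)),
    }


@dataclasses.dataclass
class StackSpec:
    k_folds: int = 5
    angles: tuple[float, ...] = DEFAULT_ANGLES
    rf_trees: int = 500
    qrf_trees: int = 500
    seed: int = 0
    base_learners: dict | None = None  # name -> unfitted estimator


@dataclasses.dataclass
class FittedStack:
    base_models: dict
    meta: ConvexCombiner
    base_order: list[str]
    feature_names: list[str]
    covariate_names: list[str]       # without oblique columns
    proj_center: tuple[float, float]
    angles: tuple[float, ...]
    fold_labels: np.ndarray
    cv_metrics: dict
    qrf: FittedIsoscapeModel          # uncertainty forest on the same features
    y_range: tuple[float, float]

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        X = frame[self.feature_names].to_numpy(float)
        Z = np.column_stack([self.base_models[n].predict(X) for n in self.base_order])
        return self.meta.predict(Z)


class ConvexCombiner:
    """Linear meta-learner constrained to a convex combination.

    Non-negative least squares on the base predictions, weights normalised
    to sum to one — the classic super-learner combiner.  Keeps the stack
    inside the envelope of its base learners, which OLS does not.
    """

    weights_: np.ndarray

    def fit(self, Z: np.ndarray, y: np.ndarray) -> "ConvexCombiner":
        from scipy.optimize import nnls
        w, _ = nnls(np.asarray(Z, float), np.asarray(y, float))
        total = w.sum()
        self.weights_ = w / total if total > 0 else np.full(Z.shape[1], 1.0 / Z.shape[1])
        return self

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, float) @ self.weights_


def spatial_folds(x, y, k: int, seed: int) -> np.ndarray:
    """k-means blocks on projected coordinates; returns labels per point."""
    xy = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
    return km.fit_predict(xy)


def _rmse(a, b) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def fit_stack(frame: pd.DataFrame, y, lon, lat, spec: StackSpec) -> FittedStack:
    """Fit the super learner with spatially blocked out-of-fold stacking.

    The meta-learner sees only out-of-fold base predictions.  A base learner
    whose fit raises is excluded with a warning and the stack proceeds on
    the remainder.
    """
    y = np.asarray(y, float)
    lon0, lat0 = float(np.mean(lon)), float(np.mean(lat))
    px, py = laea_project(lon, lat, lon0, lat0)
    obl = oblique_coordinates(px, py, spec.angles)
    full = pd.concat([frame.reset_index(drop=True), obl.reset_index(drop=True)], axis=1)
    feature_names = list(full.columns)
    X = full.to_numpy(float)

    labels = spatial_folds(px, py, spec.k_folds, spec.seed)
    learners = spec.base_learners or make_base_learners(spec.seed, spec.rf_trees)

    # out-of-fold base predictions
    names = list(learners.keys())
    Z = np.full((len(y), len(names)), np.nan)
    ok_names = []
    for j, name in enumerate(names):
        try:
            for f in np.unique(labels):
                tr, te = labels != f, labels == f
                est = copy.deepcopy(learners[name])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[tr], y[tr])
                Z[te, j] = est.predict(X[te])
            ok_names.append(name)
        except Exception as exc:  # convergence or numerical failure
            warnings.warn(f"base learner {name!r} excluded: {exc}")
    if len(ok_names) < 2:
        raise RuntimeError("fewer than two base learners usable")
    keep = [names.index(n) for n in ok_names]
    Z = Z[:, keep]

    # leakage-free stack CV: refit meta excluding the evaluated fold
    stack_pred = np.empty(len(y))
    for f in np.unique(labels):
        tr, te = labels != f, labels == f
        m = ConvexCombiner().fit(Z[tr], y[tr])
        stack_pred[te] = m.predict(Z[te])
    sst = float(np.sum((y - y.mean()) ** 2))
    cv = {
        "stack": {"rmse": _rmse(stack_pred, y),
                  "r2": 1.0 - float(np.sum((y - stack_pred) ** 2)) / sst if sst else float("nan")},
        "base": {n: {"rmse": _rmse(Z[:, ok_names.index(n)], y)} for n in sorted(ok_names)},
        "fold_sizes": np.bincount(labels).tolist(),
        "learner_params": {n: str(learners[n]) for n in ok_names},
    }
    # keep base order stable under permutation of the input dict
    order = sorted(ok_names)
    Z = Z[:, [ok_names.index(n) for n in order]]
    meta = ConvexCombiner().fit(Z, y)

    # full-data base refits for deployment
    base_models = {}
    for n in order:
        est = copy.deepcopy(learners[n])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
        base_models[n] = est

    qrf = fit_rf(full, feature_names, n_trees=spec.qrf_trees,
                 seed=spec.seed + 1, response=y)
    return FittedStack(base_models, meta, order, feature_names,
                       list(frame.columns), (lon0, lat0), tuple(spec.angles),
                       labels, cv, qrf, (float(y.min()), float(y.max())))


def predict_raster_stack(model: FittedStack, stack: dict[str, RasterGrid]) -> IsoscapeProduct:
    """EML prediction + quantile-forest SD rasters over an aligned stack."""
    missing = [n for n in model.covariate_names if n not in stack]
    if missing:
        raise KeyError(f"stack lacks covariates: {missing}")
    grids = [stack[n] for n in model.covariate_names]
    ref = grids[0]
    for g in grids[1:]:
        if not g.same_geometry(ref):
            raise ValueError("covariate rasters are not aligned")
    lons, lats = ref.cell_centers()
    px, py = laea_project(lons.ravel(), lats.ravel(), *model.proj_center)
    obl = oblique_coordinates(px, py, model.angles)
    cube = np.stack([g.values for g in grids], axis=-1)
    valid = np.all(np.isfinite(cube), axis=-1)
    flat_valid = valid.ravel()
    frame = pd.DataFrame(cube.reshape(-1, len(model.covariate_names))[flat_valid],
                         columns=model.covariate_names)
    frame = pd.concat([frame.reset_index(drop=True),
                       obl[flat_valid].reset_index(drop=True)], axis=1)
    pred = np.full(ref.shape, np.nan)
    sd = np.full(ref.shape, np.nan)
    if len(frame):
        p = model.predict_frame(frame)
        # the linear meta-combination can leave the physical training range;
        # clip to it, as forests do by construction
        p = np.clip(p, *model.y_range)
        pred[valid] = p
        sd[valid] = conditional_sd(model.qrf, frame[model.qrf.covariate_names].to_numpy(float))
    return IsoscapeProduct(ref.like(pred), ref.like(sd), {
        "learner": "stacked-ensemble",
        "base_learners": model.base_order,
        "angles": list(model.angles),
        "covariates": model.covariate_names,
    })
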