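"""Forest-based three-step variable selection (threshold, interpretation,
prediction), in the style of the VSURF procedure.

Step 1 ranks predictors by mean permutation importance over an ensemble of
forests and discards those below a data-driven threshold (the minimum of a
regression-tree fit to the importance-SD-versus-rank curve).  Step 2 grows
nested models along the ranking and keeps the smallest whose OOB error is
within one SD of the best.  Step 3 walks the interpretation set and admits a
variable only if it improves OOB error by more than the noise-level
fluctuation estimated from the discarded variables.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance
from sklearn.tree import DecisionTreeRegressor

from .covariates import CovariateMatrix
from .forest import make_forest, oob_mse


@dataclasses.dataclass
class SelectionResult:
    ranking: list[str]                   # all inputs, by mean importance desc
    importance_mean: pd.Series
    importance_sd: pd.Series
    threshold: float
    thresholded: list[str]
    interpretation: list[str]
    prediction: list[str]
    oob_trajectories: dict[str, list[float]]
    seed: int

    @property
    def informative(self) -> bool:
        return bool(self.thresholded)

    def assert_nested(self) -> None:
        assert set(self.prediction) <= set(self.interpretation)
        assert set(self.interpretation) <= set(self.thresholded)
        assert set(self.thresholded) <= set(self.ranking)

    def as_dict(self) -> dict:
        return {
            "ranking": self.ranking,
            "importance_mean": self.importance_mean.to_dict(),
            "importance_sd": self.importance_sd.to_dict(),
            "threshold": self.threshold,
            "thresholded": self.thresholded,
            "interpretation": self.interpretation,
            "prediction": self.prediction,
            "oob_trajectories": self.oob_trajectories,
            "seed": self.seed,
        }


def _xy(matrix, response):
    if isinstance(matrix, CovariateMatrix):
        return matrix.frame(), matrix.response
    return matrix, np.asarray(response, dtype=float)


def select_variables(matrix, response=None, n_forests: int = 50,
                     n_forests_nested: int = 25, n_trees: int = 300,
                     noise_walk_max: int = 8, seed: int = 0) -> SelectionResult:
    """Run the three-step selection; deterministic under ``seed``.

    An all-noise input (nothing survives the thresholding step) yields a
    result with empty sets rather than an exception.
    """
    frame, y = _xy(matrix, response)
    if len(y) < 10:
        raise ValueError("need at least 10 observations")
    names = list(frame.columns)
    X = frame.to_numpy(dtype=float)
    p = X.shape[1]
    ss = np.random.SeedSequence(seed)
    s_thresh, s_tree, s_nested, s_pred = (int(c.generate_state(1)[0] % (2**31))
                                          for c in ss.spawn(4))

    # Step 1: importance ranking and data-driven threshold.  Importance is
    # permutation importance on a held-out third (out-of-sample, so noise
    # variables score near zero), averaged over n_forests forests.
    imps = np.empty((n_forests, p))
    rng = np.random.default_rng(s_thresh)
    for f in range(n_forests):
        perm = rng.permutation(len(y))
        cut = max(10, int(0.67 * len(y)))
        tr, te = perm[:cut], perm[cut:]
        rf = make_forest(n_trees, s_thresh + f, p)
        rf.fit(X[tr], y[tr])
        pi = permutation_importance(rf, X[te], y[te], n_repeats=1,
                                    random_state=s_thresh + f, n_jobs=1)
        imps[f] = pi.importances_mean
    imp_mean = pd.Series(imps.mean(axis=0), index=names)
    imp_sd = pd.Series(imps.std(axis=0, ddof=1) if n_forests > 1 else np.zeros(p),
                       index=names)
    ranking = list(imp_mean.sort_values(ascending=False).index)
    sd_by_rank = imp_sd[ranking].to_numpy()
    rank_idx = np.arange(p, dtype=float).reshape(-1, 1)
    tree = DecisionTreeRegressor(random_state=s_tree, min_samples_leaf=max(1, p // 10))
    tree.fit(rank_idx, sd_by_rank)
    threshold = float(tree.predict(rank_idx).min())
    thresholded = [n for n in ranking if imp_mean[n] >= threshold and imp_mean[n] > 0]

    trajectories: dict[str, list[float]] = {}
    if not thresholded:
        return SelectionResult(ranking, imp_mean, imp_sd, threshold,
                               [], [], [], trajectories, seed)

    def nested_oob(subset: list[str], n_rep: int, base_seed: int) -> tuple[float, float]:
        errs = [oob_mse(frame, subset, n_trees=n_trees, seed=base_seed + r, response=y)
                for r in range(n_rep)]
        return float(np.mean(errs)), float(np.std(errs, ddof=1)) if n_rep > 1 else 0.0

    # Step 2: smallest nested model within one SD of the minimum OOB error
    means, sds = [], []
    for k in range(1, len(thresholded) + 1):
        m, s = nested_oob(thresholded[:k], n_forests_nested, s_nested + 1000 * k)
        means.append(m)
        sds.append(s)
    trajectories["interpretation"] = means
    kmin = int(np.argmin(means))
    cutoff = means[kmin] + sds[kmin]
    k_interp = next(k for k in range(len(means)) if means[k] <= cutoff)
    interpretation = thresholded[: k_interp + 1]

    # Step 3: noise-fluctuation gate over the interpretation ranking.  The
    # noise level is the mean absolute OOB-error jump along a walk that
    # appends discarded (noise) variables to the interpretation set; the
    # walk is capped — a handful of steps pins the fluctuation scale.
    discarded = [n for n in ranking if n not in interpretation][:noise_walk_max]
    n_walk = max(2, n_forests_nested // 2)
    fluct_errs = []
    base = list(interpretation)
    prev, _ = nested_oob(base, n_walk, s_pred)
    fluct_errs.append(prev)
    for j, extra in enumerate(discarded):
        cur, _ = nested_oob(base + discarded[: j + 1], n_walk,
                            s_pred + 7919 * (j + 1))
        fluct_errs.append(cur)
    trajectories["noise_walk"] = fluct_errs
    if len(fluct_errs) > 1:
        fluct = float(np.mean(np.abs(np.diff(fluct_errs))))
    else:
        fluct = sds[kmin]

    prediction = [interpretation[0]]
    current, _ = nested_oob(prediction, n_forests_nested, s_pred + 13)
    traj_pred = [current]
    for var in interpretation[1:]:
        cand, _ = nested_oob(prediction + [var], n_forests_nested,
                             s_pred + 13 + 101 * len(prediction))
        if current - cand > fluct:
            prediction = prediction + [var]
            current = cand
        traj_pred.append(cand)
    trajectories["prediction"] = traj_pred

    result = SelectionResult(ranking, imp_mean, imp_sd, threshold,
                             thresholded, interpretation, prediction,
                             trajectories, seed)
    result.assert_nested()
    return result
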