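"""Incremental sampling-effort calibration.

Quantifies how adding random fractions of a newly surveyed regional sample
set to an existing (possibly empty) baseline database improves local
prediction accuracy (held-out RMSE) and precision (mean quantile-forest SD
at the held-out sites).  Fractions run 0–100% in 10% steps; every fraction
below 1.0 is repeated with fresh random draws, while 100% is evaluated once
on all new sites (in-sample, and flagged as such).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .covariates import CovariateMatrix
from .forest import conditional_sd, fit_rf

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


@dataclasses.dataclass
class CalibrationCurve:
    table: pd.DataFrame    # fraction, repeat, n_train_new, n_eval, rmse, mean_sd, in_sample
    repeats: int
    seed: int

    def summary(self) -> pd.DataFrame:
        return (self.table.groupby("fraction", as_index=False)
                .agg(rmse=("rmse", "mean"), mean_sd=("mean_sd", "mean"),
                     n_repeats=("repeat", "nunique")))


def incremental_calibration(base: CovariateMatrix | None, new: CovariateMatrix,
                            fractions=DEFAULT_FRACTIONS, repeats: int = 10,
                            n_trees: int = 300, seed: int = 0) -> CalibrationCurve:
    """Run the incremental-addition experiment.

    ``base`` and ``new`` must share covariate columns.  For each fraction f
    and repeat, floor(f*n) new sites are drawn without replacement, the
    forest is trained on base + drawn, and RMSE / mean predicted SD are
    measured at the remaining new sites.
    """
    if len(new.site_ids) == 0:
        raise ValueError("new regional data must be nonempty")
    for f in fractions:
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"fraction {f} outside [0, 1]")
    if base is not None and list(base.names) != list(new.names):
        raise ValueError("base and new matrices carry different covariates")
    names = list(new.names)
    Xn, yn = new.values, new.response
    if base is not None:
        Xb, yb = base.values, base.response
    else:
        Xb, yb = np.empty((0, len(names))), np.empty(0)
    n_new = len(yn)
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        n_draw = int(np.floor(f * n_new))
        reps = 1 if f >= 1.0 else repeats
        for r in range(reps):
            perm = rng.permutation(n_new)
            drawn, held = perm[:n_draw], perm[n_draw:]
            in_sample = held.size == 0
            eval_idx = np.arange(n_new) if in_sample else held
            assert in_sample or not set(drawn) & set(eval_idx)
            Xtr = np.vstack([Xb, Xn[drawn]])
            ytr = np.concatenate([yb, yn[drawn]])
            if len(ytr) == 0:
                rows.append({"fraction": f, "repeat": r, "n_train_new": 0,
                             "n_eval": len(eval_idx), "rmse": np.nan,
                             "mean_sd": np.nan, "in_sample": in_sample})
                continue
            frame = pd.DataFrame(Xtr, columns=names)
            model = fit_rf(frame, names, n_trees=n_trees,
                           seed=seed + 1000 * r + int(round(f * 10)), response=ytr)
            pred = model.model.predict(Xn[eval_idx])
            sd = conditional_sd(model, Xn[eval_idx])
            rows.append({
                "fraction": f,
                "repeat": r,
                "n_train_new": int(n_draw),
                "n_eval": int(len(eval_idx)),
                "rmse": float(np.sqrt(np.mean((yn[eval_idx] - pred) ** 2))),
                "mean_sd": float(np.mean(sd)),
                "in_sample": in_sample,
            })
    return CalibrationCurve(pd.DataFrame(rows), repeats, seed)
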