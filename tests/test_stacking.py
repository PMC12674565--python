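import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression

from srscape.covariates import extract_at_points
from srscape.stacking import (StackSpec, fit_stack, laea_project,
                              oblique_coordinates, predict_raster_stack,
                              spatial_folds)


class TestObliqueCoordinates:
    def test_axis_identities(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        obl = oblique_coordinates(x, y, [0.0, 90.0])
        assert np.allclose(obl["oblique_0"], x)
        assert np.allclose(obl["oblique_90"], y)

    def test_45_degree_closed_form(self):
        obl = oblique_coordinates([1.0], [1.0], [45.0])
        assert obl["oblique_45"].iloc[0] == pytest.approx(np.sqrt(2), abs=1e-5)

    def test_empty_angles_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            obl = oblique_coordinates([1.0], [1.0], [])
        assert obl.shape[1] == 0

    def test_out_of_range_angle_rejected(self):
        with pytest.raises(ValueError):
            oblique_coordinates([0.0], [0.0], [180.0])


def test_laea_preserves_local_distances():
    # ~1 deg lat step near 48N should project to ~111 km in y
    x0, y0 = laea_project(101.0, 48.0, 101.0, 48.0)
    x1, y1 = laea_project(101.0, 49.0, 101.0, 48.0)
    assert (x0, y0) == (0.0, 0.0)
    assert np.hypot(x1 - x0, y1 - y0) == pytest.approx(111.2, abs=0.5)


def _cheap_spec(seed, learners=None):
    return StackSpec(seed=seed, rf_trees=60, qrf_trees=60, base_learners=learners)


def _cheap_learners(seed):
    return {
        "rf": RandomForestRegressor(n_estimators=60, random_state=seed, n_jobs=1),
        "lin": LinearRegression(),
    }


class TestFitStack:
    def test_constant_base_predictions_reproduced(self, small_matrix):
        """If every base learner outputs the same constant the meta-learner
        must reproduce it exactly."""
        learners = {"a": DummyRegressor(strategy="constant", constant=0.710),
                    "b": DummyRegressor(strategy="constant", constant=0.710)}
        fs = fit_stack(small_matrix.frame(), np.full(len(small_matrix.response), 0.710),
                       small_matrix.lon, small_matrix.lat, _cheap_spec(0, learners))
        query = small_matrix.frame().reset_index(drop=True).assign(
            **{n: 0.0 for n in fs.feature_names if n.startswith("oblique")})
        assert np.allclose(fs.predict_frame(query), 0.710)

    def test_spatial_blocks_are_disjoint_bruteforce(self, small_matrix):
        """No training point shares a block with a held-out point: every
        point's k-means label is checked by brute-force scan."""
        from srscape.stacking import laea_project
        px, py = laea_project(small_matrix.lon, small_matrix.lat,
                              small_matrix.lon.mean(), small_matrix.lat.mean())
        labels = spatial_folds(px, py, 5, seed=3)
        assert set(labels) == set(range(5))
        for f in range(5):
            train = np.flatnonzero(labels != f)
            held = np.flatnonzero(labels == f)
            assert not set(train) & set(held)
            assert len(train) + len(held) == len(labels)

    def test_base_order_permutation_invariant(self, small_matrix):
        frame, y = small_matrix.frame(), small_matrix.response
        a = fit_stack(frame, y, small_matrix.lon, small_matrix.lat,
                      _cheap_spec(1, _cheap_learners(1)))
        swapped = dict(reversed(list(_cheap_learners(1).items())))
        b = fit_stack(frame, y, small_matrix.lon, small_matrix.lat,
                      _cheap_spec(1, swapped))
        assert a.base_order == b.base_order
        assert np.allclose(a.meta.weights_, b.meta.weights_)

    def test_label_shuffle_collapses_stack_skill(self, small_matrix):
        """Leakage check: with shuffled responses the spatially blocked
        stack CV R^2 collapses to noise level."""
        rng = np.random.default_rng(17)
        y_shuf = rng.permutation(small_matrix.response)
        fs = fit_stack(small_matrix.frame(), y_shuf, small_matrix.lon,
                       small_matrix.lat, _cheap_spec(2, _cheap_learners(2)))
        assert fs.cv_metrics["stack"]["r2"] <= 0.1

    def test_failing_learner_excluded_with_diagnostic(self, small_matrix):
        class Exploder:
            def fit(self, X, y):
                raise FloatingPointError("no convergence")
        learners = {**_cheap_learners(3), "bad": Exploder()}
        with pytest.warns(UserWarning, match="excluded"):
            fs = fit_stack(small_matrix.frame(), small_matrix.response,
                           small_matrix.lon, small_matrix.lat, _cheap_spec(3, learners))
        assert "bad" not in fs.base_order and len(fs.base_order) == 2


class TestPredictRasterStack:
    def test_constant_response_constant_raster(self, small_world, small_matrix):
        y = np.full(len(small_matrix.response), 0.711)
        fs = fit_stack(small_matrix.frame(), y, small_matrix.lon, small_matrix.lat,
                       _cheap_spec(4, _cheap_learners(4)))
        prod = predict_raster_stack(fs, small_world.covariates)
        vals = prod.prediction.values[np.isfinite(prod.prediction.values)]
        assert np.allclose(vals, 0.711)
        assert np.nanmax(prod.sd.values) == 0.0

    def test_rf_and_eml_rasters_agree_when_signal_is_covariate_driven(
            self, small_world, small_matrix):
        """On a covariate-driven synthetic world the two isoscapes should
        differ by ~1e-3 or less on average."""
        from srscape.forest import fit_rf, predict_raster
        rf = fit_rf(small_matrix, small_matrix.names, n_trees=150, seed=5)
        rf_prod = predict_raster(rf, small_world.covariates)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fs = fit_stack(small_matrix.frame(), small_matrix.response,
                           small_matrix.lon, small_matrix.lat,
                           StackSpec(seed=5, rf_trees=150, qrf_trees=150))
        eml_prod = predict_raster_stack(fs, small_world.covariates)
        diff = np.abs(eml_prod.prediction.values - rf_prod.prediction.values)
        assert np.nanmean(diff) <= 0.001
        # EML constrains extreme spatial uncertainty relative to plain RF
        q99 = np.nanquantile(rf_prod.sd.values, 0.99)
        assert np.nanquantile(eml_prod.sd.values, 0.99) <= q99 * 1.5
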