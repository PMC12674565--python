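import numpy as np
import pandas as pd
import pytest

from srscape.forest import (conditional_sd, cross_validate, fit_rf,
                            partial_dependence, predict_raster)
from srscape.grids import RasterGrid


def _frame(rng, n=300, p=3):
    return pd.DataFrame(rng.standard_normal((n, p)),
                        columns=[f"x{i}" for i in range(p)])


class TestFit:
    def test_constant_response(self, rng):
        frame = _frame(rng)
        y = np.full(len(frame), 0.710)
        m = fit_rf(frame, list(frame.columns), n_trees=50, seed=0, response=y)
        assert m.model.predict(frame.to_numpy()) == pytest.approx(0.710, abs=1e-12)
        assert np.all(conditional_sd(m, frame.to_numpy()) == 0.0)

    def test_permuted_labels_have_no_skill(self):
        rng = np.random.default_rng(21)
        frame = _frame(rng, n=300)
        y = 0.710 + 0.003 * frame["x0"].to_numpy() + rng.normal(0, 5e-4, 300)
        y_perm = rng.permutation(y)
        cv = cross_validate(frame, list(frame.columns), k=5, repeats=2,
                            n_trees=100, seed=1, response=y_perm)
        assert cv["r2"] <= 0.1

    def test_invalid_tree_count(self, rng):
        frame = _frame(rng, n=50)
        with pytest.raises(ValueError):
            fit_rf(frame, list(frame.columns), n_trees=0, response=np.zeros(50))

    def test_predictions_within_training_range(self, small_matrix):
        m = fit_rf(small_matrix, small_matrix.names, n_trees=100, seed=2)
        pred = m.model.predict(small_matrix.values)
        assert pred.min() >= small_matrix.response.min()
        assert pred.max() <= small_matrix.response.max()


class TestCrossValidate:
    def test_noiseless_step_function_learned(self):
        """A step function of one covariate with zero noise is learned to
        near machine accuracy."""
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, 600)
        x = x[np.abs(x) > 0.05]  # margin so the step is unambiguous
        y = np.where(x > 0, 0.715, 0.708)
        frame = pd.DataFrame({"x": x})
        cv = cross_validate(frame, ["x"], k=5, repeats=2, n_trees=200,
                            seed=4, response=y)
        assert cv["rmse"] <= 1e-4 and cv["r2"] >= 0.999

    def test_rmse_tracks_known_noise_floor(self):
        """With N(0, 3e-3) response noise on a learnable signal, held-out
        RMSE sits just above the noise floor."""
        rng = np.random.default_rng(5)
        rmses = []
        for seed in range(10):
            x = rng.uniform(-1, 1, 400)
            y = 0.710 + 0.005 * x + rng.normal(0, 0.003, 400)
            cv = cross_validate(pd.DataFrame({"x": x}), ["x"], k=5, repeats=1,
                                n_trees=100, seed=seed, response=y)
            rmses.append(cv["rmse"])
        assert 0.003 <= np.mean(rmses) <= 0.0045

    def test_determinism(self, small_matrix):
        a = cross_validate(small_matrix, small_matrix.names, k=5, repeats=2,
                           n_trees=60, seed=9)
        b = cross_validate(small_matrix, small_matrix.names, k=5, repeats=2,
                           n_trees=60, seed=9)
        assert a == b

    def test_k_larger_than_n_rejected(self, rng):
        frame = _frame(rng, n=5)
        with pytest.raises(ValueError):
            cross_validate(frame, list(frame.columns), k=10, response=np.zeros(5))


class TestImportanceAndPdp:
    def test_informative_variable_dominates(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            frame = pd.DataFrame({"inf": rng.standard_normal(250),
                                  "noise": rng.standard_normal(250)})
            y = 0.710 + 0.004 * frame["inf"].to_numpy() + rng.normal(0, 1e-3, 250)
            m = fit_rf(frame, ["inf", "noise"], n_trees=100, seed=seed, response=y)
            imp = m.importance()
            wins += imp["inf"] > imp["noise"]
            assert imp.sum() == pytest.approx(1.0)
        assert wins >= 8

    def test_pdp_recovers_slope_sign(self):
        rng = np.random.default_rng(8)
        frame = pd.DataFrame({"up": rng.uniform(0, 1, 400),
                              "down": rng.uniform(0, 1, 400)})
        y = (0.710 + 0.004 * frame["up"] - 0.003 * frame["down"]).to_numpy()
        m = fit_rf(frame, ["up", "down"], n_trees=150, seed=1, response=y)
        up = partial_dependence(m, "up")["prediction"].to_numpy()
        down = partial_dependence(m, "down")["prediction"].to_numpy()
        assert up[-1] > up[0] and np.corrcoef(np.arange(len(up)), up)[0, 1] > 0.9
        assert down[-1] < down[0]

    def test_pdp_constant_covariate_flat(self, rng):
        frame = pd.DataFrame({"x": rng.standard_normal(100),
                              "const": np.full(100, 2.5)})
        y = 0.710 + 0.002 * frame["x"].to_numpy()
        m = fit_rf(frame, ["x", "const"], n_trees=50, seed=2, response=y)
        pdp = partial_dependence(m, "const")["prediction"]
        assert pdp.nunique() == 1
        assert pdp.iloc[0] == pytest.approx(m.model.predict(m.X_train).mean())

    def test_unknown_covariate_rejected(self, small_matrix):
        m = fit_rf(small_matrix, small_matrix.names[:2], n_trees=20, seed=0)
        with pytest.raises(KeyError):
            partial_dependence(m, "nope")


class TestPredictRaster:
    def test_degenerate_leaves_constant_product(self, rng):
        frame = _frame(rng, n=100, p=2)
        y = np.full(100, 0.710)
        m = fit_rf(frame, ["x0", "x1"], n_trees=50, seed=0, response=y)
        stack = {"x0": RasterGrid(rng.normal(size=(6, 6)), 0, 1, 0.1, -0.1),
                 "x1": RasterGrid(rng.normal(size=(6, 6)), 0, 1, 0.1, -0.1)}
        prod = predict_raster(m, stack)
        assert prod.prediction.values == pytest.approx(0.710, abs=1e-12)
        assert np.all(prod.sd.values == 0.0)

    def test_nodata_propagates(self, rng):
        frame = _frame(rng, n=100, p=2)
        y = 0.71 + 0.001 * frame["x0"].to_numpy()
        m = fit_rf(frame, ["x0", "x1"], n_trees=30, seed=1, response=y)
        v0 = rng.normal(size=(5, 5))
        v0[2, 3] = np.nan
        stack = {"x0": RasterGrid(v0, 0, 1, 0.1, -0.1),
                 "x1": RasterGrid(rng.normal(size=(5, 5)), 0, 1, 0.1, -0.1)}
        prod = predict_raster(m, stack)
        assert np.isnan(prod.prediction.values[2, 3]) and np.isnan(prod.sd.values[2, 3])
        assert np.isfinite(prod.prediction.values).sum() == 24

    def test_misaligned_grids_rejected(self, rng):
        frame = _frame(rng, n=50, p=2)
        m = fit_rf(frame, ["x0", "x1"], n_trees=10, seed=0,
                   response=np.full(50, 0.71))
        stack = {"x0": RasterGrid(np.zeros((5, 5)), 0, 1, 0.1, -0.1),
                 "x1": RasterGrid(np.zeros((6, 5)), 0, 1, 0.1, -0.1)}
        with pytest.raises(ValueError, match="aligned"):
            predict_raster(m, stack)

    def test_sd_raster_width_matches_injected_noise(self):
        """Cells drawn as signal + N(0, 2e-3): the quantile-forest SD raster
        averages near the injected sigma."""
        rng = np.random.default_rng(13)
        n = 1500
        frame = pd.DataFrame({"x": rng.uniform(-1, 1, n)})
        y = 0.712 + 0.004 * frame["x"].to_numpy() + rng.normal(0, 0.002, n)
        m = fit_rf(frame, ["x"], n_trees=300, seed=3, response=y)
        stack = {"x": RasterGrid(rng.uniform(-1, 1, (20, 20)), 0, 1, 0.1, -0.1)}
        prod = predict_raster(m, stack)
        assert 0.0015 <= np.nanmean(prod.sd.values) <= 0.0025
        assert np.nanmin(prod.sd.values) >= 0.0
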