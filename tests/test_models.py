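import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from conftest import fit_logistic_oracle, grid_search_logistic
from habscale.models import (
    FittedModel,
    ModelError,
    SeparationError,
    all_subsets,
    fit_logistic,
    predict_suitability,
    standardize,
)
from habscale.raster import PredictorRaster, ScaledPredictorStack


def empty_design(n):
    return pd.DataFrame(index=range(n))


class TestFitLogistic:
    def test_intercept_only_matches_closed_form_proportion(self):
        # 138 presences among 1455 stations: MLE intercept = logit(138/1455)
        y = np.zeros(1455)
        y[:138] = 1
        m = fit_logistic(empty_design(1455), y)
        assert m.intercept == pytest.approx(np.log(138 / 1317), abs=1e-6)
        assert m.intercept == pytest.approx(-2.256, abs=1e-3)

    def test_intercept_only_aicc_matches_hand_formula(self):
        y = np.zeros(1455)
        y[:138] = 1
        m = fit_logistic(empty_design(1455), y)
        p = 138 / 1455
        ll = 1455 * (p * np.log(p) + (1 - p) * np.log(1 - p))
        aic = -2 * ll + 2
        assert m.aic == pytest.approx(aic, abs=1e-6)
        assert m.aicc == pytest.approx(aic + 2 * 1 * 2 / (1455 - 2), abs=1e-6)

    def test_tiny_dataset_matches_grid_search_oracle(self):
        x = np.array([-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0])
        y = np.array([0, 0, 1, 0, 1, 0, 1, 1])
        m = fit_logistic(pd.DataFrame({"x": x}), y)
        oracle = grid_search_logistic(x, y)
        assert np.allclose(m.estimates, oracle, atol=1e-3)

    def test_wald_summary_identities(self, rng):
        x = rng.standard_normal(300)
        y = (rng.uniform(size=300) < expit(0.8 * x)).astype(int)
        m = fit_logistic(pd.DataFrame({"x": x}), y)
        assert np.allclose(m.z_values, m.estimates / m.std_errors)
        assert m.k == 2
        assert m.aicc > m.aic

    def test_null_simulation_coverage(self):
        # balanced response, zero-signal predictor: the slope should be
        # inside +/- 2 SE of zero in at least 95% of replicates
        hits = 0
        n_sims = 100
        for s in range(n_sims):
            rng = np.random.default_rng([99, s])
            x = rng.standard_normal(200)
            y = np.repeat([0, 1], 100)
            m = fit_logistic(pd.DataFrame({"x": x}), y)
            if abs(m.estimates[1]) < 2 * m.std_errors[1]:
                hits += 1
        assert hits >= 95

    def test_refit_is_deterministic(self, rng):
        x = rng.standard_normal(150)
        y = (rng.uniform(size=150) < expit(x)).astype(int)
        a = fit_logistic(pd.DataFrame({"x": x}), y)
        b = fit_logistic(pd.DataFrame({"x": x}), y)
        assert np.array_equal(a.estimates, b.estimates)

    def test_complete_separation_raises(self):
        x = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])
        y = np.repeat([0, 1], 20)
        with pytest.raises(SeparationError):
            fit_logistic(pd.DataFrame({"x": x + 0.01 * np.arange(40)}), y)

    def test_rank_deficient_design_raises(self, rng):
        x = rng.standard_normal(50)
        y = (rng.uniform(size=50) < 0.5).astype(int)
        y[0], y[1] = 0, 1
        with pytest.raises(ModelError):
            fit_logistic(pd.DataFrame({"a": x, "b": 2 * x}), y)

    def test_aicc_converges_to_aic_at_large_n(self, rng):
        x = rng.standard_normal(100_000)
        y = (rng.uniform(size=100_000) < expit(0.3 * x)).astype(int)
        m = fit_logistic(pd.DataFrame({"x": x}), y)
        assert m.aicc > m.aic
        assert m.aicc - m.aic < 0.01


class TestStandardize:
    def test_zero_mean_unit_sd_and_constants(self, rng):
        df = pd.DataFrame({"a": rng.normal(5, 3, 100), "b": rng.normal(-2, 0.5, 100)})
        z, consts = standardize(df)
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=0), 1, atol=1e-12)
        mu, sd = consts["a"]
        assert np.allclose((df["a"] - mu) / sd, z["a"])

    def test_constant_column_rejected(self):
        with pytest.raises(ModelError):
            standardize(pd.DataFrame({"a": np.ones(10)}))


class TestAllSubsets:
    def _data(self, rng, n=200, p=3, betas=(1.2, -1.0, 0.0)):
        X = rng.standard_normal((n, p))
        eta = X[:, : len(betas)] @ np.array(betas)
        y = (rng.uniform(size=n) < expit(eta)).astype(int)
        design = pd.DataFrame(X, columns=[f"c{i}@250" for i in range(p)])
        return design, y

    def test_fits_all_two_to_the_p_subsets(self, rng):
        design, y = self._data(rng)
        ranking = all_subsets(design, y)
        assert len(ranking.models) == 8
        assert ranking.delta_aicc[0] == 0.0
        assert all(np.diff([m.aicc for m in ranking.models]) >= 0)

    def test_matches_independent_brute_force_refit(self, rng):
        # oracle: refit every subset by direct NLL minimization and rank
        design, y = self._data(rng)
        ranking = all_subsets(design, y)
        oracle = []
        cols = sorted(design.columns)
        for r in range(4):
            for subset in itertools.combinations(cols, r):
                X = design[list(subset)].to_numpy()
                params, ll = fit_logistic_oracle(X, y) if subset else fit_logistic_oracle(
                    np.empty((len(y), 0)), y
                )
                k = len(subset) + 1
                aicc = -2 * ll + 2 * k + 2 * k * (k + 1) / (len(y) - k - 1)
                oracle.append((aicc, subset))
        oracle.sort()
        assert tuple(ranking.best.terms) == oracle[0][1]
        assert ranking.best.aicc == pytest.approx(oracle[0][0], abs=1e-4)

    def test_recovers_generative_subset(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng([7, s])
            design, y = self._data(rng, n=500, p=4, betas=(1.5, -1.2, 0.0, 0.0))
            best = all_subsets(design, y).best
            if {"c0@250", "c1@250"} <= set(best.terms):
                hits += 1
        assert hits >= 8

    def test_support_set_uses_delta_under_two(self, rng):
        design, y = self._data(rng)
        ranking = all_subsets(design, y)
        deltas = ranking.delta_aicc
        assert len(ranking.support_set) == int(np.sum(deltas < 2.0))

    def test_exhaustive_guard(self, rng):
        design = pd.DataFrame(rng.standard_normal((30, 21)), columns=[f"c{i}@250" for i in range(21)])
        y = np.repeat([0, 1], 15)
        with pytest.raises(ModelError, match="exhaustive"):
            all_subsets(design, y)


class TestPredictSuitability:
    def _stack_and_model(self, grid, mu=0.0, sd=1.0, intercept=-0.0563, beta=1.0):
        stack = ScaledPredictorStack()
        stack.add("p", 250.0, PredictorRaster("p", grid, 250.0, origin=(0, grid.shape[0] * 250.0)))
        model = FittedModel(
            terms=("p@250",),
            estimates=np.array([intercept, beta]),
            std_errors=np.array([0.1, 0.1]),
            loglik=-10.0,
            n=100,
            standardization={"p@250": (mu, sd)},
        )
        return stack, model

    def test_terms_at_training_mean_give_inverse_logit_intercept(self):
        # a pixel equal to the training mean has z = 0 everywhere, so the
        # prediction equals invlogit of the intercept: -0.0563 -> 0.4859
        stack, model = self._stack_and_model(np.full((4, 4), 7.3), mu=7.3, sd=2.0)
        out = predict_suitability(model, stack)
        assert np.allclose(out.grid, 0.4859, atol=1e-4)

    def test_monotone_in_positive_term(self, rng):
        grid = rng.standard_normal((6, 6))
        stack, model = self._stack_and_model(grid)
        out = predict_suitability(model, stack)
        order = np.argsort(grid.ravel())
        assert np.all(np.diff(out.grid.ravel()[order]) >= 0)
        assert out.grid.min() >= 0 and out.grid.max() <= 1

    def test_nodata_propagates(self):
        grid = np.ones((3, 3))
        grid[1, 1] = np.nan
        stack, model = self._stack_and_model(grid)
        out = predict_suitability(model, stack)
        assert np.isnan(out.grid[1, 1])
        assert np.isfinite(out.grid[0, 0])

    def test_missing_layer_errors(self):
        stack, model = self._stack_and_model(np.ones((3, 3)))
        model2 = FittedModel(
            terms=("q@500",),
            estimates=np.array([0.0, 1.0]),
            std_errors=np.array([0.1, 0.1]),
            loglik=-1.0,
            n=10,
            standardization={"q@500": (0.0, 1.0)},
        )
        with pytest.raises(KeyError):
            predict_suitability(model2, stack)
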