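"""The five model forms: contracts, recovery oracles, and cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import seasdm as s
from seasdm.grids import GridSpec, RasterLayer
from seasdm.predictors import PredictorStack, TrainingTable


def table_from_arrays(X, y, names=None):
    names = names or [f"x{i}" for i in range(X.shape[1])]
    frame = pd.DataFrame(X, columns=names)
    frame.insert(0, "label", y.astype(int))
    frame.insert(0, "col", 0)
    frame.insert(0, "row", np.arange(len(y)))
    return TrainingTable(frame, names)


def simulate_logistic(n, beta, intercept, seed, p=None):
    rng = np.random.default_rng(seed)
    p = p or len(beta)
    X = rng.normal(size=(n, p))
    eta = intercept + X[:, : len(beta)] @ np.asarray(beta)
    y = (rng.uniform(size=n) < expit(eta)).astype(int)
    return X, y


class TestContract:
    """Shared fit/predict contract across all five forms."""

    @pytest.mark.parametrize("form", s.MODEL_FORM_NAMES)
    def test_predictions_bounded_and_width_checked(self, form, small_driver_table):
        model = s.fit_model(form, small_driver_table, seed=0)
        preds = model.predict(small_driver_table.X)
        assert np.all((preds >= 0) & (preds <= 1))
        with pytest.raises(ValueError):
            model.predict(np.zeros((3, 99)))

    def test_unknown_form_rejected(self, small_driver_table):
        with pytest.raises(ValueError):
            s.fit_model("SVM", small_driver_table)


class TestGLM:
    def test_null_signal_recovers_prevalence_intercept(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2000, 1))
        y = (rng.uniform(size=2000) < 0.3).astype(int)
        model = s.fit_model("GLM", table_from_arrays(X, y))
        prev = y.mean()
        # slopes ~ 0, so the intercept carries logit(prevalence)
        assert abs(model.metadata["coef"]).max() < 0.2
        assert model.metadata["intercept"] == pytest.approx(logit(prev), abs=0.2)

    def test_independent_labels_give_chance_auc(self):
        X, _ = simulate_logistic(1500, [0.0, 0.0], 0.0, seed=1)
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=1500)
        model = s.fit_model("GLM", table_from_arrays(X, y))
        scores = model.predict(X)
        auc = s.compute_auc(scores[y == 1], scores[y == 0])
        assert 0.45 < auc < 0.58

    def test_coefficient_recovery_within_three_standard_errors(self):
        beta, intercept = [1.2, -0.8], 0.4
        X, y = simulate_logistic(5000, beta, intercept, seed=3)
        model = s.fit_model("GLM", table_from_arrays(X, y), hp={"quadratic": False})
        coefs = model.metadata["coef"]  # on standardized scale; sd ~ 1
        # Observed-information standard errors of the logistic MLE.
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        F = np.column_stack([np.ones(len(y)), Z])
        eta = model.metadata["intercept"] + Z @ coefs
        w = expit(eta) * (1 - expit(eta))
        cov = np.linalg.inv(F.T @ (F * w[:, None]))
        ses = np.sqrt(np.diag(cov))[1:]
        for j, b in enumerate(beta):
            b_std = b * X[:, j].std()
            assert abs(coefs[j] - b_std) < 3 * ses[j]


class TestMARS:
    def test_hinge_knot_recovered_near_truth(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.uniform(-2, 2, size=n)
        eta = -1.0 + 2.0 * np.maximum(x - 0.3, 0.0)
        y = (rng.uniform(size=n) < expit(eta)).astype(int)
        X = np.column_stack([x])
        model = s.fit_model("MARS", table_from_arrays(X, y, ["x"]))
        knots = [k for _, k in model.metadata["knots"]]
        assert knots, "pruning removed every term on a real hinge signal"
        # Accept a knot within the central 10% quantile band of 0.3.
        lo, hi = np.quantile(x, [0.525, 0.625])
        assert any(lo <= k <= hi for k in knots)

    def test_pure_noise_prunes_to_intercept_most_seeds(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(400, 3))
            y = rng.integers(0, 2, size=400)
            model = s.fit_model("MARS", table_from_arrays(X, y))
            hits += model.metadata["n_terms"] == 0
        assert hits >= 8

    def test_training_deviance_not_worse_than_linear_glm(self):
        # Piecewise-linear truth: the hinge basis nests the linear fit.
        rng = np.random.default_rng(5)
        n = 1500
        x = rng.uniform(-3, 3, size=n)
        eta = 1.5 * np.maximum(x, 0) - 1.0
        y = (rng.uniform(size=n) < expit(eta)).astype(int)
        table = table_from_arrays(np.column_stack([x]), y, ["x"])
        mars = s.fit_model("MARS", table)
        glm = s.fit_model("GLM", table, hp={"quadratic": False})

        def deviance(model):
            p = np.clip(model.predict(table.X), 1e-12, 1 - 1e-12)
            return -2 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

        assert deviance(mars) <= deviance(glm) + 1e-6

    def test_constant_covariate_never_selected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=800)
        y = (rng.uniform(size=800) < expit(2 * x)).astype(int)
        X = np.column_stack([np.full(800, 3.14), x])
        model = s.fit_model("MARS", table_from_arrays(X, y, ["flat", "x"]))
        assert all(name != "flat" for name, _ in model.metadata["knots"])


class TestBRT:
    def test_nonpositive_shrinkage_rejected(self, small_driver_table):
        with pytest.raises(ValueError):
            s.fit_model("BRT", small_driver_table, hp={"learning_rate": 0.0})

    def test_single_stump_reproduces_newton_leaf_values(self):
        # One depth-1 tree, shrinkage 1, no subsampling: each leaf takes
        # a single Newton step from the prior log-odds,
        # leaf = sum(y - p0) / sum(p0 (1 - p0)), hand-computed here.
        y = np.r_[np.ones(70), np.zeros(30), np.ones(30), np.zeros(70)].astype(int)
        x = np.r_[np.ones(100), np.zeros(100)]
        table = table_from_arrays(np.column_stack([x]), y, ["x"])
        model = s.fit_model("BRT", table, hp={
            "max_depth": 1, "learning_rate": 1.0, "subsample": 1.0,
            "n_estimators": 1, "n_iter_no_change": None,
        })
        p0 = y.mean()  # 0.5
        f0 = logit(p0)
        leaf_hi = (70 - 100 * p0) / (100 * p0 * (1 - p0))
        leaf_lo = (30 - 100 * p0) / (100 * p0 * (1 - p0))
        pred = model.predict(np.array([[1.0], [0.0]]))
        assert pred[0] == pytest.approx(expit(f0 + leaf_hi), abs=1e-9)
        assert pred[1] == pytest.approx(expit(f0 + leaf_lo), abs=1e-9)

    def test_many_stages_converge_to_empirical_log_odds(self):
        y = np.r_[np.ones(70), np.zeros(30), np.ones(30), np.zeros(70)].astype(int)
        x = np.r_[np.ones(100), np.zeros(100)]
        table = table_from_arrays(np.column_stack([x]), y, ["x"])
        model = s.fit_model("BRT", table, hp={
            "max_depth": 1, "learning_rate": 0.5, "subsample": 1.0,
            "n_estimators": 300, "n_iter_no_change": None,
        })
        pred = model.predict(np.array([[1.0], [0.0]]))
        assert pred[0] == pytest.approx(0.7, abs=1e-3)
        assert pred[1] == pytest.approx(0.3, abs=1e-3)

    def test_training_deviance_monotone_without_subsampling(self, small_driver_table):
        model = s.fit_model("BRT", small_driver_table, hp={
            "subsample": 1.0, "n_estimators": 200, "n_iter_no_change": None,
        }, seed=1)
        score = model.metadata["train_score"]
        assert np.all(np.diff(score) <= 1e-12)

    def test_interaction_signal_beats_additive_glm(self):
        # XOR-structured truth is invisible to an additive logistic model
        # but capturable by depth-limited trees.
        rng = np.random.default_rng(7)
        n = 2000
        X = rng.normal(size=(n, 2))
        xor = (X[:, 0] > 0) ^ (X[:, 1] > 0)
        y = (rng.uniform(size=n) < np.where(xor, 0.9, 0.1)).astype(int)
        train = table_from_arrays(X[: n // 2], y[: n // 2])
        Xte, yte = X[n // 2:], y[n // 2:]
        brt = s.fit_model("BRT", train, seed=2)
        glm = s.fit_model("GLM", train)
        auc_brt = s.compute_auc(*_split(brt.predict(Xte), yte))
        auc_glm = s.compute_auc(*_split(glm.predict(Xte), yte))
        assert auc_brt > 0.85 > auc_glm


def _split(scores, y):
    return scores[y == 1], scores[y == 0]


class TestRF:
    def test_zero_trees_rejected(self, small_driver_table):
        with pytest.raises(ValueError):
            s.fit_model("RF", small_driver_table, hp={"n_estimators": 0})

    def test_vote_granularity(self, small_driver_table):
        model = s.fit_model("RF", small_driver_table, hp={"n_estimators": 50}, seed=3)
        preds = model.predict(small_driver_table.X)
        votes = preds * 50
        assert np.allclose(votes, np.round(votes), atol=1e-9)

    def test_separable_covariate_learned_perfectly(self):
        rng = np.random.default_rng(8)
        x = np.r_[rng.uniform(1, 2, 100), rng.uniform(-2, -1, 100)]
        y = np.r_[np.ones(100), np.zeros(100)].astype(int)
        model = s.fit_model("RF", table_from_arrays(x[:, None], y, ["x"]),
                            hp={"n_estimators": 100}, seed=4)
        preds = model.predict(x[:, None])
        assert np.all((preds > 0.5) == (y == 1))

    def test_permuted_labels_give_chance_held_out_auc(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(1200, 3))
        y = rng.integers(0, 2, size=1200)
        model = s.fit_model("RF", table_from_arrays(X[:600], y[:600]),
                            hp={"n_estimators": 300}, seed=5)
        scores = model.predict(X[600:])
        auc = s.compute_auc(*_split(scores, y[600:]))
        assert 0.42 < auc < 0.58


class TestMaxent:
    def test_negative_penalty_rejected(self, small_driver_table):
        with pytest.raises(ValueError):
            s.fit_model("MAXENT", small_driver_table, hp={"penalty_multiplier": -1})

    def test_infinite_penalty_gives_uniform_surface(self, small_driver_table):
        model = s.fit_model(
            "MAXENT", small_driver_table, hp={"penalty_multiplier": 1e6}
        )
        preds = model.predict(small_driver_table.X)
        assert preds.std() < 1e-3

    def test_exponential_tilt_recovered_on_discretized_problem(self):
        # Background uniform on a 1-D grid; presence density is the
        # exponential tilt exp(beta * x) of it.  The presence-background
        # log-density-ratio slope must match beta (closed form) to 2%.
        beta = 1.3
        grid_x = np.linspace(-2, 2, 201)
        rng = np.random.default_rng(10)
        bg = rng.choice(grid_x, size=12000)
        w = np.exp(beta * grid_x)
        pres = rng.choice(grid_x, size=12000, p=w / w.sum())
        X = np.r_[pres, bg][:, None]
        y = np.r_[np.ones(12000), np.zeros(12000)].astype(int)
        model = s.fit_model(
            "MAXENT", table_from_arrays(X, y, ["x"]),
            hp={"penalty_multiplier": 0.0, "features": ("linear",)},
        )
        # Slope of the fitted log-odds in raw units via finite difference.
        p1 = model.predict(np.array([[1.0]]))[0]
        p0 = model.predict(np.array([[0.0]]))[0]
        slope = logit(p1) - logit(p0)
        assert slope == pytest.approx(beta, rel=0.02)

    def test_ranking_invariant_to_affine_covariate_rescaling(self, small_driver_table):
        table = small_driver_table
        model = s.fit_model("MAXENT", table, seed=6)
        X2 = table.X.copy()
        X2[:, 0] = 40.0 * X2[:, 0] + 7.0
        frame2 = table.frame.copy()
        frame2[table.covariate_names[0]] = X2[:, 0]
        table2 = TrainingTable(frame2, table.covariate_names)
        model2 = s.fit_model("MAXENT", table2, seed=6)
        r1 = np.argsort(np.argsort(model.predict(table.X)))
        r2 = np.argsort(np.argsort(model2.predict(X2)))
        assert np.array_equal(r1, r2)


class TestCrossValidation:
    def test_perfectly_separable_data_scores_auc_one(self):
        rng = np.random.default_rng(11)
        x = np.r_[rng.uniform(1, 2, 60), rng.uniform(-2, -1, 240)]
        y = np.r_[np.ones(60), np.zeros(240)].astype(int)
        table = table_from_arrays(x[:, None], y, ["x"])
        for form in ("GLM", "RF"):
            cv = s.cross_validate(form, table, k=10, seed=12,
                                  hp={"n_estimators": 100} if form == "RF" else None)
            assert cv.mean_auc == 1.0

    def test_same_seed_reproduces_folds_and_metrics(self, small_driver_table):
        a = s.cross_validate("GLM", small_driver_table, k=10, seed=13)
        b = s.cross_validate("GLM", small_driver_table, k=10, seed=13)
        assert a.folds == b.folds and a.mean_auc == b.mean_auc

    def test_too_few_presences_rejected_with_advice(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(50, 1))
        y = np.r_[np.ones(5), np.zeros(45)].astype(int)
        with pytest.raises(ValueError, match="reduce k"):
            s.cross_validate("GLM", table_from_arrays(X, y), k=10)

    def test_ten_folds_reported(self, small_driver_table):
        cv = s.cross_validate("GLM", small_driver_table, k=10, seed=15)
        assert len(cv.folds) == 10
        assert cv.mean_auc == pytest.approx(np.mean([f["auc"] for f in cv.folds]))


class TestPredictSurface:
    def _stack(self, values_by_name, grid):
        return PredictorStack(
            "summer",
            {n: RasterLayer(grid, n, v) for n, v in values_by_name.items()},
        )

    def test_constant_stack_gives_constant_surface(self, small_driver_table):
        grid = GridSpec(n_rows=5, n_cols=5)
        model = s.fit_model("GLM", small_driver_table)
        stack = self._stack(
            {n: np.full(grid.shape, 0.5) for n in model.covariate_names}, grid
        )
        surface = s.predict_surface(model, stack)
        assert np.allclose(surface.values, surface.values[0, 0])

    def test_surface_matches_row_prediction(self, small_driver_table):
        grid = GridSpec(n_rows=3, n_cols=3)
        rng = np.random.default_rng(16)
        model = s.fit_model("GLM", small_driver_table)
        vals = {n: rng.normal(size=grid.shape) for n in model.covariate_names}
        surface = s.predict_surface(model, self._stack(vals, grid))
        vec = np.array([[vals[n][1, 2] for n in model.covariate_names]])
        assert surface.values[1, 2] == pytest.approx(model.predict(vec)[0])

    def test_monotone_model_gives_monotone_surface_on_ramp(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=1000)
        y = (rng.uniform(size=1000) < expit(2 * x)).astype(int)
        model = s.fit_model("GLM", table_from_arrays(x[:, None], y, ["x"]),
                            hp={"quadratic": False})
        grid = GridSpec(n_rows=1, n_cols=20)
        ramp = np.linspace(-2, 2, 20)[None, :]
        surface = s.predict_surface(model, self._stack({"x": ramp}, grid))
        assert np.all(np.diff(surface.values[0]) > 0)

    def test_covariate_mismatch_rejected_with_names(self, small_driver_table):
        grid = GridSpec(n_rows=2, n_cols=2)
        model = s.fit_model("GLM", small_driver_table)
        stack = self._stack({"wrong_name": np.zeros(grid.shape)}, grid)
        with pytest.raises(ValueError, match="wrong_name"):
            s.predict_surface(model, stack)

    def test_nodata_pixels_stay_nodata(self, small_driver_table):
        grid = GridSpec(n_rows=2, n_cols=2)
        model = s.fit_model("GLM", small_driver_table)
        vals = {n: np.zeros(grid.shape) for n in model.covariate_names}
        first = model.covariate_names[0]
        vals[first] = vals[first].copy()
        vals[first][0, 0] = np.nan
        surface = s.predict_surface(model, self._stack(vals, grid))
        assert np.isnan(surface.values[0, 0]) and not np.isnan(surface.values[1, 1])
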