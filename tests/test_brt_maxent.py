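"""Boosted trees and the MaxEnt-style lasso engine."""

import numpy as np
import pytest
from scipy.special import expit

from sdmbench.engines import (
    BackgroundSet,
    BRTSettings,
    MaxentFeatureSpec,
    expand_maxent_features,
    fit_brt,
    fit_maxent_like,
    generate_background,
)
from sdmbench.evaluation import compute_auc
from sdmbench.rng import spawn_rng


class TestBRT:
    def test_separable_data_training_auc(self):
        rng = spawn_rng(1)
        X = rng.normal(size=(200, 2))
        y = (X[:, 0] > 0).astype(int)
        fit = fit_brt(y, X, BRTSettings(), rng_seed=0)
        # recover scores through the underlying model on training data
        from sklearn.ensemble import GradientBoostingClassifier

        assert fit.fit_info["train_score"] is not None
        model = GradientBoostingClassifier(
            learning_rate=0.01, max_depth=3, subsample=0.75, n_estimators=1000, random_state=0
        ).fit(X, y)
        auc = compute_auc(model.predict_proba(X)[:, 1], y)
        assert auc >= 0.99

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            BRTSettings(learning_rate=0.0)
        with pytest.raises(ValueError):
            BRTSettings(bag_fraction=0.0)
        with pytest.raises(ValueError):
            BRTSettings(tree_complexity=0)

    def test_single_class_rejected(self):
        X = spawn_rng(2).normal(size=(30, 2))
        with pytest.raises(ValueError):
            fit_brt(np.zeros(30), X)

    def test_monotone_transform_invariance(self):
        # tree splits depend only on predictor order: cubing a column
        # (strictly monotone) leaves seeded predictions unchanged
        rng = spawn_rng(3)
        X = rng.normal(size=(300, 3))
        y = (rng.random(300) < expit(X[:, 0] - X[:, 1])).astype(int)
        from sklearn.ensemble import GradientBoostingClassifier

        kw = dict(learning_rate=0.05, max_depth=2, subsample=1.0, n_estimators=100, random_state=7)
        p1 = GradientBoostingClassifier(**kw).fit(X, y).predict_proba(X)[:, 1]
        X2 = X.copy()
        X2[:, 0] = X2[:, 0] ** 3
        p2 = GradientBoostingClassifier(**kw).fit(X2, y).predict_proba(X2)[:, 1]
        assert np.max(np.abs(p1 - p2)) == 0.0


class TestMaxentFeatures:
    def test_lq_feature_count(self):
        v = spawn_rng(4).normal(size=(50, 5))
        F, _ = expand_maxent_features(v, MaxentFeatureSpec(classes=frozenset("LQ")))
        assert F.shape == (50, 10)

    def test_hinge_feature_count(self):
        v = spawn_rng(5).normal(size=(50, 1))
        F, _ = expand_maxent_features(
            v, MaxentFeatureSpec(classes=frozenset("H"), n_knots=10)
        )
        assert F.shape == (50, 20)

    @pytest.mark.parametrize(
        "n_presence,expected",
        [(5, {"L"}), (12, {"L", "Q"}), (50, {"L", "Q", "H"}), (200, {"L", "Q", "H", "P", "T"})],
    )
    def test_auto_feature_ladder(self, n_presence, expected):
        spec = MaxentFeatureSpec(classes=frozenset({"AF"}))
        assert spec.resolve_classes(n_presence) == frozenset(expected)

    def test_features_scaled_to_unit_interval(self):
        v = spawn_rng(6).normal(size=(80, 3)) * 10
        F, ex = expand_maxent_features(
            v, MaxentFeatureSpec(classes=frozenset("LQHPT"), n_knots=4)
        )
        assert F.min() >= 0.0 and F.max() <= 1.0
        # new data clipped into the same box
        F2 = ex.expand(spawn_rng(7).normal(size=(20, 3)) * 100)
        assert F2.min() >= 0.0 and F2.max() <= 1.0

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            MaxentFeatureSpec(classes=frozenset({"Z"}))
        with pytest.raises(ValueError):
            MaxentFeatureSpec(classes=frozenset({"AF", "L"}))


class TestMaxentFit:
    def _setup(self, covariates, grid, seed=8, n_pres=150):
        rng = spawn_rng(seed)
        # presences drawn preferentially where layer 0 is high
        xs, ys = grid.center_mesh()
        w = np.exp(2.0 * covariates.layers[0]).ravel()
        idx = rng.choice(grid.n_cells, size=n_pres, p=w / w.sum())
        rows, cols = np.divmod(idx, grid.n_cols)
        pres = grid.cell_to_center(rows, cols)
        bg = generate_background(grid, pres, "R", 500, rng)
        return pres, bg

    def test_full_shrinkage_limit_gives_chance_auc(self, covariates, grid, validation):
        pres, bg = self._setup(covariates, grid)
        fit = fit_maxent_like(
            pres, bg, covariates, MaxentFeatureSpec(classes=frozenset("LQ"), beta=1e6)
        )
        assert fit.fit_info["n_nonzero"] == 0
        assert np.allclose(fit.prediction, fit.prediction.flat[0])
        scores = fit.scores_at(validation.points, grid)
        assert compute_auc(scores, validation.labels) == pytest.approx(0.5)

    def test_active_set_shrinks_with_beta(self, covariates, grid):
        pres, bg = self._setup(covariates, grid)
        sizes = []
        for beta in (0.25, 1.0, 4.0, 16.0, 64.0):
            fit = fit_maxent_like(
                pres, bg, covariates,
                MaxentFeatureSpec(classes=frozenset("LQH"), beta=beta),
            )
            sizes.append(fit.fit_info["n_nonzero"])
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_sign_recovery_linear_feature(self, covariates, grid):
        pres, bg = self._setup(covariates, grid)
        fit = fit_maxent_like(
            pres, bg, covariates, MaxentFeatureSpec(classes=frozenset("L"), beta=0.5)
        )
        # suitability increases with layer 0: its linear weight is positive
        assert fit.fit_info["weights"][0] > 0

    def test_self_consistency_against_generating_model(self, covariates, grid):
        # data from a known linear-logit model: held-out AUC within 0.05
        # of the generating model's own AUC
        rng = spawn_rng(10)
        from sdmbench.landscape import SpeciesModel, Term, predict_truth_surface, sample_validation_points

        model = SpeciesModel(terms=[Term("linear", 0), Term("linear", 1)],
                             coefficients=[1.5, -1.0], intercept=-0.5)
        truth = predict_truth_surface(model, covariates, noise_sd=0.0)
        val = sample_validation_points(truth, 500, rng_seed=21)
        w = truth.p_clean.ravel()
        idx = rng.choice(grid.n_cells, size=300, p=w / w.sum())
        rows, cols = np.divmod(idx, grid.n_cols)
        pres = grid.cell_to_center(rows, cols)
        bg = generate_background(grid, pres, "R", 1000, rng)
        fit = fit_maxent_like(pres, bg, covariates, MaxentFeatureSpec(classes=frozenset("LQ"), beta=1.0))
        auc_fit = compute_auc(fit.scores_at(val.points, grid), val.labels)
        auc_gen = compute_auc(truth.p_clean[grid.point_to_cell(val.points)], val.labels)
        assert auc_fit >= auc_gen - 0.05

    def test_too_few_presences_rejected(self, covariates, grid):
        bg = generate_background(grid, None, "R", 100, rng_seed=1)
        with pytest.raises(ValueError):
            fit_maxent_like(np.array([[1.0, 1.0]]), bg, covariates, MaxentFeatureSpec())
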