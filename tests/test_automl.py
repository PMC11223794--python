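"""Bi-level search: R² objective, TPE tuner, Tabu walk, final refit."""

import math

import numpy as np
import pytest
import sklearn.metrics

from imseeker.automl import (PRESETS, AutoMLBudget, CandidateConfig,
                             SearchSpace, evaluate_config, r2_score,
                             tabu_search, tpe_optimize, train_final)
from imseeker.automl.space import (FS_PORTFOLIO, MODEL_PORTFOLIO, CatParam,
                                   IntParam, RealParam, config_param_space)
from imseeker.automl.tpe import tpe_maximize
from imseeker.features import FEATURE_NAMES


def linear_data(rng, n=200, noise=0.0):
    """y linear in the first 3 of 33 standardized features."""
    X = rng.normal(size=(n, 33))
    y = 2.0 * X[:, 0] - 1.5 * X[:, 1] + 0.5 * X[:, 2] + \
        noise * rng.normal(size=n)
    return X, y


class TestR2:
    def test_identity_is_one(self):
        y = np.array([1.0, 2.0, 5.0])
        assert r2_score(y, y) == 1.0

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2_score(y, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # SS_res = 1, SS_tot = 2
        assert r2_score([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_agrees_with_sklearn(self, rng):
        y = rng.normal(size=40)
        p = y + rng.normal(size=40) * 0.3
        assert r2_score(y, p) == pytest.approx(
            sklearn.metrics.r2_score(y, p), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r2_score([1.0, 1.0], [1.0, 2.0])


class TestSearchSpace:
    def test_default_cardinality_is_84(self):
        space = SearchSpace()
        assert space.size == 84
        assert len(space.pairs()) == 84
        assert len(FS_PORTFOLIO) == 7 and len(MODEL_PORTFOLIO) == 12

    def test_every_pair_has_a_hyper_domain(self):
        for fs in FS_PORTFOLIO:
            for m in MODEL_PORTFOLIO:
                space = config_param_space(fs, m)
                names = [p.name for p in space]
                assert len(names) == len(set(names))  # prefixes disambiguate

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(fs_portfolio=("NOPE",))


class TestEvaluateConfig:
    def test_linear_signal_near_perfect_ridge(self, rng):
        X, y = linear_data(rng, 200)
        cfg = CandidateConfig("NONE", "RIDGE", {"model__alpha": 1e-3})
        assert evaluate_config(cfg, X, y, 5, seed=0) >= 0.99

    def test_pure_noise_scores_low(self, rng):
        X = rng.normal(size=(500, 33))
        y = rng.normal(size=500)
        cfg = CandidateConfig("NONE", "RIDGE", {"model__alpha": 1.0})
        assert evaluate_config(cfg, X, y, 5, seed=0) <= 0.1

    def test_deterministic_given_seed(self, rng):
        X, y = linear_data(rng, 120, noise=0.5)
        cfg = CandidateConfig("GUS", "DTR", {
            "fs__mode": "percentile", "fs__score_func_name": "f_regression",
            "fs__percentile": 50, "fs__k_best": 10,
            "model__max_depth": 5, "model__min_samples_split": 4,
            "model__min_samples_leaf": 2})
        a = evaluate_config(cfg, X, y, 5, seed=3)
        b = evaluate_config(cfg, X, y, 5, seed=3)
        assert a == b

    def test_fit_failure_scores_minus_inf(self, rng):
        X, y = linear_data(rng, 60)
        cfg = CandidateConfig("VT", "RIDGE", {"fs__threshold": 1e9,
                                              "model__alpha": 1.0})
        assert evaluate_config(cfg, X, y, 5, seed=0) == -math.inf


class TestTPE:
    def test_exactly_n_trials_and_single_trial(self):
        space = (RealParam("x", 0.0, 1.0),)
        calls = []

        def obj(p):
            calls.append(p["x"])
            return -(p["x"] - 0.3) ** 2

        _, _, trials = tpe_maximize(obj, space, n_trials=17, seed=1)
        assert len(trials) == len(calls) == 17
        _, _, trials = tpe_maximize(obj, space, n_trials=1, seed=1)
        assert len(trials) == 1

    def test_finite_domain_finds_global_optimum(self):
        """Discrete 1-D domain no larger than the budget is solved exactly."""
        values = {"a": 0.1, "b": 0.9, "c": 0.4, "d": 0.2, "e": 0.6}
        space = (CatParam("x", tuple(values)),)
        best, val, _ = tpe_maximize(lambda p: values[p["x"]], space,
                                    n_trials=8, seed=2)
        assert best["x"] == "b" and val == 0.9
        space = (IntParam("k", 1, 6),)
        best, val, _ = tpe_maximize(lambda p: -abs(p["k"] - 5), space,
                                    n_trials=6, seed=3)
        assert best["k"] == 5

    def test_converges_toward_optimum_on_continuous_domain(self):
        space = (RealParam("x", 0.0, 1.0), RealParam("s", 1e-3, 1e1, log=True))

        def obj(p):
            return -(p["x"] - 0.7) ** 2 - (math.log10(p["s"]) - 0.0) ** 2

        best, val, trials = tpe_maximize(obj, space, n_trials=60, seed=4)
        first10 = max(t.value for t in trials[:10])
        assert val >= first10
        assert abs(best["x"] - 0.7) < 0.25

    def test_deterministic(self):
        space = (RealParam("x", 0.0, 1.0), CatParam("c", ("u", "v")))

        def obj(p):
            return p["x"] + (0.1 if p["c"] == "v" else 0.0)

        a = tpe_maximize(obj, space, 20, seed=9)
        b = tpe_maximize(obj, space, 20, seed=9)
        assert a == b

    def test_ridge_tuning_beats_fixed_default(self, rng):
        X, y = linear_data(rng, 150, noise=2.0)
        _, tuned = tpe_optimize("NONE", "RIDGE", X, y,
                                AutoMLBudget(1, 15), seed=5)
        fixed = evaluate_config(
            CandidateConfig("NONE", "RIDGE", {"model__alpha": 1.0}),
            X, y, 5, seed=5)
        assert tuned >= fixed - 1e-12


class TestTabu:
    def test_single_pair_portfolio(self, rng):
        X, y = linear_data(rng, 100)
        space = SearchSpace(fs_portfolio=("NONE",),
                            model_portfolio=("RIDGE",))
        res = tabu_search(space, X, y, AutoMLBudget(5, 4), seed=0)
        assert len(res.history) == 1
        assert res.best_config.pair == ("NONE", "RIDGE")

    def test_reproducible_history(self, rng):
        X, y = linear_data(rng, 100, noise=1.0)
        space = SearchSpace(fs_portfolio=("NONE", "VT"),
                            model_portfolio=("RIDGE", "DTR"))
        a = tabu_search(space, X, y, AutoMLBudget(3, 4), seed=7)
        b = tabu_search(space, X, y, AutoMLBudget(3, 4), seed=7)
        assert [(c.pair, v) for c, v in a.history] == \
            [(c.pair, v) for c, v in b.history]
        assert a.best_config == b.best_config

    def test_never_revisits_a_pair(self, rng):
        X, y = linear_data(rng, 100, noise=1.0)
        space = SearchSpace(fs_portfolio=("NONE", "VT", "GUS"),
                            model_portfolio=("RIDGE", "DTR"))
        res = tabu_search(space, X, y, AutoMLBudget(6, 3), seed=1)
        pairs = [c.pair for c, _ in res.history]
        assert len(pairs) == len(set(pairs)) == 6

    def test_exhaustive_budget_matches_brute_force(self, rng):
        """With budget >= |space|, Tabu equals exhaustive enumeration."""
        X, y = linear_data(rng, 120, noise=1.0)
        space = SearchSpace(fs_portfolio=("NONE", "VT", "GUS"),
                            model_portfolio=("RIDGE", "DTR", "SVR"))
        budget = AutoMLBudget(9, 5)
        res = tabu_search(space, X, y, budget, seed=11)
        assert len(res.history) == 9
        brute = []
        for fs, m in space.pairs():
            _, val = tpe_optimize(fs, m, X, y, budget, seed=11)
            brute.append(((fs, m), val))
        best_val = max(v for _, v in brute)
        best_pair = min(p for p, v in brute if v == best_val)
        assert res.best_config.pair == best_pair
        assert res.lower_objective == best_val

    def test_presets_exist_with_increasing_effort(self):
        order = ["swift_basic", "balanced", "thorough", "best_performance"]
        efforts = [PRESETS[k].upper_rounds * PRESETS[k].tpe_trials
                   for k in order]
        assert efforts == sorted(efforts)
        assert all(PRESETS[k].preset == k for k in order)


class TestTrainFinal:
    def test_none_selector_keeps_all_33(self, rng):
        X, y = linear_data(rng, 100)
        space = SearchSpace(fs_portfolio=("NONE",),
                            model_portfolio=("RIDGE",))
        res = tabu_search(space, X, y, AutoMLBudget(1, 3), seed=0)
        fitted = train_final(res, X, y)
        assert fitted.selected_features == FEATURE_NAMES
        assert len(fitted.selected_features) == 33

    def test_selector_output_is_subset_and_test_r2_recorded(self, rng):
        X, y = linear_data(rng, 160, noise=0.1)
        space = SearchSpace(fs_portfolio=("GUS",),
                            model_portfolio=("RIDGE",))
        res = tabu_search(space, X[:120], y[:120], AutoMLBudget(1, 5), seed=2)
        fitted = train_final(res, X[:120], y[:120], X[120:], y[120:])
        assert set(fitted.selected_features) <= set(FEATURE_NAMES)
        assert 0 < len(fitted.selected_features) <= 33
        assert fitted.test_r2 == res.test_r2 is not None
        assert fitted.test_r2 > 0.9  # strong linear signal
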