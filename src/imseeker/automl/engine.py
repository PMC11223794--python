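"""Bi-level model search: Tabu over (selector, regressor), TPE underneath.

The upper level walks the 84-pair portfolio as a combinatorial problem with
a full-memory tabu list (a visited pair is never re-evaluated); the lower
level tunes each visited pair's hyperparameters with TPE.  The objective at
both levels is the mean out-of-fold R^2 of the pipeline under k-fold
cross-validation on the training split; a held-out test split is scored
exactly once, after the search has finished.
"""

from __future__ import annotations

import logging
import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline

from ..features import FEATURE_NAMES
from .space import (SearchSpace, build_model, build_selector,
                    config_param_space)
from .tpe import tpe_maximize

__all__ = [
    "AutoMLBudget", "PRESETS", "CandidateConfig", "OptimizationResult",
    "FittedPipeline", "r2_score", "evaluate_config", "tpe_optimize",
    "tabu_search", "train_final",
]

logger = logging.getLogger(__name__)


def r2_score(y_true, y_pred) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    if yt.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("y_true has zero variance; R^2 undefined")
    ss_res = float(np.sum((yt - yp) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class AutoMLBudget:
    """Search effort: Tabu rounds (pairs visited) x TPE trials per pair."""

    upper_rounds: int
    tpe_trials: int
    cv_folds: int = 5
    preset: str = "custom"

    def __post_init__(self):
        if min(self.upper_rounds, self.tpe_trials, self.cv_folds) < 1:
            raise ValueError("all budget components must be positive")


PRESETS: Dict[str, AutoMLBudget] = {
    "swift_basic": AutoMLBudget(8, 10, preset="swift_basic"),
    "balanced": AutoMLBudget(20, 25, preset="balanced"),
    "thorough": AutoMLBudget(40, 60, preset="thorough"),
    "best_performance": AutoMLBudget(84, 150, preset="best_performance"),
}


@dataclass(frozen=True)
class CandidateConfig:
    """Upper-level variables (fs_method, model) plus tuned hyperparameters."""

    fs_method: str
    model: str
    hyperparams: Dict = field(default_factory=dict)

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.fs_method, self.model)


@dataclass
class OptimizationResult:
    best_config: CandidateConfig
    lower_objective: float  # CV R^2 of the best config on the training split
    upper_objective: float
    history: List[Tuple[CandidateConfig, float]]
    seed: int
    budget: AutoMLBudget
    test_r2: Optional[float] = None


@dataclass
class FittedPipeline:
    pipeline: Pipeline
    config: CandidateConfig
    selected_features: Tuple[str, ...]
    test_r2: Optional[float] = None


def _config_seed(fs_method: str, model: str, seed: int) -> int:
    return (zlib.crc32(f"{fs_method}|{model}".encode()) ^ seed) & 0x7FFFFFFF


def _build_pipeline(config: CandidateConfig, n_features_in: int,
                    seed: int) -> Pipeline:
    sel = build_selector(config.fs_method, config.hyperparams, n_features_in,
                         seed)
    mod = build_model(config.model, config.hyperparams, seed)
    return Pipeline([("select", sel), ("model", mod)])


def evaluate_config(config: CandidateConfig, X: np.ndarray, y: np.ndarray,
                    cv_folds: int = 5, seed: int = 0) -> float:
    """Mean out-of-fold R^2 of the configured pipeline (no leakage).

    The selector and model are refit inside every fold on that fold's
    training part only.  Any fit failure scores -inf so the search can
    continue.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2 * cv_folds:
        raise ValueError("need at least 2 rows per CV fold")
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    est_seed = _config_seed(config.fs_method, config.model, seed)
    scores = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for tr, te in kf.split(X):
                pipe = _build_pipeline(config, X.shape[1], est_seed)
                pipe.fit(X[tr], y[tr])
                scores.append(r2_score(y[te], pipe.predict(X[te])))
    except Exception as exc:  # fit failure: score -inf, log, keep searching
        logger.warning("config %s/%s failed: %s", config.fs_method,
                       config.model, exc)
        return -math.inf
    return float(np.mean(scores))


def tpe_optimize(fs_method: str, model: str, X: np.ndarray, y: np.ndarray,
                 budget: AutoMLBudget, seed: int
                 ) -> Tuple[Dict, float]:
    """Tune one (selector, regressor) pair; exactly budget.tpe_trials evals.

    The TPE stream is seeded from (fs_method, model, seed) alone, so the
    result is independent of the order in which the upper level visits
    pairs — exhaustive enumeration and Tabu search agree config-for-config.
    """
    space = config_param_space(fs_method, model)

    def objective(params: Dict) -> float:
        cfg = CandidateConfig(fs_method, model, params)
        return evaluate_config(cfg, X, y, budget.cv_folds, seed)

    params, value, _ = tpe_maximize(objective, space, budget.tpe_trials,
                                    seed=_config_seed(fs_method, model, seed))
    return params, value


def tabu_search(space: SearchSpace, X: np.ndarray, y: np.ndarray,
                budget: AutoMLBudget, seed: int = 0) -> OptimizationResult:
    """Upper-level combinatorial search over (selector, regressor) pairs.

    One pair is TPE-evaluated per round.  The tabu list has full memory, so
    no pair is ever scored twice; the neighbourhood of a pair is every pair
    differing in exactly one coordinate.  The next pair to evaluate is a
    seeded random non-tabu neighbour of the current incumbent; when the
    neighbourhood is exhausted the walk restarts at a random unvisited pair.
    With upper_rounds >= the portfolio size the whole space is enumerated and
    the result equals the exhaustive argmax.
    """
    rng = np.random.default_rng(seed)
    pairs = space.pairs()
    visited: Dict[Tuple[str, str], Tuple[Dict, float]] = {}
    history: List[Tuple[CandidateConfig, float]] = []
    best_pair, best_val = None, -math.inf

    current = pairs[int(rng.integers(len(pairs)))]
    rounds = min(budget.upper_rounds, len(pairs))
    for _ in range(rounds):
        hp, val = tpe_optimize(current[0], current[1], X, y, budget, seed)
        visited[current] = (hp, val)
        cfg = CandidateConfig(current[0], current[1], hp)
        history.append((cfg, val))
        if best_pair is None or val > best_val or (val == best_val
                                                   and current < best_pair):
            best_pair, best_val = current, val
        if len(visited) == len(pairs):
            break
        neigh = sorted(p for p in pairs
                       if p not in visited
                       and (p[0] == best_pair[0]) != (p[1] == best_pair[1]))
        if not neigh:
            neigh = sorted(p for p in pairs if p not in visited)
        current = neigh[int(rng.integers(len(neigh)))]

    if best_pair is None or not math.isfinite(best_val):
        raise RuntimeError("no feasible configuration found within budget")
    hp, val = visited[best_pair]
    best_config = CandidateConfig(best_pair[0], best_pair[1], hp)
    return OptimizationResult(best_config=best_config, lower_objective=val,
                              upper_objective=val, history=history,
                              seed=seed, budget=budget)


def train_final(result: OptimizationResult, X_train: np.ndarray,
                y_train: np.ndarray, X_test: Optional[np.ndarray] = None,
                y_test: Optional[np.ndarray] = None,
                feature_names: Sequence[str] = FEATURE_NAMES
                ) -> FittedPipeline:
    """Refit the best configuration on the full training split.

    Records the names of the features surviving selection and, when a
    held-out split is supplied, its R^2 — computed here exactly once.
    """
    cfg = result.best_config
    est_seed = _config_seed(cfg.fs_method, cfg.model, result.seed)
    pipe = _build_pipeline(cfg, X_train.shape[1], est_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe.fit(X_train, y_train)
    sel = pipe.named_steps["select"]
    if sel == "passthrough" or not hasattr(sel, "get_support"):
        selected = tuple(feature_names)
    else:
        mask = sel.get_support()
        selected = tuple(n for n, keep in zip(feature_names, mask) if keep)
    fitted = FittedPipeline(pipeline=pipe, config=cfg,
                            selected_features=selected)
    if X_test is not None and y_test is not None:
        fitted.test_r2 = r2_score(y_test, pipe.predict(X_test))
        result.test_r2 = fitted.test_r2
    return fitted
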