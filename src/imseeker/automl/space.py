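"""Upper-level portfolios and lower-level hyperparameter domains.

The upper-level search space is the cross product of 7 feature-selection
families (6 selectors plus a NONE pass-through) and 12 regressor families,
84 combinations in total.  Each family carries a flat hyperparameter domain
of integer, real (optionally log-scaled) and categorical dimensions; the
exact ranges below are frozen here as the package's declared configuration
space, balancing search quality against single-CPU runtime.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import partial
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
from sklearn.ensemble import (AdaBoostRegressor, BaggingRegressor,
                              ExtraTreesRegressor, GradientBoostingRegressor,
                              HistGradientBoostingRegressor,
                              RandomForestRegressor, StackingRegressor)
from sklearn.feature_selection import (RFE, RFECV, GenericUnivariateSelect,
                                       SelectFromModel,
                                       SequentialFeatureSelector,
                                       VarianceThreshold, f_regression,
                                       mutual_info_regression)
from sklearn.linear_model import Ridge
from sklearn.model_selection import ShuffleSplit
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

__all__ = [
    "RealParam", "IntParam", "CatParam", "Param",
    "FS_PORTFOLIO", "MODEL_PORTFOLIO", "SearchSpace",
    "fs_param_space", "model_param_space", "config_param_space",
    "build_selector", "build_model",
]


@dataclass(frozen=True)
class RealParam:
    name: str
    low: float
    high: float
    log: bool = False


@dataclass(frozen=True)
class IntParam:
    name: str
    low: int
    high: int
    log: bool = False


@dataclass(frozen=True)
class CatParam:
    name: str
    choices: Tuple


Param = Union[RealParam, IntParam, CatParam]

FS_PORTFOLIO: Tuple[str, ...] = ("NONE", "GUS", "SFM", "SFS", "RFE",
                                 "RFECV", "VT")
MODEL_PORTFOLIO: Tuple[str, ...] = ("RIDGE", "DTR", "RFR", "GBR", "SVR",
                                    "MLPR", "ETR", "BR", "ABR", "STR",
                                    "HGBR", "XGBR")


@dataclass(frozen=True)
class SearchSpace:
    """Upper-level portfolios; the default enumerates 7 x 12 = 84 pairs."""

    fs_portfolio: Tuple[str, ...] = FS_PORTFOLIO
    model_portfolio: Tuple[str, ...] = MODEL_PORTFOLIO

    def __post_init__(self):
        bad = set(self.fs_portfolio) - set(FS_PORTFOLIO)
        bad |= set(self.model_portfolio) - set(MODEL_PORTFOLIO)
        if bad:
            raise ValueError(f"unknown portfolio labels: {sorted(bad)}")

    def pairs(self) -> List[Tuple[str, str]]:
        return [(f, m) for f in self.fs_portfolio for m in self.model_portfolio]

    @property
    def size(self) -> int:
        return len(self.fs_portfolio) * len(self.model_portfolio)


_FS_SPACES: Dict[str, Tuple[Param, ...]] = {
    "NONE": (),
    "GUS": (
        CatParam("mode", ("percentile", "k_best")),
        CatParam("score_func_name", ("f_regression",
                                     "mutual_info_regression")),
        IntParam("percentile", 10, 90),
        IntParam("k_best", 3, 33),
    ),
    "SFM": (
        CatParam("estimator_choice", ("rfr", "etr", "ridge")),
        IntParam("n_estimators", 30, 100),
        IntParam("max_depth", 2, 8),
        CatParam("threshold", ("mean", "median", "0.5*mean")),
        IntParam("max_features", 3, 33),
    ),
    "SFS": (
        CatParam("estimator", ("ridge", "dtr")),
        CatParam("scoring_choice", ("r2", "neg_mean_squared_error")),
        CatParam("forward_choice", ("forward", "backward")),
        IntParam("k_features_value", 3, 5),
        IntParam("n_estimators", 20, 40),
        IntParam("max_depth", 2, 3),
    ),
    "RFE": (
        CatParam("estimator_name", ("ridge", "dtr", "rfr")),
        IntParam("n_features_to_select", 3, 20),
        IntParam("max_depth", 2, 8),
    ),
    "RFECV": (
        IntParam("min_features_to_select", 5, 15),
        CatParam("scoring", ("r2", "neg_mean_squared_error")),
        CatParam("estimator_name", ("ridge", "dtr", "rfr")),
        IntParam("max_depth", 2, 6),
        IntParam("n_estimators", 20, 50),
    ),
    "VT": (
        RealParam("threshold", 0.0, 0.5),
    ),
}

_MLP_LAYERS = ((16,), (32,), (64,), (128,), (64, 32), (128, 64), (64, 32, 16))

_MODEL_SPACES: Dict[str, Tuple[Param, ...]] = {
    "RIDGE": (
        RealParam("alpha", 1e-3, 1e3, log=True),
    ),
    "DTR": (
        IntParam("max_depth", 2, 12),
        IntParam("min_samples_split", 2, 20),
        IntParam("min_samples_leaf", 1, 10),
    ),
    "RFR": (
        IntParam("n_estimators", 50, 150, log=True),
        IntParam("max_depth", 2, 12),
        IntParam("min_samples_split", 2, 20),
        IntParam("min_samples_leaf", 1, 10),
    ),
    "GBR": (
        IntParam("n_estimators", 50, 150, log=True),
        RealParam("learning_rate", 0.01, 0.3, log=True),
        IntParam("max_depth", 2, 8),
        IntParam("min_samples_split", 2, 20),
        IntParam("min_samples_leaf", 1, 10),
    ),
    "SVR": (
        RealParam("c", 1e-2, 1e2, log=True),
        CatParam("kernel", ("linear", "rbf", "sigmoid")),
    ),
    "MLPR": (
        CatParam("batch_size", (32, 64, 128)),
        RealParam("alpha", 1e-6, 1e-1, log=True),
        CatParam("learning_rate", ("constant", "adaptive")),
        RealParam("learning_rate_init", 1e-4, 1e-1, log=True),
        RealParam("momentum", 0.5, 0.95),
        CatParam("hidden_layer_sizes", _MLP_LAYERS),
        CatParam("activation", ("relu", "tanh", "logistic")),
        CatParam("solver", ("adam", "sgd")),
    ),
    "ETR": (
        IntParam("n_estimators", 50, 150, log=True),
        IntParam("max_depth", 2, 12),
        IntParam("min_samples_split", 2, 20),
        IntParam("min_samples_leaf", 1, 10),
    ),
    "BR": (
        IntParam("n_estimators", 10, 40, log=True),
        RealParam("max_samples", 0.5, 1.0),
        RealParam("max_features", 0.5, 1.0),
        CatParam("base_estimator", ("dtr", "ridge")),
    ),
    "ABR": (
        CatParam("base_estimator", ("dtr",)),
        IntParam("max_depth", 2, 8),
        IntParam("n_estimators", 40, 120, log=True),
        RealParam("learning_rate", 0.01, 1.0, log=True),
    ),
    "STR": (
        CatParam("final_estimator_name", ("ridge", "hgbr")),
        IntParam("n_estimators", 20, 40, log=True),
        IntParam("max_depth", 2, 8),
        IntParam("max_iter", 40, 80, log=True),
        RealParam("learning_rate", 0.03, 0.3, log=True),
        IntParam("min_samples_leaf", 5, 30),
    ),
    "HGBR": (
        IntParam("max_iter", 50, 250, log=True),
        RealParam("learning_rate", 0.01, 0.3, log=True),
        IntParam("max_depth", 2, 12),
        IntParam("min_samples_leaf", 5, 50),
    ),
    "XGBR": (
        CatParam("booster", ("gbtree", "gblinear")),
        RealParam("lambda", 1e-3, 10.0, log=True),
        RealParam("alpha", 1e-3, 10.0, log=True),
        RealParam("subsample", 0.5, 1.0),
        RealParam("colsample_bytree", 0.5, 1.0),
        IntParam("max_depth", 2, 10),
        RealParam("min_child_weight", 0.5, 10.0, log=True),
        RealParam("eta", 1e-3, 0.3, log=True),
        RealParam("gamma", 1e-3, 5.0, log=True),
        CatParam("grow_policy", ("depthwise", "lossguide")),
    ),
}


def _prefix(params: Sequence[Param], prefix: str) -> Tuple[Param, ...]:
    out = []
    for p in params:
        kw = {**p.__dict__, "name": f"{prefix}{p.name}"}
        out.append(type(p)(**kw))
    return tuple(out)


def fs_param_space(label: str) -> Tuple[Param, ...]:
    return _prefix(_FS_SPACES[label], "fs__")


def model_param_space(label: str) -> Tuple[Param, ...]:
    return _prefix(_MODEL_SPACES[label], "model__")


def config_param_space(fs_method: str, model: str) -> Tuple[Param, ...]:
    """The flat lower-level domain for one (selector, regressor) pair."""
    return fs_param_space(fs_method) + model_param_space(model)


def _strip(hp: Dict, prefix: str) -> Dict:
    return {k[len(prefix):]: v for k, v in hp.items() if k.startswith(prefix)}


def _inner_estimator(name: str, hp: Dict, seed: int):
    if name == "ridge":
        return Ridge(alpha=1.0)
    if name == "dtr":
        return DecisionTreeRegressor(max_depth=hp.get("max_depth", 5),
                                     random_state=seed)
    if name in ("rfr", "etr"):
        cls = RandomForestRegressor if name == "rfr" else ExtraTreesRegressor
        return cls(n_estimators=hp.get("n_estimators", 50),
                   max_depth=hp.get("max_depth", 5), random_state=seed,
                   n_jobs=1)
    raise ValueError(name)


def build_selector(label: str, hyperparams: Dict, n_features_in: int,
                   seed: int):
    """Instantiate the feature-selection step ('passthrough' for NONE)."""
    hp = _strip(hyperparams, "fs__")
    nf = n_features_in
    if label == "NONE":
        return "passthrough"
    if label == "GUS":
        score = (f_regression if hp["score_func_name"] == "f_regression"
                 else partial(mutual_info_regression, random_state=seed))
        param = (hp["percentile"] if hp["mode"] == "percentile"
                 else min(hp["k_best"], nf))
        return GenericUnivariateSelect(score_func=score, mode=hp["mode"],
                                       param=param)
    if label == "SFM":
        est = _inner_estimator(hp["estimator_choice"], hp, seed)
        return SelectFromModel(est, threshold=hp["threshold"],
                               max_features=min(hp["max_features"], nf))
    if label == "SFS":
        est = _inner_estimator(hp["estimator"], hp, seed)
        # k_features_value counts selection steps: features added (forward)
        # or removed (backward); a single shuffle split keeps the inner
        # search affordable inside cross-validated evaluation
        k = min(hp["k_features_value"], nf - 1)
        n_select = k if hp["forward_choice"] == "forward" else nf - k
        return SequentialFeatureSelector(
            est, n_features_to_select=n_select,
            direction=hp["forward_choice"], scoring=hp["scoring_choice"],
            cv=ShuffleSplit(n_splits=1, test_size=0.3, random_state=seed),
            n_jobs=1)
    if label == "RFE":
        est = _inner_estimator(hp["estimator_name"], hp, seed)
        return RFE(est, n_features_to_select=min(hp["n_features_to_select"],
                                                 nf), step=0.2)
    if label == "RFECV":
        est = _inner_estimator(hp["estimator_name"], hp, seed)
        return RFECV(est,
                     min_features_to_select=min(hp["min_features_to_select"],
                                                nf),
                     scoring=hp["scoring"], step=0.3, cv=2, n_jobs=1)
    if label == "VT":
        return VarianceThreshold(threshold=hp["threshold"])
    raise ValueError(f"unknown selector family {label!r}")


def build_model(label: str, hyperparams: Dict, seed: int):
    """Instantiate the regressor for one portfolio family."""
    hp = _strip(hyperparams, "model__")
    if label == "RIDGE":
        return Ridge(alpha=hp["alpha"])
    if label == "DTR":
        return DecisionTreeRegressor(random_state=seed, **hp)
    if label == "RFR":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **hp)
    if label == "GBR":
        return GradientBoostingRegressor(random_state=seed, **hp)
    if label == "SVR":
        return SVR(C=hp["c"], kernel=hp["kernel"])
    if label == "MLPR":
        return MLPRegressor(random_state=seed, max_iter=200, **hp)
    if label == "ETR":
        return ExtraTreesRegressor(random_state=seed, n_jobs=1, **hp)
    if label == "BR":
        base = _inner_estimator(hp.pop("base_estimator"), {"max_depth": 8},
                                seed)
        return BaggingRegressor(estimator=base, random_state=seed, n_jobs=1,
                                **hp)
    if label == "ABR":
        hp.pop("base_estimator")
        base = DecisionTreeRegressor(max_depth=hp.pop("max_depth"),
                                     random_state=seed)
        return AdaBoostRegressor(estimator=base, random_state=seed, **hp)
    if label == "STR":
        hgbr = HistGradientBoostingRegressor(
            max_iter=hp["max_iter"], learning_rate=hp["learning_rate"],
            min_samples_leaf=hp["min_samples_leaf"], random_state=seed)
        rfr = RandomForestRegressor(n_estimators=hp["n_estimators"],
                                    max_depth=hp["max_depth"],
                                    random_state=seed, n_jobs=1)
        final = (Ridge(alpha=1.0) if hp["final_estimator_name"] == "ridge"
                 else HistGradientBoostingRegressor(random_state=seed))
        return StackingRegressor(estimators=[("ridge", Ridge(alpha=1.0)),
                                             ("rfr", rfr), ("hgbr", hgbr)],
                                 final_estimator=final, cv=2, n_jobs=1)
    if label == "HGBR":
        return HistGradientBoostingRegressor(random_state=seed, **hp)
    if label == "XGBR":
        return XGBRegressor(
            n_estimators=100, booster=hp["booster"],
            reg_lambda=hp["lambda"], reg_alpha=hp["alpha"],
            subsample=hp["subsample"], colsample_bytree=hp["colsample_bytree"],
            max_depth=hp["max_depth"], min_child_weight=hp["min_child_weight"],
            learning_rate=hp["eta"], gamma=hp["gamma"],
            grow_policy=hp["grow_policy"], tree_method="hist",
            random_state=seed, n_jobs=1, verbosity=0)
    raise ValueError(f"unknown model family {label!r}")
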