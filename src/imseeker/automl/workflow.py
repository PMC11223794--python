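"""End-to-end AutoML workflow: CSV in, fitted scoring model out.

Training data is a CSV with columns ``sequence,label`` where the label is
any quantitative i-motif property (transition pH, melting point, ...).
Sequences are re-validated against the detection parameters; rows without a
valid i-motif candidate are reported and dropped.  Features are extracted
from the leftmost candidate of each sequence, a normalizer is fitted
on the training split only, and the bi-level search runs on the normalized
training matrix.  The held-out split (20% by default) is scored once at the
end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from ..detect import DetectionParams, IMotifCandidate, enumerate_candidates
from ..features import (FEATURE_NAMES, Normalizer, apply_normalizer,
                        feature_matrix, fit_normalizer)
from .engine import (PRESETS, AutoMLBudget, FittedPipeline,
                     OptimizationResult, tabu_search, train_final)
from .space import SearchSpace

__all__ = ["AutoMLRun", "validate_sequences", "featurize_table", "run_automl"]


@dataclass
class AutoMLRun:
    """Everything produced by one training run, ready for bundling."""

    result: OptimizationResult
    fitted: FittedPipeline
    normalizer: Normalizer
    feature_names: Tuple[str, ...]
    label_min: float
    label_max: float
    n_train: int
    n_test: int
    dropped_rows: Tuple[int, ...]

    def report(self) -> dict:
        return {
            "best_config": {
                "fs_method": self.result.best_config.fs_method,
                "model": self.result.best_config.model,
                "hyperparams": {k: (list(v) if isinstance(v, tuple) else v)
                                for k, v in
                                self.result.best_config.hyperparams.items()},
            },
            "cv_r2": self.result.lower_objective,
            "test_r2": self.result.test_r2,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_dropped": len(self.dropped_rows),
            "selected_features": list(self.fitted.selected_features),
            "seed": self.result.seed,
            "budget": {
                "preset": self.result.budget.preset,
                "upper_rounds": self.result.budget.upper_rounds,
                "tpe_trials": self.result.budget.tpe_trials,
                "cv_folds": self.result.budget.cv_folds,
            },
            "history": [
                {"fs_method": c.fs_method, "model": c.model, "cv_r2": v}
                for c, v in self.result.history
            ],
        }


def validate_sequences(sequences: Sequence[str],
                       params: Optional[DetectionParams] = None
                       ) -> Tuple[List[Optional[IMotifCandidate]], List[int]]:
    """Re-validate training sequences against the detection parameters.

    A sequence is valid iff forward-strand detection with the configured
    parameters yields at least one candidate; the leftmost candidate
    represents it, so featurization matches what a scan of the same
    sequence would report.
    Returns (candidate-or-None per row, indices of invalid rows).
    """
    if params is None:
        params = DetectionParams()
    greedy = replace(params, allow_overlap=False,
                     scan_reverse_complement=False)
    out: List[Optional[IMotifCandidate]] = []
    bad: List[int] = []
    for i, seq in enumerate(sequences):
        cands = enumerate_candidates(str(seq), greedy)
        if cands:
            out.append(cands[0])
        else:
            out.append(None)
            bad.append(i)
    return out, bad


def featurize_table(df: pd.DataFrame,
                    params: Optional[DetectionParams] = None
                    ) -> Tuple[pd.DataFrame, np.ndarray, List[int]]:
    """Feature matrix and labels for a ``sequence,label`` table.

    Returns (X as a DataFrame with canonical columns, y, dropped row
    indices).  Raises on a missing header or non-numeric labels.
    """
    for col in ("sequence", "label"):
        if col not in df.columns:
            raise ValueError(f"training CSV must have a {col!r} column")
    labels = pd.to_numeric(df["label"], errors="raise").to_numpy(dtype=float)
    cands, bad = validate_sequences(df["sequence"].tolist(), params)
    keep = [i for i, c in enumerate(cands) if c is not None]
    X = feature_matrix([cands[i] for i in keep])
    return X, labels[keep], bad


def run_automl(df: pd.DataFrame,
               params: Optional[DetectionParams] = None,
               budget: Optional[AutoMLBudget] = None,
               preset: str = "balanced",
               seed: int = 0,
               space: Optional[SearchSpace] = None,
               features: Optional[Sequence[str]] = None,
               test_size: float = 0.2) -> AutoMLRun:
    """Full training run on a ``sequence,label`` table.

    ``features`` pins a user-chosen subset of the canonical 33 names;
    selectors then operate only within it.  The search never sees the
    held-out split.
    """
    if budget is None:
        budget = PRESETS[preset]
    if space is None:
        space = SearchSpace()
    X_df, y, bad = featurize_table(df, params)
    if features is not None:
        unknown = set(features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        names = tuple(n for n in FEATURE_NAMES if n in set(features))
        X_df = X_df[list(names)]
    else:
        names = FEATURE_NAMES
    if len(X_df) < 5 * budget.cv_folds:
        raise ValueError("too few valid training rows for the CV budget")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X_df.to_numpy(), y, test_size=test_size, random_state=seed,
        shuffle=True)
    norm = fit_normalizer(X_tr, method="zscore")
    Xn_tr = apply_normalizer(norm, X_tr)
    Xn_te = apply_normalizer(norm, X_te)
    result = tabu_search(space, Xn_tr, y_tr, budget, seed=seed)
    fitted = train_final(result, Xn_tr, y_tr, Xn_te, y_te,
                         feature_names=names)
    return AutoMLRun(result=result, fitted=fitted, normalizer=norm,
                     feature_names=names,
                     label_min=float(np.min(y_tr)),
                     label_max=float(np.max(y_tr)),
                     n_train=len(y_tr), n_test=len(y_te),
                     dropped_rows=tuple(bad))
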