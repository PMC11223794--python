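"""The 33 canonical i-motif features and feature normalization.

Every scoring model in the package consumes the same fixed, ordered set of
33 numeric features per candidate: 13 structural descriptors (motif length,
tract and loop geometry), 4 mono-nucleotide fractions, and the 16
dinucleotide frequencies.  The order is frozen in :data:`FEATURE_NAMES` so
that model bundles remain portable and self-describing.

Conventions: variances are population (divide-by-n) variances; dinucleotide
frequencies use motif length - 1 as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .detect import IMotifCandidate

__all__ = [
    "FEATURE_NAMES",
    "N_FEATURES",
    "FeatureVector",
    "Normalizer",
    "extract_features",
    "feature_matrix",
    "fit_normalizer",
    "apply_normalizer",
    "invert_normalizer",
]

_DINUCS = tuple(a + b for a in "ACGT" for b in "ACGT")

#: Canonical ordered feature names; the contract shared by all models.
FEATURE_NAMES: Tuple[str, ...] = (
    "length",
    "n_tracts",
    "tract_len_mean",
    "tract_len_min",
    "tract_len_max",
    "tract_len_var",
    "n_loops",
    "loop_len_mean",
    "loop_len_min",
    "loop_len_max",
    "loop_len_var",
    "loop_len_total",
    "tract_fraction",
    "frac_A",
    "frac_C",
    "frac_G",
    "frac_T",
) + tuple(f"di_{d}" for d in _DINUCS)

N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 33

#: Index of the first compositional feature; features before this depend only
#: on the tract/loop geometry, not on loop nucleotide identity.
STRUCTURAL_SPLIT = FEATURE_NAMES.index("frac_A")


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: Tuple[str, ...] = FEATURE_NAMES

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values.tolist()))


def _pop_var(xs: Sequence[float]) -> float:
    m = sum(xs) / len(xs)
    return sum((x - m) ** 2 for x in xs) / len(xs)


def extract_features(candidate: IMotifCandidate) -> FeatureVector:
    """Compute the canonical 33-dimension feature vector of a candidate."""
    seq = candidate.sequence
    n = len(seq)
    tract_lens = [t.length for t in candidate.tracts]
    loop_lens = [lp.length for lp in candidate.loops]
    vals: List[float] = [
        float(n),
        float(len(tract_lens)),
        float(np.mean(tract_lens)),
        float(min(tract_lens)),
        float(max(tract_lens)),
        _pop_var(tract_lens),
        float(len(loop_lens)),
        float(np.mean(loop_lens)) if loop_lens else 0.0,
        float(min(loop_lens)) if loop_lens else 0.0,
        float(max(loop_lens)) if loop_lens else 0.0,
        _pop_var(loop_lens) if loop_lens else 0.0,
        float(sum(loop_lens)),
        sum(tract_lens) / n,
    ]
    for base in "ACGT":
        vals.append(seq.count(base) / n)
    denom = max(n - 1, 1)
    for d in _DINUCS:
        count = sum(1 for i in range(n - 1) if seq[i:i + 2] == d)
        vals.append(count / denom)
    return FeatureVector(np.asarray(vals, dtype=float))


def feature_matrix(candidates: Iterable[IMotifCandidate]) -> pd.DataFrame:
    """Feature vectors for many candidates as a DataFrame (columns = names)."""
    rows = [extract_features(c).values for c in candidates]
    if not rows:
        return pd.DataFrame(columns=list(FEATURE_NAMES))
    return pd.DataFrame(np.vstack(rows), columns=list(FEATURE_NAMES))


@dataclass(frozen=True)
class Normalizer:
    """Column-wise affine normalization fitted on a training matrix.

    ``zscore`` centers on the mean and divides by the population standard
    deviation; ``minmax`` maps the training range onto [0, 1].  Columns with
    zero spread keep scale 1 (flagged in ``constant``) and pass through
    centered only.
    """

    center: np.ndarray
    scale: np.ndarray
    method: str
    constant: np.ndarray  # boolean mask of zero-spread columns

    @property
    def n_features(self) -> int:
        return self.center.shape[0]


def fit_normalizer(matrix: np.ndarray, method: str = "zscore") -> Normalizer:
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D feature matrix")
    if method == "zscore":
        if X.shape[0] < 2:
            raise ValueError("zscore normalization needs at least 2 rows")
        center = X.mean(axis=0)
        scale = X.std(axis=0)  # population sd
    elif method == "minmax":
        center = X.min(axis=0)
        scale = X.max(axis=0) - center
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    constant = scale == 0.0
    scale = np.where(constant, 1.0, scale)
    return Normalizer(center=center, scale=scale, method=method,
                      constant=constant)


def apply_normalizer(norm: Normalizer, matrix: np.ndarray) -> np.ndarray:
    X = np.asarray(matrix, dtype=float)
    return (X - norm.center) / norm.scale


def invert_normalizer(norm: Normalizer, matrix: np.ndarray) -> np.ndarray:
    X = np.asarray(matrix, dtype=float)
    return X * norm.scale + norm.center
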