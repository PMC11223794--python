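"""Tree-structured Parzen Estimator for the lower-level hyperparameter search.

Classic TPE: past trials are split by objective value into a *good* fraction
(top ``gamma``) and the rest; two one-dimensional Parzen densities l(x) and
g(x) are fitted per dimension (Gaussian mixtures over observed values plus a
wide domain prior for numeric dimensions; reweighted categorical frequencies
with a unit pseudo-count for categorical ones), and the next trial maximizes
the density ratio l(x)/g(x) over a batch of candidates drawn from l.
Numeric dimensions may be log-scaled; integer dimensions are quantized after
sampling.  Because each (selector, regressor) pair has a flat, unconditional
domain here, per-dimension independent densities suffice — the "tree" of
conditional choices collapses to a product.

When the whole domain is finite and small, proposals are de-duplicated
against previous trials so distinct configurations are preferred while
untried ones remain (the objective is deterministic, so repeats carry no
information).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .space import CatParam, IntParam, Param, RealParam

__all__ = ["Trial", "tpe_minimize", "tpe_maximize"]


@dataclass(frozen=True)
class Trial:
    params: Dict
    value: float


def _to_unit(p: Param, v) -> float:
    if isinstance(p, CatParam):
        raise TypeError
    lo, hi = (math.log(p.low), math.log(p.high)) if p.log else (p.low, p.high)
    x = math.log(v) if p.log else float(v)
    return (x - lo) / (hi - lo) if hi > lo else 0.5


def _from_unit(p: Param, u: float):
    u = min(max(u, 0.0), 1.0)
    lo, hi = (math.log(p.low), math.log(p.high)) if p.log else (p.low, p.high)
    x = lo + u * (hi - lo)
    v = math.exp(x) if p.log else x
    if isinstance(p, IntParam):
        return int(min(max(int(round(v)), p.low), p.high))
    return float(min(max(v, p.low), p.high))


def _sample_uniform(p: Param, rng: np.random.Generator):
    if isinstance(p, CatParam):
        return p.choices[int(rng.integers(len(p.choices)))]
    return _from_unit(p, float(rng.random()))


class _NumericParzen:
    """1-D Parzen mixture over unit-interval observations + uniform prior."""

    def __init__(self, obs: Sequence[float]):
        self.mu = np.asarray(sorted(obs), dtype=float)
        n = len(self.mu)
        if n == 0:
            self.sigma = np.array([])
        else:
            # bandwidth: distance to the larger neighbour gap, clipped
            ext = np.concatenate(([0.0], self.mu, [1.0]))
            left = np.diff(ext)[:-1]
            right = np.diff(ext)[1:]
            self.sigma = np.clip(np.maximum(left, right), 1.0 / max(n, 2), 1.0)

    def sample(self, rng: np.random.Generator) -> float:
        n = len(self.mu)
        i = int(rng.integers(n + 1))
        if i == n:  # the uniform prior component
            return float(rng.random())
        return float(rng.normal(self.mu[i], self.sigma[i]))

    def logpdf(self, x: float) -> float:
        n = len(self.mu)
        dens = 1.0  # uniform prior on [0, 1]
        if n:
            z = (x - self.mu) / self.sigma
            dens += np.sum(np.exp(-0.5 * z * z) / (self.sigma * math.sqrt(2 * math.pi)))
        return math.log(dens / (n + 1) + 1e-300)


class _CategoricalParzen:
    def __init__(self, choices: Sequence, obs: Sequence):
        counts = np.ones(len(choices))  # unit pseudo-count prior
        index = {c: i for i, c in enumerate(choices)}
        for v in obs:
            counts[index[v]] += 1
        self.choices = tuple(choices)
        self.index = index
        self.p = counts / counts.sum()

    def sample(self, rng: np.random.Generator):
        return self.choices[int(rng.choice(len(self.choices), p=self.p))]

    def logpdf(self, v) -> float:
        return math.log(self.p[self.index[v]] + 1e-300)


def _finite_size(space: Sequence[Param], cap: int = 100_000) -> Optional[int]:
    total = 1
    for p in space:
        if isinstance(p, CatParam):
            total *= len(p.choices)
        elif isinstance(p, IntParam) and not p.log:
            total *= p.high - p.low + 1
        elif isinstance(p, IntParam):
            total *= p.high - p.low + 1
        else:
            return None
        if total > cap:
            return None
    return total


def tpe_maximize(objective: Callable[[Dict], float], space: Sequence[Param],
                 n_trials: int, seed: int, gamma: float = 0.25,
                 n_ei_candidates: int = 24,
                 n_startup: Optional[int] = None) -> Tuple[Dict, float, List[Trial]]:
    """Maximize ``objective`` over the domain with exactly ``n_trials`` calls.

    Returns (best params, best value, full trial history).  Deterministic
    given the seed.  Failed evaluations should be signalled by the objective
    returning -inf; they land in the *bad* density like any poor trial.
    """
    rng = np.random.default_rng(seed)
    if n_startup is None:
        n_startup = max(3, min(10, n_trials // 3))
    trials: List[Trial] = []
    seen = set()
    domain_size = _finite_size(space)

    def key(params: Dict) -> Tuple:
        return tuple(params[p.name] for p in space)

    for t in range(n_trials):
        if t < n_startup or len(trials) < 2:
            params = {p.name: _sample_uniform(p, rng) for p in space}
        else:
            params = _propose(space, trials, rng, gamma, n_ei_candidates)
        if domain_size is not None and len(seen) < domain_size:
            tries = 0
            while key(params) in seen and tries < 50:
                params = {p.name: _sample_uniform(p, rng) for p in space}
                tries += 1
        seen.add(key(params))
        value = objective(params)
        trials.append(Trial(params=params, value=float(value)))
    best = max(trials, key=lambda tr: (tr.value, ))
    return best.params, best.value, trials


def _propose(space: Sequence[Param], trials: Sequence[Trial],
             rng: np.random.Generator, gamma: float,
             n_ei: int) -> Dict:
    order = sorted(trials, key=lambda tr: tr.value, reverse=True)
    n_good = max(1, int(math.ceil(gamma * len(order))))
    good, bad = order[:n_good], order[n_good:] or order[n_good - 1:]
    best_params, best_score = None, -math.inf
    models = []
    for p in space:
        gv = [tr.params[p.name] for tr in good]
        bv = [tr.params[p.name] for tr in bad]
        if isinstance(p, CatParam):
            models.append((p, _CategoricalParzen(p.choices, gv),
                           _CategoricalParzen(p.choices, bv)))
        else:
            models.append((p, _NumericParzen([_to_unit(p, v) for v in gv]),
                           _NumericParzen([_to_unit(p, v) for v in bv])))
    for _ in range(n_ei):
        cand = {}
        score = 0.0
        for p, l_model, g_model in models:
            if isinstance(p, CatParam):
                v = l_model.sample(rng)
                score += l_model.logpdf(v) - g_model.logpdf(v)
                cand[p.name] = v
            else:
                u = l_model.sample(rng)
                u = min(max(u, 0.0), 1.0)
                v = _from_unit(p, u)
                # score at the quantized value actually proposed
                uq = _to_unit(p, v)
                score += l_model.logpdf(uq) - g_model.logpdf(uq)
                cand[p.name] = v
        if score > best_score:
            best_score, best_params = score, cand
    return best_params


def tpe_minimize(objective, space, n_trials, seed, **kw):
    params, value, trials = tpe_maximize(lambda p: -objective(p), space,
                                         n_trials, seed, **kw)
    return params, -value, [Trial(t.params, -t.value) for t in trials]
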