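"""Tree-structured Parzen estimator (TPE) for hyperparameter search.

Sequential model-based optimization: after ``n_startup`` uniformly random
trials, observed trials are split at the gamma-quantile of their objective
values into a "good" set and a "bad" set.  Each is modelled with a univariate
Parzen (kernel-density) mixture per parameter; candidates are drawn from the
good density l(x) and the one maximizing the acquisition ratio l(x)/g(x) is
suggested.  Parameters declared log-scaled are modelled in log space;
integers are rounded after sampling; categoricals use smoothed frequency
estimates.

The objective is maximized.  All randomness flows from one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Real:
    low: float
    high: float
    log: bool = False


@dataclass(frozen=True)
class Integer:
    low: int
    high: int
    log: bool = False


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def __init__(self, choices):
        object.__setattr__(self, "choices", tuple(choices))


SearchSpace = dict[str, Real | Integer | Categorical]


@dataclass
class Trial:
    number: int
    params: dict
    score: float  # NaN marks a failed trial

    @property
    def ok(self) -> bool:
        return math.isfinite(self.score)


def _to_internal(value, dim) -> float:
    if isinstance(dim, Categorical):
        return float(dim.choices.index(value))
    v = float(value)
    return math.log(v) if dim.log else v


def _from_internal(x: float, dim):
    if isinstance(dim, Categorical):
        return dim.choices[int(round(x))]
    v = math.exp(x) if dim.log else x
    if isinstance(dim, Integer):
        return int(min(max(round(v), dim.low), dim.high))
    return float(min(max(v, dim.low), dim.high))


def _bounds(dim) -> tuple[float, float]:
    lo, hi = float(dim.low), float(dim.high)
    if dim.log:
        lo, hi = math.log(lo), math.log(hi)
    return lo, hi


class TPESampler:
    """Ask/tell interface: ``ask()`` suggests params, ``tell(params, score)``
    records the (to-be-maximized) objective."""

    def __init__(self, space: SearchSpace, seed: int = 0, n_startup: int = 30,
                 gamma: float = 0.25, n_candidates: int = 24):
        if not space:
            raise ValueError("empty search space")
        self.space = space
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self.rng = np.random.default_rng(seed)
        self.trials: list[Trial] = []

    # -- sampling -----------------------------------------------------------

    def _random_params(self) -> dict:
        params = {}
        for name, dim in self.space.items():
            if isinstance(dim, Categorical):
                params[name] = dim.choices[self.rng.integers(len(dim.choices))]
            else:
                lo, hi = _bounds(dim)
                params[name] = _from_internal(self.rng.uniform(lo, hi), dim)
        return params

    def _parzen_logpdf(self, x: np.ndarray, obs: np.ndarray, dim) -> np.ndarray:
        """Log density of a Gaussian Parzen mixture with a uniform prior
        component over the bounded domain."""
        lo, hi = _bounds(dim)
        span = max(hi - lo, 1e-12)
        bw = max(span / max(math.sqrt(len(obs)), 1.0), 1e-12)
        # mixture: uniform prior + one kernel per observation, equal weights
        comps = [np.full_like(x, -math.log(span))]
        for mu in obs:
            z = (x - mu) / bw
            comps.append(-0.5 * z * z - math.log(bw * math.sqrt(2 * math.pi)))
        stack = np.stack(comps)
        weight = math.log(1.0 / (len(obs) + 1))
        return weight + _logsumexp(stack, axis=0)

    def _sample_parzen(self, obs: np.ndarray, dim, size: int) -> np.ndarray:
        lo, hi = _bounds(dim)
        span = hi - lo
        bw = max(span / max(math.sqrt(len(obs)), 1.0), 1e-12)
        out = np.empty(size)
        which = self.rng.integers(0, len(obs) + 1, size=size)
        for i, w in enumerate(which):
            if w == 0:
                out[i] = self.rng.uniform(lo, hi)
            else:
                out[i] = np.clip(self.rng.normal(obs[w - 1], bw), lo, hi)
        return out

    def ask(self) -> dict:
        done = [t for t in self.trials if t.ok]
        if len(done) < self.n_startup:
            return self._random_params()
        scores = np.array([t.score for t in done])
        order = np.argsort(-scores, kind="stable")
        n_good = max(1, math.ceil(self.gamma * len(done)))
        good = [done[i] for i in order[:n_good]]
        bad = [done[i] for i in order[n_good:]] or good
        params = {}
        for name, dim in self.space.items():
            g_obs = np.array([_to_internal(t.params[name], dim) for t in good])
            b_obs = np.array([_to_internal(t.params[name], dim) for t in bad])
            if isinstance(dim, Categorical):
                k = len(dim.choices)
                g_cnt = np.bincount(g_obs.astype(int), minlength=k) + 1.0
                b_cnt = np.bincount(b_obs.astype(int), minlength=k) + 1.0
                ratio = (g_cnt / g_cnt.sum()) / (b_cnt / b_cnt.sum())
                params[name] = dim.choices[int(np.argmax(ratio))]
                continue
            cand = self._sample_parzen(g_obs, dim, self.n_candidates)
            score = (self._parzen_logpdf(cand, g_obs, dim)
                     - self._parzen_logpdf(cand, b_obs, dim))
            params[name] = _from_internal(float(cand[np.argmax(score)]), dim)
        return params

    def tell(self, params: dict, score: float) -> Trial:
        trial = Trial(number=len(self.trials), params=dict(params),
                      score=float(score))
        self.trials.append(trial)
        return trial


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis)
    return m + np.log(np.sum(np.exp(a - np.expand_dims(m, axis)), axis=axis))
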