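"""Nested sampling for Bayesian calibration.

A self-contained static nested sampler with likelihood-bounded random-walk
replacement (the strategy MultiNest popularized, in its MCMC flavour):
live points contract the prior volume by a factor e^(-1/n_live) per
iteration, each discarded point is replaced by a constrained random walk
started from a surviving live point, and the evidence is accumulated with
the standard trapezoidal weights.  The sampler works on the unit hypercube;
a ``prior_transform`` maps cube coordinates to parameter values.

The interface is deliberately small (prior transform + log-likelihood in,
weighted samples + evidence out) so a different backend could be plugged in
behind it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import logsumexp

__all__ = ["NestedResult", "run_nested_sampling", "weighted_quantile"]


@dataclass
class NestedResult:
    """Weighted posterior samples and evidence from one nested run."""

    samples: np.ndarray      # (n, ndim) parameter values
    log_weights: np.ndarray  # (n,) unnormalized ln(L_i * dX_i)
    log_likes: np.ndarray    # (n,)
    logz: float
    logzerr: float
    n_calls: int
    n_iter: int

    @property
    def weights(self) -> np.ndarray:
        """Normalized importance weights."""
        w = np.exp(self.log_weights - logsumexp(self.log_weights))
        return w / w.sum()

    def quantiles(self, probs=(0.05, 0.5, 0.95)) -> np.ndarray:
        """(len(probs), ndim) weighted posterior quantiles."""
        return np.stack([
            weighted_quantile(self.samples[:, j], probs, self.weights)
            for j in range(self.samples.shape[1])
        ], axis=1)

    def mean(self) -> np.ndarray:
        return self.weights @ self.samples

    def resample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(self.samples.shape[0], size=n, p=self.weights)
        return self.samples[idx]


def weighted_quantile(x, probs, weights) -> np.ndarray:
    """Weighted quantiles with the midpoint plotting-position convention
    (equal weights on {1..100} give a median of 50.5)."""
    x = np.asarray(x, dtype=float)
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    w = np.asarray(weights, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    order = np.argsort(x)
    xs = x[order]
    ws = w[order] / w.sum()
    pos = np.cumsum(ws) - 0.5 * ws
    q = np.interp(probs, pos, xs, left=xs[0], right=xs[-1])
    return q if q.size > 1 else q


def run_nested_sampling(loglike: Callable[[np.ndarray], float],
                        prior_transform: Callable[[np.ndarray], np.ndarray],
                        ndim: int,
                        n_live: int = 500,
                        seed: int = 0,
                        dlogz: float = 0.01,
                        walk_steps: int = 20,
                        max_iter: int = 200000) -> NestedResult:
    """Run nested sampling and return weighted samples plus evidence.

    ``loglike`` receives parameter values (after ``prior_transform``) and
    may return -inf for failed forward runs, which the sampler treats as
    excluded regions.  Deterministic for a fixed seed.
    """
    if n_live < 2 * ndim:
        raise ValueError("n_live must be at least twice the dimension")
    rng = np.random.default_rng(seed)
    n_calls = 0

    u_live = rng.uniform(size=(n_live, ndim))
    v_live = np.array([prior_transform(u) for u in u_live])
    logl_live = np.empty(n_live)
    for i in range(n_live):
        logl_live[i] = loglike(v_live[i])
        n_calls += 1
    # re-draw any pathological starting points
    for i in range(n_live):
        tries = 0
        while not np.isfinite(logl_live[i]):
            u_live[i] = rng.uniform(size=ndim)
            v_live[i] = prior_transform(u_live[i])
            logl_live[i] = loglike(v_live[i])
            n_calls += 1
            tries += 1
            if tries > 200:
                raise RuntimeError("cannot find finite likelihood in the "
                                   "prior volume")

    dead_v: list[np.ndarray] = []
    dead_logl: list[float] = []
    dead_logwt: list[float] = []

    logz = -np.inf
    log_shrink = -1.0 / n_live
    log_width0 = np.log1p(-np.exp(log_shrink))  # ln(1 - e^{-1/n})
    step_fac = 1.0

    it = 0
    while it < max_iter:
        it += 1
        worst = int(np.argmin(logl_live))
        logl_star = logl_live[worst]
        logx_prev = log_shrink * (it - 1)
        logwt = logl_star + log_width0 + logx_prev
        dead_v.append(v_live[worst].copy())
        dead_logl.append(float(logl_star))
        dead_logwt.append(float(logwt))
        logz = np.logaddexp(logz, logwt)

        # replacement: constrained random walk from a random live point
        scale = np.std(u_live, axis=0)
        scale = np.maximum(scale, 1e-7) * 2.38 / np.sqrt(ndim)
        start = worst
        while start == worst and n_live > 1:
            start = int(rng.integers(n_live))
        u = u_live[start].copy()
        lu = logl_live[start]
        n_acc = 0
        for _ in range(walk_steps):
            prop = u + step_fac * scale * rng.standard_normal(ndim)
            # reflect into the unit cube
            prop = np.where(prop < 0.0, -prop, prop)
            prop = np.where(prop > 1.0, 2.0 - prop, prop)
            prop = np.clip(prop, 0.0, 1.0)
            lp = loglike(prior_transform(prop))
            n_calls += 1
            if lp > logl_star:
                u = prop
                lu = lp
                n_acc += 1
        step_fac *= np.exp((n_acc / walk_steps - 0.5) * 0.3)
        step_fac = min(max(step_fac, 1e-3), 10.0)
        u_live[worst] = u
        v_live[worst] = prior_transform(u)
        logl_live[worst] = lu

        # stop when the live points cannot move the evidence by > dlogz
        logz_remain = np.max(logl_live) + log_shrink * it
        if np.logaddexp(logz, logz_remain) - logz < dlogz:
            break

    # distribute the final prior volume over the remaining live points
    logx_final = log_shrink * it
    lw_live = logx_final - np.log(n_live)
    order = np.argsort(logl_live)
    for i in order:
        logwt = logl_live[i] + lw_live
        dead_v.append(v_live[i].copy())
        dead_logl.append(float(logl_live[i]))
        dead_logwt.append(float(logwt))
        logz = np.logaddexp(logz, logwt)

    samples = np.array(dead_v)
    log_weights = np.array(dead_logwt)
    log_likes = np.array(dead_logl)
    wn = np.exp(log_weights - logsumexp(log_weights))
    h = float(np.sum(wn * (log_likes - logz)))
    logzerr = float(np.sqrt(max(h, 0.0) / n_live))
    return NestedResult(samples=samples, log_weights=log_weights,
                        log_likes=log_likes, logz=float(logz),
                        logzerr=logzerr, n_calls=n_calls, n_iter=it)
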