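"""Bayesian calibration of the soil-plant model.

The likelihood assumes uncorrelated Gaussian residuals with a constant,
known variance per observation set (the variance comes from the column
replicates, it is not inferred):

    l_j = -(k/2) ln(2 pi sigma_j^2) - sum_i (H_i - ybar_i)^2 / (2 sigma_j^2)

and the total log-likelihood is the sum over all sets.  Priors are uniform
over the parameter bounds; sampling is nested sampling (see
:mod:`soilplant.nested`), which yields weighted posterior samples, the
evidence, posterior quantiles and predictive-check ensembles.

Besides the full 15-parameter problem this module provides the two reduced
forward models used in recovery experiments: a flow-only model (the four
VGM shape parameters against water-content/pressure-head series) and a
plant-only model (six plant parameters against tissue concentrations, with
the soil solution fixed from a reference run).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .forward import ForwardResult, run_forward
from .grid import make_grid
from .hydro import Forcing, TimeStepControl, solve_richards
from .nested import NestedResult, run_nested_sampling, weighted_quantile
from .params import (FREE_PARAMETER_NAMES, Scenario, free_parameter_bounds,
                     median_free_parameters, scenario_from_vector)
from .plant import simulate_plant

__all__ = [
    "ObservationSet",
    "ParameterSpace",
    "log_likelihood_set",
    "total_log_likelihood",
    "run_nested_sampling",
    "posterior_quantiles",
    "posterior_predictive",
    "sampler_convergence",
    "FlowForwardModel",
    "PlantForwardModel",
    "CoupledForwardModel",
]


@dataclass
class ObservationSet:
    """One measurement series: times [day], replicate means, and the
    replicate-derived noise standard deviation (one sigma per set).
    ``extractor`` names the forward-model output the set is compared to
    (defaults to the label)."""

    label: str
    times: np.ndarray
    values: np.ndarray
    sigma: float
    extractor: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.size < 1:
            raise ValueError("times and values must be equal-length, "
                             "nonempty")
        if self.sigma <= 0.0:
            raise ValueError("sigma must be positive")
        if not self.extractor:
            self.extractor = self.label

    @property
    def k(self) -> int:
        return self.times.size


@dataclass
class ParameterSpace:
    """Ordered free parameters with uniform prior bounds."""

    names: tuple[str, ...]
    bounds: np.ndarray  # (ndim, 2)

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.bounds.shape != (len(self.names), 2):
            raise ValueError("bounds must be (ndim, 2)")
        if not np.all(np.isfinite(self.bounds)):
            raise ValueError("bounds must be finite")
        if np.any(self.bounds[:, 0] >= self.bounds[:, 1]):
            raise ValueError("lower bounds must be below upper bounds")

    @classmethod
    def subset(cls, names: Sequence[str]) -> "ParameterSpace":
        all_bounds = free_parameter_bounds()
        return cls(tuple(names),
                   np.array([all_bounds[nm] for nm in names]))

    @classmethod
    def full(cls) -> "ParameterSpace":
        return cls.subset(FREE_PARAMETER_NAMES)

    @property
    def ndim(self) -> int:
        return len(self.names)

    def prior_transform(self, u: np.ndarray) -> np.ndarray:
        """Map the unit hypercube to parameter values (bijective)."""
        return self.bounds[:, 0] + u * (self.bounds[:, 1] - self.bounds[:, 0])

    def contains(self, theta: np.ndarray) -> bool:
        return bool(np.all(theta >= self.bounds[:, 0])
                    and np.all(theta <= self.bounds[:, 1]))


def log_likelihood_set(model_series: np.ndarray,
                       obs: ObservationSet) -> float:
    """Gaussian log-likelihood of one observation set given the model
    series aligned to its times."""
    model_series = np.asarray(model_series, dtype=float)
    if model_series.shape != obs.values.shape:
        raise ValueError("model series misaligned with observations")
    res = model_series - obs.values
    s2 = obs.sigma ** 2
    return float(-0.5 * obs.k * np.log(2.0 * np.pi * s2)
                 - np.sum(res ** 2) / (2.0 * s2))


def total_log_likelihood(theta: np.ndarray,
                         data: Sequence[ObservationSet],
                         forward: Callable[[np.ndarray], object]) -> float:
    """Aggregated log-likelihood: one forward run, summed over all sets.
    Forward-model failures map to -inf (rejected sample)."""
    try:
        result = forward(np.asarray(theta, dtype=float))
    except (RuntimeError, ValueError, FloatingPointError):
        return -np.inf
    total = 0.0
    for obs in data:
        series = result.sample(obs.extractor, obs.times)
        if not np.all(np.isfinite(series)):
            return -np.inf
        total += log_likelihood_set(series, obs)
    return total


def posterior_quantiles(result: NestedResult,
                        probs: Sequence[float] = (0.05, 0.5, 0.95)
                        ) -> np.ndarray:
    """Weighted posterior quantiles, shape (len(probs), ndim)."""
    if result.samples.size == 0:
        raise ValueError("empty posterior")
    return result.quantiles(tuple(probs))


def posterior_predictive(result: NestedResult,
                         forward: Callable[[np.ndarray], object],
                         labels: Sequence[str],
                         times: dict[str, np.ndarray],
                         n_draws: int = 100,
                         seed: int = 0) -> dict:
    """Ensemble of forward trajectories from posterior draws.

    Returns per-label arrays of shape (n_ok, len(times[label])), the 5/50/95
    percent envelope, the trajectory of the posterior-median parameter
    vector, and the count of failed draws (skipped)."""
    rng = np.random.default_rng(seed)
    draws = result.resample(n_draws, rng)
    ensembles = {lab: [] for lab in labels}
    n_failed = 0
    for theta in draws:
        try:
            res = forward(theta)
        except (RuntimeError, ValueError, FloatingPointError):
            n_failed += 1
            continue
        for lab in labels:
            ensembles[lab].append(res.sample(lab, times[lab]))
    med_theta = result.quantiles((0.5,))[0]
    med_res = forward(med_theta)
    out = {"n_failed": n_failed, "median_theta": med_theta,
           "trajectories": {}, "envelope": {}, "median_solution": {}}
    for lab in labels:
        arr = np.array(ensembles[lab])
        out["trajectories"][lab] = arr
        out["envelope"][lab] = np.percentile(arr, [5.0, 50.0, 95.0], axis=0)
        out["median_solution"][lab] = med_res.sample(lab, times[lab])
    return out


def sampler_convergence(space: ParameterSpace,
                        loglike: Callable[[np.ndarray], float],
                        n_live_grid: Sequence[int],
                        seeds: Sequence[int],
                        dlogz: float = 0.01,
                        walk_steps: int = 20,
                        quantile_tol: float = 0.1,
                        logz_tol: float = 0.5) -> dict:
    """Stability of evidence and posterior medians across sampler
    settings; ``flag`` is raised when the drift between the two largest
    n_live settings exceeds the tolerances (relative to the prior width
    for quantiles, absolute nats for the evidence)."""
    if len(n_live_grid) < 2 and len(seeds) < 2:
        raise ValueError("need at least two settings")
    runs = []
    for n_live in n_live_grid:
        for seed in seeds:
            r = run_nested_sampling(loglike, space.prior_transform,
                                    space.ndim, n_live=n_live, seed=seed,
                                    dlogz=dlogz, walk_steps=walk_steps)
            runs.append({
                "n_live": n_live, "seed": seed, "logz": r.logz,
                "logzerr": r.logzerr,
                "median": r.quantiles((0.5,))[0],
            })
    logzs = np.array([r["logz"] for r in runs])
    medians = np.array([r["median"] for r in runs])
    width = space.bounds[:, 1] - space.bounds[:, 0]
    logz_drift = float(logzs.max() - logzs.min())
    med_drift = float(np.max(np.abs(medians.max(axis=0)
                                    - medians.min(axis=0)) / width)) \
        if len(runs) > 1 else 0.0
    return {
        "runs": runs,
        "logz_drift": logz_drift,
        "median_drift_rel": med_drift,
        "flag": logz_drift > logz_tol or med_drift > quantile_tol,
    }


# ---------------------------------------------------------------------------
# Forward-model wrappers for calibration
# ---------------------------------------------------------------------------

class _SeriesResult:
    """Minimal forward-result view: label -> (t, values), with linear
    interpolation at observation times."""

    def __init__(self, series: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._series = series

    def series(self, label: str):
        return self._series[label]

    def sample(self, label: str, times: np.ndarray) -> np.ndarray:
        t, v = self._series[label]
        return np.interp(times, t, v)


@dataclass
class CoupledForwardModel:
    """theta (over ``space.names``) -> full soil-plant forward run."""

    space: ParameterSpace
    forcing: Forcing
    n_elements: int = 100
    dt_control: TimeStepControl | None = None
    base: dict[str, float] = field(default_factory=dict)

    def __call__(self, theta: np.ndarray) -> ForwardResult:
        scenario = scenario_from_vector(theta, self.space.names, self.base)
        return run_forward(scenario, self.forcing,
                           n_elements=self.n_elements,
                           dt_control=self.dt_control)


@dataclass
class FlowForwardModel:
    """theta -> water-flow-only forward run exposing the theta/h sensor
    series; used for the VGM-parameter recovery experiment."""

    space: ParameterSpace
    forcing: Forcing
    n_elements: int = 20
    # calibration solver settings: coarse output, mixed tolerance, and a
    # step budget so pathological parameter corners fail fast (-> -inf
    # likelihood) instead of stalling the sampler
    dt_control: TimeStepControl = field(default_factory=lambda:
                                        TimeStepControl(dt_out=1.0,
                                                        tol=1e-3,
                                                        rel_tol=3e-4,
                                                        dt_max=0.25,
                                                        dt_init=0.01,
                                                        dt_min=1e-5,
                                                        max_iter=12,
                                                        max_steps=25_000))
    base: dict[str, float] = field(default_factory=dict)
    theta_depths: tuple[float, ...] = (2.5, 15.0)
    head_depths: tuple[float, ...] = (5.0, 15.0)

    def __post_init__(self) -> None:
        scen = scenario_from_vector(
            np.array([median_free_parameters()[nm]
                      for nm in self.space.names]),
            self.space.names, self.base)
        self._grid = make_grid(scen.horizons, n_elements=self.n_elements)

    def __call__(self, theta: np.ndarray) -> _SeriesResult:
        scenario = scenario_from_vector(theta, self.space.names, self.base)
        flow = solve_richards(self._grid, scenario.horizons, self.forcing,
                              scenario.feddes, scenario.roots,
                              scenario.theta_init,
                              (0.0, scenario.t_end), self.dt_control)
        series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for d in self.theta_depths:
            label = f"theta_{d:g}"
            series[label] = (flow.t, flow.theta_at(d))
        for d in self.head_depths:
            series[f"h_{d:g}"] = (flow.t, flow.head_at(d))
        return _SeriesResult(series)


@dataclass
class PlantForwardModel:
    """theta (plant parameters) -> tissue-concentration series, with the
    soil solution and transpiration stream frozen from a reference run."""

    space: ParameterSpace
    uptake_t: np.ndarray
    uptake_rate: dict[str, np.ndarray]  # mol day^-1 (whole column)
    q_total: np.ndarray                 # cm^3 day^-1
    t_out: np.ndarray
    base: dict[str, float] = field(default_factory=dict)
    plant_dt: float = 0.05

    def __call__(self, theta: np.ndarray) -> _SeriesResult:
        scenario = scenario_from_vector(theta, self.space.names, self.base)
        ps = simulate_plant(self.uptake_t, self.uptake_rate, self.q_total,
                            scenario.compartments, scenario.species,
                            t_out=self.t_out, dt=self.plant_dt)
        series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for comp in ("roots", "stem", "leaves", "fruits"):
            for sp in scenario.species:
                series[f"{comp}_{sp.name}"] = \
                    (ps.t, ps.concentration(sp.name, comp))
        return _SeriesResult(series)
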