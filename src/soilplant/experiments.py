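"""Self-contained synthetic recovery experiments.

Each experiment generates its own data from the reference scenario at the
calibrated median parameter values (the generating truths), adds
replicate-level noise, runs nested-sampling calibration of a reduced
parameter set, and reports posterior quantiles next to the truths.

Two experiments are provided:

* plant-only - the soil solution and transpiration stream are frozen from
  a median forward run; the six identifiable plant parameters (root and
  stem partition coefficients and transformation rates, plus the leaves
  pair) are calibrated against noisy tissue concentrations at the
  destructive sampling days.
* flow-only - the four van Genuchten-Mualem shape parameters are
  calibrated against daily water-content and pressure-head series from
  the two sensor pairs.

A single integer seed drives every random element (weather noise in the
forcing, observation noise, the sampler).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .calibrate import (FlowForwardModel, ObservationSet, ParameterSpace,
                        PlantForwardModel, total_log_likelihood)
from .forward import run_forward
from .nested import NestedResult, run_nested_sampling
from .params import COLUMN_AREA_CM2, median_free_parameters
from .synth import ExperimentTemplate, generate_forcing

__all__ = ["RecoveryReport", "plant_recovery_experiment",
           "flow_recovery_experiment"]

PLANT_PARAMETERS = ("K_RW", "tau_R", "K_SW", "tau_S", "K_LW", "tau_L")
FLOW_PARAMETERS = ("alpha1", "n1", "alpha2", "n2")
TISSUE_SAMPLING_DAYS = (23.0, 30.0, 41.0, 48.0)


def _subseed(seed: int, stage: str) -> int:
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RecoveryReport:
    names: tuple[str, ...]
    truths: np.ndarray
    quantiles: np.ndarray  # (3, ndim): 5/50/95%
    result: NestedResult

    @property
    def medians(self) -> np.ndarray:
        return self.quantiles[1]

    def median_of(self, name: str) -> float:
        return float(self.medians[self.names.index(name)])

    def relative_errors(self) -> np.ndarray:
        return (self.medians - self.truths) / self.truths

    def ci_covers_truth(self) -> np.ndarray:
        return ((self.quantiles[0] <= self.truths)
                & (self.truths <= self.quantiles[2]))


def plant_recovery_experiment(seed: int = 1,
                              n_live: int = 300,
                              walk_steps: int = 16,
                              dlogz: float = 0.05,
                              noise_cv: float = 0.15,
                              n_elements: int = 50) -> RecoveryReport:
    """Recover the plant parameters from synthetic tissue concentrations.

    CBZ and EPX tissue observations in all four compartments at the
    sampling days, with ``noise_cv`` relative noise (one sigma per set,
    from the series' RMS magnitude).  Soil is fixed: the uptake and
    transpiration series come from the median forward run.
    """
    from . import default_scenario  # local import avoids a cycle at init

    scenario = default_scenario()
    forcing = generate_forcing(ExperimentTemplate(),
                               seed=_subseed(seed, "forcing"),
                               scenario=scenario)
    ref = run_forward(scenario, forcing, n_elements=n_elements)
    uptake = {nm: r * COLUMN_AREA_CM2
              for nm, r in ref.solute.uptake_rate.items()}
    q_total = ref.flow.Ta * COLUMN_AREA_CM2

    space = ParameterSpace.subset(PLANT_PARAMETERS)
    fwd = PlantForwardModel(space, ref.flow.t, uptake, q_total,
                            t_out=ref.flow.t)
    truths = np.array([median_free_parameters()[nm]
                       for nm in PLANT_PARAMETERS])
    clean_model = fwd(truths)

    rng = np.random.default_rng(_subseed(seed, "noise"))
    days = np.array(TISSUE_SAMPLING_DAYS)
    data = []
    for comp in ("roots", "stem", "leaves", "fruits"):
        for sp_name in ("CBZ", "EPX"):
            label = f"{comp}_{sp_name}"
            clean = clean_model.sample(label, days)
            sigma = max(noise_cv * float(np.sqrt(np.mean(clean ** 2))),
                        1e-12)
            data.append(ObservationSet(
                label, days, clean + rng.normal(0.0, sigma, days.size),
                sigma))

    def loglike(theta):
        return total_log_likelihood(theta, data, fwd)

    result = run_nested_sampling(loglike, space.prior_transform,
                                 space.ndim, n_live=n_live,
                                 seed=_subseed(seed, "sampler"),
                                 dlogz=dlogz, walk_steps=walk_steps)
    return RecoveryReport(PLANT_PARAMETERS, truths,
                          result.quantiles((0.05, 0.5, 0.95)), result)


def flow_recovery_experiment(seed: int = 1,
                             n_live: int = 80,
                             walk_steps: int = 10,
                             dlogz: float = 0.1,
                             theta_sd: float = 0.01,
                             head_cv: float = 0.10,
                             n_elements: int = 20) -> RecoveryReport:
    """Recover the VGM shape parameters from synthetic sensor series.

    Daily water content at 2.5/15 cm depth (absolute noise ``theta_sd``)
    and pressure head at 5/15 cm (relative noise ``head_cv``), generated
    by the same coarse-grid forward model used in the calibration.
    """
    from . import default_scenario

    scenario = default_scenario()
    forcing = generate_forcing(ExperimentTemplate(),
                               seed=_subseed(seed, "forcing"),
                               scenario=scenario)
    space = ParameterSpace.subset(FLOW_PARAMETERS)
    fwd = FlowForwardModel(space, forcing, n_elements=n_elements)
    truths = np.array([median_free_parameters()[nm]
                       for nm in FLOW_PARAMETERS])
    clean_model = fwd(truths)

    rng = np.random.default_rng(_subseed(seed, "noise"))
    days = np.arange(1.0, 49.0)
    data = []
    for label in ("theta_2.5", "theta_15"):
        clean = clean_model.sample(label, days)
        data.append(ObservationSet(
            label, days, clean + rng.normal(0.0, theta_sd, days.size),
            theta_sd))
    for label in ("h_5", "h_15"):
        clean = clean_model.sample(label, days)
        sigma = head_cv * float(np.sqrt(np.mean(clean ** 2)))
        data.append(ObservationSet(
            label, days, clean + rng.normal(0.0, sigma, days.size),
            sigma))

    def loglike(theta):
        return total_log_likelihood(theta, data, fwd)

    result = run_nested_sampling(loglike, space.prior_transform,
                                 space.ndim, n_live=n_live,
                                 seed=_subseed(seed, "sampler"),
                                 dlogz=dlogz, walk_steps=walk_steps)
    return RecoveryReport(FLOW_PARAMETERS, truths,
                          result.quantiles((0.05, 0.5, 0.95)), result)
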