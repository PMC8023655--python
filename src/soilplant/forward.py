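"""One-way coupled forward model: water flow -> solute transport -> plant.

A single forward run solves the Richards equation for the column, transports
CBZ/EPX through the soil on the resulting flow field, and feeds the root
uptake and transpiration series to the plant compartment cascade.  The
result object exposes the 14 observable series used in calibration: water
content at the two sensor depths, pressure head at the two tensiometer
depths, whole-soil CBZ and EPX concentration in the sampled top layer, and
tissue CBZ and EPX concentrations in the four plant compartments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import make_grid
from .hydro import Forcing, SoilWaterState, TimeStepControl, solve_richards
from .params import COLUMN_AREA_CM2, Scenario
from .plant import PlantState, simulate_plant
from .solute import SoluteState, solve_transport

__all__ = ["ForwardResult", "run_forward", "OBSERVABLE_LABELS",
           "SOIL_SAMPLE_DEPTH_CM"]

#: Depth of the sampled surface soil layer whose average concentration is
#: reported (the 0 to -5 cm layer).
SOIL_SAMPLE_DEPTH_CM = 5.0

OBSERVABLE_LABELS = (
    "theta_2.5", "theta_15", "h_5", "h_15",
    "soil_CBZ", "soil_EPX",
    "roots_CBZ", "stem_CBZ", "leaves_CBZ", "fruits_CBZ",
    "roots_EPX", "stem_EPX", "leaves_EPX", "fruits_EPX",
)


@dataclass
class ForwardResult:
    scenario: Scenario
    forcing: Forcing
    flow: SoilWaterState
    solute: SoluteState
    plant: PlantState

    def series(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """(time, values) of one observable series."""
        if label.startswith("theta_"):
            depth = float(label.split("_")[1])
            return self.flow.t, self.flow.theta_at(depth)
        if label.startswith("h_"):
            depth = float(label.split("_")[1])
            return self.flow.t, self.flow.head_at(depth)
        if label.startswith("soil_"):
            nm = label.split("_")[1]
            sp = self.scenario.species_by_name(nm)
            prof = self.solute.total_ng_per_g(
                nm, self.flow.theta, sp.molar_mass,
                self.scenario.medium.bulk_density)
            w = self.flow.grid.w_cv.copy()
            w[self.flow.grid.z < -SOIL_SAMPLE_DEPTH_CM] = 0.0
            return self.flow.t, prof @ w / w.sum()
        comp, nm = label.rsplit("_", 1)
        return self.plant.t, self.plant.concentration(nm, comp)

    def sample(self, label: str, times: np.ndarray) -> np.ndarray:
        t, v = self.series(label)
        return np.interp(times, t, v)


def run_forward(scenario: Scenario, forcing: Forcing,
                n_elements: int = 100,
                dt_control: TimeStepControl | None = None,
                plant_dt: float = 0.02) -> ForwardResult:
    """Run the full soil-plant chain for one scenario and forcing."""
    grid = make_grid(scenario.horizons, n_elements=n_elements)
    flow = solve_richards(grid, scenario.horizons, forcing, scenario.feddes,
                          scenario.roots, scenario.theta_init,
                          (0.0, scenario.t_end), dt_control)
    sol = solve_transport(flow, scenario.species, scenario.medium, forcing)
    uptake = {nm: rate * COLUMN_AREA_CM2
              for nm, rate in sol.uptake_rate.items()}
    q_total = flow.Ta * COLUMN_AREA_CM2
    plant = simulate_plant(flow.t, uptake, q_total,
                           scenario.compartments, scenario.species,
                           t_out=flow.t, dt=plant_dt)
    return ForwardResult(scenario=scenario, forcing=forcing, flow=flow,
                         solute=sol, plant=plant)
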