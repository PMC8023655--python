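"""Domain parameter types for the coupled soil-plant uptake model.

The model simulates translocation of carbamazepine (CBZ) and its epoxide
metabolite (EPX) from irrigated soil into green pea tissues.  Parameters are
grouped the way the physics is: soil hydraulics per horizon (van
Genuchten-Mualem), root water stress (Feddes), chemical properties per solute
species (Freundlich sorption, sequential first-order decay, capped passive
root uptake), and per-tissue plant compartment parameters (logistic growth,
tissue-water partitioning, in-plant metabolization).

``median_free_parameters`` / ``free_parameter_bounds`` expose the 15-parameter
calibration space; everything else is fixed from laboratory experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "SoilHorizon",
    "FeddesParams",
    "RootDistribution",
    "SoluteSpecies",
    "TransportMedium",
    "PlantCompartment",
    "Scenario",
    "COLUMN_HEIGHT_CM",
    "COLUMN_DIAMETER_CM",
    "COLUMN_AREA_CM2",
    "FREE_PARAMETER_NAMES",
    "free_parameter_bounds",
    "median_free_parameters",
    "default_scenario",
]

#: Soil column geometry of the greenhouse experiment.
COLUMN_HEIGHT_CM = 20.0
COLUMN_DIAMETER_CM = 15.4
COLUMN_AREA_CM2 = math.pi * (COLUMN_DIAMETER_CM / 2.0) ** 2

#: Beer-law canopy light-extinction coefficient used to split ET demand
#: into potential evaporation and transpiration from the leaf area index.
CANOPY_EXTINCTION = 0.463


@dataclass(frozen=True)
class SoilHorizon:
    """Van Genuchten-Mualem hydraulic parameter set for one soil layer.

    Units: water contents in cm^3 cm^-3, ``alpha`` in cm^-1, ``Ks`` in
    cm day^-1, horizon extent ``z_top``/``z_bot`` in cm (negative downward,
    ``z_top > z_bot``).
    """

    theta_r: float
    theta_s: float
    alpha: float
    n: float
    Ks: float
    z_top: float
    z_bot: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_r < self.theta_s <= 1.0:
            raise ValueError("require 0 <= theta_r < theta_s <= 1")
        if self.alpha <= 0.0:
            raise ValueError("alpha must be positive")
        if self.n <= 1.0:
            raise ValueError("n must exceed 1")
        if self.Ks <= 0.0:
            raise ValueError("Ks must be positive")
        if self.z_top <= self.z_bot:
            raise ValueError("z_top must lie above z_bot")

    @property
    def m(self) -> float:
        return 1.0 - 1.0 / self.n


@dataclass(frozen=True)
class FeddesParams:
    """Pressure-head thresholds (cm) of the piecewise-linear root water
    stress function, plus the two potential-transpiration rates
    (cm day^-1) between which the P2 threshold is interpolated."""

    P0: float = -15.0
    POpt: float = -30.0
    P2H: float = -300.0
    P2L: float = -500.0
    P3: float = -8000.0
    r2H: float = 0.5
    r2L: float = 0.1

    def __post_init__(self) -> None:
        if not (self.P0 > self.POpt > self.P2H >= self.P2L > self.P3):
            raise ValueError("require P0 > POpt > P2H >= P2L > P3")
        if self.r2H <= self.r2L:
            raise ValueError("require r2H > r2L")


@dataclass(frozen=True)
class RootDistribution:
    """Logistic-in-time rooted depth with linearly decreasing density
    toward the rooting front.

    ``growth_rate`` [day^-1] is the logistic rate fitted to root masses;
    ``depth0``/``depth_max`` [cm] are the initial and asymptotic rooted
    depths (positive numbers, measured downward from the surface).
    """

    growth_rate: float = 0.2
    depth0: float = 2.0
    depth_max: float = 20.0

    def rooted_depth(self, t: float) -> float:
        """Rooted depth [cm] at time ``t`` [day]."""
        e = math.exp(self.growth_rate * t)
        return (self.depth_max * self.depth0 * e
                / (self.depth_max + self.depth0 * (e - 1.0)))


@dataclass(frozen=True)
class SoluteSpecies:
    """Chemical parameters for one solute.

    ``Kf`` [cm^3b ug^(1-b) g^-1] and ``beta`` parameterize the Freundlich
    isotherm in mass units (ug, cm^3, g); ``mu_L``/``mu_S`` [day^-1] are
    first-order transformation rates in liquid/solid phase; ``Cmax``
    [g cm^-3] caps the solution concentration available to passive root
    uptake.  ``daughter`` names the transformation product, if any.
    """

    name: str
    molar_mass: float
    Kf: float
    beta: float
    mu_L: float
    mu_S: float
    Cmax: float
    daughter: str | None = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0.0:
            raise ValueError("molar_mass must be positive")
        if self.Kf < 0.0 or not 0.0 < self.beta <= 1.0:
            raise ValueError("require Kf >= 0 and 0 < beta <= 1")
        if self.mu_L < 0.0 or self.mu_S < 0.0 or self.Cmax < 0.0:
            raise ValueError("rates and Cmax must be nonnegative")

    @property
    def cmax_molar(self) -> float:
        """Uptake cap converted to mol cm^-3."""
        return self.Cmax / self.molar_mass


@dataclass(frozen=True)
class TransportMedium:
    """Bulk density [g cm^-3] and longitudinal dispersivity [cm]."""

    bulk_density: float = 1.1
    dispersivity: float = 1.0

    def __post_init__(self) -> None:
        if self.bulk_density <= 0.0 or self.dispersivity < 0.0:
            raise ValueError("require bulk_density > 0, dispersivity >= 0")


@dataclass(frozen=True)
class PlantCompartment:
    """Growth, partitioning and metabolization parameters for one tissue.

    ``W`` [cm^3 g_fw^-1] tissue water content (metadata, used for fresh/dry
    conversions); ``K_PW`` [cm^3 g_fw^-1] tissue-water partition
    coefficient; ``M0``/``Mmax`` [g_fw] logistic mass extremes; ``Kgr``
    [day^-1] logistic growth rate; ``tau`` [day^-1] first-order CBZ->EPX
    transformation rate; ``S_A`` [cm^2 g_fw^-1] specific area (leaves and
    fruits only, used to split the transpiration stream); ``onset`` [day]
    the day the compartment appears (fruits only; 0 otherwise).
    """

    name: str
    W: float
    K_PW: float
    M0: float
    Mmax: float
    Kgr: float
    tau: float
    S_A: float = 0.0
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in ("roots", "stem", "leaves", "fruits"):
            raise ValueError("unknown compartment name")
        if self.K_PW <= 0.0 or self.tau < 0.0:
            raise ValueError("require K_PW > 0 and tau >= 0")
        if self.Mmax <= 0.0 or self.M0 < 0.0 or self.M0 > self.Mmax:
            raise ValueError("require 0 <= M0 <= Mmax")


@dataclass
class Scenario:
    """Full configuration of one greenhouse-column simulation."""

    horizons: tuple[SoilHorizon, SoilHorizon]
    feddes: FeddesParams
    roots: RootDistribution
    medium: TransportMedium
    species: tuple[SoluteSpecies, SoluteSpecies]
    compartments: dict[str, PlantCompartment]
    theta_init: float = 0.24
    t_end: float = 48.0

    def species_by_name(self, name: str) -> SoluteSpecies:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Calibrated parameter space: 15 free parameters with uniform prior bounds;
# the values below are the posterior medians used as the reference scenario
# and as generating truths in recovery experiments.
# ---------------------------------------------------------------------------

FREE_PARAMETER_NAMES: tuple[str, ...] = (
    "alpha1", "n1", "alpha2", "n2",
    "Kf_CBZ", "Cmax_CBZ", "Cmax_EPX",
    "K_RW", "tau_R", "K_SW", "tau_S",
    "K_LW", "tau_L", "K_FW", "tau_F",
)

_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha1": (0.001, 0.1),
    "n1": (1.1, 3.0),
    "alpha2": (0.001, 0.1),
    "n2": (1.1, 3.0),
    "Kf_CBZ": (1.1, 10.0),
    "Cmax_CBZ": (1e-9, 1e-8),
    "Cmax_EPX": (0.0, 1e-8),
    "K_RW": (1.0, 30.0),
    "tau_R": (0.0, 0.55),
    "K_SW": (1.0, 30.0),
    "tau_S": (0.0, 0.55),
    "K_LW": (1.0, 30.0),
    "tau_L": (0.0, 0.55),
    "K_FW": (1.0, 30.0),
    "tau_F": (0.0, 0.55),
}

_MEDIANS: dict[str, float] = {
    "alpha1": 0.013, "n1": 2.07, "alpha2": 0.022, "n2": 2.45,
    "Kf_CBZ": 2.44, "Cmax_CBZ": 4.05e-9, "Cmax_EPX": 8.0e-11,
    "K_RW": 13.3, "tau_R": 0.01, "K_SW": 11.8, "tau_S": 0.05,
    "K_LW": 15.2, "tau_L": 0.44, "K_FW": 15.2, "tau_F": 0.02,
}

MOLAR_MASS_CBZ = 236.27
MOLAR_MASS_EPX = 252.28
FREUNDLICH_BETA = 0.89
MU_CBZ = 0.0068  # day^-1, both phases
FRUIT_ONSET_DAY = 25.0
FRUIT_ONSET_MASS = 1e-3  # g_fw seed mass replacing M0 = 0 at onset


def free_parameter_bounds() -> dict[str, tuple[float, float]]:
    """Uniform prior bounds of the 15 calibrated parameters."""
    return dict(_BOUNDS)


def median_free_parameters() -> dict[str, float]:
    """Posterior-median values of the 15 calibrated parameters."""
    return dict(_MEDIANS)


def default_scenario(overrides: dict[str, float] | None = None) -> Scenario:
    """Reference scenario: fixed laboratory parameters plus the calibrated
    medians, optionally overriding any of the 15 free parameters."""
    p = median_free_parameters()
    if overrides:
        unknown = set(overrides) - set(p)
        if unknown:
            raise KeyError(f"unknown free parameters: {sorted(unknown)}")
        p.update(overrides)

    horizons = (
        SoilHorizon(theta_r=0.18, theta_s=0.51, alpha=p["alpha1"], n=p["n1"],
                    Ks=70.0, z_top=0.0, z_bot=-10.0),
        SoilHorizon(theta_r=0.18, theta_s=0.51, alpha=p["alpha2"], n=p["n2"],
                    Ks=70.0, z_top=-10.0, z_bot=-COLUMN_HEIGHT_CM),
    )
    species = (
        SoluteSpecies("CBZ", MOLAR_MASS_CBZ, p["Kf_CBZ"], FREUNDLICH_BETA,
                      MU_CBZ, MU_CBZ, p["Cmax_CBZ"], daughter="EPX"),
        # EPX shares CBZ's sorption parameters; its further degradation in
        # soil is neglected.
        SoluteSpecies("EPX", MOLAR_MASS_EPX, p["Kf_CBZ"], FREUNDLICH_BETA,
                      0.0, 0.0, p["Cmax_EPX"], daughter=None),
    )
    compartments = {
        "roots": PlantCompartment("roots", W=0.88, K_PW=p["K_RW"], M0=15.0,
                                  Mmax=308.0, Kgr=0.2, tau=p["tau_R"]),
        "stem": PlantCompartment("stem", W=0.84, K_PW=p["K_SW"], M0=10.0,
                                 Mmax=591.0, Kgr=0.14, tau=p["tau_S"]),
        "leaves": PlantCompartment("leaves", W=0.84, K_PW=p["K_LW"], M0=14.0,
                                   Mmax=757.0, Kgr=0.13, tau=p["tau_L"],
                                   S_A=70.0),
        "fruits": PlantCompartment("fruits", W=0.83, K_PW=p["K_FW"],
                                   M0=FRUIT_ONSET_MASS, Mmax=720.0, Kgr=0.65,
                                   tau=p["tau_F"], S_A=50.0,
                                   onset=FRUIT_ONSET_DAY),
    }
    return Scenario(
        horizons=horizons,
        feddes=FeddesParams(),
        roots=RootDistribution(growth_rate=0.2),
        medium=TransportMedium(bulk_density=1.1, dispersivity=1.0),
        species=species,
        compartments=compartments,
    )


def scenario_from_vector(theta, names: tuple[str, ...] = FREE_PARAMETER_NAMES,
                         base: dict[str, float] | None = None) -> Scenario:
    """Build a scenario from a parameter vector over ``names``; parameters
    not in ``names`` are taken from ``base`` (default: medians)."""
    p = median_free_parameters()
    if base:
        p.update(base)
    for name, value in zip(names, theta, strict=True):
        p[name] = float(value)
    return default_scenario(p)
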