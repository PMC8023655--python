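"""Four-compartment dynamic plant uptake model.

Chemical taken up by the roots travels with the xylem transpiration stream
through the stem and is delivered to leaves and fruits in proportion to
their specific-area-weighted masses.  Each compartment grows logistically,
partitions chemical between tissue and water phase (K_PW), and transforms
CBZ into EPX with a first-order rate tau.  Phloem return flow is neglected,
so the cascade is strictly upward: roots -> stem -> {leaves, fruits}.

State is the molar amount A per compartment and species; concentrations are
reported per gram fresh weight.  The ODE system is linear with
time-varying coefficients and is integrated with a fixed-step RK4 kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import PlantCompartment, SoluteSpecies

__all__ = [
    "logistic_mass",
    "allocate_transpiration",
    "plant_rhs",
    "simulate_plant",
    "PlantState",
]

COMPARTMENT_ORDER = ("roots", "stem", "leaves", "fruits")


def logistic_mass(t, c: PlantCompartment):
    """Fresh mass M(t) [g_fw] of a compartment under logistic growth,
    M(t) = Mmax*M0*e^(Kgr t) / (Mmax + M0*(e^(Kgr t) - 1)); compartments
    with a growth onset (fruits) stay at zero mass before it."""
    t = np.asarray(t, dtype=float)
    tt = t - c.onset
    if c.M0 == 0.0:
        m = np.zeros_like(tt)
    else:
        # overflow-safe equivalent of Mmax*M0*e/(Mmax + M0*(e - 1))
        e = np.exp(-c.Kgr * np.maximum(tt, 0.0))
        m = np.where(tt < 0.0, 0.0,
                     c.Mmax / (1.0 + (c.Mmax / c.M0 - 1.0) * e))
    return m if m.ndim else float(m)


def allocate_transpiration(Q_total: float, t: float,
                           leaves: PlantCompartment,
                           fruits: PlantCompartment) -> tuple[float, float]:
    """Split the transpiration stream [cm^3 day^-1] between leaves and
    fruits in proportion to specific area times current mass."""
    if Q_total < 0.0:
        raise ValueError("Q_total must be nonnegative")
    w_l = leaves.S_A * logistic_mass(t, leaves)
    w_f = fruits.S_A * logistic_mass(t, fruits)
    tot = w_l + w_f
    if tot <= 0.0:
        if Q_total > 0.0:
            raise ValueError("no transpiring surface to allocate flow to")
        return 0.0, 0.0
    return Q_total * w_l / tot, Q_total * w_f / tot


def _compartment_arrays(compartments: dict[str, PlantCompartment]):
    order = [compartments[nm] for nm in COMPARTMENT_ORDER]
    kpw = np.array([c.K_PW for c in order])
    tau = np.array([c.tau for c in order])
    m0 = np.array([c.M0 for c in order])
    mmax = np.array([c.Mmax for c in order])
    kgr = np.array([c.Kgr for c in order])
    onset = np.array([c.onset for c in order])
    return kpw, tau, m0, mmax, kgr, onset


def plant_rhs(A: np.ndarray, t: float, uptake_rate: dict[str, float],
              Q_total: float, compartments: dict[str, PlantCompartment],
              species: tuple[SoluteSpecies, ...]) -> np.ndarray:
    """Time derivative of the amount matrix A[(species, compartment)] in
    mol day^-1 (species rows ordered CBZ, EPX; compartments ordered
    roots, stem, leaves, fruits).  Reference implementation of the
    cascade; the integrator uses the compiled equivalent."""
    A = np.asarray(A, dtype=float)
    if np.any(A < -1e-25):
        raise ValueError("negative compartment amounts")
    kpw, tau, m0, mmax, kgr, onset = _compartment_arrays(compartments)
    leaves = compartments["leaves"]
    fruits = compartments["fruits"]
    m = np.array([logistic_mass(t, compartments[nm])
                  for nm in COMPARTMENT_ORDER])
    q_l, q_f = allocate_transpiration(Q_total, t, leaves, fruits)
    ex_r = Q_total / (kpw[0] * m[0]) if m[0] > 0 else 0.0
    den_s = kpw[1] * m[1]
    ex_s = Q_total / den_s if den_s > 0 else 0.0
    in_l = q_l / den_s if den_s > 0 else 0.0
    in_f = q_f / den_s if den_s > 0 else 0.0

    dA = np.zeros_like(A)
    u = [uptake_rate.get(sp.name, 0.0) for sp in species]
    cbz, epx = 0, 1
    dA[cbz, 0] = u[cbz] - ex_r * A[cbz, 0] - tau[0] * A[cbz, 0]
    dA[cbz, 1] = ex_r * A[cbz, 0] - ex_s * A[cbz, 1] - tau[1] * A[cbz, 1]
    dA[cbz, 2] = in_l * A[cbz, 1] - tau[2] * A[cbz, 2]
    dA[cbz, 3] = in_f * A[cbz, 1] - tau[3] * A[cbz, 3]
    dA[epx, 0] = u[epx] - ex_r * A[epx, 0] + tau[0] * A[cbz, 0]
    dA[epx, 1] = ex_r * A[epx, 0] - ex_s * A[epx, 1] + tau[1] * A[cbz, 1]
    dA[epx, 2] = in_l * A[epx, 1] + tau[2] * A[cbz, 2]
    dA[epx, 3] = in_f * A[epx, 1] + tau[3] * A[cbz, 3]
    return dA


@dataclass
class PlantState:
    """Plant trajectory: amounts [mol] and derived tissue concentrations
    [ng g_fw^-1] per species and compartment on the output time grid."""

    t: np.ndarray
    amounts: dict[str, np.ndarray]        # species -> (nt, 4) mol
    concentrations: dict[str, np.ndarray]  # species -> (nt, 4) ng/g_fw
    masses: np.ndarray                     # (nt, 4) g_fw
    ledger: dict[str, float]

    def concentration(self, species_name: str,
                      compartment: str) -> np.ndarray:
        j = COMPARTMENT_ORDER.index(compartment)
        return self.concentrations[species_name][:, j]


def simulate_plant(uptake_t: np.ndarray,
                   uptake_rate: dict[str, np.ndarray],
                   Q_total: np.ndarray,
                   compartments: dict[str, PlantCompartment],
                   species: tuple[SoluteSpecies, ...],
                   t_out: np.ndarray,
                   dt: float = 0.02) -> PlantState:
    """Integrate the compartment cascade over ``t_out``.

    ``uptake_rate`` maps species name to the root uptake rate series
    [mol day^-1] on the (uniformly spaced) ``uptake_t`` grid; ``Q_total``
    is the transpiration stream [cm^3 day^-1] on the same grid.  Both are
    interpolated linearly inside the integrator.
    """
    uptake_t = np.asarray(uptake_t, dtype=float)
    t_out = np.asarray(t_out, dtype=float)
    if uptake_t[0] > t_out[0] or uptake_t[-1] < t_out[-1] - 1e-9:
        raise ValueError("input series do not cover the output span")
    steps = np.diff(uptake_t)
    if not np.allclose(steps, steps[0]):
        raise ValueError("input series must be uniformly spaced")
    kpw, tau, m0, mmax, kgr, onset = _compartment_arrays(compartments)
    sa_leaf = compartments["leaves"].S_A
    sa_fruit = compartments["fruits"].S_A

    u_cbz = np.ascontiguousarray(uptake_rate[species[0].name], dtype=float)
    u_epx = np.ascontiguousarray(uptake_rate[species[1].name], dtype=float)
    q = np.ascontiguousarray(Q_total, dtype=float)

    A = _kernels.plant_integrate(uptake_t[0], float(steps[0]),
                                 u_cbz, u_epx, q,
                                 kpw, tau, m0, mmax, kgr, onset,
                                 sa_leaf, sa_fruit, t_out, dt)
    if np.any(A < -1e-12 * max(1e-30, float(np.max(np.abs(A))))):
        raise RuntimeError("plant integration produced negative amounts")
    A = np.maximum(A, 0.0)

    masses = np.column_stack([logistic_mass(t_out, compartments[nm])
                              for nm in COMPARTMENT_ORDER])
    amounts = {species[0].name: A[:, :4], species[1].name: A[:, 4:]}
    concs = {}
    for sp in species:
        with np.errstate(divide="ignore", invalid="ignore"):
            c = amounts[sp.name] * sp.molar_mass * 1e9 \
                / np.where(masses > 0.0, masses, np.nan)
        concs[sp.name] = np.where(masses > 0.0, c, 0.0)

    # molar ledger: uptake in == stored, split by species, with CBZ->EPX
    # transformation internal (mole conserving)
    span = (uptake_t >= t_out[0] - 1e-12) & (uptake_t <= t_out[-1] + 1e-12)
    cum_in = {nm: float(np.trapezoid(uptake_rate[nm][span],
                                     uptake_t[span]))
              for nm in (species[0].name, species[1].name)}
    stored_total = float(A[-1].sum())
    total_in = sum(cum_in.values())
    ledger = {
        "uptake_in_mol": total_in,
        "stored_mol": stored_total,
        "balance_error_rel": (abs(total_in - stored_total)
                              / max(total_in, 1e-30)),
    }
    return PlantState(t=t_out, amounts=amounts, concentrations=concs,
                      masses=masses, ledger=ledger)
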