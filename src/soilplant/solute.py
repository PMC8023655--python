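"""Advection-dispersion-reaction transport of CBZ and EPX in the column.

The two solutes exist in liquid and solid phase; sorption follows a
Freundlich isotherm (EPX shares CBZ's sorption parameters), CBZ transforms
into EPX by first-order sequential decay in both phases, and dissolved
chemical is passively removed by roots at the water-uptake rate, capped at
the species' maximum uptake concentration Cmax.

Numerics: operator splitting per flow-output interval — implicit upwind
advection-dispersion with Picard iteration on the Freundlich retardation
term, then exact (Bateman) decay, then the uptake sink.  Concentrations are
carried in molar units (mol cm^-3 liquid, mol g^-1 sorbed); the Freundlich
isotherm itself is evaluated in the mass units it was measured in
(ug cm^-3, ug g^-1).  All amounts are per unit column cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .hydro import Forcing, SoilWaterState
from .params import SoluteSpecies, TransportMedium

__all__ = [
    "freundlich_sorbed",
    "freundlich_dissolved",
    "decay_chain_step",
    "root_solute_uptake",
    "solve_transport",
    "SoluteState",
]

_UG_PER_MOL = 1e6  # ug per g times g per mol handled via molar mass

#: Liquid concentration floor [ug cm^-3] below which the Freundlich slope
#: is frozen (the isotherm's derivative diverges at zero for beta < 1).
C_FLOOR_UG = 1e-9


def freundlich_sorbed(C, species: SoluteSpecies, unit_mode: str = "mass"):
    """Equilibrium sorbed concentration s = Kf * C^beta.

    ``unit_mode='mass'``: C in ug cm^-3, result in ug g^-1 (the units the
    isotherm was fitted in).  ``unit_mode='molar'``: C in mol cm^-3,
    result in mol g^-1.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0.0):
        raise ValueError("concentration must be nonnegative")
    if unit_mode == "mass":
        s = species.Kf * C ** species.beta
    elif unit_mode == "molar":
        c_ug = C * species.molar_mass * _UG_PER_MOL
        s = (species.Kf * c_ug ** species.beta
             / (species.molar_mass * _UG_PER_MOL))
    else:
        raise ValueError("unit_mode must be 'mass' or 'molar'")
    return s if s.ndim else float(s)


def freundlich_dissolved(s, species: SoluteSpecies, unit_mode: str = "mass"):
    """Inverse isotherm C(s) = (s / Kf)^(1/beta); units as in
    :func:`freundlich_sorbed`."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0.0):
        raise ValueError("sorbed concentration must be nonnegative")
    if unit_mode == "mass":
        c = (s / species.Kf) ** (1.0 / species.beta)
    elif unit_mode == "molar":
        s_ug = s * species.molar_mass * _UG_PER_MOL
        c = ((s_ug / species.Kf) ** (1.0 / species.beta)
             / (species.molar_mass * _UG_PER_MOL))
    else:
        raise ValueError("unit_mode must be 'mass' or 'molar'")
    return c if c.ndim else float(c)


def _freundlich_slope_molar(C_mol, species: SoluteSpecies) -> np.ndarray:
    """d s / d C [cm^3 g^-1] in molar units (equal to the mass-unit slope),
    with the concentration floored to keep the derivative finite."""
    c_ug = np.maximum(np.asarray(C_mol, dtype=float)
                      * species.molar_mass * _UG_PER_MOL, C_FLOOR_UG)
    return species.Kf * species.beta * c_ug ** (species.beta - 1.0)


def decay_chain_step(amounts: np.ndarray, rates: np.ndarray,
                     dt: float) -> np.ndarray:
    """Advance a sequential first-order decay chain exactly over ``dt``.

    ``amounts[i]`` is the molar amount of chain member i; member i
    transforms into member i+1 at rate ``rates[i]`` (the last member's rate
    is its terminal loss, zero for a stable end member).  Uses the exact
    exponential solution member by member, so sub-stepping is exactly
    consistent (semigroup property).
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    amounts = np.array(amounts, dtype=float)
    if np.any(amounts < 0.0):
        raise ValueError("amounts must be nonnegative")
    rates = np.asarray(rates, dtype=float)
    out = amounts.copy()
    transfer = np.zeros_like(out)
    for i, mu in enumerate(rates):
        if mu > 0.0:
            decayed = out[i] * (1.0 - np.exp(-mu * dt))
            out[i] -= decayed
            transfer[i] = decayed
    # route parent losses into the next chain member
    for i in range(len(rates) - 1):
        out[i + 1] += transfer[i]
    return out


def root_solute_uptake(C: np.ndarray, S: np.ndarray,
                       species: SoluteSpecies) -> np.ndarray:
    """Passive root uptake rate profile r_a(z) [mol cm^-3 day^-1]:
    water-uptake rate times dissolved concentration, capped at the
    species' maximum uptake concentration."""
    C = np.asarray(C, dtype=float)
    S = np.asarray(S, dtype=float)
    if C.shape != S.shape:
        raise ValueError("concentration and uptake profiles must share "
                         "the same grid")
    return S * np.minimum(C, species.cmax_molar)


@dataclass
class SoluteState:
    """Transport solution trajectories and molar bookkeeping.

    ``conc``/``sorbed`` map species name to (nt, nz) arrays of liquid
    [mol cm^-3] and sorbed [mol g^-1] concentration; ``uptake_rate`` to the
    (nt,) root uptake rate per unit area [mol cm^-2 day^-1].
    """

    t: np.ndarray
    z: np.ndarray
    conc: dict[str, np.ndarray]
    sorbed: dict[str, np.ndarray]
    uptake_rate: dict[str, np.ndarray]
    ledger: dict[str, dict[str, float]]

    def total_ng_per_g(self, species_name: str, theta: np.ndarray,
                       molar_mass: float, bulk_density: float) -> np.ndarray:
        """Whole-soil concentration [ng per g dry soil] combining liquid
        and sorbed phase: (theta*C + rho*s) * M / rho."""
        c = self.conc[species_name]
        s = self.sorbed[species_name]
        return ((theta * c + bulk_density * s) * molar_mass * 1e9
                / bulk_density)


def solve_transport(flow: SoilWaterState,
                    species: tuple[SoluteSpecies, ...],
                    medium: TransportMedium,
                    forcing: Forcing,
                    picard_tol: float = 1e-6,
                    max_picard: int = 40) -> SoluteState:
    """March the coupled species over the flow trajectory.

    Initial concentrations are zero (no solute in the soil before the
    experiment); the surface boundary is Cauchy-type (irrigation water
    carries the dosed concentration in, evaporation carries nothing out),
    the bottom a zero-concentration-gradient condition.  Raises
    ``RuntimeError`` on a non-convergent sorption iteration.
    """
    grid = flow.grid
    nz = grid.n_nodes
    nt = flow.t.size
    wcv = grid.w_cv
    dzf = grid.dz_face
    rho = medium.bulk_density
    lam = medium.dispersivity

    names = [sp.name for sp in species]
    conc = {nm: np.zeros((nt, nz)) for nm in names}
    sorb = {nm: np.zeros((nt, nz)) for nm in names}
    upt = {nm: np.zeros(nt) for nm in names}
    applied = dict.fromkeys(names, 0.0)
    uptaken = dict.fromkeys(names, 0.0)
    transformed = dict.fromkeys(names, 0.0)  # moles lost by transformation
    gained = dict.fromkeys(names, 0.0)       # moles gained from the parent
    bottom_out = dict.fromkeys(names, 0.0)

    C = {nm: np.zeros(nz) for nm in names}
    Ssorb = {nm: np.zeros(nz) for nm in names}

    ab = np.zeros((3, nz))

    for k in range(nt - 1):
        dt = flow.t[k + 1] - flow.t[k]
        th0 = flow.theta[k]
        th1 = flow.theta[k + 1]
        qf = 0.5 * (flow.q_face[k] + flow.q_face[k + 1])
        snk = 0.5 * (flow.sink[k] + flow.sink[k + 1])
        day = min(int(flow.t[k] + 1e-9), forcing.n_days - 1)
        irr = forcing.irrigation[day]

        # face conductances (interior faces 1..nz-1)
        qin = qf[1:nz]                      # flux at face below node i
        g = lam * np.abs(qin) / dzf         # theta*D/dz, theta cancels
        q_bot = qf[0]

        for sp in species:
            nm = sp.name
            c_old = C[nm]
            s_old = Ssorb[nm]
            c_in = forcing.concentration(nm)[day]

            mass_old = wcv * (th0 * c_old + rho * s_old)
            cp = c_old.copy()
            for _ in range(max_picard):
                cp = np.maximum(cp, 0.0)
                dsdc = _freundlich_slope_molar(cp, sp)
                s_lin = freundlich_sorbed(cp, sp, "molar") - dsdc * cp
                diag = wcv * (th1 + rho * dsdc) / dt
                rhs = mass_old / dt - wcv * rho * s_lin / dt

                sub = np.zeros(nz)
                sup = np.zeros(nz)
                # interior faces: -F_below, +F_above contributions
                sub[1:] += -np.maximum(qin, 0.0) - g
                diag[1:] += -np.minimum(qin, 0.0) + g
                diag[:-1] += np.maximum(qin, 0.0) + g
                sup[:-1] += np.minimum(qin, 0.0) - g
                # bottom face: zero-gradient, advective outflow only
                if q_bot < 0.0:
                    diag[0] += -q_bot
                # top face: imposed Cauchy influx
                rhs[-1] += irr * c_in

                ab[0, 1:] = sup[:-1]
                ab[1, :] = diag
                ab[2, :-1] = sub[1:]
                c_new = solve_banded((1, 1), ab, rhs)
                if np.max(np.abs(c_new - cp)) <= picard_tol * max(
                        1e-30, float(np.max(np.abs(c_new)))):
                    cp = c_new
                    break
                cp = c_new
            else:
                raise RuntimeError("Freundlich sorption iteration did not "
                                   f"converge at t = {flow.t[k]:.3f} d")
            c_new = np.maximum(cp, 0.0)
            s_new = freundlich_sorbed(c_new, sp, "molar")
            applied[nm] += irr * c_in * dt
            if q_bot < 0.0:
                bottom_out[nm] += -q_bot * float(c_new[0]) * dt
            C[nm] = c_new
            Ssorb[nm] = s_new

        # exact sequential decay in each phase, parent -> daughter
        for sp in species:
            if sp.daughter is None or (sp.mu_L == 0.0 and sp.mu_S == 0.0):
                continue
            nm, dn = sp.name, sp.daughter
            liq_loss = C[nm] * (1.0 - np.exp(-sp.mu_L * dt))
            sol_loss = Ssorb[nm] * (1.0 - np.exp(-sp.mu_S * dt))
            C[nm] = C[nm] - liq_loss
            Ssorb[nm] = Ssorb[nm] - sol_loss
            C[dn] = C[dn] + liq_loss
            Ssorb[dn] = Ssorb[dn] + sol_loss
            moles = float(np.sum(wcv * (th1 * liq_loss + rho * sol_loss)))
            transformed[nm] += moles
            gained[dn] += moles

        # capped passive root uptake from the liquid phase
        for sp in species:
            nm = sp.name
            r = root_solute_uptake(C[nm], snk, sp)
            dc = np.minimum(r * dt / np.maximum(th1, 1e-9), C[nm])
            C[nm] = C[nm] - dc
            taken = float(np.sum(wcv * th1 * dc))
            uptaken[nm] += taken
            upt[nm][k + 1] = taken / dt

        for nm in names:
            conc[nm][k + 1] = C[nm]
            sorb[nm][k + 1] = Ssorb[nm]

    ledger: dict[str, dict[str, float]] = {}
    for i, sp in enumerate(species):
        nm = sp.name
        th_end = flow.theta[-1]
        stored = float(np.sum(wcv * (th_end * C[nm] + rho * Ssorb[nm])))
        inflow = applied[nm] + gained[nm]
        outflow = uptaken[nm] + transformed[nm] + bottom_out[nm] + stored
        ref = max(inflow, 1e-30)
        ledger[nm] = {
            "applied": applied[nm],
            "stored": stored,
            "uptaken": uptaken[nm],
            "transformed_out": transformed[nm],
            "transformed_in": gained[nm],
            "bottom_outflow": bottom_out[nm],
            "balance_error_rel": abs(inflow - outflow) / ref,
        }
    return SoluteState(t=flow.t.copy(), z=grid.z.copy(), conc=conc,
                       sorbed=sorb, uptake_rate=upt, ledger=ledger)
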