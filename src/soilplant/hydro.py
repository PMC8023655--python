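"""Variably saturated water flow in the two-horizon soil column.

Public surface of the flow component: van Genuchten-Mualem retention and
conductivity, the Feddes root water stress function, the time-dependent
normalized root density profile, Beer-law partitioning of evapotranspiration
demand, and :func:`solve_richards`, which integrates the 1D Richards
equation with root water extraction, an atmospheric upper boundary and a
seepage-face lower boundary.

Conventions: the vertical coordinate z is in cm, negative downward, with the
surface at z = 0 and the column bottom at z = -20; fluxes are in cm day^-1,
positive upward (so infiltration is a negative surface flux).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .grid import Grid, make_grid
from .params import (CANOPY_EXTINCTION, FeddesParams, RootDistribution,
                     SoilHorizon)

__all__ = [
    "Forcing",
    "TimeStepControl",
    "SoilWaterState",
    "vgm_retention",
    "vgm_conductivity",
    "vgm_pressure_head",
    "feddes_stress",
    "root_density_profile",
    "partition_et",
    "solve_richards",
]


# ---------------------------------------------------------------------------
# Closed-form hydraulic functions
# ---------------------------------------------------------------------------

def vgm_retention(h, horizon: SoilHorizon):
    """Water content theta(h) [cm^3 cm^-3] from the unimodal van
    Genuchten-Mualem retention function; theta_s for h >= 0."""
    h = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("pressure head must be finite")
    m = horizon.m
    theta = np.where(
        h >= 0.0,
        horizon.theta_s,
        horizon.theta_r + (horizon.theta_s - horizon.theta_r)
        * (1.0 + (horizon.alpha * np.abs(np.minimum(h, 0.0))) ** horizon.n)
        ** (-m),
    )
    return theta if theta.ndim else float(theta)


def vgm_conductivity(h, horizon: SoilHorizon):
    """Unsaturated conductivity K(h) [cm day^-1], Mualem pore-connectivity
    exponent 0.5; Ks for h >= 0."""
    h = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("pressure head must be finite")
    m = horizon.m
    se = np.where(
        h >= 0.0, 1.0,
        (1.0 + (horizon.alpha * np.abs(np.minimum(h, 0.0))) ** horizon.n)
        ** (-m),
    )
    se = np.clip(se, 0.0, 1.0)
    with np.errstate(invalid="ignore"):
        k = horizon.Ks * np.sqrt(se) \
            * (1.0 - (1.0 - se ** (1.0 / m)) ** m) ** 2
    k = np.where(se <= 1e-14, 0.0, k)
    return k if k.ndim else float(k)


def vgm_pressure_head(theta, horizon: SoilHorizon):
    """Inverse retention: pressure head h(theta) [cm] for
    theta_r < theta <= theta_s."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= horizon.theta_r) or np.any(theta > horizon.theta_s):
        raise ValueError("theta outside (theta_r, theta_s]")
    se = (theta - horizon.theta_r) / (horizon.theta_s - horizon.theta_r)
    m = horizon.m
    with np.errstate(divide="ignore"):
        h = np.where(
            se >= 1.0, 0.0,
            -(se ** (-1.0 / m) - 1.0) ** (1.0 / horizon.n) / horizon.alpha,
        )
    return h if h.ndim else float(h)


def feddes_stress(h, Tp: float, p: FeddesParams):
    """Piecewise-linear root water stress factor in [0, 1].

    Zero above P0 (anoxia) and below P3 (wilting), one on the optimal
    plateau [P2(Tp), POpt], linear ramps elsewhere; the P2 threshold is
    interpolated between P2H and P2L by the potential transpiration rate.
    """
    h = np.asarray(h, dtype=float)
    if Tp >= p.r2H:
        p2 = p.P2H
    elif Tp <= p.r2L:
        p2 = p.P2L
    else:
        p2 = p.P2L + (p.P2H - p.P2L) * (Tp - p.r2L) / (p.r2H - p.r2L)
    a = np.zeros_like(h)
    ramp_hi = (h < p.P0) & (h > p.POpt)
    a[ramp_hi] = (p.P0 - h[ramp_hi]) / (p.P0 - p.POpt)
    a[(h <= p.POpt) & (h >= p2)] = 1.0
    ramp_lo = (h < p2) & (h > p.P3)
    a[ramp_lo] = (h[ramp_lo] - p.P3) / (p2 - p.P3)
    return a if a.ndim else float(a)


def root_density_profile(t: float, params: RootDistribution,
                         grid: Grid) -> np.ndarray:
    """Normalized root density b(z) [cm^-1] on the grid nodes at time t:
    integrates to one over the rooted depth, decreases linearly from the
    surface to the rooting front, whose depth grows logistically."""
    if grid.n_nodes == 0:
        raise ValueError("empty grid")
    b = np.empty(grid.n_nodes)
    _kernels.root_density_fill(float(t), grid.z, grid.w_cv,
                               params.growth_rate, params.depth0,
                               params.depth_max, b)
    return b


def partition_et(ET: float, LAI: float, k: float = CANOPY_EXTINCTION):
    """Split evapotranspiration demand into (Ep, Tp) [cm day^-1] with
    Beer-law canopy extinction: Tp = ET * (1 - exp(-k * LAI))."""
    if ET < 0.0 or LAI < 0.0:
        raise ValueError("ET and LAI must be nonnegative")
    tp = ET * (1.0 - np.exp(-k * LAI))
    return ET - tp, tp


# ---------------------------------------------------------------------------
# Forcing and solver state
# ---------------------------------------------------------------------------

@dataclass
class Forcing:
    """Daily forcing series (piecewise constant over each day).

    ``irrigation``, ``et`` in cm day^-1, ``lai`` dimensionless;
    ``conc`` maps species name to irrigation-water concentration
    [mol cm^-3] per day.  ``ep``/``tp`` are filled from the Beer-law
    partition unless given explicitly.
    """

    t: np.ndarray
    irrigation: np.ndarray
    et: np.ndarray
    lai: np.ndarray
    conc: dict[str, np.ndarray] = field(default_factory=dict)
    ep: np.ndarray | None = None
    tp: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("irrigation", "et", "lai"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            if np.any(arr < 0.0):
                raise ValueError(f"{name} must be nonnegative")
            setattr(self, name, arr)
        if self.ep is None or self.tp is None:
            ep = np.empty(n)
            tp = np.empty(n)
            for i in range(n):
                ep[i], tp[i] = partition_et(self.et[i], self.lai[i])
            self.ep, self.tp = ep, tp
        else:
            self.ep = np.asarray(self.ep, dtype=float)
            self.tp = np.asarray(self.tp, dtype=float)
            if not np.allclose(self.ep + self.tp, self.et, atol=1e-9):
                raise ValueError("Ep + Tp must equal ET demand")

    @property
    def n_days(self) -> int:
        return len(self.t)

    def concentration(self, species: str) -> np.ndarray:
        return self.conc.get(species,
                             np.zeros(self.n_days))


@dataclass(frozen=True)
class TimeStepControl:
    """Adaptive time-stepping and iteration controls for the Picard
    solver.  ``tol`` is the absolute convergence tolerance on h [cm];
    ``h_crit`` the evaporation-limiting surface pressure head."""

    dt_init: float = 1e-3
    dt_min: float = 1e-8
    dt_max: float = 0.2
    tol: float = 1e-4
    rel_tol: float = 1e-4
    max_iter: int = 20
    h_crit: float = -1e5
    dt_out: float = 0.1
    max_steps: int = 5_000_000


@dataclass
class SoilWaterState:
    """Trajectories of the flow solution on the output time grid."""

    grid: Grid
    t: np.ndarray            # (nt,) days
    h: np.ndarray            # (nt, nz) pressure head [cm]
    theta: np.ndarray        # (nt, nz) water content
    q_face: np.ndarray       # (nt, nz+1) fluxes, [ ,0] bottom, [ ,nz] top
    sink: np.ndarray         # (nt, nz) root uptake [day^-1]
    Ta: np.ndarray           # (nt,) actual transpiration [cm day^-1]
    ledger: dict[str, float]

    def interp_depth(self, field: np.ndarray, depth_cm: float) -> np.ndarray:
        """Series of a nodal field at a sensor depth [cm, positive down]."""
        z_target = -abs(depth_cm)
        return np.array([np.interp(z_target, self.grid.z, row)
                         for row in field])

    def theta_at(self, depth_cm: float) -> np.ndarray:
        return self.interp_depth(self.theta, depth_cm)

    def head_at(self, depth_cm: float) -> np.ndarray:
        return self.interp_depth(self.h, depth_cm)

    def column_average_theta(self) -> np.ndarray:
        w = self.grid.w_cv
        return self.theta @ w / w.sum()


def _hydraulic_tables(horizons: tuple[SoilHorizon, ...],
                      pf_min: float = -3.0, pf_max: float = 7.5,
                      nx: int = 800):
    """Per-horizon lookup tables of theta(h), dtheta/dh and K(h) on a
    uniform pF = log10(-h) grid, used by the compiled solver core.  The
    grid spans pF -3 (|h| = 1e-3 cm, effectively saturated) to pF 7.5
    (far beyond wilting); 800 points keep the interpolation error well
    below the solver's discretization error."""
    x = np.linspace(pf_min, pf_max, nx)
    h = -(10.0 ** x)
    nh = len(horizons)
    tab_th = np.empty((nh, nx))
    tab_cap = np.empty((nh, nx))
    tab_k = np.empty((nh, nx))
    for j, hor in enumerate(horizons):
        m = hor.m
        ah = hor.alpha * (-h)
        ahn = ah ** hor.n
        denom = 1.0 + ahn
        se = denom ** (-m)
        tab_th[j] = hor.theta_r + (hor.theta_s - hor.theta_r) * se
        tab_cap[j] = ((hor.theta_s - hor.theta_r) * hor.alpha * hor.n * m
                      * (ahn / ah) * (se / denom))
        tab_k[j] = vgm_conductivity(h, hor)
    return x[0], x[1] - x[0], tab_th, tab_cap, tab_k


def solve_richards(grid: Grid,
                   horizons: tuple[SoilHorizon, ...],
                   forcing: Forcing,
                   feddes: FeddesParams,
                   roots: RootDistribution,
                   init_theta: float | np.ndarray,
                   t_span: tuple[float, float] | None = None,
                   dt_control: TimeStepControl | None = None
                   ) -> SoilWaterState:
    """Integrate the Richards equation over ``t_span`` (default: the
    forcing span) and return the state trajectory.

    The initial condition is a water content (uniform scalar or per node)
    converted to pressure head through the inverse retention curve of each
    node's horizon.  Raises ``RuntimeError`` if the Picard iteration fails
    to converge even at the minimum time step.
    """
    ctl = dt_control or TimeStepControl()
    if t_span is None:
        t_span = (0.0, float(forcing.n_days))
    t0, t1 = t_span
    if t0 != 0.0:
        raise ValueError("simulations start at t = 0")

    nz = grid.n_nodes
    thr = np.empty(nz)
    ths = np.empty(nz)
    ks = np.empty(nz)
    for i, hidx in enumerate(grid.horizon_index):
        hor = horizons[hidx]
        thr[i], ths[i], ks[i] = hor.theta_r, hor.theta_s, hor.Ks

    init_theta = np.broadcast_to(np.asarray(init_theta, dtype=float),
                                 (nz,)).copy()
    if np.any(init_theta <= thr) or np.any(init_theta > ths):
        raise ValueError("initial theta outside physical bounds")
    h0 = np.empty(nz)
    for i in range(nz):
        hor = horizons[grid.horizon_index[i]]
        h0[i] = vgm_pressure_head(init_theta[i], hor)

    tab_x0, tab_dx, tab_th, tab_cap, tab_k = _hydraulic_tables(horizons)

    n_out = int(round((t1 - t0) / ctl.dt_out))
    t_out = np.linspace(t0, t1, n_out + 1)

    status, H, TH, QF, SNK, TA, ledger = _kernels.richards_integrate(
        grid.z, grid.dz_face, grid.w_cv, grid.horizon_index, ths, ks,
        tab_x0, tab_dx, tab_th, tab_cap, tab_k,
        h0,
        forcing.irrigation, forcing.ep, forcing.tp,
        feddes.P0, feddes.POpt, feddes.P2H, feddes.P2L, feddes.P3,
        feddes.r2H, feddes.r2L,
        roots.growth_rate, roots.depth0, roots.depth_max,
        t_out,
        ctl.dt_init, ctl.dt_min, ctl.dt_max, ctl.tol, ctl.rel_tol,
        ctl.max_iter, ctl.h_crit, float(ctl.max_steps),
    )
    if status == 1:
        raise RuntimeError(
            "Richards solver failed to converge after adaptive step "
            "reduction below dt_min")
    if status == 2:
        raise RuntimeError(
            "Richards solver exceeded its step budget "
            f"(max_steps = {ctl.max_steps})")
    led = {
        "infiltration": float(ledger[0]),
        "evaporation_actual": float(ledger[1]),
        "transpiration_actual": float(ledger[2]),
        "bottom_outflow": float(ledger[3]),
        "surface_excess": float(ledger[4]),
        "mass_balance_error_rel": float(ledger[5]),
        "evaporation_potential": float(ledger[6]),
        "transpiration_potential": float(ledger[7]),
        "n_steps": float(ledger[8]),
        "n_failed_attempts": float(ledger[9]),
    }
    return SoilWaterState(grid=grid, t=t_out, h=H, theta=TH, q_face=QF,
                          sink=SNK, Ta=TA, ledger=led)
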