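"""Vertical finite-element grid for the 20 cm soil column.

Node coordinates run from the column bottom (z = -20 cm) to the surface
(z = 0), refined geometrically toward the surface where atmospheric forcing
induces the steepest gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import COLUMN_HEIGHT_CM, SoilHorizon

__all__ = ["Grid", "make_grid"]


@dataclass(frozen=True)
class Grid:
    """Node depths ``z`` [cm] ascending from -H to 0, plus per-node horizon
    membership and control-volume widths."""

    z: np.ndarray          # (n_nodes,) ascending, z[0] = -H, z[-1] = 0
    horizon_index: np.ndarray  # (n_nodes,) index into the horizon tuple
    dz_face: np.ndarray    # (n_nodes-1,) spacing between adjacent nodes
    w_cv: np.ndarray       # (n_nodes,) control volume width per node

    @property
    def n_nodes(self) -> int:
        return self.z.size

    @property
    def n_elements(self) -> int:
        return self.z.size - 1


def _geometric_spacings(height: float, n_el: int, top_dz: float) -> np.ndarray:
    """Element widths (top to bottom) in geometric progression with the
    surface element equal to ``top_dz``."""

    def total(r: float) -> float:
        if abs(r - 1.0) < 1e-12:
            return top_dz * n_el - height
        return top_dz * (r ** n_el - 1.0) / (r - 1.0) - height

    r = brentq(total, 1.0 + 1e-10, 2.0)
    return top_dz * r ** np.arange(n_el)


def make_grid(horizons: tuple[SoilHorizon, ...], n_elements: int = 100,
              top_dz: float | None = None) -> Grid:
    """Build the top-refined column grid.

    The default 100-element grid uses a surface element of 0.05 cm; coarser
    grids scale the surface element so the refinement ratio stays moderate.
    Horizon membership is assigned by element midpoint and mapped to nodes
    (a node on the interface belongs to the upper horizon).
    """
    if n_elements < 4:
        raise ValueError("need at least 4 elements")
    height = horizons[0].z_top - horizons[-1].z_bot
    if abs(height - COLUMN_HEIGHT_CM) > 1e-9:
        height = float(height)
    if top_dz is None:
        top_dz = 0.05 * (100.0 / n_elements)
    widths = _geometric_spacings(height, n_elements, top_dz)  # top to bottom
    z = np.concatenate(([0.0], -np.cumsum(widths)))[::-1]  # ascending
    z[0] = -height
    hidx = np.empty(z.size, dtype=np.int64)
    for i, zi in enumerate(z):
        hidx[i] = _horizon_of(zi, horizons)
    dz_face = np.diff(z)
    w_cv = np.empty(z.size)
    w_cv[0] = dz_face[0] / 2.0
    w_cv[-1] = dz_face[-1] / 2.0
    w_cv[1:-1] = (dz_face[:-1] + dz_face[1:]) / 2.0
    return Grid(z=z, horizon_index=hidx, dz_face=dz_face, w_cv=w_cv)


def _horizon_of(z: float, horizons: tuple[SoilHorizon, ...]) -> int:
    for k, hor in enumerate(horizons):
        if hor.z_bot <= z <= hor.z_top:
            return k
    return len(horizons) - 1
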