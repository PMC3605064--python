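"""Steady-state VEGF concentration field.

VEGF is released by parenchymal cells at a PO2-dependent rate (basal under
normoxia, up to six-fold basal under anoxia), diffuses through the tissue
sheet, and is degraded with first-order kinetics. The steady concentration
satisfies the modified-Helmholtz balance D_G∇²C − K_G·C + M_G(PO2) = 0 with
no-flux tissue boundaries; it is solved by a sparse finite-difference
discretization on the tissue-point grid. Exchange with vessels is neglected.
Attainable concentrations therefore span M_G0/K_G (≈0.7 pM) to 6·M_G0/K_G
(≈4.2 pM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import eye as speye
from scipy.sparse.linalg import spsolve

from .params import VegfParameters
from .tissue import TissueDomain


def release_rate(P_O2, params: Optional[VegfParameters] = None):
    """VEGF release rate (pM/s) as a function of tissue PO2 (mmHg).

    Piecewise-linear hypoxic response: basal rate M_G0 for PO2 at or above
    the well-oxygenated level, rising linearly to the anoxic maximum
    (release_max_factor × basal) at PO2 = 0.
    """
    params = params or VegfParameters()
    P = np.maximum(np.asarray(P_O2, dtype=float), 0.0)
    excess = np.maximum(1.0 - P / params.release_po2_scale, 0.0)
    return params.M_G0 * (1.0 + (params.release_max_factor - 1.0) * excess)


@dataclass
class VegfState:
    concentration: np.ndarray          # pM per tissue point
    above_threshold: np.ndarray        # boolean mask per tissue point

    @property
    def fraction_above_threshold(self) -> float:
        return float(np.mean(self.above_threshold)) if self.above_threshold.size else 0.0


def solve_vegf(
    tissue_po2: np.ndarray,
    domain: TissueDomain,
    params: Optional[VegfParameters] = None,
) -> VegfState:
    """Solve D_G∇²C − K_G·C + M_G(PO2) = 0 with zero-flux boundaries.

    The 5-point Laplacian on the tissue lattice: link conductance D_G (the
    grid spacing cancels for a 2-D sheet when the equation is integrated
    over a cell), degradation K_G·h² per cell.
    """
    params = params or VegfParameters()
    if domain.n_points == 0:
        raise ValueError("tissue domain has no tissue points")
    if len(tissue_po2) != domain.n_points:
        raise ValueError("tissue_po2 length does not match the tissue grid")

    h_cm = domain.spacing * 1e-4
    Lap = domain.neumann_laplacian() * params.D_G        # cm²/s per link
    A = Lap + speye(domain.n_points) * (params.K_G * h_cm**2)
    b = release_rate(tissue_po2, params) * h_cm**2       # pM/s per cell
    C = spsolve(A.tocsc(), b)
    C = np.maximum(C, 0.0)
    return VegfState(C, C > params.C_th)


def local_concentration(state: VegfState, domain: TissueDomain, position) -> float:
    """Bilinearly interpolated concentration (pM) at an arbitrary position."""
    return domain.interpolate(state.concentration, np.asarray(position, dtype=float))
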