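"""Derived double-layer diagnostics.

Apparent surface charge, relative potential profiles, the integrated polymer
cation/anion partition ratio, and exponential decay-length fits of force
curves.  These are the quantities that expose the counterion-only character of
the polyampholyte double layer: near-complete co-ion exclusion shows up as an
enormous partition ratio and a σ_app(z) profile that stays linear across the
slit instead of dropping steeply at the surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .quadrature import win_cumtrapz, win_trapz
from .scf_solver import EquilibriumState

__all__ = ["PartitionRatio", "DecayFit", "apparent_surface_charge",
           "chain_partition_ratio", "potential_difference_profile",
           "decay_length_fit"]


@dataclass
class PartitionRatio:
    """Integrated polymer cation/anion ratio; ``infinite`` flags a zero denominator."""

    ratio: float
    cation_per_area: float
    anion_per_area: float
    infinite: bool = False


@dataclass
class DecayFit:
    """Exponential decay length from a log-linear fit, with diagnostics."""

    decay_length: float
    slope: float
    intercept: float
    r_squared: float
    h_window: tuple[float, float]


def apparent_surface_charge(state: EquilibriumState) -> np.ndarray:
    """σ_app(z) = σ + ∫₀^z ρ_c dz′: wall plus accumulated fluid charge (e/Å²).

    Equals σ at the wall and, for a converged symmetric state, 0 at the
    mid-plane.
    """
    sigma = state.bulk.params.sigma
    return sigma + win_cumtrapz(state.rho_c, state.grid)


def chain_partition_ratio(state: EquilibriumState) -> PartitionRatio:
    """Ratio of integrated polymer cation to polymer anion content in the slit.

    Chain-level densities (monomer density / r, exact for monodisperse linear
    chains) are integrated across the slit.  Note: for r > 1 this is a polymer
    ratio, not a monomer ratio.
    """
    cat = float(win_trapz(state.chain_density_plus, state.grid))
    an = float(win_trapz(state.chain_density_minus, state.grid))
    if an == 0.0:
        return PartitionRatio(ratio=np.inf, cation_per_area=cat,
                              anion_per_area=an, infinite=True)
    return PartitionRatio(ratio=cat / an, cation_per_area=cat, anion_per_area=an)


def potential_difference_profile(state: EquilibriumState) -> np.ndarray:
    """ψ(z) − ψ_s with ψ_s the value at the first accessible node (k_BT/e).

    Inside the charge-excluded zone z < d/2 the variation is trivially linear.
    """
    return state.psi - state.psi[state.grid.i_contact]


def decay_length_fit(h: np.ndarray, values: np.ndarray,
                     window: tuple[float, float] | None = None) -> DecayFit:
    """Least-squares decay length of ln|values| vs h over an h-window.

    All values inside the window must share one sign; a sign change means the
    curve is not a single exponential there and is rejected with the offending
    separations.
    """
    h = np.asarray(h, dtype=float)
    values = np.asarray(values, dtype=float)
    if window is None:
        window = (float(h[0]), float(h[-1]))
    sel = (h >= window[0]) & (h <= window[1])
    if sel.sum() < 3:
        raise ValueError("need at least 3 points inside the fit window")
    hw, vw = h[sel], values[sel]
    if np.any(vw == 0) or (np.sign(vw) != np.sign(vw[0])).any():
        bad = hw[np.sign(vw) != np.sign(vw[0])]
        raise ValueError(f"sign change inside the fit window at h = {bad}")
    fit = linregress(hw, np.log(np.abs(vw)))
    if fit.slope >= 0:
        raise ValueError("values do not decay over the fit window")
    return DecayFit(decay_length=-1.0 / fit.slope, slope=float(fit.slope),
                    intercept=float(fit.intercept),
                    r_squared=float(fit.rvalue**2),
                    h_window=(float(hw[0]), float(hw[-1])))
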