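"""Mean-field 1D electrostatics for the charged slit.

With planar symmetry the (x, y)-integrated Coulomb interaction between unit
charges at z and z′ is βϕ(z, z′) = −2π l_B |z − z′| per unit pair surface
density.  The reduced potential ψ(z) ≡ βeΨ(z) entering the Boltzmann weights
is the sum of a Donnan offset ψ_D, the (constant, inside the slit) wall term,
and the fluid convolution ∫ −2π l_B |z−z′| ρ_c(z′) dz′, evaluated in O(N) by
trapezoid prefix sums (exact for piecewise-linear ρ_c).  The discrete field
satisfies d²ψ/dz² = −4π l_B ρ_c in the interior.

Global electroneutrality ∫ρ_c dz + 2σ = 0 is enforced through ψ_D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Grid
from .quadrature import win_cumtrapz, win_trapz

__all__ = [
    "ChargeProfile",
    "PotentialField",
    "integrated_coulomb",
    "fluid_potential",
    "solve_potential",
    "electroneutrality_residual",
    "update_donnan",
]


@dataclass
class ChargeProfile:
    """Local fluid charge density ρ_c(z) (e/Å³) plus the wall charge σ (e/Å²)."""

    rho_c: np.ndarray
    sigma: float


@dataclass
class PotentialField:
    """Reduced potential ψ(z) = βeΨ(z) and its Donnan offset."""

    psi: np.ndarray
    psi_D: float


def integrated_coulomb(z: float, zp: float, Z_gamma: float = 1.0, Z_delta: float = 1.0,
                       l_B: float = 7.16) -> float:
    """Laterally integrated Coulomb kernel βϕ = −2π Z_γ Z_δ l_B |z − z′|."""
    return -2.0 * np.pi * Z_gamma * Z_delta * l_B * abs(z - zp)


def fluid_potential(rho_c: np.ndarray, grid: Grid, l_B: float) -> np.ndarray:
    """ψ_fluid(z) = ∫ (−2π l_B |z − z′|) ρ_c(z′) dz′ via prefix sums.

    ρ_c is taken as supported on the accessible window (it vanishes in the
    steric exclusion zones, jumping at the contact planes); the prefix sums
    are window-aware trapezoids, exact for ρ_c piecewise linear inside the
    window.  O(N).
    """
    z = grid.z
    if rho_c.shape != z.shape:
        raise ValueError("charge profile does not match the grid")
    m0 = win_cumtrapz(rho_c, grid)
    m1 = win_cumtrapz(rho_c * z, grid)
    m0_tot, m1_tot = m0[-1], m1[-1]
    # ∫|z−z′|ρ = z(2 M0(z) − M0T) − 2 M1(z) + M1T
    conv = z * (2.0 * m0 - m0_tot) - 2.0 * m1 + m1_tot
    return -2.0 * np.pi * l_B * conv


def solve_potential(charge: ChargeProfile, grid: Grid, psi_D: float,
                    l_B: float) -> PotentialField:
    """Total reduced potential: Donnan offset + wall terms + fluid convolution.

    Both walls carry σ; inside the slit their combined contribution is the
    constant −2π l_B σ h.
    """
    psi_wall = -2.0 * np.pi * l_B * charge.sigma * grid.h
    psi = psi_D + psi_wall + fluid_potential(charge.rho_c, grid, l_B)
    return PotentialField(psi=psi, psi_D=psi_D)


def electroneutrality_residual(charge: ChargeProfile, grid: Grid) -> float:
    """∫ρ_c dz + 2σ (e/Å²); zero for a globally neutral slit."""
    return float(win_trapz(charge.rho_c, grid) + 2.0 * charge.sigma)


def update_donnan(psi_D_old: float, residual: float, damping: float = 0.1,
                  susceptibility: float = 1.0) -> float:
    """Damped monotone corrector for the Donnan offset.

    A positive residual (net positive excess in the slit) is suppressed by
    raising ψ_D, since cations carry Boltzmann weight e^{−ψ}.  ``susceptibility``
    is an estimate of −∂residual/∂ψ_D (e/Å² per k_BT/e), e.g. κ²λ_D/(4π l_B)
    for a slit wider than the screening length; it makes the step
    dimensionless.  The fixed point is residual = 0, and the step is linear in
    the damping factor.
    """
    if not 0.0 < damping <= 1.0:
        raise ValueError("damping must be in (0, 1]")
    if susceptibility <= 0:
        raise ValueError("susceptibility must be positive")
    return psi_D_old + damping * residual / susceptibility
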