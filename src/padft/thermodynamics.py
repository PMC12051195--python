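"""Grand potential, interaction free energy, net pressure and Derjaguin transform.

The equilibrium grand potential per area of a converged slit state is
evaluated from the functional using the stationarity identity for the ideal
chain term (ln N = μ′ − V_b − Σ_i u_i), which leaves

    βΩ/A = −(Γ₊ + Γ₋) + ∫[f_ex(n) − λ_ex(n) n] dz − ½∫ψ_fl ρ_c dz
           − ψ_D Q_f − 2π l_B σ² h,

with Γ_s the chains per area, ψ_fl the fluid part of the potential, Q_f the
integrated fluid charge and the last term the (x,y)-integrated wall–wall
Coulomb energy.  All h-independent additive constants cancel in the net
interaction free energy

    g_s(h) = Ω_eq/A + p_b h,     Δg_s(h) = g_s(h) − g_s(h_ref),

whose far limit vanishes; the crossed-cylinder force follows from the
Derjaguin approximation F/R = 2π Δg_s, and the net pressure either as the
discrete derivative p_net = −∂Δg_s/∂h or from the monomer contact values:

    βp_net = n(d/2) + βp_ex(n(d/2)) − 2π l_B σ² − βp_b,

where βp_ex(n) = (n/r)[Z_r(η) − 1] is the local excess pressure of the GFD
fluid at the contact density.  The excess term is required for consistency
with the free-energy derivative under a local-density excess functional (the
soft-wall limit picks up ∫ n dλ_ex across the wall region); both routes agree
at convergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from . import gfd_eos
from .electrostatics import fluid_potential
from .model import Grid, SystemParams
from .quadrature import win_trapz
from .scf_solver import BulkState, EquilibriumState

__all__ = ["ForceCurve", "grand_potential_per_area", "interaction_free_energy",
           "net_pressure_contact", "net_pressure", "kt_per_A2_to_mJ_per_m2",
           "kt_per_A3_to_bar"]

_KB = 1.380649e-23


def kt_per_A2_to_mJ_per_m2(value: float, T: float = 298.0) -> float:
    """Convert a free energy per area from k_BT/Å² to mJ/m²."""
    return value * _KB * T / 1e-20 * 1e3


def kt_per_A3_to_bar(value: float, T: float = 298.0) -> float:
    """Convert a pressure from k_BT/Å³ to bar."""
    return value * _KB * T / 1e-30 / 1e5


@dataclass
class ForceCurve:
    """Interaction free energy and pressures over a separation scan.

    All arrays are aligned with ``h``; Δg_s is referenced to the largest
    separation in the scan, so Δg_s(h_max) = 0 by construction and
    F/R = 2π Δg_s pointwise.
    """

    h: np.ndarray
    g_s: np.ndarray             # k_BT/Å²
    dg_s: np.ndarray            # k_BT/Å²
    p_net: np.ndarray           # derivative route, k_BT/Å³
    p_net_contact: np.ndarray   # contact-value route, k_BT/Å³
    T: float = 298.0

    @property
    def F_over_R(self) -> np.ndarray:
        """Derjaguin crossed-cylinder force per radius, mN/m."""
        return 2.0 * np.pi * kt_per_A2_to_mJ_per_m2(self.dg_s, self.T)

    @property
    def dg_s_mJ_per_m2(self) -> np.ndarray:
        return kt_per_A2_to_mJ_per_m2(self.dg_s, self.T)

    @property
    def p_net_bar(self) -> np.ndarray:
        return kt_per_A3_to_bar(self.p_net, self.T)


def grand_potential_per_area(state: EquilibriumState, bulk: BulkState,
                             params: SystemParams | None = None,
                             grid: Grid | None = None) -> float:
    """Equilibrium grand potential per area, k_BT/Å².

    Only defined for converged states: the evaluation uses the stationarity
    of the density profiles, so an unconverged state is rejected.
    """
    if not state.converged:
        raise ValueError("grand potential requires a converged state")
    params = params or bulk.params
    grid = grid or state.grid
    arch = params.cation_arch
    z = grid.z

    n_tot = state.n_tot
    rho_c = state.rho_c
    gamma = float(win_trapz(state.n_plus + state.n_minus, grid)) / arch.r
    f_ex = np.asarray(gfd_eos.excess_free_energy_density(n_tot, arch.r, arch.d, arch.b))
    lam = np.asarray(gfd_eos.excess_field(n_tot, arch.r, arch.d, arch.b))
    psi_fl = fluid_potential(rho_c, grid, params.l_B)
    q_f = float(win_trapz(rho_c, grid))

    omega = (
        -gamma
        + float(win_trapz(f_ex - lam * n_tot, grid))
        - 0.5 * float(win_trapz(psi_fl * rho_c, grid))
        - state.psi_D * q_f
        - 2.0 * np.pi * params.l_B * params.sigma**2 * grid.h
    )
    return float(omega)


def net_pressure_contact(state: EquilibriumState, bulk: BulkState) -> float:
    """Net pressure from the monomer contact value at the wall, k_BT/Å³."""
    arch = bulk.params.cation_arch
    n_c = float(state.n_tot[state.grid.i_contact])
    eta_c = float(gfd_eos.packing_fraction(n_c, arch.d))
    z_r = float(gfd_eos.gfd_compressibility(min(eta_c, 0.9999), arch.r, arch.d, arch.b))
    p_ex = (n_c / arch.r) * (z_r - 1.0)
    maxwell = 2.0 * np.pi * bulk.params.l_B * bulk.params.sigma**2
    return n_c + p_ex - maxwell - bulk.p_b


def interaction_free_energy(states: list[EquilibriumState], bulk: BulkState,
                            allow_short_reference: bool = False) -> ForceCurve:
    """Force curve from a scan of converged states (ascending, distinct h).

    The largest separation serves as the Δg_s reference; unless
    ``allow_short_reference`` it must exceed 40 λ_D (or 300 Å, whichever is
    smaller) so the residual tail is negligible.
    """
    h = np.array([s.grid.h for s in states], dtype=float)
    if len(h) < 2:
        raise ValueError("a scan needs at least two separations")
    if np.any(np.diff(h) <= 0):
        raise ValueError("separations must be strictly increasing without duplicates")
    h_far = min(40.0 * bulk.lambda_D, 300.0)
    if not allow_short_reference and h[-1] < h_far:
        raise ValueError(
            f"reference separation {h[-1]:.0f} Å is too small; need ≥ {h_far:.0f} Å "
            "or pass allow_short_reference=True")

    omega = np.array([grand_potential_per_area(s, bulk) for s in states])
    g_s = omega + bulk.p_b * h
    dg_s = g_s - g_s[-1]
    p_deriv = -np.gradient(dg_s, h) if len(h) >= 3 else np.full_like(h, np.nan)
    p_contact = np.array([net_pressure_contact(s, bulk) for s in states])
    return ForceCurve(h=h, g_s=g_s, dg_s=dg_s, p_net=p_deriv,
                      p_net_contact=p_contact, T=bulk.params.T)


def net_pressure(states: list[EquilibriumState], bulk: BulkState,
                 method: str = "contact") -> np.ndarray:
    """Net pressure over a scan by the requested route, k_BT/Å³."""
    if method == "contact":
        return np.array([net_pressure_contact(s, bulk) for s in states])
    if method == "derivative":
        if len(states) < 3:
            raise ValueError("the derivative route needs at least 3 separations")
        curve = interaction_free_energy(states, bulk, allow_short_reference=True)
        return curve.p_net
    raise ValueError(f"unknown method {method!r}; use 'contact' or 'derivative'")
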