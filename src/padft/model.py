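"""Polyampholyte salt model definitions: chain architecture, system parameters, grid.

The model is a symmetric monovalent polyampholyte salt: an equimolar mixture of
cationic and anionic linear chains of ``r`` tangent charged hard spheres with
alternating valencies ±1, both chain ends carrying the same sign, so each chain
has net charge ±1e.  ``r`` must be odd — an even alternating chain would be net
neutral.  The solvent is implicit (dielectric continuum), the confining geometry
a planar slit of width ``h`` with identical surface charge density ``sigma`` on
both walls.

Units throughout the package: lengths in Å, energies in k_BT, charges in e,
number densities in Å⁻³.  Molar concentrations are converted at this interface
layer only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AVOGADRO_PER_M_TO_A3",
    "KT_JOULE_298",
    "ChainArchitecture",
    "SystemParams",
    "Grid",
    "build_linear_alternating",
    "bjerrum_length",
    "concentration_to_density",
]

# e^2/(4 pi eps0 kB) in Å·K  (CODATA constants)
_E2_OVER_4PI_EPS0_KB_AK = 1.671009e5
#: mol/L → Å⁻³
AVOGADRO_PER_M_TO_A3 = 6.02214076e-4
#: k_B·T in joule at 298 K, used for mJ/m² and bar output views
KT_JOULE_298 = 1.380649e-23 * 298.0


def bjerrum_length(epsilon_r: float, T: float) -> float:
    """Bjerrum length l_B = e²/(4πε₀ε_r k_B T) in Å.

    For water at 298 K (ε_r = 78.3) this is ≈ 7.16 Å.
    """
    if epsilon_r <= 0 or T <= 0:
        raise ValueError("epsilon_r and T must be positive")
    return _E2_OVER_4PI_EPS0_KB_AK / (epsilon_r * T)


def concentration_to_density(c_molar: float) -> float:
    """Convert a molar concentration to a number density in Å⁻³."""
    if c_molar < 0:
        raise ValueError("concentration must be non-negative")
    return c_molar * AVOGADRO_PER_M_TO_A3


@dataclass(frozen=True)
class ChainArchitecture:
    """One polyampholyte species: charge sequence, bond length and diameter.

    Attributes
    ----------
    r : int
        Number of charged monomers; odd.
    charges : tuple[int, ...]
        Valencies ±1 along the chain, alternating, ends equal.
    b : float
        Fixed bond length between connected monomers (Å).
    d : float
        Hard-sphere monomer diameter (Å), 0 < d ≤ b.
    """

    r: int
    charges: tuple[int, ...]
    b: float
    d: float

    def __post_init__(self) -> None:
        if self.r < 1 or self.r % 2 == 0:
            raise ValueError(
                "r must be an odd integer >= 1: an even alternating chain is net "
                "neutral and carries no Donnan response"
            )
        if len(self.charges) != self.r:
            raise ValueError("charge sequence length must equal r")
        if any(abs(z) != 1 for z in self.charges):
            raise ValueError("all monomer valencies must be ±1")
        for i in range(1, self.r):
            if self.charges[i] != -self.charges[i - 1]:
                raise ValueError("charges must alternate in sign along the chain")
        if not (0.0 < self.d <= self.b):
            raise ValueError(
                "need 0 < d <= b: overlapping bonded hard spheres are not modeled"
            )

    @property
    def net_charge(self) -> int:
        return int(sum(self.charges))

    def mirrored(self) -> "ChainArchitecture":
        """The oppositely charged species (global sign flip)."""
        return ChainArchitecture(
            self.r, tuple(-z for z in self.charges), self.b, self.d
        )


def build_linear_alternating(
    r: int, net_sign: int, b: float = 4.0, d: float = 4.0
) -> ChainArchitecture:
    """Build a linear alternating ±1 chain with both ends of sign ``net_sign``.

    A cation (net_sign=+1) carries (r+1)/2 positive and (r−1)/2 negative
    monomers; the anion is the sign mirror.
    """
    if net_sign not in (+1, -1):
        raise ValueError("net_sign must be +1 or -1")
    if r < 1 or r % 2 == 0:
        raise ValueError(
            "r must be odd: with alternating charges an even r gives a net-neutral "
            "polymer, not a polyampholyte ion"
        )
    charges = tuple(net_sign * (-1) ** i for i in range(r))
    return ChainArchitecture(r=r, charges=charges, b=float(b), d=float(d))


@dataclass(frozen=True)
class SystemParams:
    """Thermodynamic state and wall parameters for one calculation.

    ``c_salt`` is the bulk polyampholyte *salt* concentration in M: the chain
    concentration of each species (equimolar cations and anions), not the
    monomer concentration.
    """

    cation_arch: ChainArchitecture
    c_salt: float
    sigma: float = -1.0 / 70.0
    epsilon_r: float = 78.3
    T: float = 298.0
    anion_arch: ChainArchitecture = field(init=False)

    def __post_init__(self) -> None:
        if self.c_salt < 0:
            raise ValueError("c_salt must be non-negative")
        if self.cation_arch.net_charge != +1:
            raise ValueError("cation_arch must have net charge +1")
        object.__setattr__(self, "anion_arch", self.cation_arch.mirrored())

    @property
    def l_B(self) -> float:
        return bjerrum_length(self.epsilon_r, self.T)

    @property
    def n_chain_bulk(self) -> float:
        """Bulk chain number density of each species (Å⁻³)."""
        return concentration_to_density(self.c_salt)

    @property
    def n_monomer_bulk(self) -> float:
        """Bulk total monomer number density, both species (Å⁻³)."""
        return 2.0 * self.cation_arch.r * self.n_chain_bulk


def _is_multiple(x: float, dz: float, rtol: float = 1e-6) -> bool:
    k = round(x / dz)
    return k > 0 and abs(x - k * dz) <= rtol * max(x, dz)


@dataclass(frozen=True)
class Grid:
    """Uniform 1D grid on [0, h] with hard walls at z = 0 and z = h.

    Monomer centers are sterically excluded outside the accessible window
    [d/2, h − d/2]; densities are identically zero there.  ``dz`` must divide
    b, d and d/2 (to one part in 10⁶) so bond-kernel supports and the contact
    plane fall exactly on nodes.
    """

    h: float
    dz: float
    d: float
    b: float

    def __post_init__(self) -> None:
        if self.h <= self.d:
            raise ValueError("slit width h must exceed the monomer diameter d")
        if self.dz <= 0:
            raise ValueError("dz must be positive")
        for name, x in (("h", self.h), ("b", self.b), ("d", self.d), ("d/2", self.d / 2)):
            if not _is_multiple(x, self.dz):
                raise ValueError(
                    f"dz = {self.dz} must divide {name} = {x} to 1e-6 so kernel "
                    "supports and the contact plane align with grid nodes"
                )
        if self.b < self.dz:
            raise ValueError("bond length b must be at least one grid step")

    @property
    def n_nodes(self) -> int:
        return round(self.h / self.dz) + 1

    @property
    def z(self) -> np.ndarray:
        return np.linspace(0.0, self.h, self.n_nodes)

    @property
    def i_contact(self) -> int:
        """Index of the first accessible node, z = d/2."""
        return round(self.d / 2 / self.dz)

    @property
    def accessible(self) -> np.ndarray:
        """Boolean mask of nodes inside [d/2, h − d/2]."""
        i0 = self.i_contact
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[i0 : self.n_nodes - i0] = True
        return mask

    @property
    def n_bond(self) -> int:
        """Bond length in grid steps."""
        return round(self.b / self.dz)
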