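"""Generalized Flory-dimer (GFD) excluded-volume equation of state.

Hard-sphere-chain thermodynamics enter the functional through a local
excess free-energy density evaluated at the *total* monomer density
n(z) = n₊(z) + n₋(z).  The GFD construction interpolates between the
Carnahan–Starling monomer fluid and the Tildesley–Streett tangent-dimer
fluid using ratios of the volumes an r-mer excludes to a test monomer:
end monomers exclude less volume than free monomers, and interior
monomers less still.  The exclusion volumes are computed geometrically
from sphere-union volumes; the trimer 1–3 overlap lens is averaged over
flexible bond-angle configurations subject to the 1–3 hard-core
constraint, which is what distinguishes interior from end units.

Both reference EOS have the Percus-Yevick-like cubic form
Z(η) = (1 + aη + bη² + cη³)/(1−η)³, so the excess free energy per chain
∫₀^η [Z(η′) − 1]/η′ dη′ is available in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import quad

__all__ = [
    "GfdModel",
    "packing_fraction",
    "hs_compressibility",
    "dimer_compressibility",
    "gfd_compressibility",
    "excess_free_energy_density",
    "excess_field",
]

# Carnahan-Starling: Z = (1 + η + η² − η³)/(1−η)³
_CS = (1.0, 1.0, -1.0)
# Tildesley-Streett tangent hard dumbbell (L* = 1)
_TS = (2.45696, 4.10386, -3.75503)


def packing_fraction(n_tot: float | np.ndarray, d: float):
    """η = (π/6) d³ n_tot for total monomer density n_tot."""
    n_tot = np.asarray(n_tot, dtype=float)
    if np.any(n_tot < 0):
        raise ValueError("monomer density must be non-negative")
    return (np.pi / 6.0) * d**3 * n_tot


def _check_eta(eta) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < 0):
        raise ValueError("packing fraction must be non-negative")
    if np.any(eta >= 1):
        raise ValueError("packing fraction must be < 1 (hard spheres overlap-free)")
    return eta


def _z_cubic(eta: np.ndarray, coef: tuple[float, float, float]) -> np.ndarray:
    a, b, c = coef
    return (1.0 + a * eta + b * eta**2 + c * eta**3) / (1.0 - eta) ** 3


def _int_zm1_over_eta(eta: np.ndarray, coef: tuple[float, float, float]) -> np.ndarray:
    """∫₀^η [Z(η′) − 1]/η′ dη′ for the cubic-over-(1−η)³ EOS form, closed form."""
    a, b, c = coef
    A, B, C = a + 3.0, b - 3.0, c + 1.0
    u = 1.0 - eta
    return (
        (A + B + C) * 0.5 * (1.0 / u**2 - 1.0)
        - (B + 2.0 * C) * (1.0 / u - 1.0)
        - C * np.log(u)
    )


def _lens_volume(R: float, L: float) -> float:
    """Overlap volume of two spheres of radius R with centers L apart."""
    if L >= 2.0 * R:
        return 0.0
    return (np.pi / 12.0) * (4.0 * R + L) * (2.0 * R - L) ** 2


@lru_cache(maxsize=64)
def _exclusion_volumes(d: float, b: float) -> tuple[float, float, float]:
    """Volumes excluded to a test monomer by a monomer, dimer and flexible trimer.

    The excluded-volume sphere around each monomer has radius d.  Bonded
    neighbours sit at distance b; for the trimer the 1–3 separation
    L = b√(2+2t) (t = cos of the bond-bond angle, uniform on [−1, 1]) is
    averaged over configurations allowed by the 1–3 hard core L ≥ d.
    """
    v1 = (4.0 * np.pi / 3.0) * d**3
    lens12 = _lens_volume(d, b)
    v2 = 2.0 * v1 - lens12

    t_min = max(-1.0, d * d / (2.0 * b * b) - 1.0)
    if t_min >= 1.0:
        mean_lens13 = 0.0
    else:
        val, _ = quad(
            lambda t: _lens_volume(d, b * np.sqrt(2.0 + 2.0 * t)), t_min, 1.0
        )
        mean_lens13 = val / (1.0 - t_min)
    v3 = 3.0 * v1 - 2.0 * lens12 - mean_lens13
    return v1, v2, v3


@dataclass(frozen=True)
class GfdModel:
    """GFD chain EOS for r-mers of diameter d and bond length b.

    Reduces exactly to the Carnahan–Starling fluid at r = 1 and to the
    Tildesley–Streett dimer EOS at r = 2.
    """

    r: int
    d: float
    b: float | None = None

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("chain length r must be >= 1")
        if self.d <= 0:
            raise ValueError("monomer diameter must be positive")
        if self.b is None:
            object.__setattr__(self, "b", self.d)  # tangent spheres by default

    @property
    def weight(self) -> float:
        """Interpolation weight w_r = (v_e(r) − v_e(2))/(v_e(2) − v_e(1))."""
        if self.r == 1:
            return -1.0
        v1, v2, v3 = _exclusion_volumes(self.d, self.b)
        v_r = v2 + (self.r - 2) * (v3 - v2)
        return (v_r - v2) / (v2 - v1)

    def compressibility(self, eta) -> np.ndarray:
        """Z_r(η) = Z₂(η) + w_r (Z₂(η) − Z₁(η))."""
        eta = _check_eta(eta)
        w = self.weight
        return _z_cubic(eta, _TS) + w * (_z_cubic(eta, _TS) - _z_cubic(eta, _CS))

    def excess_per_chain(self, eta) -> np.ndarray:
        """βa_ex(η) = ∫₀^η [Z_r − 1]/η′ dη′, excess free energy per chain."""
        eta = _check_eta(eta)
        w = self.weight
        return (1.0 + w) * _int_zm1_over_eta(eta, _TS) - w * _int_zm1_over_eta(
            eta, _CS
        )


def hs_compressibility(eta) -> np.ndarray:
    """Carnahan–Starling compressibility factor (1 + η + η² − η³)/(1−η)³."""
    return _z_cubic(_check_eta(eta), _CS)


def dimer_compressibility(eta) -> np.ndarray:
    """Tildesley–Streett tangent hard-dumbbell compressibility factor."""
    return _z_cubic(_check_eta(eta), _TS)


def gfd_compressibility(eta, r: int, d: float = 1.0, b: float | None = None):
    """GFD compressibility factor Z_r(η) for r-mers (per chain)."""
    return GfdModel(r=r, d=d, b=b).compressibility(eta)


def excess_free_energy_density(n_tot, r: int, d: float, b: float | None = None):
    """βf_ex per volume: (n/r) ∫₀^η [Z_r(η′) − 1]/η′ dη′, zero at zero density."""
    n_tot = np.asarray(n_tot, dtype=float)
    eta = packing_fraction(n_tot, d)
    model = GfdModel(r=r, d=d, b=b)
    return (n_tot / r) * model.excess_per_chain(eta)


def excess_field(n_tot, r: int, d: float, b: float | None = None):
    """λ_ex = ∂(βf_ex)/∂n_tot, the local excess field per monomer (k_BT).

    Analytic: λ_ex = [βa_ex(η) + Z_r(η) − 1]/r, which makes the consistency
    identity n ∂f/∂n − f = (n/r)(Z_r − 1) hold exactly.
    """
    n_tot = np.asarray(n_tot, dtype=float)
    eta = packing_fraction(n_tot, d)
    model = GfdModel(r=r, d=d, b=b)
    return (model.excess_per_chain(eta) + model.compressibility(eta) - 1.0) / r
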